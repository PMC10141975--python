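"""Reference endpoint classifiers.

Real deployments plug a trained network into the
:data:`~ellipick.pipeline.EndpointClassifier` contract; these lightweight
implementations close the loop without one.  The brightness-cue classifier
reads the bright blossom/flower cue the synthetic generator plants near the
head endpoint; the constant classifier exercises the same-class conflict
rule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pipeline import HEAD, ROOT

__all__ = ["BrightnessCueClassifier", "ConstantClassifier"]


@dataclass(frozen=True)
class BrightnessCueClassifier:
    """Labels a patch ``head`` when it contains saturated-bright pixels.

    Flowers frequently remain attached near the fruit's blossom end, so a
    local brightness cue is a plausible (if simplistic) discriminator; it is
    exactly the cue the synthetic generator plants.  Confidence grows with
    the bright-pixel fraction and is clipped to [0, 1].
    """

    threshold: int = 230
    base_confidence: float = 0.9

    def __call__(self, patch: np.ndarray) -> tuple[str, float]:
        luminance = patch.max(axis=2) if patch.ndim == 3 else patch
        frac = float((luminance >= self.threshold).mean())
        if frac > 0.0:
            return HEAD, float(np.clip(0.5 + 10.0 * frac, 0.5, 1.0))
        return ROOT, self.base_confidence


@dataclass(frozen=True)
class ConstantClassifier:
    """Always predicts ``label``; confidence is fixed or patch-derived.

    With ``confidence=None`` the confidence is the patch's mean intensity
    divided by 255, which makes two patches generally disagree and lets
    tests drive the higher-confidence-wins conflict rule deterministically.
    """

    label: str = HEAD
    confidence: float | None = None

    def __post_init__(self) -> None:
        if self.label not in (HEAD, ROOT):
            raise ValueError(f"label must be 'head' or 'root', got {self.label!r}")

    def __call__(self, patch: np.ndarray) -> tuple[str, float]:
        if self.confidence is not None:
            return self.label, self.confidence
        return self.label, float(np.mean(patch)) / 255.0
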