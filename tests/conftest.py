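"""Shared fixtures and geometry helpers for the test suite."""

from __future__ import annotations

import math

import numpy as np
import pytest

from ellipick.ellipse import EllipseParams


def sample_ellipse_points(
    e: EllipseParams, n: int, noise_sigma: float = 0.0, rng: np.random.Generator | None = None
) -> np.ndarray:
    """``n`` points on (or near) the ellipse boundary as an (n, 2) array."""
    t = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    ct, st = math.cos(e.theta), math.sin(e.theta)
    x = e.cx + e.a * np.cos(t) * ct - e.b * np.sin(t) * st
    y = e.cy + e.a * np.cos(t) * st + e.b * np.sin(t) * ct
    pts = np.column_stack([x, y])
    if noise_sigma > 0.0:
        assert rng is not None
        pts = pts + rng.normal(0.0, noise_sigma, pts.shape)
    return pts


def random_ellipse(rng: np.random.Generator, max_center: float = 200.0) -> EllipseParams:
    """A random well-formed ellipse with distinct axes."""
    a = rng.uniform(10.0, 80.0)
    b = a / rng.uniform(1.2, 3.0)
    return EllipseParams(
        cx=float(rng.uniform(-max_center, max_center)),
        cy=float(rng.uniform(-max_center, max_center)),
        a=float(a),
        b=float(b),
        theta=float(rng.uniform(0.0, math.pi)),
    )


def angle_close(t1: float, t2: float, tol: float) -> bool:
    """Compare axis angles modulo pi."""
    d = abs(t1 - t2) % math.pi
    return min(d, math.pi - d) <= tol


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
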