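"""Shared fixtures and geometric helpers."""

import math

import numpy as np
import pytest

from alveomorph.geometry import AlveolusTrace, PolygonTrace


def regular_polygon(n: int, radius: float = 1.0, center=(0.0, 0.0)) -> np.ndarray:
    theta = np.linspace(0.0, 2.0 * math.pi, n, endpoint=False)
    cx, cy = center
    return np.column_stack(
        (cx + radius * np.cos(theta), cy + radius * np.sin(theta))
    )


def circle_trace(radius: float = 1.0, n: int = 2000, center=(0.0, 0.0), **kw):
    return PolygonTrace(regular_polygon(n, radius, center), **kw)


def square_trace(side: float = 1.0, center=(0.0, 0.0)) -> PolygonTrace:
    h = side / 2.0
    cx, cy = center
    verts = np.array(
        [[cx - h, cy - h], [cx + h, cy - h], [cx + h, cy + h], [cx - h, cy + h]]
    )
    return PolygonTrace(verts)


def concentric_circle_alveolus(
    r_inner: float, r_outer: float, n: int = 2000, center=(0.0, 0.0), **kw
) -> AlveolusTrace:
    return AlveolusTrace(
        inner=circle_trace(r_inner, n, center),
        outer=circle_trace(r_outer, n, center),
        alveolus_id=kw.pop("alveolus_id", "circles"),
        **kw,
    )


def star_polygon(rng: np.random.Generator, n: int = 64) -> np.ndarray:
    """Random simple star-convex polygon around the origin."""
    theta = np.sort(rng.uniform(0.0, 2.0 * math.pi, size=n))
    # Keep consecutive angles distinct so edges are non-degenerate.
    theta += np.linspace(0.0, 1e-6, n)
    r = rng.uniform(0.5, 1.5, size=n)
    return np.column_stack((r * np.cos(theta), r * np.sin(theta)))


@pytest.fixture
def rng():
    return np.random.default_rng(20240320)
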