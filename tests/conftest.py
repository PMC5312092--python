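"""Shared fixtures: random star polygons and a rasterization area oracle."""

from __future__ import annotations

import numpy as np
import pytest
from matplotlib.path import Path as _MplPath

from gliamet.geometry import Contour, validate_contour


def random_star_polygon(
    rng: np.random.Generator,
    n_vertices: int = 12,
    base_radius: float = 3.0,
    roughness: float = 0.3,
    center: tuple[float, float] = (0.0, 0.0),
) -> Contour:
    """Random simple (star-shaped) polygon around ``center``.

    Vertex angles are built from positive gaps normalized to wrap the full
    circle, so the polygon is star-shaped about ``center`` and hence always
    simple.
    """
    gaps = rng.uniform(0.5, 1.5, n_vertices)
    theta = 2.0 * np.pi * np.cumsum(gaps) / gaps.sum() + rng.uniform(0, 2 * np.pi)
    r = base_radius * (1.0 + roughness * rng.uniform(-1.0, 1.0, n_vertices))
    verts = np.column_stack([
        center[0] + r * np.cos(theta), center[1] + r * np.sin(theta)
    ])
    return validate_contour(verts)


def raster_area(vertices: np.ndarray, grid: float = 0.01) -> float:
    """Pixel-count area oracle on a ``grid``-um raster (matplotlib winding).

    Independent of both the shoelace formula and shapely: counts grid-cell
    centers inside the polygon path.
    """
    v = np.asarray(vertices, dtype=float)
    path = _MplPath(np.vstack([v, v[:1]]), closed=True)
    xmin, ymin = v.min(axis=0) - grid
    xmax, ymax = v.max(axis=0) + grid
    xs = np.arange(xmin + grid / 2, xmax, grid)
    ys = np.arange(ymin + grid / 2, ymax, grid)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    inside = path.contains_points(pts)
    return float(inside.sum()) * grid * grid


def raster_masks(a: np.ndarray, b: np.ndarray, grid: float = 0.01):
    """Inside-masks of two polygons on a shared grid, for difference oracles."""
    va, vb = np.asarray(a, float), np.asarray(b, float)
    allv = np.vstack([va, vb])
    xmin, ymin = allv.min(axis=0) - grid
    xmax, ymax = allv.max(axis=0) + grid
    xs = np.arange(xmin + grid / 2, xmax, grid)
    ys = np.arange(ymin + grid / 2, ymax, grid)
    xx, yy = np.meshgrid(xs, ys)
    pts = np.column_stack([xx.ravel(), yy.ravel()])
    pa = _MplPath(np.vstack([va, va[:1]]), closed=True)
    pb = _MplPath(np.vstack([vb, vb[:1]]), closed=True)
    return pa.contains_points(pts), pb.contains_points(pts), grid * grid


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)


@pytest.fixture
def unit_square() -> Contour:
    return validate_contour([(0, 0), (1, 0), (1, 1), (0, 1)])
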