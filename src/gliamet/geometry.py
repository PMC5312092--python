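"""Planar contour geometry for traced cell outlines.

Cell outlines are closed simple polygons in continuous Cartesian coordinates
(x right, y up), units micrometres.  There is no pixel grid: traces are vector
outlines, and continuous geometry keeps the extension/retraction area
accounting exact (see :func:`polygon_difference`).

Conventions
-----------
* A contour stores its vertices *open*: the first vertex is not repeated at
  the end; closure is implicit.
* Canonical orientation is counter-clockwise (signed shoelace area > 0).
* Self-intersecting input is rejected, never silently repaired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterator, Literal, Sequence

import numpy as np
import shapely
from shapely.geometry import Polygon as _Poly


class GeometryError(ValueError):
    """Base class for contour-geometry failures."""


class DegenerateContourError(GeometryError):
    """Fewer than three distinct vertices, or zero enclosed area."""


class InvalidGeometryError(GeometryError):
    """Self-intersecting (non-simple) polygon."""


class SamplingError(ValueError):
    """Frame times of a series are not uniformly spaced."""


class DisjointContoursWarning(UserWarning):
    """The two contours of a frame transition do not overlap at all."""


#: boolean-difference pieces below this area (um^2) are degenerate-touching
#: artifacts (shared edges/points) and are dropped
AREA_EPS = 1e-9


# ---------------------------------------------------------------------------
# scalar polygon measures (authored primitives; cross-checked against shapely
# and a rasterization oracle in the test suite)
# ---------------------------------------------------------------------------

def shoelace_area(vertices: np.ndarray) -> float:
    """Signed area of a closed polygon by the shoelace formula.

    Positive for counter-clockwise vertex order.
    """
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def polyline_perimeter(vertices: np.ndarray) -> float:
    """Length of the closed polyline through ``vertices``."""
    v = np.asarray(vertices, dtype=float)
    return float(np.sum(np.hypot(*(np.roll(v, -1, axis=0) - v).T)))


def polygon_centroid(vertices: np.ndarray) -> tuple[float, float]:
    """Area centroid of a simple closed polygon."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    xn, yn = np.roll(x, -1), np.roll(y, -1)
    cross = x * yn - xn * y
    a = 0.5 * float(np.sum(cross))
    cx = float(np.sum((x + xn) * cross)) / (6.0 * a)
    cy = float(np.sum((y + yn) * cross)) / (6.0 * a)
    return cx, cy


# ---------------------------------------------------------------------------
# contour container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Contour:
    """One cell outline at one time point.

    Build through :func:`validate_contour`; direct construction skips the
    simplicity and orientation checks.

    Parameters
    ----------
    vertices : (n, 2) ndarray
        Open vertex list, um, counter-clockwise.
    cell_id : str
        Opaque identifier of the traced cell.
    t : float
        Time in minutes (frame index times the sampling interval).
    """

    vertices: np.ndarray
    cell_id: str = ""
    t: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "vertices", np.asarray(self.vertices, dtype=float)
        )

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def area(self) -> float:
        """Enclosed area, um^2 (positive for a valid contour)."""
        return shoelace_area(self.vertices)

    @property
    def perimeter(self) -> float:
        return polyline_perimeter(self.vertices)

    @property
    def centroid(self) -> tuple[float, float]:
        return polygon_centroid(self.vertices)

    def to_shapely(self) -> _Poly:
        return _Poly(self.vertices)

    def translated(self, dx: float, dy: float) -> "Contour":
        return replace(self, vertices=self.vertices + [dx, dy])

    def rotated(self, angle_rad: float, about: tuple[float, float] = (0.0, 0.0)) -> "Contour":
        c, s = np.cos(angle_rad), np.sin(angle_rad)
        rot = np.array([[c, -s], [s, c]])
        v = (self.vertices - about) @ rot.T + about
        return replace(self, vertices=v)

    def scaled(self, factor: float, about: tuple[float, float] | None = None) -> "Contour":
        if about is None:
            about = self.centroid
        return replace(self, vertices=(self.vertices - about) * factor + about)


def validate_contour(
    raw_vertices: Sequence[Sequence[float]] | np.ndarray,
    cell_id: str = "",
    t: float = 0.0,
) -> Contour:
    """Validate and canonicalize a raw vertex list into a :class:`Contour`.

    Consecutive duplicate vertices (including a repeated closing vertex) are
    removed, and orientation is normalized to counter-clockwise.

    Raises
    ------
    DegenerateContourError
        Fewer than 3 distinct vertices, non-finite coordinates, or zero area.
    InvalidGeometryError
        Self-intersecting polygon (no silent repair is attempted).
    """
    v = np.asarray(raw_vertices, dtype=float)
    if v.ndim != 2 or v.shape[1] != 2:
        raise DegenerateContourError(
            f"expected an (n, 2) vertex array, got shape {v.shape}"
        )
    if not np.all(np.isfinite(v)):
        raise DegenerateContourError("non-finite vertex coordinates")
    # drop consecutive duplicates, wrapping around the implicit closure
    keep = np.any(v != np.roll(v, 1, axis=0), axis=1)
    v = v[keep]
    if len(v) < 3:
        raise DegenerateContourError(
            f"fewer than 3 distinct vertices ({len(v)} after deduplication)"
        )
    edges = np.diff(np.vstack([v, v[:1]]), axis=0)
    cross = edges[:-1, 0] * edges[1:, 1] - edges[:-1, 1] * edges[1:, 0]
    if np.allclose(cross, 0.0):
        raise DegenerateContourError("zero enclosed area (collinear vertices)")
    if not _Poly(v).is_valid:
        raise InvalidGeometryError(
            f"self-intersecting contour (cell {cell_id!r}, t={t})"
        )
    signed = shoelace_area(v)
    if signed == 0.0:
        raise DegenerateContourError("zero enclosed area")
    if signed < 0.0:
        v = v[::-1]
    return Contour(vertices=v, cell_id=cell_id, t=t)


# ---------------------------------------------------------------------------
# morphometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Morphometry:
    """Scalar shape measures of one contour.

    ``compactness_pa`` is the perimeter/area ratio (um^-1): lower values mean
    a more compact cell at a given size.  ``compactness_iq`` is the
    dimensionless isoperimetric quotient 4*pi*A/P^2, which is 1 for a circle
    and scale-invariant.
    """

    area: float
    perimeter: float
    compactness_pa: float
    compactness_iq: float
    centroid: tuple[float, float]


def morphometry(c: Contour) -> Morphometry:
    """Area, perimeter, both compactness variants and centroid of a contour."""
    a = c.area
    p = c.perimeter
    return Morphometry(
        area=a,
        perimeter=p,
        compactness_pa=p / a,
        compactness_iq=4.0 * np.pi * a / p**2,
        centroid=c.centroid,
    )


# ---------------------------------------------------------------------------
# polygon differencing: extension / retraction decomposition
# ---------------------------------------------------------------------------

Sign = Literal["extension", "retraction"]


@dataclass(frozen=True)
class DiffComponent:
    """One connected component of a frame-to-frame polygon difference.

    ``polygon`` holds the exterior ring (open vertex list, um); ``area`` is
    the exact component area, which accounts for interior rings in the rare
    annulus case (one contour strictly inside the other).
    """

    polygon: np.ndarray
    area: float
    sign: Sign

    @property
    def centroid(self) -> tuple[float, float]:
        return polygon_centroid(self.polygon)


def _components(geom, sign: Sign, area_eps: float) -> list[DiffComponent]:
    out: list[DiffComponent] = []
    for part in shapely.get_parts(geom) if geom.geom_type != "Polygon" else [geom]:
        if part.geom_type != "Polygon" or part.is_empty:
            continue
        if part.area <= area_eps:
            continue
        verts = np.asarray(part.exterior.coords)[:-1]
        out.append(DiffComponent(polygon=verts, area=part.area, sign=sign))
    return out


def polygon_difference(
    a: Contour,
    b: Contour,
    area_eps: float = AREA_EPS,
    align_centroids: bool = False,
) -> list[DiffComponent]:
    """Decompose the change from contour ``a`` to ``b`` into signed components.

    Connected components of ``b`` minus ``a`` are extensions (area protruding
    over the earlier outline); components of ``a`` minus ``b`` are retractions
    (area receding from it).  The accounting is conservative:

        area(b) - area(a) = sum(extension areas) - sum(retraction areas)

    to numerical tolerance, because the decomposition is continuous-geometry
    boolean clipping rather than raster subtraction.  Degenerate touching
    pieces below ``area_eps`` are dropped.

    Frames are assumed co-registered (drift is corrected at acquisition);
    ``align_centroids=True`` optionally shifts ``b`` onto ``a``'s centroid
    first.

    A disjoint pair is not an error: a warning is emitted and the whole of
    ``b`` is one extension component, the whole of ``a`` one retraction.
    """
    if align_centroids:
        ca, cb = a.centroid, b.centroid
        b = b.translated(ca[0] - cb[0], ca[1] - cb[1])
    pa, pb = a.to_shapely(), b.to_shapely()
    if not pa.intersects(pb) or pa.intersection(pb).area <= area_eps:
        warnings.warn(
            f"contours of cell {a.cell_id!r} at t={a.t} and t={b.t} do not "
            "overlap; treating them as one whole-cell extension and one "
            "whole-cell retraction",
            DisjointContoursWarning,
            stacklevel=2,
        )
    ext = _components(pb.difference(pa), "extension", area_eps)
    ret = _components(pa.difference(pb), "retraction", area_eps)
    return ext + ret


# ---------------------------------------------------------------------------
# time series of contours
# ---------------------------------------------------------------------------

@dataclass
class ContourSeries:
    """Ordered contours of one cell at uniform sampling intervals.

    The default sampling interval is 1 min (stacks acquired once per minute);
    non-uniform spacing is rejected unless ``allow_gaps`` is set.
    """

    contours: list[Contour]
    genotype: str = ""
    allow_gaps: bool = False
    dt: float = field(init=False, default=1.0)

    def __post_init__(self) -> None:
        if not self.contours:
            raise SamplingError("empty contour series")
        ids = {c.cell_id for c in self.contours}
        if len(ids) > 1:
            raise GeometryError(f"series mixes cells: {sorted(ids)}")
        ts = np.array([c.t for c in self.contours], dtype=float)
        if len(ts) > 1:
            d = np.diff(ts)
            if np.any(d <= 0):
                raise SamplingError("frame times must be strictly increasing")
            self.dt = float(d[0])
            if not self.allow_gaps and not np.allclose(d, self.dt):
                raise SamplingError(
                    f"non-uniform sampling for cell {self.cell_id!r}: "
                    f"intervals {sorted(set(np.round(d, 9)))} min"
                )

    @property
    def cell_id(self) -> str:
        return self.contours[0].cell_id

    @property
    def times(self) -> np.ndarray:
        return np.array([c.t for c in self.contours])

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area for c in self.contours])

    @property
    def n_frames(self) -> int:
        return len(self.contours)

    def __len__(self) -> int:
        return len(self.contours)

    def __getitem__(self, i: int) -> Contour:
        return self.contours[i]

    def __iter__(self) -> Iterator[Contour]:
        return iter(self.contours)

    def transitions(self) -> Iterator[tuple[Contour, Contour]]:
        """Consecutive frame pairs (t, t+dt)."""
        return zip(self.contours[:-1], self.contours[1:])

    def transformed(self, dx=0.0, dy=0.0, angle_rad=0.0) -> "ContourSeries":
        """Rigidly moved copy (same motion applied to every frame)."""
        cs = [c.rotated(angle_rad).translated(dx, dy) for c in self.contours]
        return ContourSeries(cs, genotype=self.genotype, allow_gaps=self.allow_gaps)
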