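"""Ground-truth generators for every input the pipeline consumes.

The generators emulate the study conditions of the live-imaging morphometry:

* growing star-shaped cell contours with Poisson-injected protrusion
  (extension) and retraction events of lognormal size, each event logged with
  its realized area so detection can be scored against known ground truth;
* linear nerve-cord condensation with Gaussian noise, for staging
  calibration;
* two-band intensity images with Gaussian noise, for polarization and
  insulation ratios;
* constant-width ribbon masks (straight or circular-arc), for junction-belt
  width estimation;
* Voronoi-tiled epithelial scenes with programmed coverage and hole spectra,
  for closure staging.

Every generator is deterministic given its seed.  Events are smooth
circular-cap radial bumps/dents spanning a bounded angular window (default
20 degrees), placed without angular overlap within one transition, so each
injected event corresponds to exactly one connected difference component and
the detection ground truth is unambiguous.  Because the windows are disjoint,
the shoelace area change of a transition is exactly the sum of the per-event
changes, and the logged areas equal the realized polygon-area changes.

The genotype presets put all net growth into the extension/retraction size
imbalance (deterministic isotropic growth 0): the wild-type-like preset has
equal extension and retraction frequencies with extensions markedly larger;
the *moody*-like preset has retractions outnumbering extensions with larger
retracted chunks (destabilized substrate contacts); the *loco*-like preset
additionally reduces extension size and frequency.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
import shapely.affinity
from scipy.optimize import brentq
from shapely.geometry import LineString, MultiPoint, Point
from shapely.ops import split, voronoi_diagram

from .geometry import Contour, ContourSeries, shoelace_area, validate_contour
from .imaging import IntensityImage, RoiSpec, rectangle_roi
from .staging import CLOSED, LARGE_HOLES, PRE_CONTACT, SMALL_GAPS


class GenerationError(RuntimeError):
    """Parameter set cannot be realized as valid geometry."""


# ---------------------------------------------------------------------------
# cell contour series with injected events
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellSimParams:
    """Parameters of the contour-series generator.

    Defaults are the wild-type-like preset; see :func:`wt_params`,
    :func:`moody_params`, :func:`loco_params`.

    base_radius um; growth_rate um^2/min (deterministic isotropic term);
    lambda_* events/min; *_size_median um^2 (lognormal medians); size_sigma
    lognormal shape; event_window_deg angular footprint of one event.
    """

    base_radius: float = 10.0
    aspect: float = 1.2
    n_vertices: int = 256
    growth_rate: float = 0.0
    lambda_ext: float = 0.5
    lambda_ret: float = 0.5
    ext_size_median: float = 8.0
    ret_size_median: float = 2.5
    size_sigma: float = 0.4
    n_frames: int = 21
    dt: float = 1.0
    seed: int = 0
    event_window_deg: float = 20.0
    radial_noise: float = 0.04
    cell_id: str = "cell"
    genotype: str = "WT"

    def __post_init__(self) -> None:
        if self.lambda_ext < 0 or self.lambda_ret < 0:
            raise ValueError("event rates must be >= 0")
        if self.base_radius <= 0:
            raise ValueError("base_radius must be > 0")
        if self.n_vertices < 12:
            raise ValueError("n_vertices must be >= 12")


def wt_params(seed: int = 0, **overrides) -> CellSimParams:
    """Wild-type-like preset: balanced rates, extensions larger than retractions."""
    return replace(CellSimParams(seed=seed, genotype="WT"), **overrides)


def moody_params(seed: int = 0, **overrides) -> CellSimParams:
    """GPCR loss-of-function-like preset: retractions outnumber extensions and
    remove larger chunks, so net growth is near zero and highly variable."""
    base = CellSimParams(
        seed=seed, genotype="moody",
        lambda_ext=0.5, lambda_ret=0.8,
        ext_size_median=8.0, ret_size_median=5.0,
    )
    return replace(base, **overrides)


def loco_params(seed: int = 0, **overrides) -> CellSimParams:
    """Pathway overactivity-like preset: additionally reduced extension size
    and frequency (curtailed protrusive activity, retarded growth)."""
    base = CellSimParams(
        seed=seed, genotype="loco",
        lambda_ext=0.3, lambda_ret=0.8,
        ext_size_median=6.0, ret_size_median=2.5,
    )
    return replace(base, **overrides)


@dataclass(frozen=True)
class InjectedEvent:
    """Ground-truth record of one injected event.

    ``transition`` is the index i of the frame pair (i, i+1); ``area`` is the
    realized polygon-area change of the event alone (um^2, positive).
    """

    transition: int
    sign: str
    center_deg: float
    width_deg: float
    area: float


@dataclass
class EventLog:
    """All injected events of one simulated cell."""

    events: list[InjectedEvent] = field(default_factory=list)

    def for_transition(self, i: int) -> list[InjectedEvent]:
        return [e for e in self.events if e.transition == i]

    def count(self, sign: str | None = None) -> int:
        return sum(1 for e in self.events if sign is None or e.sign == sign)

    def areas(self, sign: str) -> list[float]:
        return [e.area for e in self.events if e.sign == sign]


def _circ_dist(a: np.ndarray, b: float) -> np.ndarray:
    return np.abs((a - b + np.pi) % (2.0 * np.pi) - np.pi)


def _radial_area(theta: np.ndarray, r: np.ndarray) -> float:
    v = np.column_stack([r * np.cos(theta), r * np.sin(theta)])
    return shoelace_area(v)


class _RadialCell:
    """Star-shaped contour as a radius profile on a fixed angular grid."""

    def __init__(self, p: CellSimParams, rng: np.random.Generator):
        self.theta = np.linspace(0.0, 2.0 * np.pi, p.n_vertices, endpoint=False)
        a = p.base_radius * np.sqrt(p.aspect)
        b = p.base_radius / np.sqrt(p.aspect)
        r = a * b / np.hypot(b * np.cos(self.theta), a * np.sin(self.theta))
        bump = np.zeros_like(r)
        for k in range(2, 6):
            amp = rng.normal(0.0, p.radial_noise / k)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            bump += amp * np.cos(k * self.theta + phase)
        self.r = r * (1.0 + bump)
        if self.r.min() <= 0.2 * p.base_radius:
            raise GenerationError("radial noise too large for base radius")

    @property
    def area(self) -> float:
        return _radial_area(self.theta, self.r)

    def vertices(self) -> np.ndarray:
        return np.column_stack([
            self.r * np.cos(self.theta), self.r * np.sin(self.theta)
        ])

    def profile(self, center: float, width: float) -> np.ndarray:
        """Smooth circular-cap profile: cos^2 taper, zero at the window edge."""
        u = _circ_dist(self.theta, center) / (width / 2.0)
        f = np.where(u < 1.0, np.cos(np.pi * np.clip(u, 0, 1) / 2.0) ** 2, 0.0)
        return f

    def apply_event(self, center: float, width: float, target_area: float,
                    sign: str) -> float:
        """Deform the profile to realize an event; return the realized area.

        The amplitude is solved so the shoelace-area change matches
        ``target_area``; a dent that would require pinching the radius to
        zero is reported as infeasible (ValueError) so the caller can widen
        the window.
        """
        f = self.profile(center, width)
        a0 = self.area

        if sign == "extension":
            def delta(eps: float) -> float:
                return _radial_area(self.theta, self.r * (1.0 + eps * f)) - a0

            hi = 1.0
            while delta(hi) < target_area:
                hi *= 2.0
                if hi > 64.0:
                    raise ValueError("extension target unreachable")
            eps = brentq(lambda e: delta(e) - target_area, 0.0, hi, xtol=1e-12)
            self.r = self.r * (1.0 + eps * f)
        else:
            def delta(eps: float) -> float:
                return a0 - _radial_area(self.theta, self.r * (1.0 - eps * f))

            if delta(0.95) < target_area:
                raise ValueError("dent deeper than local radius")
            eps = brentq(lambda e: delta(e) - target_area, 0.0, 0.95, xtol=1e-12)
            self.r = self.r * (1.0 - eps * f)
        return abs(self.area - a0)


def generate_cell_series(p: CellSimParams) -> tuple[ContourSeries, EventLog]:
    """Simulate one cell's contour series with logged ground-truth events.

    Each transition applies the deterministic isotropic area growth
    ``growth_rate * dt`` (an exact radial rescaling) followed by
    Poisson(lambda_ext) outward bumps and Poisson(lambda_ret) inward dents at
    non-overlapping angular windows with lognormal target areas.  Dent
    windows are widened (up to 6x the default) when the drawn size would
    pinch the local radius; a still-infeasible dent raises
    :class:`GenerationError` naming the offending frame.
    """
    rng = np.random.default_rng(p.seed)
    cell = _RadialCell(p, rng)
    contours = [validate_contour(cell.vertices(), cell_id=p.cell_id, t=0.0)]
    log = EventLog()
    base_w = np.deg2rad(p.event_window_deg)
    margin = 2.0 * np.pi / p.n_vertices * 2.0  # two vertex spacings

    for i in range(p.n_frames - 1):
        if p.growth_rate != 0.0:
            a = cell.area
            target = a + p.growth_rate * p.dt
            if target <= 0:
                raise GenerationError(f"shrinkage below zero area at frame {i + 1}")
            cell.r = cell.r * np.sqrt(target / a)
        k_ext = rng.poisson(p.lambda_ext * p.dt)
        k_ret = rng.poisson(p.lambda_ret * p.dt)
        sizes = [("extension", s) for s in rng.lognormal(
            np.log(p.ext_size_median), p.size_sigma, k_ext)]
        sizes += [("retraction", s) for s in rng.lognormal(
            np.log(p.ret_size_median), p.size_sigma, k_ret)]
        placed: list[tuple[float, float]] = []  # (center, width)
        for sign, size in sizes:
            ok = False
            for _ in range(200):
                center = rng.uniform(0.0, 2.0 * np.pi)
                width = base_w
                while width <= 6.0 * base_w:
                    clash = any(
                        _circ_dist(np.array([center]), c0)[0]
                        < (width + w0) / 2.0 + margin
                        for c0, w0 in placed
                    )
                    if clash:
                        break
                    try:
                        realized = cell.apply_event(center, width, size, sign)
                    except ValueError:
                        width *= 1.4
                        continue
                    placed.append((center, width))
                    log.events.append(InjectedEvent(
                        transition=i, sign=sign,
                        center_deg=float(np.rad2deg(center)),
                        width_deg=float(np.rad2deg(width)),
                        area=realized,
                    ))
                    ok = True
                    break
                if ok:
                    break
            if not ok:
                raise GenerationError(
                    f"could not place a {sign} of {size:.2f} um^2 at frame {i + 1}"
                )
        contours.append(validate_contour(
            cell.vertices(), cell_id=p.cell_id, t=(i + 1) * p.dt))
    return ContourSeries(contours, genotype=p.genotype), log


def generate_area_series(
    slope: float,
    sigma: float,
    n: int = 21,
    intercept: float = 300.0,
    dt: float = 1.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Area-vs-time series with a known slope and iid Gaussian noise.

    The calibration ground truth for growth classification: the OLS slope
    test has its nominal operating characteristics exactly under this model.
    Returns (times_min, areas_um2).
    """
    rng = np.random.default_rng(seed)
    t = np.arange(n, dtype=float) * dt
    areas = intercept + slope * t + rng.normal(0.0, sigma, n)
    return t, areas


# ---------------------------------------------------------------------------
# ribbon masks
# ---------------------------------------------------------------------------

def generate_sj_ribbon(
    width: float,
    length: float,
    curvature: float = 0.0,
    pixel_size: float = 0.05,
    seed: int = 0,
) -> IntensityImage:
    """Binary mask of a constant-width ribbon along a straight or arc centerline.

    ``curvature`` is 1/um (0 = straight); ends are cut flat (perpendicular to
    the centerline) so the width is constant along the whole length.  Raises
    :class:`GenerationError` when the width is under 3 pixels (below
    resolution).
    """
    if width < 3.0 * pixel_size:
        raise GenerationError(
            f"ribbon width {width} um is under resolution at "
            f"pixel size {pixel_size} um (need >= 3 px)"
        )
    pad = width / 2.0 + 4.0 * pixel_size
    if curvature == 0.0:
        w_img = int(np.ceil((length + 2 * pad) / pixel_size))
        h_img = int(np.ceil((width + 2 * pad) / pixel_size))
        cols, rows = np.meshgrid(np.arange(w_img), np.arange(h_img))
        x = (cols + 0.5) * pixel_size
        y = (rows + 0.5) * pixel_size
        y0 = h_img * pixel_size / 2.0
        mask = (np.abs(y - y0) <= width / 2.0) & (x >= pad) & (x <= pad + length)
    else:
        rc = 1.0 / curvature
        span = length / rc  # subtended angle
        if span > 1.5 * np.pi:
            raise GenerationError("arc longer than 3/4 of a full circle")
        # arc from angle 0 to span around a center placed to keep coords positive
        cx = pad + rc + width
        cy = pad + rc + width
        w_img = int(np.ceil((cx + rc + pad) / pixel_size))
        h_img = w_img
        cols, rows = np.meshgrid(np.arange(w_img), np.arange(h_img))
        x = (cols + 0.5) * pixel_size - cx
        y = (rows + 0.5) * pixel_size - cy
        rad = np.hypot(x, y)
        ang = np.arctan2(y, x) % (2.0 * np.pi)
        mask = (np.abs(rad - rc) <= width / 2.0) & (ang <= span)
    return IntensityImage(mask.astype(np.uint8), pixel_size)


# ---------------------------------------------------------------------------
# two-band intensity images
# ---------------------------------------------------------------------------

def _two_band_image(
    upper_mean: float,
    lower_mean: float,
    noise_sigma: float,
    pixel_size: float,
    rng: np.random.Generator,
    shape: tuple[int, int] = (80, 80),
) -> IntensityImage:
    h, w = shape
    px = np.empty((h, w), dtype=float)
    px[: h // 2] = upper_mean
    px[h // 2:] = lower_mean
    if noise_sigma > 0:
        px += rng.normal(0.0, noise_sigma, px.shape)
    return IntensityImage(np.clip(px, 0.0, None), pixel_size)


def generate_polarization_image(
    true_ratio: float,
    noise_sigma: float = 0.0,
    pixel_size: float = 0.2,
    seed: int = 0,
    apical_mean: float = 100.0,
) -> tuple[IntensityImage, RoiSpec, RoiSpec]:
    """Two-band image with a known basal/apical intensity ratio.

    The apical (nervous-system-facing) band occupies the upper half of the
    image, the basal (hemolymph-facing) band the lower half, with means
    (apical_mean, apical_mean * true_ratio) plus Gaussian noise.  Returns the
    image and rectangular ROIs centered in each band.
    """
    rng = np.random.default_rng(seed)
    img = _two_band_image(apical_mean, apical_mean * true_ratio,
                          noise_sigma, pixel_size, rng)
    h, w = img.shape
    xext = w * pixel_size
    yext = h * pixel_size
    inset = 0.1 * yext
    apical = rectangle_roi("apical", inset, inset, xext - inset, yext / 2 - inset)
    basal = rectangle_roi("basal", inset, yext / 2 + inset, xext - inset, yext - inset)
    return img, apical, basal


def generate_insulation_image(
    true_index: float,
    noise_sigma: float = 0.0,
    pixel_size: float = 0.2,
    seed: int = 0,
    outside_mean: float = 100.0,
) -> tuple[IntensityImage, RoiSpec, RoiSpec]:
    """Two-band dye image with a known inside/outside (CNS/hemolymph) ratio.

    The CNS occupies the upper half with mean outside_mean * true_index; the
    outside (hemolymph) the lower half with mean outside_mean.
    """
    rng = np.random.default_rng(seed)
    img = _two_band_image(outside_mean * true_index, outside_mean,
                          noise_sigma, pixel_size, rng)
    h, w = img.shape
    xext = w * pixel_size
    yext = h * pixel_size
    inset = 0.1 * yext
    cns = rectangle_roi("cns", inset, inset, xext - inset, yext / 2 - inset)
    outside = rectangle_roi("outside", inset, yext / 2 + inset, xext - inset, yext - inset)
    return img, cns, outside


# ---------------------------------------------------------------------------
# condensation calibration data
# ---------------------------------------------------------------------------

def generate_condensation_series(
    a: float = 50.0,
    b: float = -2.0,
    sigma: float = 0.5,
    n: int = 20,
    age_range: tuple[float, float] = (11.0, 18.0),
    seed: int = 0,
    genotype: str = "WT",
) -> pd.DataFrame:
    """Noisy linear condensation observations: width = a + b*age + N(0, sigma^2).

    Ages are uniform over ``age_range`` (default 11-18 h AEL).  Returns a
    DataFrame with columns genotype, age_h, mean_segment_width_um.
    """
    rng = np.random.default_rng(seed)
    ages = rng.uniform(age_range[0], age_range[1], n)
    widths = a + b * ages + rng.normal(0.0, sigma, n)
    return pd.DataFrame({
        "genotype": genotype,
        "age_h": ages,
        "mean_segment_width_um": widths,
    })


# ---------------------------------------------------------------------------
# epithelial closure scenes
# ---------------------------------------------------------------------------

DEFAULT_REGION_SIDE = 100.0  # um


def _voronoi_cells(region, n_cells: int, rng: np.random.Generator):
    """Jittered-grid Voronoi tiling of the region (exact cover)."""
    k = int(np.ceil(np.sqrt(n_cells)))
    minx, miny, maxx, maxy = region.bounds
    sx = (maxx - minx) / k
    sy = (maxy - miny) / k
    pts = []
    for gi in range(k):
        for gj in range(k):
            pts.append((
                minx + (gi + rng.uniform(0.15, 0.85)) * sx,
                miny + (gj + rng.uniform(0.15, 0.85)) * sy,
            ))
    vor = voronoi_diagram(MultiPoint(pts), envelope=region.buffer(max(sx, sy)))
    cells = []
    for g in shapely.get_parts(vor):
        clipped = g.intersection(region)
        for part in shapely.get_parts(clipped) if clipped.geom_type != "Polygon" else [clipped]:
            if part.geom_type == "Polygon" and part.area > 1e-6:
                cells.append(part)
    return cells


def _polygon_parts(geom, min_area: float = 1e-6):
    parts = shapely.get_parts(geom) if geom.geom_type != "Polygon" else [geom]
    return [g for g in parts if g.geom_type == "Polygon" and g.area > min_area]


def _punch_disc(pieces, disc, rng: np.random.Generator, extent: float):
    """Subtract a disc from polygon pieces, splitting any piece in which the
    disc would leave an interior ring (cells stay simple polygons)."""
    out = []
    for piece in pieces:
        if not disc.intersects(piece):
            out.append(piece)
            continue
        parts = _polygon_parts(piece.difference(disc))
        if any(g.interiors for g in parts):
            ang = rng.uniform(0.0, np.pi)
            cx, cy = disc.centroid.x, disc.centroid.y
            chord = LineString([
                (cx - extent * np.cos(ang), cy - extent * np.sin(ang)),
                (cx + extent * np.cos(ang), cy + extent * np.sin(ang)),
            ])
            parts = []
            for half in shapely.get_parts(split(piece, chord)):
                if half.geom_type == "Polygon":
                    parts.extend(_polygon_parts(half.difference(disc)))
        out.extend(parts)
    return out


def generate_closure_scene(
    region: Contour | None = None,
    target_coverage: float = 1.0,
    hole_spectrum: list[float] | None = None,
    n_cells: int = 16,
    seed: int = 0,
) -> tuple[list[Contour], Contour, str]:
    """Voronoi-like epithelial scene with a programmed closure stage.

    Regimes (mirroring the four visual closure categories):

    * ``target_coverage == 1``: the exact tiling; true stage ``closed``.
    * ``target_coverage >= 0.5``: disjoint discs with areas from
      ``hole_spectrum`` (defaults derived from the uncovered budget) are
      punched at jittered grid sites inside the tiling, so the uncovered set
      is exactly those discs; a cell that a disc would leave with an interior
      ring is first split along a chord, keeping every cell a simple polygon.
      True stage is ``small_gaps`` when every hole is below 25 um^2 with at
      most 5 holes, else ``large_holes``.
    * ``target_coverage < 0.5``: every cell is shrunk about its centroid to
      the target coverage; true stage ``pre_contact``.

    Returns (cells, region, true_stage).  Raises :class:`GenerationError`
    for infeasible coverage/hole combinations.
    """
    if not 0.0 < target_coverage <= 1.0:
        raise GenerationError("target_coverage must be in (0, 1]")
    rng = np.random.default_rng(seed)
    if region is None:
        s = DEFAULT_REGION_SIDE
        region = validate_contour(
            [(0, 0), (s, 0), (s, s), (0, s)], cell_id="REGION")
    rpoly = region.to_shapely()
    cells = _voronoi_cells(rpoly, n_cells, rng)
    budget = (1.0 - target_coverage) * rpoly.area

    if target_coverage >= 1.0 - 1e-12:
        true_stage = CLOSED
    elif target_coverage >= 0.5:
        if hole_spectrum is None:
            if budget <= 120.0:
                k = max(1, min(5, int(np.ceil(budget / 24.0))))
            else:
                k = max(1, int(round(budget / 500.0)))
            hole_spectrum = [budget / k] * k
        if abs(sum(hole_spectrum) - budget) > 0.05 * max(budget, 1.0):
            raise GenerationError(
                f"hole_spectrum sums to {sum(hole_spectrum):.1f} um^2 but the "
                f"uncovered budget at coverage {target_coverage} is {budget:.1f}"
            )
        # deterministic-feasibility placement: discs at jittered grid sites
        # well inside the region, pairwise disjoint
        r_max = float(np.sqrt(max(hole_spectrum) / np.pi))
        hole_margin = r_max + 0.5
        pitch = 2.0 * r_max + 1.0
        minx, miny, maxx, maxy = rpoly.bounds
        sites = [
            (x, y)
            for x in np.arange(minx + hole_margin, maxx - hole_margin + 1e-9, pitch)
            for y in np.arange(miny + hole_margin, maxy - hole_margin + 1e-9, pitch)
            if rpoly.contains(Point(x, y))
            and rpoly.exterior.distance(Point(x, y)) >= hole_margin - 1e-6
        ]
        if len(sites) < len(hole_spectrum):
            raise GenerationError(
                f"cannot fit {len(hole_spectrum)} disjoint holes of up to "
                f"{max(hole_spectrum):.1f} um^2 in the region "
                f"(coverage {target_coverage})"
            )
        order = rng.permutation(len(sites))
        jitter = 0.25
        extent = 4.0 * max(maxx - minx, maxy - miny)
        for area, si in zip(hole_spectrum, order):
            x, y = sites[int(si)]
            pt = Point(x + rng.uniform(-jitter, jitter),
                       y + rng.uniform(-jitter, jitter))
            disc = pt.buffer(np.sqrt(area / np.pi), quad_segs=64)
            # rescale so the polygonal disc area matches the target hole
            disc = shapely.affinity.scale(
                disc, *(np.sqrt(area / disc.area),) * 2, origin=pt)
            cells = _punch_disc(cells, disc, rng, extent)
        small = all(a < 25.0 for a in hole_spectrum) and len(hole_spectrum) <= 5
        true_stage = SMALL_GAPS if small else LARGE_HOLES
    else:
        factor = np.sqrt(target_coverage)
        cells = [shapely.affinity.scale(c, factor, factor, origin=c.centroid)
                 for c in cells]
        true_stage = PRE_CONTACT

    contours = [
        validate_contour(np.asarray(c.exterior.coords)[:-1], cell_id=f"cell{i:03d}")
        for i, c in enumerate(cells)
    ]
    return contours, region, true_stage
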