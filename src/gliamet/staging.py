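"""Embryo staging from nerve-cord condensation, and epithelial-closure staging.

The ventral nerve cord condenses along its anterior-posterior axis during
mid-embryogenesis, so the mean segment width falls roughly linearly with age.
A per-genotype least-squares line (width = a + b*t) fitted to calibration
observations is inverted to estimate embryo age from a measured width; the
calibration is a reliable age measure between 11 and 18 h after egg laying
(AEL), and estimates outside that range are flagged, not rejected.

Epithelial closure of a scene of cell polygons inside a region is staged into
four visual categories: cells with under 50% mutual contact (pre_contact),
over 50% contact but large holes remaining (large_holes), only a few small
gaps (small_gaps), and a completely closed sheet (closed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.ops import unary_union

from .dynamics import _ols_line
from .geometry import AREA_EPS, Contour, GeometryError

PRE_CONTACT = "pre_contact"
LARGE_HOLES = "large_holes"
SMALL_GAPS = "small_gaps"
CLOSED = "closed"
STAGES = (PRE_CONTACT, LARGE_HOLES, SMALL_GAPS, CLOSED)

#: default h AEL interval over which condensation is a reliable age measure
DEFAULT_VALID_RANGE = (11.0, 18.0)

# closure thresholds: the visual categories carry no published numbers, so
# these are declared defaults, configurable and recorded in output metadata
DEFAULT_CONTACT_EPS = 0.5        # um
DEFAULT_LARGE_HOLE_AREA = 25.0   # um^2
DEFAULT_SMALL_GAP_COUNT_MAX = 5
DEFAULT_CLOSED_EPS_AREA = 1.0    # um^2
#: uncovered slivers below this area (um^2) are clipping artifacts, not gaps
HOLE_SLIVER_EPS = 1e-6


class CalibrationError(ValueError):
    """Degenerate or insufficient calibration observations."""


@dataclass(frozen=True)
class AgeEstimate:
    """Inverse-regression age estimate, h AEL, with a validity flag."""

    age_h: float
    in_range: bool


@dataclass(frozen=True)
class StagingModel:
    """Fitted linear map between mean nerve-cord segment width and age.

    width = intercept_a + slope_b * age, slope_b in um/h (negative during
    condensation).  Separate models are fitted per genotype because
    condensation is mildly impaired in some mutants.
    """

    genotype: str
    intercept_a: float
    slope_b: float
    fit_r2: float
    n_obs: int
    valid_range: tuple[float, float] = DEFAULT_VALID_RANGE

    def estimate_age(self, width_um: float) -> AgeEstimate:
        return estimate_age(self, width_um)

    def summary(self) -> str:
        lo, hi = self.valid_range
        return "\n".join([
            f"Condensation staging model ({self.genotype or 'unspecified'})",
            "-" * 42,
            f"width = {self.intercept_a:.3f} {self.slope_b:+.3f} * age_h  (um)",
            f"R^2          {self.fit_r2:8.4f}",
            f"n            {self.n_obs:8d}",
            f"valid range  {lo:.0f}-{hi:.0f} h AEL",
        ])


def calibrate_staging(
    observations,
    genotype: str = "WT",
    valid_range: tuple[float, float] = DEFAULT_VALID_RANGE,
    min_span_h: float = 2.0,
) -> StagingModel:
    """Least-squares width-vs-age line from (age_h, mean_segment_width_um) pairs.

    Accepts an (n, 2) array-like or a DataFrame with columns ``age_h`` and
    ``mean_segment_width_um``.  Requires at least 3 observations spanning at
    least ``min_span_h`` hours.
    """
    if hasattr(observations, "columns"):
        obs = np.column_stack([
            np.asarray(observations["age_h"], dtype=float),
            np.asarray(observations["mean_segment_width_um"], dtype=float),
        ])
    else:
        obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] != 2 or len(obs) < 3:
        raise CalibrationError(
            "need >= 3 (age_h, width_um) observations for calibration"
        )
    ages, widths = obs[:, 0], obs[:, 1]
    if np.ptp(ages) < min_span_h:
        raise CalibrationError(
            f"calibration ages span {np.ptp(ages):.2f} h; need >= {min_span_h} h"
        )
    slope, intercept, r, _, _ = _ols_line(ages, widths)
    if slope == 0.0:
        raise CalibrationError("no condensation trend (zero slope)")
    return StagingModel(
        genotype=genotype,
        intercept_a=intercept,
        slope_b=slope,
        fit_r2=r * r,
        n_obs=len(obs),
        valid_range=valid_range,
    )


def estimate_age(model: StagingModel, width_um: float) -> AgeEstimate:
    """Invert the calibration line: t = (width - a) / b.

    Out-of-range estimates are returned with ``in_range=False`` rather than
    raising; the point estimate carries no calibration interval.
    """
    age = (width_um - model.intercept_a) / model.slope_b
    lo, hi = model.valid_range
    return AgeEstimate(age_h=float(age), in_range=bool(lo <= age <= hi))


class CondensationStaging:
    """Model-style wrapper: construct from data, ``fit()`` -> StagingModel."""

    def __init__(self, observations, genotype: str = "WT"):
        self.observations = observations
        self.genotype = genotype

    @classmethod
    def from_dataframe(cls, df, genotype: str = "WT") -> "CondensationStaging":
        return cls(df, genotype=genotype)

    def fit(self, **kwargs) -> StagingModel:
        return calibrate_staging(self.observations, genotype=self.genotype, **kwargs)


# ---------------------------------------------------------------------------
# epithelial closure
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClosureStage:
    """Closure classification of one scene.

    ``holes`` lists the areas (um^2) of the uncovered connected components;
    ``contact_fraction`` is the fraction of total cell perimeter lying within
    ``contact_eps`` of another cell or of the region boundary.
    """

    stage: str
    contact_fraction: float
    holes: list[float]

    @property
    def uncovered_area(self) -> float:
        return float(sum(self.holes))


def _contact_fraction(polys, region, contact_eps: float) -> float:
    region_band = region.exterior.buffer(contact_eps)
    total_perim = 0.0
    contact_len = 0.0
    for i, p in enumerate(polys):
        others = [q for j, q in enumerate(polys) if j != i]
        band = unary_union([q.buffer(contact_eps) for q in others] + [region_band])
        total_perim += p.exterior.length
        contact_len += p.exterior.intersection(band).length
    return contact_len / total_perim if total_perim > 0 else 0.0


def classify_closure(
    cells: list[Contour],
    region: Contour,
    contact_eps: float = DEFAULT_CONTACT_EPS,
    large_hole_area: float = DEFAULT_LARGE_HOLE_AREA,
    small_gap_count_max: int = DEFAULT_SMALL_GAP_COUNT_MAX,
    closed_eps_area: float = DEFAULT_CLOSED_EPS_AREA,
    overlap_tol: float = 1e-6,
) -> ClosureStage:
    """Stage the closure of an epithelial scene.

    The uncovered set is region minus the union of cells; its connected
    components are the holes.  Staging, in order of precedence:

    * ``closed`` -- total uncovered area <= ``closed_eps_area``;
    * ``small_gaps`` -- every hole smaller than ``large_hole_area`` and at
      most ``small_gap_count_max`` holes;
    * ``large_holes`` -- contact fraction >= 0.5 (over 50% mutual contact);
    * ``pre_contact`` -- otherwise.

    Cells must lie inside the region and be pairwise non-overlapping beyond
    ``overlap_tol`` (um^2); shared edges are fine.
    """
    if not cells:
        raise GeometryError("closure scene has no cells")
    rpoly = region.to_shapely()
    polys = [c.to_shapely() for c in cells]
    for c, p in zip(cells, polys):
        if p.difference(rpoly).area > overlap_tol:
            raise GeometryError(
                f"cell {c.cell_id!r} overlaps the region boundary"
            )
    tree = shapely.STRtree(polys)
    for i, p in enumerate(polys):
        for j in tree.query(p):
            j = int(j)
            if j <= i:
                continue
            if p.intersection(polys[j]).area > overlap_tol:
                raise GeometryError(
                    f"cells {cells[i].cell_id!r} and {cells[j].cell_id!r} overlap"
                )
    uncovered = rpoly.difference(unary_union(polys))
    holes = sorted(
        (g.area for g in shapely.get_parts(uncovered)
         if g.geom_type == "Polygon" and g.area > HOLE_SLIVER_EPS),
        reverse=True,
    )
    total_uncovered = uncovered.area
    frac = _contact_fraction(polys, rpoly, contact_eps)
    if total_uncovered <= closed_eps_area:
        stage = CLOSED
    elif holes and all(h < large_hole_area for h in holes) and len(holes) <= small_gap_count_max:
        stage = SMALL_GAPS
    elif frac >= 0.5:
        stage = LARGE_HOLES
    else:
        stage = PRE_CONTACT
    return ClosureStage(stage=stage, contact_fraction=frac, holes=list(holes))
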