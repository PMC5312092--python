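"""Growth fitting, growth classification, and extension/retraction dynamics.

Glial growth is measured by ordinary least squares of cell area against time
over a window (defaults 20 and 75 min).  The slope is the growth rate
(um^2/min) and the correlation coefficient R separates significant growth
(R near 1) from shrinkage (R near -1) and no change (R near 0); "significant"
is operationalized as the two-sided slope t-test at alpha = 0.05, which is
equivalent to testing R != 0.

Extension/retraction events of one frame transition are the connected
components of the polygon difference between the outline at t and at t+1 min
(see :mod:`gliamet.geometry`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .geometry import Contour, ContourSeries, DiffComponent, polygon_difference

GROWTH = "growth"
NO_CHANGE = "no_change"
SHRINKAGE = "shrinkage"

DEFAULT_ALPHA = 0.05
#: um^2; manual tracing implicitly ignores sub-resolution wiggles
DEFAULT_MIN_AREA = 0.1


class InsufficientDataError(ValueError):
    """Too few frames for the requested window."""


class DegenerateWindowError(ValueError):
    """No time variance inside the window."""


class ParameterError(ValueError):
    """Invalid analysis parameter (e.g. alpha outside (0, 1))."""


@dataclass(frozen=True)
class GrowthFit:
    """OLS fit of cell area on time over one window.

    Attributes
    ----------
    slope : float
        Growth rate, um^2/min.
    intercept : float
        Fitted area at t=0, um^2.
    r : float
        Pearson correlation of area vs time, in [-1, 1].
    p_slope : float
        Two-sided p-value of the slope t-test (H0: slope = 0).
    stderr : float
        Standard error of the slope.
    window : tuple of float
        (t_start, t_end) of the frames used, minutes.
    n_frames : int
    """

    slope: float
    intercept: float
    r: float
    p_slope: float
    stderr: float
    window: tuple[float, float]
    n_frames: int

    def classify(self, alpha: float = DEFAULT_ALPHA) -> str:
        return classify_growth(self, alpha)

    def predicted(self, t: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(t, dtype=float)

    def summary(self) -> str:
        lines = [
            "Growth fit (area ~ time, OLS)",
            "-" * 38,
            f"window        {self.window[0]:8.1f} .. {self.window[1]:.1f} min",
            f"n frames      {self.n_frames:8d}",
            f"slope         {self.slope:8.4f} um^2/min (SE {self.stderr:.4f})",
            f"intercept     {self.intercept:8.2f} um^2",
            f"R             {self.r:8.4f}",
            f"p (slope!=0)  {self.p_slope:8.2e}",
            f"class         {self.classify():>8s} (alpha={DEFAULT_ALPHA})",
        ]
        return "\n".join(lines)


def _ols_line(t: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float, float]:
    """Slope, intercept, r, p, slope SE, with well-defined degenerate cases.

    A constant response gives slope 0, r 0, p 1; an exact non-constant line
    gives p 0.  Cross-checked against scipy.stats.linregress in the tests.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(t)
    tm, ym = t.mean(), y.mean()
    sxx = float(np.sum((t - tm) ** 2))
    if sxx == 0.0:
        raise DegenerateWindowError("zero time variance in window")
    sxy = float(np.sum((t - tm) * (y - ym)))
    syy = float(np.sum((y - ym) ** 2))
    slope = sxy / sxx
    intercept = ym - slope * tm
    r = 0.0 if syy == 0.0 else sxy / np.sqrt(sxx * syy)
    rss = max(syy - slope * sxy, 0.0)
    if rss == 0.0:
        # exact fit: the t statistic diverges unless the line is flat
        p = 1.0 if slope == 0.0 else 0.0
        se = 0.0
    else:
        se = np.sqrt(rss / (n - 2) / sxx)
        tstat = slope / se
        p = 2.0 * float(_stats.t.sf(abs(tstat), df=n - 2))
    return slope, intercept, float(np.clip(r, -1.0, 1.0)), p, se


def fit_growth(
    series: ContourSeries,
    window_min: float = 20.0,
    t_start: float | None = None,
) -> GrowthFit:
    """Fit area(t) over the window [t_start, t_start + window_min].

    ``t_start`` defaults to the first frame of the series.  At least 3 frames
    must fall inside the window.
    """
    if window_min <= 0:
        raise ParameterError("window_min must be positive")
    t = series.times
    if t_start is None:
        t_start = float(t[0])
    t_end = t_start + window_min
    mask = (t >= t_start - 1e-9) & (t <= t_end + 1e-9)
    if int(mask.sum()) < 3:
        raise InsufficientDataError(
            f"only {int(mask.sum())} frames in window [{t_start}, {t_end}] min"
            " (need >= 3)"
        )
    tw = t[mask]
    yw = series.areas[mask]
    slope, intercept, r, p, se = _ols_line(tw, yw)
    return GrowthFit(
        slope=slope,
        intercept=intercept,
        r=r,
        p_slope=p,
        stderr=se,
        window=(float(tw[0]), float(tw[-1])),
        n_frames=len(tw),
    )


def fit_area_series(t, areas) -> GrowthFit:
    """Fit a growth line to raw (time, area) arrays (no window selection).

    The array-based twin of :func:`fit_growth`, for area traces that do not
    come with contours (e.g. calibration simulations).
    """
    t = np.asarray(t, dtype=float)
    areas = np.asarray(areas, dtype=float)
    if len(t) < 3:
        raise InsufficientDataError(f"need >= 3 points, got {len(t)}")
    slope, intercept, r, p, se = _ols_line(t, areas)
    return GrowthFit(
        slope=slope, intercept=intercept, r=r, p_slope=p, stderr=se,
        window=(float(t.min()), float(t.max())), n_frames=len(t),
    )


def classify_growth(fit: GrowthFit, alpha: float = DEFAULT_ALPHA) -> str:
    """Classify a fit as ``growth``, ``shrinkage`` or ``no_change``.

    Growth requires a significant positive slope at level ``alpha``,
    shrinkage a significant negative one; everything else is no change.
    """
    if not 0.0 < alpha < 1.0:
        raise ParameterError(f"alpha must be in (0, 1), got {alpha}")
    if fit.p_slope < alpha and fit.slope > 0:
        return GROWTH
    if fit.p_slope < alpha and fit.slope < 0:
        return SHRINKAGE
    return NO_CHANGE


@dataclass(frozen=True)
class EventSet:
    """Extensions and retractions of one frame transition.

    ``net_area_change`` is area(b) - area(a); by the conservation property it
    equals the extension total minus the retraction total of the *unfiltered*
    decomposition, whose residual is reported as ``conservation_error``.
    The ``extensions``/``retractions`` lists exclude components below the
    ``min_area`` floor.
    """

    transition: tuple[float, float]
    extensions: list[DiffComponent]
    retractions: list[DiffComponent]
    net_area_change: float
    conservation_error: float

    @property
    def n_extensions(self) -> int:
        return len(self.extensions)

    @property
    def n_retractions(self) -> int:
        return len(self.retractions)


def detect_events(
    a: Contour,
    b: Contour,
    min_area: float = DEFAULT_MIN_AREA,
) -> EventSet:
    """Detect extension/retraction events between consecutive frames.

    Components smaller than ``min_area`` (um^2) are dropped from the reported
    lists; the conservation identity is evaluated against the unfiltered
    decomposition.
    """
    comps = polygon_difference(a, b)
    ext_all = [c for c in comps if c.sign == "extension"]
    ret_all = [c for c in comps if c.sign == "retraction"]
    net = b.area - a.area
    residual = net - (sum(c.area for c in ext_all) - sum(c.area for c in ret_all))
    return EventSet(
        transition=(a.t, b.t),
        extensions=[c for c in ext_all if c.area >= min_area],
        retractions=[c for c in ret_all if c.area >= min_area],
        net_area_change=net,
        conservation_error=residual,
    )


@dataclass(frozen=True)
class DynamicsSummary:
    """Per-cell event statistics over a run of transitions.

    Rates are events per minute; mean sizes are um^2 and are ``None`` when no
    event of that sign was detected.
    """

    ext_per_min: float
    ret_per_min: float
    mean_ext_size: float | None
    mean_ret_size: float | None
    n_transitions: int


def summarize_dynamics(
    series: ContourSeries,
    window: int = 20,
    min_area: float = DEFAULT_MIN_AREA,
) -> DynamicsSummary:
    """Event rates and mean sizes over the first ``window`` transitions.

    The default of 20 transitions matches analysing 20 time points per cell
    at 1-min sampling.
    """
    if window < 1:
        raise ParameterError("window must be >= 1 transition")
    if series.n_frames < window + 1:
        raise InsufficientDataError(
            f"series has {series.n_frames} frames; window of {window} "
            "transitions needs at least window+1"
        )
    ext_sizes: list[float] = []
    ret_sizes: list[float] = []
    for i in range(window):
        ev = detect_events(series[i], series[i + 1], min_area=min_area)
        ext_sizes.extend(c.area for c in ev.extensions)
        ret_sizes.extend(c.area for c in ev.retractions)
    duration = window * series.dt
    return DynamicsSummary(
        ext_per_min=len(ext_sizes) / duration,
        ret_per_min=len(ret_sizes) / duration,
        mean_ext_size=float(np.mean(ext_sizes)) if ext_sizes else None,
        mean_ret_size=float(np.mean(ret_sizes)) if ret_sizes else None,
        n_transitions=window,
    )


class CellGrowthModel:
    """Model-style front door for one cell's contour series.

    ``fit()`` returns a :class:`GrowthFit` results object; ``dynamics()``
    returns the event-rate summary.  A thin convenience over the module
    functions.
    """

    def __init__(self, series: ContourSeries):
        self.series = series

    def fit(self, window_min: float = 20.0, t_start: float | None = None) -> GrowthFit:
        return fit_growth(self.series, window_min=window_min, t_start=t_start)

    def dynamics(self, window: int = 20, min_area: float = DEFAULT_MIN_AREA) -> DynamicsSummary:
        return summarize_dynamics(self.series, window=window, min_area=min_area)

    def plot_growth(self, ax=None, window_min: float = 20.0):
        """Area-vs-time scatter with the fitted regression line."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        t, a = self.series.times, self.series.areas
        ax.plot(t, a, "o", ms=3, label=self.series.cell_id or "cell")
        fit = self.fit(window_min=window_min)
        tt = np.linspace(*fit.window, 50)
        ax.plot(tt, fit.predicted(tt), "-", label=f"slope {fit.slope:.2f} um$^2$/min")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("area (um$^2$)")
        ax.legend(frameon=False)
        return ax
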