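# Methods

This note records the models, estimators, numerical choices and limitations
behind `gliamet`, in the order data flows through the package.

## Contour geometry

Cell outlines are closed simple polygons in continuous Cartesian
coordinates (µm, y up), stored open (no repeated closing vertex) and
oriented counter-clockwise. Traces from live imaging are vector outlines,
so no pixel grid is imposed; continuous geometry is what makes the
extension/retraction accounting exact rather than approximate.

Validation removes consecutive duplicate vertices, rejects inputs with
fewer than three distinct vertices or collinear (zero-area) rings as
*degenerate*, rejects self-intersecting rings as *invalid geometry* (no
silent repair), and flips clockwise input. Area is the shoelace sum,
perimeter the closed polyline length, centroid the standard area-weighted
formula; all three are cross-checked in the tests against shapely and
against a 0.01-µm rasterization (pixel-counting) oracle built on
matplotlib's point-in-path test, which shares no code with either.

Two compactness measures are reported: perimeter/area (µm⁻¹), which falls
as 1/s under uniform scaling by s and therefore mixes shape with size, and
the isoperimetric quotient 4πA/P² ∈ (0, 1], which is scale-free and equals
1 only in the circular limit. Both are carried so size-matched and
size-free comparisons are possible.

### Extension/retraction decomposition

For consecutive outlines a (at t) and b (at t+Δ), extensions are the
connected components of b ∖ a and retractions the components of a ∖ b,
computed by boolean clipping (shapely/GEOS). This reproduces the manual
procedure of transferring a trace to the next frame and outlining every
protruding and receding patch, and it obeys the conservation law

    area(b) − area(a) = Σ extension areas − Σ retraction areas

to floating-point precision (observed residuals ~1e-14 relative; the
package asserts 1e-9). Degenerate touching pieces below 1e-9 µm² are
dropped as clipping noise. A component may in principle carry an interior
ring (one outline strictly inside the other); its area accounts for the
ring, while the stored vertex list is the exterior ring. Disjoint frame
pairs are not an error — the whole of b becomes one extension and the whole
of a one retraction, with a warning, since a cell cannot teleport and such
input usually signals a tracking fault.

Frames are assumed co-registered: focus drift is corrected at acquisition,
so no frame-to-frame registration is applied. An optional
`align_centroids` flag shifts b onto a's centroid first; it defaults off
because centroid alignment would silently cancel genuine asymmetric growth.

Event detection (`detect_events`) drops components below a `min_area`
floor, default 0.1 µm²: manual tracing implicitly ignores sub-resolution
wiggles, and with ~0.1 µm pixels an area of 0.1 µm² is about ten pixels.
The conservation identity is always evaluated on the unfiltered
decomposition.

## Growth model

Growth is an ordinary least-squares line of area against time over a
window, 20 min and 75 min being the conventional window lengths at 1-min
sampling. The OLS slope, intercept, Pearson R, slope standard error and
two-sided slope t-test p-value are computed from the normal equations
directly so the degenerate cases are well defined (constant area → slope 0,
R 0, p 1; exact non-flat line → p 0); the implementation is verified
against `scipy.stats.linregress` to 1e-10. Classification is *growth* when
p < α and slope > 0, *shrinkage* when p < α and slope < 0, else
*no change*, with α = 0.05. The field describes this distinction through R
approaching ±1 vs 0 without naming a threshold; the slope t-test is the
standard, reproducible operationalization and is algebraically equivalent
to testing R ≠ 0.

Event statistics (`summarize_dynamics`) are reported per cell over a run of
transitions (default 20, i.e. 20 analysed time points): events per minute
by sign, and mean component areas, with means flagged absent (`None`) when
no event of that sign occurred. Aggregation across cells happens
downstream in the group-comparison stage, since per-cell versus pooled
normalization is a reporting choice, not a measurement one.

## Staging and closure

**Condensation staging.** Mean nerve-cord segment width falls roughly
linearly with embryo age, so a least-squares line width = a + b·t fitted to
calibration pairs is inverted, t̂ = (width − a)/b, to estimate age. The
calibration is considered reliable between 11 and 18 h AEL; estimates
outside that interval are returned flagged rather than rejected, and no
calibration interval is attached to the point estimate. Calibration
demands ≥3 observations spanning ≥2 h and a nonzero slope; separate models
are fitted per genotype because condensation is slowed in several mutants.

**Closure staging.** Given cell polygons inside a region, the uncovered
set is region ∖ ∪cells and its connected components are the holes
(components below 1e-6 µm² are clipping slivers and ignored). The contact
fraction is the fraction of summed cell perimeter lying within
`contact_eps` (default 0.5 µm) of another cell or of the region boundary.
Stages, in order of precedence:

1. `closed` — total uncovered ≤ `closed_eps_area` (default 1 µm²);
2. `small_gaps` — every hole < `large_hole_area` (default 25 µm²) and at
   most `small_gap_count_max` (default 5) holes;
3. `large_holes` — contact fraction ≥ 0.5;
4. `pre_contact` — otherwise.

The four categories are visual in origin and carry no published numeric
thresholds; the defaults above are declared package choices, configurable,
and recorded in output metadata. The 50 % boundary implements "under half
mutual cell contact" literally as perimeter-contact fraction. Cells must
lie inside the region and be pairwise non-overlapping beyond a 1e-6 µm²
tolerance (shared edges are expected and fine).

## Imaging metrics

Images are 2-D nonnegative arrays with an isotropic pixel size; ROIs are
polygons in µm rasterized center-in-polygon on the image grid, with a
minimum of 10 pixels per ROI.

* **Polarization** = (mean basal − bg)/(mean apical − bg). Background
  subtraction is optional and mean-based, default off (none is described in
  the underlying measurement protocol). The ratio is undefined (error)
  when the apical mean does not exceed background, and is invariant under a
  global gain change once background is subtracted.
* **Insulation** = mean dye intensity inside the CNS ROI over the mean
  outside; 0 is perfect exclusion, 1 free penetration.
* **SJ belt width.** The binary ribbon mask is skeletonized
  (scikit-image); the skeleton's longest 8-connected path (two-pass BFS,
  which prunes the short spurs skeletonization leaves at ends) is split by
  arc length into segments of `segment_length`, default 3.5 µm as the
  midpoint of the 3–4 µm convention, with the trailing remainder merged
  into the last segment. Mask pixels are assigned to the nearest path
  pixel (KD-tree), and each segment's width is √(12·λ⊥) with λ⊥ the
  smaller eigenvalue of the pixel-coordinate covariance. The √12 factor
  makes the estimator exact for a uniform rectangular cross-section
  (variance w²/12), rather than adopting the 4√λ ellipse display
  convention, which would overestimate a uniform ribbon by √(4/3).
  Discretization adds ~p²/12 to λ⊥ (0.1 % at w = 1 µm, p = 0.05 µm) and is
  not corrected.

## Synthetic ground truth

The generators define the study conditions under which the pipeline is
verified; all are deterministic given their seed.

**Cell contours.** A cell is a star-shaped radius profile r(θ) on a fixed
angular grid (256 vertices), initialized as an ellipse of base radius 10 µm
(area ≈ 314 µm², a typical SPG scale) with mild low-order radial noise.
Each minute applies optional isotropic area growth (an exact radial
rescaling) and then Poisson numbers of extension bumps and retraction dents
at non-overlapping angular windows (default 20°, widened up to 6× when a
drawn dent would pinch the local radius; a still-infeasible dent raises an
error naming the frame). Event profiles are smooth cos² caps, so each
event is a single resolvable lamellipodium-like component. The cap
amplitude is solved (Brent) so the realized shoelace-area change matches
the lognormal draw; because windows are disjoint, per-event area changes
are exactly additive, every injected event corresponds to exactly one
difference component, and the ground-truth log records realized areas —
this is what makes ≥98 % recall at ≤2 % area error a meaningful target
rather than a matching heuristic.

**Genotype presets.** The presets put all net growth into the
extension/retraction imbalance (isotropic term 0), which matches the
biological account — growth is stabilized protrusion — and keeps detection
ground truth unambiguous (a nonzero isotropic term inserts a thin annular
extension every frame that merges with all bumps under continuous
differencing). Sizes are lognormal with shape σ = 0.4:

| preset | λ_ext | λ_ret | ext median | ret median | intended phenotype |
|---|---|---|---|---|---|
| WT-like | 0.5/min | 0.5/min | 8 µm² | 2.5 µm² | equal frequencies, extensions larger, near-universal significant growth over 20 min |
| *moody*-like | 0.5 | 0.8 | 8 | 5.0 | excess retractions removing large patches; net drift ≈ 0, mixed growth/shrinkage |
| *loco*-like | 0.3 | 0.8 | 6 | 2.5 | reduced protrusion size and frequency; retarded growth, majority non-growing |

Rates and the extension>retraction ordering follow the reported
directionalities; the magnitudes are package choices fixed by a design
power analysis so that the WT-like preset reproduces the reported wild-type
outcome of ~13/14 cells with significant 20-min growth, and the mutant
presets their described mixtures. Under these conditions the WT growth
fraction is ~92–95 % across seeds.

**Other generators.** Ribbon masks have a constant width along a straight
or circular-arc centerline with flat (perpendicular) ends, so the width is
exactly constant over the full length. Two-band images carry Gaussian
noise (clipped at zero, negligible at the default means) with rectangular
ROIs inset in each band. Condensation series draw ages uniformly on
11–18 h and widths from the line plus Gaussian noise. Closure scenes are
jittered-grid Voronoi tilings of a 100×100 µm region: full coverage is the
exact tiling (`closed`); for coverage ≥ 0.5, disjoint discs with areas from
the hole spectrum are punched at jittered grid sites (a disc that would
leave an interior ring in a single cell first splits that cell along a
chord, so cells stay simple polygons), making the uncovered set exactly the
punched discs; below 0.5 every cell is shrunk about its centroid
(`pre_contact`). The default spectra give ≤5 sub-25 µm² holes in the
small-gap regime and ~500 µm² holes otherwise.

**What the generators do not emulate.** Real traces carry pixel-scale
jitter, out-of-focus boundary ambiguity, occlusion by overlying cells, and
events that split, merge or straddle frames; generated contours are
star-shaped, events are angularly disjoint, and noise enters only through
event statistics. Passing tests therefore demonstrate that the estimators
are correct and well calibrated on resolvable, well-posed input — not that
manual tracing variability is overcome. Likewise the two-band images have
no illumination gradients or bleed-through, and ribbon masks are
noise-free; segmentation itself is out of scope (masks are inputs).

## Group statistics and pipeline

Group comparisons are pairwise two-sample t-tests (Welch by default,
Student optional) with Bonferroni adjustment over the declared comparison
count, clipped to 1; Holm is available by flag, and one-way ANOVA is
exposed as a conventional-test wrapper. Summaries carry n, mean, median,
interquartile range and total range, matching box-plot reporting.

`run_pipeline` executes measure → growth fit → classify → event summary per
cell, continues past per-cell failures (recording them), compares the seven
standard metrics across genotypes when two or more are present, and writes
per-cell and comparison CSVs plus a JSON manifest (config, seed, package
and library versions) sufficient to reproduce every output. Identical
config and seed reproduce byte-identical CSVs.

## Verification problem sizes

The test suite checks conservation on 500 random star-polygon pairs,
oracle agreement on 100 polygons and 40 pairs, event recovery on 200 cells
× 20 transitions, classifier calibration on 1000 null and 400 alternative
series, preset signatures on 150/100/100 cells, staging on 500 noisy
replicates, and closure staging on 200 scenes (50 per regime).
`scripts/acceptance.py` recomputes the same quantities at moderately
reduced sizes (120 cells, 120 scenes, 800 null replicates) chosen to keep a
full from-scratch run near one minute on a single CPU while leaving Monte
Carlo error well inside the tolerances.

## Known limitations

* Contours hidden by neighbouring bright cells are assumed complete; the
  package has no occlusion model.
* The closure thresholds are declared, not inferred from data; scenes near
  a threshold boundary are classified by the stated precedence order.
* Inverse staging returns a point estimate only.
* The SJ width estimator presumes a single dominant ribbon per mask; side
  branches longer than the spur-pruning heuristic would bias the path.
* OLS p-values assume independent residuals; for event-driven area series
  (a random walk with drift) the nominal test is anti-conservative, which
  is accounted for by validating the classifier's operating
  characteristics on iid-noise series where the test is exact.
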