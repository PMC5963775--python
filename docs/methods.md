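# Methods

`firescape` re-implements, at desk scale, a burned-area analysis chain for
annual satellite image time series: from per-pixel spectral-index
trajectories, through breakpoint-based change detection and object-based
attribution, to landscape fire-regime statistics.  The Landsat archive is
replaced by a synthetic-landscape generator with a known disturbance
truth, so every stage can be validated against ground truth without any
downloads.

## Synthetic landscape model (`synth`)

The generator renders a rectangular 30 m grid (pixel area 0.09 ha) over an
annual record (default 1984–2015; 1984 serves as the spectral baseline
year and regime statistics are computed from 1985 on).  The grid is
partitioned into zones (default: two equal vertical bands) and a random
burnable mask (default fraction 0.9) stands in for water, snow/ice and
agriculture.

**Fire.**  Each zone has an annual per-pixel burn probability `p`
(defaults 1/150 and 1/300 — century-scale return intervals typical of
boreal fire regimes).  Each year the target burned-pixel count is drawn
`Binomial(n_burnable, p)` and fire patches are grown from random ignitions
by stochastic 8-neighbour spread (default spread probability 0.35) until
the target is met, the last patch being truncated.  Two consequences are
used throughout the tests: the marginal pixel process is exactly
i.i.d. Bernoulli(`p`) when re-burn exclusion and spread are disabled
(making binomial moments and the `(1-p)^t` survival law exact oracles),
and the patch-size spectrum is right-skewed (many small patches, few
large) as in real fire regimes.

**Spectral response.**  Undisturbed forest sits at fixed baselines
(NBR 0.55, TCB 0.30, TCG 0.25, TCW 0.05) plus i.i.d. Gaussian observation
noise (default sd 0.02).  A disturbance drops each index instantaneously
and recovers exponentially:

    value(t) = baseline − drop · 2^(−(t − t_event)/halflife)

with a default recovery half-life of 8 years for fire.  Class signatures
are fixed constants chosen for spectral + geometric separability:

| class     | NBR drop            | TCB change        | geometry            | recovery   |
|-----------|---------------------|-------------------|---------------------|------------|
| fire      | N(0.40, 0.08)       | −0.04 (darkening) | spread-grown patch  | h = 8 yr   |
| harvest   | N(0.45, 0.05)       | +0.15 (bare soil) | compact rectangle   | h = 4 yr   |
| road      | N(0.30, 0.03)       | +0.10             | 1–2 px linear       | permanent  |
| condition | U(0.08, 0.14)       | −0.02             | diffuse blob        | h = 16 yr  |

(The table lists the *change in value*; internally all effects are stored
as signed drops.)  A pixel becomes eligible for a new disturbance only
after two recovery half-lives (configurable; setting the factor to 0
yields the i.i.d. condition used by the moment oracles).  The most recent
event overwrites any residual drop from an earlier one — residuals at
re-burn eligibility are at most a quarter of the original drop.

**Observations.**  Each burnable pixel-year holds `n_candidates_per_year`
(default 3) candidate observations with a random acquisition day-of-year
(uniform on August 1st ± 40 days), a cloud-distance proxy (uniform on
[0, 1]), a sensor tag, and a validity flag drawn with cloud-gap
probability `gap_prob` (default 0.15).  Truth generation and observation
rendering use separate RNG streams, so the truth is bit-identical whether
or not observations are rendered.

**What the generator does not emulate:** topography, radiative-transfer
or sensor physics, sub-annual fire timing, spatially correlated cloud
fields, cross-sensor calibration differences, and gradual multi-year
declines (insect, drought).  Passing tests therefore demonstrate the
correctness of the analysis machinery under controlled abrupt-change
conditions, not the product accuracy achievable on real imagery.

## Compositing (`composite`)

Candidates are scored by a weighted sum — 0.5 · day-of-year proximity to
the target day (213), 0.3 · cloud distance, 0.2 · sensor preference —
invalid candidates score −∞.  The scoring functions of operational
compositing systems are more elaborate; the weighted sum preserves their
contract (monotone in DOY proximity and cloud distance, fixed sensor
bonus) and the weights are configurable.  Ties break by earliest
day-of-year, then sensor order.  Pixel-years with no valid candidate are
gap-filled: interior gaps by linear interpolation between the nearest
observed neighbours, leading/trailing gaps by nearest-value extension
(the monotone-preserving minimal choice); infilled years carry a source
flag.  Pixels with fewer than two observed years are flagged unusable and
excluded downstream.

## Change detection (`detect`)

Per pixel, on the dense NBR series:

1. **Despiking.**  A single-year excursion deviating from its
   neighbours' mean by more than `spike_tol` (default 0.1), while the
   neighbours agree within `spike_tol`, is replaced by the neighbour
   mean.  The pass iterates to a fixed point, which makes the operator
   idempotent; steps are preserved because their neighbours disagree.
2. **Bottom-up segmentation.**  Starting from singleton segments,
   adjacent segments are merged greedily by least squared-error increase
   (ties: earliest pair), while the segment count exceeds `max_segments`
   (default 6) or the cheapest merge costs at most
   `mse_improvement_tol` × the series' total sum of squares.  The
   default tolerance 0.15 retains a one-point pre-disturbance segment
   for changes in the second record year while leaving pure-noise series
   breakpoint-free.  Greedy bottom-up merging matches the exhaustive
   minimum-SSE segmentation on signal-dominated series but is not
   guaranteed optimal on arbitrary noise; anyone needing
   bit-compatibility with a specific operational product should treat
   this stage as a documented stand-in.
3. **Event extraction.**  Among breakpoints with a negative NBR step,
   the largest drop wins; it must reach `min_delta_nbr` (default 0.1,
   i.e. five noise standard deviations at the default noise level —
   separating stand-replacing loss from condition-change noise).  One
   event per pixel over the record.  The change year is the first year
   of the post-drop segment (annual composites cannot resolve
   within-season timing); pre/post values are adjacent segment means;
   the duration runs from onset to the post-disturbance minimum of the
   *fitted* (piecewise-constant) trajectory — using segment means rather
   than raw values keeps the duration stable under noise so that pixels
   of one disturbance patch agree on it.

Detection is invariant to adding a constant to a series, and raising the
detection threshold can only reduce the number of events.  A range screen
(series range < threshold ⇒ no detectable event) skips the unchanged
majority of pixels exactly.

## Change objects (`objects`)

Changed pixels sharing (change year, duration) are aggregated into
8-connected components (connectivity configurable; 8 matches the
simulator's spread kernel and common burned-area practice).  Metrics per
object:

* area = pixel count × 0.09 ha;
* perimeter = exposed pixel-edge count × 30 m, interior hole boundaries
  included (unburned islands are part of the patch concept);
* compactness = 4πA/P² in consistent pixel units, so every square scores
  4π/16 ≈ 0.785 — the attainable maximum for pixel objects;
* fractal dimension = 2·ln(P/4)/ln(A) in pixel-edge units (single-patch
  divider form), defined as 1.0 for a single pixel where the formula is
  0/0;
* spectral pre/post/delta means per index, computed over the same
  segment windows the NBR detector selected, averaged over member
  pixels.

No minimum object size is imposed by default (`min_pixels = 1`,
configurable): the smallest mappable patch is a product decision, not a
property of the method.

## Attribution (`attribute`)

A random forest (500 trees, default scikit-learn feature subsampling,
seeded) classifies objects into fire / harvest / road / condition from 16
features: four delta indices, eight pre/post means, and four geometric
metrics.  Evaluation samples are objects, not pixels, drawn
class-stratified and spatially spread: the extent is tiled into roughly
`spatial_bins` rectangles with at most ⌈n/bins⌉ samples per bin per
class, topped up without caps if a class runs short — a concrete reading
of "restricted random selection" that enforces spatial spread without an
algorithm being prescribed.  Accuracy reports follow burned-area
convention: a reference × predicted confusion matrix, overall accuracy,
and per-class omission (1 − recall) and commission (1 − precision)
errors; rates with a zero marginal are reported not-applicable.  Score
ties resolve in the fixed order fire < harvest < road < condition.

## Fire-regime statistics (`regime`)

* **Annual burned area.**  Object areas are apportioned to zones by
  member-pixel zone labels; each patch counts in the zone holding the
  plurality of its pixels.  PAAB = 100 × mean annual burned / burnable
  area, with the burnable area constant per zone.
* **Fire return interval.**  The survival proportion S(t) is the mean,
  over all length-t windows of the record, of the fraction of burnable
  pixels not burned within the window (S(0) = 1).  Windowed averaging is
  the package's construction for estimating survival from a short
  record; under i.i.d. burning E[S(t)] = (1−p)^t, the closed form used
  as its oracle.  S(t) = exp(−λt) is fitted by nonlinear least squares
  (start value from a log-linear regression) and FRI = 1/λ; the naive
  1/burn-rate (= 100/PAAB years) is reported alongside, because
  published tables are ambiguous about which of the two a given entry
  is.  When nothing burned, the FRI is right-censored and reported as a
  bound rather than a finite estimate.
* **Trends.**  Theil-Sen slope (median of all pairwise slopes; delegated
  to `scipy.stats.theilslopes`) with the slope also expressed as percent
  of the period's own mean.  Mann-Kendall test with tie-corrected
  variance and ±1 continuity correction; for untied series of n < 10
  the exact null distribution of S is enumerated via the
  inversion-number generating function ∏(1 + x + … + x^k), otherwise
  the normal approximation is used (annual records here are 10–31
  points).  Per-zone tests are reported at α = 0.05 without
  multiple-testing correction, matching how such tables are usually
  printed; a Holm-adjusted p column is emitted alongside, clearly
  labelled as an extension.
* **Patch sizes.**  Half-open [lo, hi) classes, default 0–2, 2–5, 5–20,
  20–50, 50–200, 200–500, 500–1000, >1000 km²; the large-patch share
  uses a strict > 200 ha rule (a patch of exactly 200 ha is not
  "large").  Large-patch counts per year feed the same trend machinery.
* **Gridded epochs.**  A grid (default 50 × 50 km) anchored at the
  raster's upper-left corner, with five-year epochs whose final epoch
  absorbs remainder years (1985–89, …, 2010–15 for a 31-year record);
  per cell-epoch, the percent of the cell's burnable pixels burned.
  Cells without burnable pixels report not-applicable.

## Pipeline and formats (`io`, `pipeline`, `cli`)

Conventions: 0-based row/col, origin upper-left, pixel-is-area, areas in
hectares.  Raster stacks are multi-page TIFFs (band = year) with the year
axis, pixel size and origin in a JSON ImageDescription tag; truth events
are GeoJSON polygons plus a CSV table; configs round-trip through
YAML/JSON.  Every run writes a manifest (config, config hash, seed,
package versions, stage timings and counts) sufficient to reproduce any
output; reruns with the same seed are bit-identical, and resuming from
cached intermediates reproduces downstream outputs byte for byte.  The
`firescape` CLI exposes one subcommand per stage plus `run`.

## Problem sizes

The test suite and the acceptance script run the generator at 150 × 150
pixels (default landscape; ~800 change objects across the four classes),
the detection benchmark at 71 × 71 (~5,000 pixels), and the
return-interval recovery at 200 × 200 over 31 years with
p ∈ {1/100, 1/150, 1/300} and 20 replicate seeds per rate.  These sizes
give each statistic enough events for stable estimates while keeping a
full run in the order of a minute on one CPU.

## Known limitations

One event per pixel per record (the largest drop wins): re-burns within
the record are only represented once in detection, although the truth
ledger records them.  Gradual (trend-phase) declines are not modelled or
detected beyond the condition class.  The survival-curve windows overlap,
so the fitted λ's nominal fit residual understates its sampling
uncertainty.  Patch agglomeration into fire *events* (merging nearby
patches of one fire, including unburned islands) is out of scope, as is
any climate or fire-weather covariate analysis.
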