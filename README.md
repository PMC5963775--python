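# firescape

Burned-area mapping from annual satellite image time series, at desk
scale.  `firescape` implements the full analysis chain used to
characterise fire regimes from 30 m annual composites — per-pixel
spectral trajectories, breakpoint change detection, object-based change
attribution, and regime statistics — with a synthetic-landscape
generator standing in for the image archive, so every stage runs and is
testable on a laptop with known ground truth.

It is aimed at remote-sensing and landscape-ecology researchers who want
a transparent, seedable reference implementation of this kind of
pipeline: to study its statistical behaviour, to benchmark alternative
detectors or classifiers against a controlled truth, or to teach how
burned-area products and fire-regime tables are built.

## What it computes

* **Synthetic landscapes** (`firescape.synth`): multi-year 30 m grids
  with zone-dependent annual burn probability *p*, spread-grown fire
  patches, harvest / road / condition-change events, exponential
  post-disturbance recovery `NBR(t) = baseline − drop·2^(−Δt/h)`, cloud
  gaps, and a complete truth ledger.
* **Best-available-pixel composites** (`firescape.composite`): score
  candidate observations (day-of-year proximity, cloud distance, sensor
  preference), keep the best per pixel-year, gap-fill to dense annual
  series.
* **Change detection** (`firescape.detect`): despiking, bottom-up
  merging of segments under a squared-error criterion, extraction of the
  largest abrupt NBR loss per pixel (year, duration, magnitude ΔNBR).
* **Change objects** (`firescape.objects`): 8-connected aggregation of
  changed pixels by (year, duration); area, perimeter, compactness
  4πA/P², fractal dimension 2·ln(P/4)/ln(A), spectral pre/post/delta
  means.
* **Attribution** (`firescape.attribute`): random-forest labelling into
  fire / harvest / road / condition, spatially restricted stratified
  reference sampling, and accuracy reports with per-class omission and
  commission errors.
* **Fire-regime statistics** (`firescape.regime`): annual burned area
  per zone; percent annual area burned (PAAB = 100·mean burned /
  burnable); fire return interval as the mean of a negative-exponential
  fit S(t) = e^(−λt) to the surviving-area proportion, FRI = 1/λ,
  alongside the naive 1/burn-rate; Theil-Sen slopes with Mann-Kendall
  significance (tie-corrected variance, exact small-sample null);
  patch-size distributions with large-patch (> 200 ha) shares and
  trends; and 50 × 50 km five-year-epoch grids.

See `docs/methods.md` for the model, parameter defaults, and numerical
choices.

## Worked example

Run the default two-zone landscape (150 × 150 pixels, 1984–2015, burn
probabilities 1/150 west and 1/300 east) through the whole chain:

```python
import pandas as pd
from firescape.config import RunConfig, LandscapeConfig
from firescape.pipeline import run_pipeline

config = RunConfig(landscape=LandscapeConfig(seed=1), seed=1)
out = run_pipeline(config, "example_run")
print(pd.read_csv(out / "zone_stats.csv")[
    ["zone", "mean_burned_ha", "sd_burned_ha", "paab_pct",
     "fri_naive_yr", "fri_fit_yr"]].round(3))
```

```
   zone  mean_burned_ha  sd_burned_ha  paab_pct  fri_naive_yr  fri_fit_yr
0  west           5.629         0.968     0.619       161.507     148.371
1  east           2.889         0.782     0.317       315.141     301.403
```

The west zone was generated with an annual burn probability of 1/150 and
the fitted fire return interval recovers 148 years; the east zone
(p = 1/300) fits 301 years.  The naive 1/burn-rate estimates sit a few
percent above the exponential fits, as expected when detection misses a
small fraction of burned pixels.  The attribution stage reports a
held-out confusion matrix (`accuracy_report.csv`); on this run the
overall accuracy is 98%, with fire omission and commission both 0% and
the only confusion between road and harvest.

The same chain is available from the shell:

```bash
firescape init-config config.yaml
firescape run --config config.yaml --outdir example_run --seed 1
```

Each run writes `zone_annual.csv`, `zone_stats.csv`, `trends.csv`,
`survival_curve.csv`, `patch_sizes.csv`, `grid_epoch.csv`, truth vectors
(GeoJSON/CSV), and a `manifest.json` that records the exact
configuration, seed and versions; reruns with the same seed are
bit-identical.

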