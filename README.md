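# nightglow

Trend detection in nighttime-lights satellite composites that carry **no
onboard calibration**. The DMSP/OLS "stable lights" archive — annual
cloud-free composites from 1992 onwards, 6-bit digital numbers (DN 0–63) at
nominally 1 km — is the only multi-decade record of artificial light at
night, but its six satellites have different, drifting sensor responses and
small geolocation errors, so raw DN cannot be compared across years.
`nightglow` implements a robust pipeline that makes those comparisons
possible, for researchers studying light pollution and its ecological and
health impacts:

1. **Geolocation correction** — each year's image is shifted over every
   integer offset in [−5, +5]² (121 candidates) and correlated with the
   previous corrected image; the offset maximizing Pearson r is applied.
2. **Robust intercalibration** — every satellite-year *t* is mapped onto the
   scale of a base year by 6th-order polynomial **quantile regression on the
   median**, fitted within a calibration window:

   *DN*₍base₎ = c₀,ₜ + c₁,ₜ·*DN*ₜ + … + c₆,ₜ·*DN*ₜ⁶ ,

   minimizing Σ|residual| rather than Σresidual². Because the conditional
   median has a breakdown point of 0.5, up to half of the calibration pixels
   may undergo genuine brightness change without biasing the curve — no
   "no-change region" assumption is needed, only that changes are localised.
   The base year is the one with the highest proportion of window pixels at
   DN 0 plus DN 63, and calibrated values are truncated to [0, 63].
3. **Change detection** — the difference of mean composites for two epochs
   (default 2005–2010 minus 1995–2000) is classified with a strict ±3 DN
   threshold (increase iff diff > +3, decrease iff diff < −3); pixels
   saturated throughout both epochs are masked as undetectable; contiguous
   same-sign pixels form discrete change patches; regions of interest get
   area proportions and annual mean brightness series.

Because no public archive snapshot ships with the package, a first-class
**synthetic benchmark generator** emulates the data structure — static
scene, per-satellite monotone saturating gain curves, ±3-pixel jitter,
additive noise, 6-bit quantization, dual-satellite years, planted change
events — so every stage can be scored against known ground truth.

The stages are scikit-learn-style estimators (`ShiftAligner`,
`MedianIntercalibrator`, `ChangeDetector`) with thin functional wrappers,
plus a `nightglow` CLI (`simulate | align | calibrate | change | summarize |
run-all`).

## Worked example

```python
import nightglow as ng

spec = ng.SceneSpec(shape=(160, 160), years=(1992, 2010), seed=7)
config = ng.RunConfig(scene=spec, out_dir="demo")
result = ng.run_pipeline(config)

print("base year:", result.base_year)
inc = sum(p.change_class == "increase" for p in result.patches)
print(f"{inc} increasing / {len(result.patches) - inc} decreasing patches")
rep = result.recovery
print("shift recovery rate:", rep.shift_recovery_rate)
print("false-positive area fraction:", round(rep.false_positive_fraction, 4))
for s in result.summaries:
    if s.region_id == "all_land":
        print(f"all land: prop_increase={s.prop_increase:.4f}, "
              f"prop_decrease={s.prop_decrease:.4f}")
```

prints

```
base year: 2000
7 increasing / 4 decreasing patches
shift recovery rate: 1.0
false-positive area fraction: 0.0
all land: prop_increase=0.0179, prop_decrease=0.0170
```

Reading the numbers: the year 2000 image had the largest fraction of
calibration-window pixels pinned at DN 0 or DN 63 and became the reference
scale; the benchmark's planted brightening/dimming discs were recovered as
7 + 4 contiguous patches; every planted geolocation jitter was recovered
exactly; no pixel outside a planted event was classified as change; and
about 1.8% / 1.7% of land area lies in patches brighter / dimmer by more
than 3 DN between the two epochs. The run directory `demo/` holds the
corrections, calibration-model and patch tables (CSV), change maps
(GeoTIFF), the per-region summary, a recovery report scored against the
generator's ground truth, and a manifest with input checksums.

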