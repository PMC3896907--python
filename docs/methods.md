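# Methods

## The estimation problem

Annual "stable lights" composites record brightness as 6-bit digital
numbers (DN 0–63). Three properties of the record make naive year-on-year
differencing meaningless: the sensors have no onboard calibration and their
gain is adjusted in flight, so each satellite-year sits on its own unknown
monotone DN scale; images of the same region can be mutually offset by up to
about 3 pixels; and bright urban cores saturate at DN 63, where no trend is
observable. The pipeline addresses each in turn and only then differences
epoch means.

## Geolocation correction

Every image is compared with the previous *corrected* image at each integer
offset (dx, dy) ∈ [−5, +5]², i.e. 121 candidates for the default search
radius 5. Each candidate is scored by the Pearson correlation over the
jointly valid overlap — nodata (sea) pixels and the margins vacated by the
trial translation are excluded, since they contain no data. The maximizing
offset is applied by translating the data within the fixed grid (the
geotransform is untouched; vacated margins become nodata). Ties are broken
toward the smallest offset magnitude, then lexicographically by (dy, dx):
absent evidence, the null correction is preferred. Alignment is *chained* —
year t is registered against the already-corrected year t−1, anchored at the
earliest year — matching a consecutive previous-image comparison; an
"anchor" mode registering everything to the first year is available
(`ShiftAligner(mode="anchor")`) for long series where chaining could drift.
Only integer-pixel shifts are estimated; the product's geolocation error is
integer-valued at the composite grid scale, and sub-pixel registration is
out of scope.

## Intercalibration by median quantile regression

Year t is mapped to the base-year scale by DN_base = Σₖ cₖ,ₜ·DN_tᵏ,
k = 0…6 (seven coefficients; a 6th-order polynomial requires seven
constants). The coefficients minimize the sum of absolute residuals over
calibration-window pixels valid in both images — quantile regression at the
median. The estimator's insensitivity to outlying conditional values is the
point: pixels that genuinely brightened or dimmed inside the window act as
outliers in the (DN_t, DN_base) cloud, and the conditional median ignores
them as long as they are a minority at each DN level. The window must span
the full DN range — dark rural land through saturated cores — so DN 0 and
DN 63 pixels are deliberately included in the fit; without them the
polynomial is unconstrained at the ends of the scale.

Numerics: the DN axis is rescaled to [0, 1] before the degree-6 Vandermonde
design is built (raw 63⁶ monomials make the design numerically singular);
reported coefficients are mapped back to the raw-DN basis by cₖ → cₖ/63ᵏ.
The L1 problem is solved as a linear program in its dual form
(max yᵀa s.t. Vᵀa = ½·Vᵀ1, a ∈ [0,1]ⁿ) with the HiGHS solver; the primal
coefficients are the equality-constraint duals. The dual LP was chosen over
iteratively-reweighted least squares because the IRLS iteration cycles on
calibration data with heavy ties (integer DN with large point masses at 0
and 63), while the LP is exact and solves a 20,000-pixel window in under a
second; the IRLS route is retained as an alternative solver and as an
independent cross-check in the tests. An exact-interpolation shortcut
handles degenerate inputs (a year calibrated against itself) where zero
residuals defeat both solvers' assumptions.

The base year is the year whose window has the highest proportion of valid
pixels at DN 0 plus DN 63 (ties → earliest year; the sum rule is one
reading of "both zero and 63" — a `combine="min"` alternative is provided).
Anchoring there means no other year is stretched beyond the detection floor
or saturation. Calibrated values are truncated to [0, 63] and kept
real-valued: re-quantizing to integers would discard precision that the
±3 DN epoch differencing needs. In years observed by two satellites, both
are calibrated and compared (`dual_satellite_check` reports pixelwise bias
before and after, over jointly valid unsaturated pixels); the most recent
satellite's product — by explicit precedence list, default the trailing
number of the label — represents the year downstream.

## Change detection and summaries

Epoch means are pixelwise arithmetic means over each epoch's years, with
nodata propagated if any year is missing. A pixel is masked as saturated
only if it reads ≥ 63 − 10⁻⁶ in *every* year of both epochs: any
unsaturated year carries trend information. Classification uses strict
inequalities (diff > +3 → increase, diff < −3 → decrease; exactly ±3 is no
change). Patches are connected components within each class —
8-connectivity by default, which suits blob-like lit areas; 4-connectivity
is a parameter — ordered deterministically by top-left member pixel.
Region summaries report proportions with two denominators (all land, and
unsaturated land only), since either convention is defensible; land is
defined by the nodata mask, with no auxiliary land-cover product in scope.

## The synthetic benchmark

The generator emulates exactly the statistical structure the method
assumes, with known ground truth for scoring:

* **Scene**: dark background, 25 Gaussian urban blobs (20% with peaks of
  160–260 radiance units, saturating every default sensor; the rest 15–85),
  120 dim "villages" (peaks 2–10), a 12% sea margin carried as nodata. One
  saturating core is pinned at the calibration-window centre so the window
  always spans the full DN range. Radiance is in arbitrary linear units
  scaled so a unit maps to roughly one DN at the dark end.
* **Changes**: 12 well-separated discs (radius 2–6 px) by default — dimming
  events centred on moderately lit blobs, brightening events on dark land —
  switching on at a planted onset year (step change, persisting). Planted
  footprints must stay a minority of land pixels, or the spec is rejected:
  the calibration's breakdown assumption is part of the study conditions.
* **Sensors**: per-satellite gain A·(1 − exp(−r/τ)) clipped at 63 —
  monotone and saturating, the minimal structure the intercalibration must
  invert — with defaults F10 (75, 55), F12 (90, 70), F15 (70, 50) over
  1992–2010 and two-year overlaps at the handovers. Gaussian noise
  (default sd 0.5 radiance units — a free choice, the sensors' noise
  magnitude is not characterized anywhere authoritative) is added in
  radiance before the gain curve and 6-bit quantization. Each year draws an
  integer jitter in [−3, +3]² (first year pinned at zero so the truth frame
  equals the anchor frame); both satellites of an overlap year share the
  year's jitter, geolocation error being a property of the year's
  compositing rather than the sensor.
* Reproducibility: a single seed drives per-purpose, per-year, per-satellite
  substreams, so any year can be regenerated in isolation.

What the generator does **not** emulate: skyglow physics, cloud and
moonlight screening, intra-annual compositing, spatially correlated noise,
gradual (non-step) trends, and sensor spectral response differences.
Passing recovery tests therefore shows the pipeline inverts the distortions
it models — not that real-archive artifacts beyond these are handled.

## Recovery scoring

With ground truth present, a run reports: the fraction of planted jitters
recovered exactly (the correction applied to year t must equal minus the
planted jitter, since the anchor frame is the truth frame); the maximum
deviation over DN 0–60 between each fitted calibration curve and the true
sensor-to-sensor map g_base(g_t⁻¹(DN)); per event, the overlap of its
footprint with correct-sign classified pixels, and the onset year inferred
from the footprint's annual mean series; and the classified area outside
all planted footprints as a fraction of land. Onset inference uses a
minimal sustained-departure rule — the first year whose mean departs from
the pre-period median by more than a tolerance (default 2 DN) and stays
departed with one sign — an artifact extension for automated scoring, not a
claim about the underlying method.

## Default parameters

| parameter | default | units | rationale |
|---|---|---|---|
| search radius | 5 | px | covers the ≤3 px geolocation error with margin; 121 candidates |
| min overlap | 64 | px | below this a correlation is too unstable to rank offsets |
| polynomial degree | 6 | — | flexible enough for smooth monotone gain ratios without oscillation on 64 levels |
| epochs | 1995–2000, 2005–2010 | years | six-year means average over gain adjustments and noise |
| change threshold | 3.0 | DN | separates real change from residual calibration noise (~0.5 DN) |
| connectivity | 8 | — | blob-like lit areas; 4 available |
| noise_sd | 0.5 | radiance | free choice; ~½ DN at the dark end, comparable to quantization noise |
| jitter_max | 3 | px | the product's documented geolocation error bound |
| onset tolerance | 2.0 | DN | departures must exceed epoch-mean noise to count |

Benchmark problem sizes (256×256 default scene, 160×160 and smaller in the
test suite, 20,000-pair calibration sets in the robustness experiments) are
the package's chosen study conditions: large enough that window fits see
thousands of pixels per DN level and small enough to iterate on freely.

## Known limitations

* Integer-pixel registration only; rotation/scale errors are out of scope.
* Chained alignment can in principle accumulate drift over very long series;
  the anchor mode avoids this at the cost of lower overlap correlation.
* The calibration is relative (to a base year), never absolute radiometric
  calibration — the sensors' unlogged gain adjustments make that impossible.
* Saturated-throughout pixels are undetectable by construction; trends in
  bright urban cores are not estimated.
* Breakdown of the median fit is a per-DN-level property; adversarial
  contamination concentrated at a single DN level can bias the curve locally
  at fractions below 0.5 of the whole window.
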