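# Methods

This note documents the statistical conventions, default parameters and
design choices behind microstab, in the package's own words. It states
no empirical result that the test suite or `scripts/acceptance.py` does
not itself compute.

## Calibration

The calibration line is fit by weighted least squares with the weight
multiplying the squared residual; `"1/x"` means wᵢ = 1/xᵢ, the dominant
bioanalytical convention for that label. Each replicate response enters
the regression as its own point rather than being averaged per level,
preserving the degrees of freedom behind the intercept standard error
that the ICH LOD/LOQ formulas consume. The fit itself is delegated to
statsmodels WLS; tests verify it against an independently written
normal-equation solver to 1e-9 relative tolerance.

r² for a weighted fit is the weighted coefficient of determination,
1 − SSE_w/SST_w with SST_w taken about the weighted mean. This is the
standard WLS convention, reduces to the OLS r² at equal weights, and is
exactly 1 on noiseless collinear data.

Back-calculated concentrations may be negative for sub-blank responses
and are returned as-is; truncating at zero would bias accuracy
statistics, so any clipping is left to the caller.

Degenerate designs (fewer than three distinct levels, or zero variance
in x) and 1/x-type weighting with non-positive concentrations raise
typed errors rather than producing numbers.

## Validation battery

%RSD is 100·SD/mean with the n − 1 sample SD; recovery − 100 equals %E
by construction, which the tests assert as an identity. Pass thresholds
default to 15% for |%E| and %RSD, relaxed to 20% at the LLOQ; the
guideline the battery follows names no numbers in the reproduced
tables, so both thresholds are configurable. All internal computation is
full precision; rounding (half-up) happens once, at report emission.

When the battery is evaluated from printed summary tables rather than
raw replicates, the recomputed %E/%RSD can differ from published cells
by the quantization of the two-decimal printed means and SDs — up to
about ±0.5 percentage points at a 1 ng/mL level. Tests compare such
cells with a quantization-derived tolerance instead of pretending the
printed values carry hidden precision.

## Depletion kinetics

Percent remaining is normalised to the measured time-zero replicate
mean (replicates are averaged per timepoint before normalisation), so
the t = 0 point is exactly 100% and its ln is ln 100 ≈ 4.605. The
ln-linear fit is unweighted OLS on (t, ln %remaining) within the chosen
window.

Window choice: `fixed_window` (default 0–25 min, the conventional
early-segment choice for curves that flatten late) or `auto`, which
scans every contiguous prefix of at least four points and takes the one
maximising r². Ties within 1e-9 — which arise on noiseless
single-exponential data, where every prefix is collinear — resolve to
the longest window. Neither mode is claimed to replicate how any
particular published window was chosen by its authors.

Half-life uses full-precision ln 2, while the intrinsic-clearance
scaling uses the conventional printed factor 0.693. Keeping both
conventions reproduces published half-life and clearance values
simultaneously; the relative discrepancy (2×10⁻⁴) is far below
reporting precision. Default human scaling constants: 1 mL incubation
per mg microsomal protein, 45 mg protein per g liver, 26 g liver per kg
body weight (product 1170).

The bundled reference time-course carries a known internal
inconsistency: its prose rate constant (0.0383/min) disagrees with its
printed regression equation (slope −0.04479/min), and only the equation
value is consistent with the printed half-life via t½ = ln 2/|slope|.
The package adopts the equation value. Separately, refitting from means
printed at two decimals reproduces that slope only to ~±0.0005; the
derived t½ (15.53 min) and Clint (52.20 mL/min/kg) therefore differ
from the published 15.48/52.39 by the same rounding propagation, while
feeding the published slope itself through the pipeline reproduces both
published values exactly at two-decimal reporting.

Clearance banding: the usual DMPK grading is phrased on in-vitro
half-life (stable beyond 60 min, rapid below 30 min); mapped through
the default scaling these become Clint edges of 13.5 and 27 mL/min/kg,
used as configurable defaults since no numeric cut-offs are printed in
the reproduced report. Values exactly on an edge classify upward.

Negative-control check: a profile is flagged non-depleting when the 95%
two-sided confidence interval of its ln-linear slope contains zero *or*
the point estimate implies less than 5% loss over the 60 min incubation
(|slope| < −ln 0.95/60 ≈ 8.5×10⁻⁴/min). The equivalence clause exists
because a pure significance test has exactly its nominal 5% false-alarm
rate regardless of how small the noise is, and would also flag
practically irrelevant trends as depletion at low noise; "no meaningful
change" is a statement about magnitude as well as significance. Exactly
constant profiles (zero residual variance) are flagged non-depleting.

CSL = k_total/(k_total + k_w) is a pure aggregation of externally
supplied rate constants; the package does not predict per-atom
reactivities.

## Greenness

The eco-scale is the weighted arithmetic mean of the twelve sub-scores.
The reference tool's internal rounding is unpublished; recomputing from
sub-scores displayed at two decimals reproduces its published overall
value only to about ±0.02, and tests state that tolerance explicitly
rather than asserting hidden agreement. The clock pictogram is reduced
to a per-principle colour-band table with configurable thresholds; no
graphics fidelity is claimed.

## Synthetic data

The generator emulates the reproduced study's design: eight calibration
levels over 1–3000 ng/mL on a 1.035x + 0.8911 response line, four QC
levels (1, 3, 900, 2400 ng/mL), and first-order depletion from
380.45 ng/mL with a 15.48 min default half-life sampled at 0, 2.5, 5,
7.5, 15, 20, 25, 30, 45, 60 min with three replicates. Noise is
lognormal with a stated CV (default 5%) and unit mean, keeping
concentrations positive; additive and mixed noise are available. An
optional non-depleting fraction f (default 0) yields
C(t) = C₀[(1−f)e^(−kt) + f], reproducing the late-time flattening real
microsomal curves show and motivating the 0–25 min window. The
no-cofactor negative control is a constant mean with replicate noise.

Generated data are byte-identical under a fixed seed; per-generator
streams are derived from the seed with a stable CRC32-based spawn key
so calibration, QC and depletion draws are independent.

What the generator does *not* emulate: chromatographic peak shape and
integration error, carry-over, matrix-dependent ionisation drift,
inter-day instrument drift, non-first-order (saturating) kinetics, and
correlated replicate errors. Tests passing on synthetic data therefore
demonstrate the correctness of the statistical pipeline under its own
assumptions, not instrument-level robustness.

## Problem sizes and runtime choices

Monte-Carlo checks use 200 seeded runs for parameter-recovery and
negative-control properties and 500 simulated curves for the
weighting-comparison and slope-bias checks — sizes at which the binomial
noise on the asserted proportions is comfortably below the asserted
margins while the full suite stays fast on a single CPU.

## Known limitations

* Michaelis–Menten kinetics are out of scope; the depletion model
  assumes the substrate stays well below K_m.
* Clearance banding beyond Clint (hepatic extraction, blood-flow
  models) is not implemented.
* The greenness module aggregates sub-scores it is given; it does not
  derive sub-scores from method facts (flow rate, solvent fraction).
* Stability-condition evaluation consumes summary tables; raw
  condition-level replicates are supported only through the same QC
  schemas.
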