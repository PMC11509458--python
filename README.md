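# microstab

Quantitative toolkit for in-vitro metabolic-stability studies run on
LC-MS/MS: weighted calibration with ICH detection limits, the FDA-style
bioanalytical validation battery, substrate-depletion kinetics with
well-stirred intrinsic clearance, composite-site-lability scoring, and a
twelve-principle green-analytical-chemistry (AGREE-style) eco-scale —
plus a synthetic-data generator that produces every input with known
ground truth.

It is written for DMPK and bioanalytical scientists who have the
standard outputs of a microsomal stability study — calibration response
ratios, QC replicates, peak-area groups, concentration–time tables — and
want the downstream statistics computed reproducibly instead of in a
spreadsheet.

## The model

**Calibration.** The response ratio y (analyte peak area / internal
standard peak area) is fit against nominal concentration x (ng/mL) by
weighted least squares, minimising Σ wᵢ(yᵢ − a xᵢ − b)² with wᵢ ∈
{1, 1/xᵢ, 1/xᵢ²}. 1/x weighting is the usual choice for curves spanning
three decades with proportional noise. Detection limits follow the ICH
intercept-SE convention: LOD = 3.3·SD(b)/|a|, LOQ = 10·SD(b)/|a|.

**Validation battery.** Accuracy %E = 100(mean − nominal)/nominal,
precision %RSD = 100·SD/mean (sample SD, n − 1), recovery =
100·mean(B)/mean(A), matrix effect ME = 100·mean(matrix)/mean(neat), and
the IS-normalised matrix effect ME_analyte/ME_IS. QC levels pass at
|%E|, %RSD ≤ 15% (20% at the LLOQ); thresholds are configurable.
Stability-condition QCs (long-term, auto-sampler, freeze–thaw,
short-term) reuse the same battery.

**Depletion kinetics.** Percent remaining is normalised to the measured
time-zero mean; ordinary least squares on (t, ln %remaining) over the
log-linear window (default 0–25 min, or automatic prefix selection by
r²) gives the depletion rate constant k. Then

    t½    = ln 2 / |k|                                   [min]
    Clint = (0.693 / t½) · (mL/mg) · (mg/g liver) · (g liver/kg)
                                                          [mL/min/kg]

with default human scaling 1 mL/mg × 45 mg/g × 26 g/kg = 1170. Clint is
banded low / intermediate / high (defaults at 13.5 and 27 mL/min/kg,
the 60 and 30 min half-life cut-offs mapped through the scaling). The
composite site lability CSL = k_total/(k_total + k_w) summarises
predicted P450 lability, where k_w is the water-formation rate constant.

**Greenness.** Twelve principle sub-scores sᵢ ∈ [0,1] with integer
weights aggregate as Σ sᵢwᵢ / Σ wᵢ, banded at ≥ 0.75 for high greenness.

## Worked example

The bundled reference tables include a dovitinib microsomal depletion
time-course (time-zero mean 380.45 ng/mL, three replicates averaged per
point):

```python
from microstab import DepletionKinetics, load_reference_tables

tables = load_reference_tables()
est = DepletionKinetics().fit(
    tables["depletion"][["time_min", "mean_conc_ng_per_ml"]]
)
print(f"slope k : {est.slope_:.5f} per min (r2 = {est.r_squared_:.4f})")
print(f"t1/2    : {est.t_half_:.2f} min")
print(f"Clint   : {est.clint_:.2f} mL/min/kg -> {est.clearance_class_}")
```

prints

```
slope k : -0.04462 per min (r2 = 0.9919)
t1/2    : 15.53 min
Clint   : 52.20 mL/min/kg -> high
```

The slope is the first-order depletion rate constant over the 0–25 min
log-linear segment (seven points); r² confirms log-linearity. The
half-life and the well-stirred intrinsic clearance classify the compound
as high-clearance on the default human banding. (Refitting from means
printed at two decimals shifts the slope by ~0.4% relative to a fit on
the unrounded data.)

The same pipeline runs from the shell:

```bash
microstab stability --in depletion.csv --window 0:25
microstab run-study --config study.yaml --out report.json
microstab simulate depletion --seed 7 --out sim/
```

`run-study` executes calibrate → QC battery → matrix effect → depletion
kinetics → greenness for whichever tables the YAML config provides and
emits a deterministic JSON report (rounded half-up only at emission).

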