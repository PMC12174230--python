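# Methods

## Quantification model

A SPECT/CT activity volume is converted to body-weight SUV,
`SUV = C[Bq/mL] · weight[g] / A(t)[Bq]`, with the injected activity
decay-corrected to acquisition start, `A(t) = A₀·2^(−t/T½)` (Lu-177
T½ = 6.647 d, In-111 T½ = 2.805 d; configurable). Lean-mass
normalisation is not offered.

The reference region is the largest sphere inscribed in a skeletal-muscle
mask, capped at 5 cm diameter. Placement maximises the Euclidean distance
from a voxel center to the mask exterior (computed by an exact distance
transform; the grid boundary counts as exterior), with ties broken by the
lowest linear voxel index so placement is deterministic. Membership of a
voxel in any region — the sphere or the segmentation — is decided by its
center, with no partial-volume weighting; this makes every quantity
exactly reproducible against brute-force oracles.

Background statistics use the sample SD (n−1). The segmentation keeps
every voxel with `SUV ≥ mean + k·SD` (inclusive, default k = 2),
restricted to a body mask when given, with **no** connected-component
filtering: physiological uptake in kidneys, spleen and the urinary tract
contributes to body retention and is deliberately retained. The
total-uptake index is `SUVmean(segment) × volume(segment in mL)`
(SUV·mL), equal to `Σ SUV · voxel volume`; it is additive over disjoint
masks and scales linearly with the SUV field.

Masks must share the volume's grid exactly; this package performs no
resampling or inter-scan registration.

## Dose-rate model and prediction chain

Pooled ordinary least squares with intercept:

    LateEDR[µSv/h] = a₁·LUTtotal + a₂·(dose/BW)[MBq/kg] + c + ε

Repeated cycles from the same patient are pooled without a clustering
adjustment — a deliberate replication of the original analysis design and
a known limitation. Inference is t-based (two-sided p, 95% CI on
n−p−1 df); standardized β = coefficient × sd(x)/sd(y) with sample SDs
(the population/sample choice cancels in the ratio); VIFⱼ = 1/(1−R²ⱼ)
from auxiliary regressions, with perfect collinearity reported as
infinite rather than raising. p values below 10⁻⁴ print as "< 0.0001".

The cross-tracer bridge `LUTtotal = b₁·OCTtotal + b₀` is a simple OLS on
paired scans (the two tracers share strong SSTR2 affinity, which is what
makes the pretreatment scan informative). Substituting the bridge into
the dose-rate model at a fixed planned activity D (default 7400 MBq)
gives the two-variable pretreatment predictor

    predict(OCT, BW) = a₁·(b₁·OCT + b₀) + a₂·D/BW + c .

The intercept is retained throughout. Coefficients are data: the
published source for this procedure rendered its fitted equations as
unreadable figures, so no numeric coefficients are (or can honestly be)
hard-coded; a site fits its own cohort and freezes the result as JSON.

Evaluation: RMSE and MAE in µSv/h; Bland–Altman bias and limits of
agreement `bias ± 1.96·SD` of paired differences; release classification
`EDR ≤ limit` with the limit **inclusive** (default 18 µSv/h, the
Japanese criterion) and configurable as a scalar.

## Synthetic data: what it emulates

**Phantoms.** A box body mask (grid inset by a margin, default 9 mm)
filled with Gaussian background noise (default mean 0.1 SUV, SD 0.05,
the scale of gluteal muscle on a post-therapy scan), plus disjoint hot
spheres for a tumour (SUV 8), kidneys (4), spleen (3) and bladder (6),
rasterized by voxel-center inclusion. Grid 96×96×64 at 3 mm isotropic.
Ground truth reports the *rasterized* compartment volumes, so on a
noiseless phantom the quantified total equals truth exactly. Noise is
clipped at zero (SUV is non-negative); with the default background mean
at 2 SD from zero the clip touches ~2% of voxels, so noise-recovery
tests use a background far from zero. Not emulated: point-spread,
scatter, attenuation artefacts, anatomy — a green phantom test
establishes the correctness of the threshold/segmentation arithmetic,
not reconstruction fidelity.

**Cohorts.** Generating structure

    LUTtotal = b₁·OCTtotal + b₀ + ε′,  ε′ ~ N(0, σ_lut), floored at 0
    LateEDR  = a₁·LUTtotal + a₂·dose/BW + c + ε,  ε ~ N(0, σ_edr), floored at 0

with the dose rate generated from the *realized* (post-floor) LUTtotal,
so the dose-rate model stays exactly specified on every generated table.
Covariates: body weight truncated-normal 61.4 ± 14.6 kg on (30, 120) —
bounds chosen so the implied dose/BW reproduces the published
126 ± 29 MBq/kg; administered activity N(7350, 90) MBq; OCTtotal
log-normal moment-matched to 8306 ± 9871 SUV·mL; age truncated-normal
61.4 ± 8.6 y; ~53% female; creatinine log-normal (median 0.8 mg/dL,
σ 0.25), albumin N(40, 4) g/L, bilirubin log-normal (median 10 µmol/L,
σ 0.3) — jointly giving CCr ≈ 74 ± 26 mL/min and ALBI ≈ −2.7 ± 0.3.
An optional Gaussian-copula correlation couples weight and OCTtotal
(default 0) to study the low-weight/high-burden bias seen clinically.

Default coefficients a₁ = 4.1×10⁻⁴ µSv/h per SUV·mL, a₂ = 0.073 µSv/h
per MBq/kg, c = −5.4 µSv/h, σ_edr = 2.2 µSv/h are **scale-matched** to
the published moments (they yield Late EDR ≈ 4–26 µSv/h over LUTtotal
3,189–53,775, standardized-β dominance of uptake over dose/BW, and a
residual share consistent with adjusted R² ≈ 0.8); b₁ = 1.3, b₀ = 2000,
σ_lut = 3000 give a cross-tracer correlation ≈ 0.97. They are a
plausible stated world, not published constants. Residual noise is
homoscedastic; real uptake indices are likely heteroscedastic — a
limitation of the generator, not the estimator.

## Clinical covariates

Cockcroft–Gault CCr `(140 − age)·weight/(72·Scr)` (× 0.85 for women),
actual body weight, uncapped. ALBI `0.66·log₁₀(bilirubin µmol/L) −
0.085·albumin g/L`. Units fixed (creatinine mg/dL, albumin g/L,
bilirubin µmol/L) with explicit converters for the common alternates.

## Numerical and design choices

* Inclusive threshold (≥) and inclusive release boundary (≤), matching
  the governing wording of each rule.
* Sphere-placement ties broken by lowest linear index; distances via an
  exact Euclidean distance transform with anisotropic sampling.
* Background SD requires ≥ 2 in-sphere voxel centers (else error).
* Empty segmentation returns all-zero metrics rather than NaN.
* Rank-deficient designs raise with the collinear columns named;
  zero-variance predictors are rejected before fitting.
* The seven-case validation table is transcribed at the printed
  one-decimal precision; aggregate metrics recomputed from its
  measured/predicted columns carry ±0.05 µSv/h rounding tolerance. Its
  printed per-case absolute error for case 7 (5.8) differs from the
  recomputed 5.7 by one print-rounding step; the table is preserved
  verbatim and metrics are always recomputed. The published test-cohort
  OCTtotal summary (3558 ± 2940) is inconsistent with this table's
  OCTtotal column (mean ≈ 6860); the discrepancy is documented, not
  resolved.
* All randomness flows from a single integer seed per generator or run
  config; identical configuration implies byte-identical outputs
  (manifests contain no timestamps).

## Known limitations

Pooled OLS ignores within-patient correlation across cycles. Elapsed
time from administration to measurement is not modelled (measurements
cluster near 20 h). SPECT SUV quantification is device- and
reconstruction-dependent; the muscle-relative threshold mitigates but
does not remove this. The generator matches printed marginal moments,
not the unpublished joint structure of real cohorts, so green
statistical tests establish estimator correctness under the stated
world, not clinical transportability.
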