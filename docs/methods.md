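# Methods

## Problem setting

The pipeline estimates two grain metabolites — total flavonoids and total
phenols, expressed as % of dry powder mass — from diffuse-reflectance
spectra of milled Tartary-buckwheat grain measured at 1 nm resolution over
350–2500 nm (2151 bands). Reflectance of a powder carries the concentration
signal multiplicatively distorted by particle-size scatter and additively
shifted by baseline drift, and the instrument's detector edges are noisy;
the workflow therefore combines edge trimming, scatter-correcting and
derivative preprocessing, a structured calibration/validation split, and a
latent-variable regression suited to thousands of collinear predictors.

## Synthetic data model

Real acquisitions of this kind are rarely deposited, so the package ships a
generator whose defaults define the study conditions; all tests and the
acceptance script run against it.

**Concentrations.** Each analyte's population is specified by mean, SD, and
range (defaults: flavonoids 0.9733 ± 0.3653 % in [0.4275, 1.9275]; phenols
2.7298 ± 0.4352 % in [1.9115, 4.0968]). Draws come from a truncated normal
whose *parent* mean and SD are solved numerically so that the *truncated*
distribution has exactly the target mean and SD — naive truncation of
N(mean, sd²) would shift the mean by ≈ 0.05 % for these asymmetric ranges.
The two analytes are coupled through a Gaussian copula with latent
correlation ρ = 0.6 (both metabolites respond to the same agronomic
treatments, so independence would be unrealistic); for ρ ≥ 0 the latent
normals are built by an equicorrelation factor model, which remains exact at
ρ = 1.

**Spectra.** Noise-free absorbance is Beer–Lambert:
`A_i(λ) = baseline(λ) + Σ_analytes Σ_bands gain · c_i · exp(−(λ−center)²/2width²)`,
`R_i = 10^(−A_i)`. The baseline is a fixed sum of a visible pigment edge,
water features at 970/1450/1940 nm, a slow NIR rise and a long-wavelength
edge, giving curves that rise from 350 nm, peak near 800–1300 nm and fall
toward 2500 nm with reflection peaks and absorption valleys. Analyte bands
are a modelling convenience, not a claim about buckwheat chemistry: no
published band assignment exists for these analytes, and recovery tests need
known ground truth. Defaults place flavonoid absorption at 1415/1660/2050 nm
(gains 0.12/0.10/0.08 absorbance per %) and phenol absorption on the
disjoint regions 1130/1780/2240 nm (0.05/0.06/0.045), with Gaussian widths
of 35–55 nm.

Observed reflectance is `a_i·R_i + b_i + ε(λ)` with per-sample
`a_i ~ lognormal(0, 0.05)` (multiplicative scatter), `b_i ~ N(0, 0.01)`
(additive offset), and Gaussian noise of SD 0.0015 inside 401–2450 nm and
0.006 outside — the inflated edges make the trimming step meaningful. Values
are clipped into (0, 1]; absorbance above 6 is capped with a warning. One
master seed feeds deterministic child streams for concentrations and for
scatter/noise.

**What the generator does not emulate.** Instrument line-shape and detector
stitching artifacts, wavelength-dependent scatter (the planted scatter is a
single slope/offset per sample, exactly the model MSC inverts), non-Gaussian
concentration tails, and matrix interferents beyond the fixed baseline.
Passing tests therefore demonstrate that the pipeline's machinery is
correct and that it recovers signal under the artifacts it was designed to
remove — not that real grain spectra would reach the same accuracy; the
synthetic accuracies are substantially higher than field studies report.

## Preprocessing

All transforms are pure `SpectraSet → SpectraSet`; bands a stencil cannot
reach are masked (NaN) rather than extrapolated, and masked bands never
enter distances, correlations or fits.

- **MSC**: reference = mean spectrum over samples; per-sample OLS slope/
  offset against it; corrected = (x − offset)/slope. A sample with no
  variance against the reference is rejected by ID.
- **SNV**: per-spectrum standardization (population SD). The per-spectrum
  convention is the default because a single global affine map could not
  remove per-sample diffuse-reflection differences and would leave band-wise
  correlations unchanged; a `global` pooled mode is kept for literal
  comparisons.
- **Lg**: `log10(1/R)` — base 10, the absorbance convention.
- **FD/SD**: central 3-point differences `(f_{j+1} − f_{j−1})/2` and
  `f_{j+1} − 2f_j + f_{j−1}` by default; literal forward differences as an
  option. The step is one band (= 1 nm on the default grid), treated as unit
  step, so derivative units are "reflectance per band^α"; one band is masked
  at each affected end.
- **FOD (Grünwald–Letnikov)**: weights `w_m = (−1)^m C(α, m)` via the
  recurrence `w_m = w_{m−1}(m−1−α)/m`, which avoids the gamma-function poles
  of the textbook ratio form at integer orders and reduces exactly to
  `[1, −1]` and `[1, −2, 1]` at α = 1, 2. Window `t = 40` points. The
  burn-in mask covers the *effective weight support*: for fractional α all
  `t` leading bands are masked; for integer α the weights vanish exactly
  beyond `m = α`, so only α bands are lost. This keeps FOD at α = 1
  column-equivalent to the forward first difference (PLS1 is invariant under
  band permutation), an internal consistency check the pipeline asserts.
  Losing 40 of ~2050 usable bands to burn-in is a negligible cost compared
  with inventing padding values.

A note on the weight partial sums: `Σ_{m≤t} w_m = (−1)^t C(α−1, t)`, which
decays like `t^(−α)` toward zero. At `t = 40` the magnitude is ≈ 0.089 for
α = 0.5 and ≤ 0.001 for α ≥ 1.5; the property tests assert the closed form
rather than a single loose bound.

## Band range

Analysis is restricted to 401–2450 nm before splitting, correlation and
modeling; the 350–400 and 2451–2500 nm edges of field spectroradiometers
are noise-dominated (and the generator plants exactly that).

## SPXY split

Pairwise distances `d_x` (Euclidean on valid raw-reflectance bands) and
`d_y = |y_i − y_j|` are each normalized by their maximum and summed. The
greedy selection seeds with the maximal-distance pair and repeatedly adds
the sample with the largest minimum distance to the selected set, giving
nested calibration sets; ties break toward the lowest original sample index,
making the split fully deterministic. The calibration size is
`round(n · 2/3)` (64 of 96). The split is computed **once per analyte on the
raw trimmed spectra** and reused across all 26 preprocessing variants, so
every model of an analyte sees the same calibration/validation composition;
per-analyte splits (rather than one joint split) guarantee each analyte's
own extremes land in its calibration set. Distances use raw reflectance —
whether to standardize first is genuinely open; raw keeps the split
independent of the preprocessing roster. Setting the y-weight to 0
degenerates to Kennard–Stone on X alone (exposed for testing only).

## PLSR and latent-variable selection

NIPALS PLS1 on mean-centered X and y with no column scaling (bands share
units). Per component: weight `w ∝ X'y`, score `t = Xw`, loading
`p = X't/t't`, y-loading `q = y't/t't`, then deflation of X and y. The
coefficient vector is `B = W(P'W)^{-1}q`; prediction is
`ŷ = ȳ + (X − x̄)B`. Deflation stops with an error if the residual vanishes
before the requested component count (strict mode, used for final fits) or
silently truncates (cross-validation folds, where the prediction is frozen
at the last reachable component).

The component count is chosen on a 1..20 grid by leave-one-out
cross-validation **on the calibration set only**: each fold refits from
scratch and the nested structure of NIPALS yields predictions at every
component count from a single pass; `chosen_lv` is the argmin of RMSE_cv
with ties broken toward fewer components. A brute-force refit oracle (one
fresh fit per fold and component count) pins this fast path to 1e-10.

## Metrics and ranking

R² = 1 − SS_res/SS_tot about each set's own mean (the squared-correlation
variant is available behind a flag for sensitivity checks, as reporting
conventions differ across the chemometrics literature). RMSE is the root
mean squared residual. RPD = SD(y_val)/RMSE_v with the population-SD
convention, which reproduces published RPDs from published SD/RMSE pairs to
within print rounding; an RPD with zero validation SD, or an RMSE at float
roundoff, is reported as missing with a warning rather than as a spurious
number. Ranking per analyte: RPD descending, ties by higher validation R²
then fewer latent variables; the top row is flagged best. No calibration
threshold gates the ranking — calibration metrics are recorded alongside for
inspection.

## Pipeline and reproducibility

The roster is the 6 named transforms plus the fractional-order sweep
0.1–2.0 in steps of 0.1 — order 0 is the raw spectrum and is deduplicated —
for 26 variants, 52 models over two analytes (about 20 s on one CPU at the
default problem size of 96 samples × 2050 usable bands). Each run writes
model reports (with full CV curves), correlation profiles, splits, a ranking
table, and a manifest containing a configuration hash (excluding the output
directory), the master seed and the package version; identical
configurations produce byte-identical JSON artifacts.

## Numerical choices and degenerate inputs

- Zero-variance detection (SNV rows, MSC samples, correlation bands) uses a
  relative threshold of 1e-12 on the data scale, because the floating-point
  SD of a constant vector is ~1e-17, not zero.
- CSV round trips use `%.17g` on write and round-trip float parsing on
  read, so artifacts are lossless and bit-reproducible.
- All ties (SPXY selection, CV argmin, peak-correlation band) break toward
  the lowest index/wavelength; floating-point comparisons are exact, since
  all quantities derive deterministically from the inputs.
- Seeds: one master seed per simulated acquisition; child streams are spawned
  per stage so adding noise terms never perturbs the concentration draws.

## Known limitations

- The generator's scatter model matches the correction model (MSC) by
  design; it cannot probe MSC's failure modes on wavelength-dependent
  scatter.
- Band assignments for the analytes are synthetic; peak-wavelength results
  are statements about the generator, not about buckwheat.
- PLS1 only (single response); no SIMPLS/kernel variants, no
  variable-selection wrappers, no prediction intervals.
- The fractional-derivative window (t = 40) is fixed rather than selected;
  larger windows change little beyond extending the burn-in mask.
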