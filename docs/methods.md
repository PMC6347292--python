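# Methods

This note documents the models behind each analysis stage, the defaults and
why they were chosen, what the synthetic-data generators do and do not
emulate, and the numerical conventions adopted where the field leaves a
choice open.

## Shared regression machinery

Every fitted quantity in the package reduces to unweighted ordinary least
squares (`stats_core.fit_line`). Standard errors use the residual variance on
n − 2 degrees of freedom; a two-point fit is exact with zero standard errors.
No weighting or robust variant is offered: the assays modelled here report
roughly constant relative error over their linear ranges, and the upstream
study designs (4–12 points per fit) give no leverage for estimating a
variance function.

**Parallelism test.** Whether two regression slopes differ is tested with the
pooled-variance statistic

t₀ = (a₁ − a₂)/S, S² = (RSS₁ + RSS₂)/(n₁ + n₂ − 4) · (1/Sxx₁ + 1/Sxx₂),

compared against the two-sided Student quantile on n₁ + n₂ − 4 degrees of
freedom. Both residual sums are squared deviations from the respective
regression lines. When both fits are exact but the slopes differ (a limit
that noise-free synthetic inputs reach), S = 0 and the statistic diverges;
this is reported as an `exact_separation` flag with t₀ = ±∞ and
`significant=True` rather than raising, so deterministic pipelines remain
runnable. Numerically, "exact" means S ≤ 10⁻¹⁰ × max(|a₁|, |a₂|), absorbing
float round-off of analytically perfect fits.

**Calibration metrics.** LOD = 3·SD/|a| and LOQ = 10·SD/|a|, where SD is the
averaged standard deviation of determinations in the lower linearity range
and a the calibration slope; LOQ/LOD = 10/3 identically. Recovery and RSD are
computed from replicate determinations when supplied.

## Phase solubility

An A_L-type (linear ascending, slope < 1) Higuchi–Connors diagram implies 1:1
complexation with apparent constant K₁:₁ = slope/(S₀·(1 − slope)). Decisions:

- **S₀ source.** Intercept of the fitted line by default, with a mandatory
  override parameter: practitioners often fit a truncated linear range whose
  extrapolated intercept is not the independently measured intrinsic
  solubility. Neither convention is universal, so both are supported.
- **Linear-range detection.** Diagrams frequently bend once the host
  saturates. The widest linear prefix is found by shrinking from the right
  until a curvature F-test (quadratic term added to the linear model, default
  α = 0.05) no longer rejects. A pure-error lack-of-fit test would be
  preferable but requires replicate points, which averaged diagrams lack.
- Replicates at the same host level are averaged before fitting; SDs are
  carried as metadata only.
- K₁:₁ is reported in L·mol⁻¹ (≡ M⁻¹). Slope ≥ 1 or S₀ ≤ 0 makes the constant
  undefined and is flagged with a reason rather than raised, since diagram
  classification is itself a result.

## Dissolution similarity

f₁ and f₂ are computed on the intersection of the two time grids. The
`plateau` selection rule (default) drops points after both profiles first
exceed 85% dissolved, keeping at most one such point — the standard
regulatory convention, since post-plateau points carry no discriminating
information and inflate f₂. Base-10 logarithm is required for the f₂ = 100
identity at equal profiles. Verdict bands: f₂ ≥ 50 similar, f₂ < 50
dissimilar; an optional strict mode additionally requires f₁ ≤ 15 and labels
f₂-pass/f₁-fail cases "borderline". f₁ is deliberately asymmetric (its
denominator is the reference curve); tests pin this.

**Serial-sampling correction.** With aliquot volume v replaced from a vessel
of volume V at each draw, the cumulative value at draw j is reconstructed as
measuredⱼ + (v/V)·Σᵢ₍ⱼ measuredᵢ. The generator can apply this correction in
reverse, so the analyzer's correction is validated by an exact round trip.

## Degradation kinetics

First-order loss: ln c(t) = ln c₀ − kobs·t, fitted per (formulation,
humidity condition, temperature) series; kobs = −slope, with confidence
half-width Δk = slope_se × t(α, n−2), α = 0.05 default. A non-negative slope
is flagged "non-degrading" with a warning instead of an error, because
screening panels legitimately contain stable arms. Temperatures are never
pooled across humidity conditions; each condition gets its own Arrhenius fit.

Arrhenius: OLS of ln kobs on 1/T (≥ 3 distinct temperatures), Eₐ = −slope·R,
ln A = intercept. Activation parameters at t_ref = 298 K:

- ΔH‡ = Eₐ − R·t_ref (an exact identity, pinned by test);
- ΔS‡ in two variants. The standard transition-state expression is
  R·(ln A − ln(k_B·t_ref/h)) and is the default output. Some published
  stability tables instead tabulate −R·ln(k_B·t_ref/h) ≈ −244.9 J·K⁻¹·mol⁻¹
  — a constant independent of ln A, i.e. the ln A term dropped. Because such
  tables exist for exactly the benchmark system this package ships reference
  data for, the lnA-free value is exposed as `dS_as_printed` alongside the
  standard one; the package never silently substitutes one for the other.

Two constant sets are selectable: `PRINTED` (R = 8.3144 J·K⁻¹·mol⁻¹,
k_B = 1.3807×10⁻²³, h = 6.626×10⁻³⁴ — the rounded values used in the
published tables, and the default so those tables reproduce exactly) and
`CODATA` (exact SI values). The difference is far below every tolerance used.

Shelf life: t = −ln(fraction)/kobs (t90 at fraction 0.9).

## Caco-2 permeability

Papp = (dQ/dt)/(A·C₀) — the universal sink-condition definition; cumulative
receiver amount is reconstructed with the same serial-sampling correction as
above (draw volume default 100 µL; the analyzer and generator share the
geometry object, and with zero draw volume corrected and raw amounts
coincide). Default geometry: A = 0.6 cm², apical 400 µL, basolateral 600 µL,
C₀ = 5 mg·mL⁻¹, five draws at 15–120 min — a standard 12-well Transwell
design. Papp is computed per replicate well, then aggregated mean ± SD.
Donor depletion is not modelled (sink assumption; receiver < 10% of donor in
all shipped designs).

Classification: low < 1×10⁻⁶ ≤ medium ≤ 1×10⁻⁵ < high (cm·s⁻¹); both band
edges are assigned to "medium" since the literature band is stated as
"between" without inclusivity. TEER gate: strict > 450 Ω pre and post assay
(450 Ω exactly fails); missing readings fail with reason "no TEER". Efflux
ratio = Papp(B→A)/Papp(A→B), displayed at 2 decimals with full precision
retained; > 2 is labelled "active efflux likely".

## MIC analysis

The MIC is the lowest tested concentration opening an unbroken growth-free
suffix of the (sorted) dilution series. Growth everywhere → censored
"> max"; growth nowhere → "≤ min". Skipped wells (growth above a
growth-free well) are flagged and the MIC taken at the highest clean suffix —
the most conservative uncensored call; no published rule exists. Arbitrary
monotone series are accepted, not just exact two-fold ladders, because
published tables round (15/31/62/125 mg·L⁻¹). Fold change is reported as the
plain ratio MIC_free/MIC_complex (log₂ also available); censored values are
never compared numerically. Unmatched strains between tables are listed in
the summary, never dropped silently.

## Synthetic-data generators

Each generator emits the dataset plus the ground truth that produced it.
Defaults mirror the benchmark study design: 7 host levels over 0–3 mmol·L⁻¹
for phase solubility; 4 temperatures × 12 sampling points for degradation
(12 points per series being the sampling density implied by 10 regression
degrees of freedom in the benchmark validation table), spanning ~2 half-lives
of the slowest series; five transport draws at 15–120 min in the default
geometry; a rounded two-fold MIC ladder. Dissolution sampling (7 points over
60 min, 3 replicates) is a choice, not an inference — no replicate counts are
published for that stage.

**Noise model.** Multiplicative Gaussian noise on each measured value
(assay-CV model), factor truncated at zero to keep measurements nonnegative;
2% CV is the realistic default for a validated HPLC assay. A single global
seed drives everything; each scenario derives a deterministic substream from
(seed, CRC32 of the scenario label), so identical seed + parameters give
byte-identical outputs while scenarios stay independent.

**What the generators do not emulate:** drift or autocorrelated assay error,
heteroscedasticity beyond constant CV, non-first-order degradation,
mechanistic dissolution models (Weibull/Higuchi), donor depletion or
paracellular leak in transport, and biological MIC variability beyond an
optional independent per-well misclassification probability. Passing
closed-loop tests therefore demonstrates correctness of the estimators under
their stated models, not robustness to real-data violations of them.

## Problem sizes and statistical checks

The noisy-recovery check uses 100 seeded replicates of the paper-like designs
(Eₐ and K₁:₁ each recovered within 10% in ≥ 90% of replicates at 2% CV); the
parallelism type-I-error check uses 1000 null replicates against the nominal
α = 0.05 within ±0.02 (≈3 binomial SDs). These sizes give stable pass/fail
behaviour at negligible runtime.

## Known limitations

- The f₂ statistic is computed on mean profiles; bootstrap confidence
  intervals for f₂ with replicate-level data are out of scope.
- Arrhenius extrapolation assumes a single mechanism over the studied
  temperature band; the package reports per-condition fits and never pools
  across humidity.
- The curvature-based linear-prefix test is approximate when diagrams bend
  gradually; an explicit `linear_range` argument overrides it.
- Exit-code and schema conventions are documented in `cdpreform.cli`;
  warnings never change exit status.
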