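# Methods

This note documents the models and procedures implemented in `rootnir`, the
parameters that matter, the design choices made where conventions diverge,
and what the synthetic-data tests do and do not demonstrate.

## Wet-chemistry arithmetic

Acetyl-bromide-solubilized lignin is quantified by UV absorbance at 280 nm.
The specific absorption coefficient of one replicate is

    SAC = (OD_S − OD_B) · F / W_d        [mL cm⁻¹ mg⁻¹]

with OD_S/OD_B the sample and blank optical densities, F the dilution factor
(default 50) and W_d the sample weight in mg. The cuvette path length d
(1 cm) appears in the units but not in the working formula; it is carried as
an `AbsorbanceReading` field and assumed 1 cm. Per-sample SAC is the
arithmetic mean over replicates (2–4 expected; counts outside that range
warn). The calibration line

    L [%] = (SAC − 0.05) · 100 / 13.06

maps SAC to lignin as percent of dry mass; its endpoints (SAC 0.05 → 0 %,
SAC 13.11 → 100 %) and exact invertibility are enforced by tests. Values
outside [0, 100] % are *flagged, never clipped*, so QC retains them.
`fit_calibration_curve` recovers such a line from (lignin %, SAC) standards
by ordinary least squares. Replicate spread is reported as the pooled
replicate standard deviation, √(Σᵢ Σⱼ (xᵢⱼ − x̄ᵢ)² / Σᵢ (nᵢ − 1)); a pooled
standard-error-of-mean variant is selectable (`variant="se"`). The pooled-SD
definition is a documented choice — the quantity has no unique convention.

## Pre-processing

Seven methods, all operating per spectrum (or per set for MSC's default
reference), so calibration and validation data can be processed with no
information flow between them:

* **raw** — identity.
* **snv** — per-spectrum (x − mean)/sd with the n−1 SD (the n−1 denominator
  is a convention choice; it only rescales rows uniformly).
* **msc** — OLS regression of each spectrum on a reference (default: the
  mean spectrum of the set being processed), corrected to (x − a)/b. The
  set-dependent default reference is deliberate: it reproduces the
  operationally realistic divergence between independently processed
  calibration and validation sets. A fixed external reference can be passed
  for production use.
* **b.als** — asymmetric least squares: baseline z minimizes
  Σ wᵢ(yᵢ−zᵢ)² + λ‖Δ²z‖² with w = p above the baseline and 1−p below,
  iterated to weight stabilization. Defaults λ = 1e6, p = 0.05, 10
  iterations — common published defaults for grids of a few hundred points;
  λ trades baseline stiffness against peak leakage.
* **b.irls** — same penalized smoother with continuous robust reweighting:
  points above the current baseline get Cauchy weights 1/(1 + (r/3s)²), s
  being the scale of the below-baseline residuals. This is a generic
  iteratively-reweighted ("restricted") baseline corrector; exact
  equivalence to any particular reference implementation is not claimed.
* **d1/d2** — Savitzky–Golay derivatives, window 11, polyorder 2
  (configurable), length preserved by the filter's polynomial edge handling.
  The derivative step is scaled by the mean wavelength spacing; on grids
  uniform in wavenumber this is an approximation, immaterial when the
  derivative feeds a regression (it is a fixed linear filter either way).

Both baseline correctors return exactly zero on constant spectra (a constant
solves the penalized system for any weights), which the tests pin.

## PLS1 and latent-variable selection

PLS1 is fit by the NIPALS recursion on mean-centered data (no variance
scaling — the chemometric convention for absorbance spectra). Weights,
loadings and y-loadings are stored; the rotation R = W(PᵀW)⁻¹ folds them
into a coefficient vector per truncation, so one fit yields predictions for
every smaller component count (NIPALS components are nested). Coefficient-
and score-form predictions agree to 1e-10 (tested), and at full rank the
coefficients equal the normal-equations least-squares solution (tested
against an independent oracle). If deflation exhausts the predictor rank the
fit stops early with a warning and the effective component count.

nLV is chosen by seeded K-fold cross-validation (default 10 folds, shuffle
split into folds as equal as possible): the RMSECV profile over 1..max_nlv
is minimized globally, ties to the smaller model. The default search ceiling
is 15 components, safely above anything the validation engine selects, and
is capped so the largest held-out fold still leaves sufficient training
rank. The global-minimum rule (rather than one-SE) is the simplest rule
consistent with fractional mean nLV across repeated splits.

## CARS wavelength selection

At sampling run i of N (default N = 50):

1. draw ⌈0.8·n⌉ calibration samples without replacement (Monte Carlo);
2. fit PLS on the currently retained bands, nLV by 10-fold CV on that
   subset, capped at max_nlv;
3. forced removal: keep the top ⌈r_i·p⌉ bands by |coefficient|, where
   r_i = a·e^(−k·i), a = (p/2)^(1/(N−1)), k = ln(p/2)/(N−1), so r_1 = 1 and
   r_N = 2/p exactly;
4. adaptive reweighted sampling: p draws with replacement, probability
   ∝ |coefficient| among the survivors; the unique drawn indices form the
   next retained set. Drawing p times (the full band count) rather than
   ⌈r_i·p⌉ times matters: it makes the EDF, not the draw count, govern the
   decay — with fewer draws the ~63 % unique-set shrinkage compounds and the
   retained set collapses within a few runs. An exact-size
   without-replacement variant is available (`exact_size_ars=True`);
5. score the retained set by 10-fold RMSECV on the full calibration set.

The subset of the run with minimal RMSECV wins; ties prefer fewer bands,
then the earlier run. Retained sets shrink monotonically; a set about to
drop below 2 bands is clamped at 2 with a warning. All randomness flows from
one seed, so a trace is exactly replayable. N = 50 and the 0.8 Monte-Carlo
ratio follow the algorithm's customary settings; inner CV folds match the
validation engine's 10 for consistency. The inner RMSECV is computed on the
same calibration samples that drove selection and is therefore optimistically
biased — which is why model quality is only ever claimed from the *outer*
validation split. `cluster_bands` groups a selected subset into adjacent
wavelength clusters (gap ≤ 10 nm by default) purely for reporting.

## Repeated hold-out validation

`make_splits` draws seeded calibration/validation partitions (default
100 repeats of 44/30 out of 74). Per-repeat seeds derive from the master
seed by a fixed affine map, and the same `SplitPlan` objects are reused for
every model variant being compared, so full-spectrum and CARS results are
evaluated on identical draws. Per split: pre-process calibration and
validation sets independently, select nLV and fit (and run CARS, seeded by
the plan) on calibration only, predict the validation set, and score

    BIAS  = mean(pred − obs)
    RMSEP = √(mean((pred − obs)²))
    SEP   = √(Σ(e − BIAS)²/(n − 1))
    R²p   = squared Pearson correlation(pred, obs)
    RPD   = sd(obs, n−1) / SEP

These definitions satisfy RMSEP² = SEP²·(n−1)/n + BIAS² and RPD·SEP =
sd(obs) as identities (tested on 1000 random vectors). BIAS is signed as
predicted minus observed; under-prediction is negative. R²p as squared
Pearson correlation is the default; the 1 − SSE/SST variant is available
(`r2_variant="ssr"`). Degenerate cases (zero observation variance, zero SEP)
are flagged rather than silently propagated. Aggregation reports per-metric
mean ± n−1 SD over repeats; fractional mean nLV is expected. Wavelength
selection frequency is the percentage of repeats whose best subset contains
each band. The literature-survey summary computes column-wise min, Q25,
median, Q75, max with linear interpolation of order statistics, ignoring
missing cells and reporting per-column n.

## Synthetic data generator

The generator produces datasets with the statistical structure the analysis
assumes, not a radiative-transfer model of roots:

* **Grid** — 662 points uniform in wavenumber from 12489 to 3594 cm⁻¹,
  reported in nm (≈800.7–2782.4 nm). The true instrument grid of an
  8 cm⁻¹-resolution FT analyzer is not uniquely determined by its endpoints;
  uniform-in-wavenumber is declared, not inferred.
* **Band library** — Gaussian bands (σ = 25 nm) at chemically assigned
  centers: lignin 1243, 1428, 1881, 2274 nm; wax 1409 nm; polyoses 1715 nm;
  cellulose 1735 nm; protein 2035, 2437 nm; broad water bands (σ = 60 nm) at
  1450 and 1940 nm. Lignin amplitudes dominate so the regression signal is
  recoverable.
* **Composition** — lignin is drawn by rejection sampling from a truncated
  normal on [7.7, 42.8] % whose *truncated* mean equals 20.52 % (the
  underlying location is solved numerically; naive truncation at these
  asymmetric bounds would shift the realized mean to ≈21.3 %). The realized
  SD falls slightly below the nominal 7.7 because truncation removes tail
  mass. The non-lignin remainder is split cellulose/polyoses/protein/wax/
  residual around nominal shares 40/20/15/10/15 % with Dirichlet jitter
  (concentration 50) — plausible plant-tissue proportions, configurable.
  Rows sum to 100 exactly.
* **Spectra** — Beer–Lambert mixing A_i = Σ_k (c_ik/100)·s_k plus a fixed
  5 % moisture water background, then distortion: log-normal multiplicative
  scatter (σ = 0.10), a random degree-2 polynomial baseline (coefficient SD
  0.02 absorbance) and additive Gaussian band noise.
* **Band noise** — SD 0.03 absorbance with a Gaussian correlation length of
  10 bands (≈30 nm), generated by smoothing padded white noise and rescaling
  so the per-band marginal SD is exact. Two reasons for correlated rather
  than white noise: physically, residual noise in ground-plant-powder NIR is
  dominated by sample presentation and heterogeneity effects that vary
  smoothly across wavelength, not by white detector noise; statistically,
  662 *independent* noise dimensions against ~44 calibration samples create
  massive chance-correlation overfitting that no wavelength selector
  survives, a regime real FT-NIR data does not present. The nuisance levels
  were fixed so that full-spectrum SNV-PLSR on the default configuration
  lands in the accuracy regime reported for field fine-root data (RPD ≈
  1.8–2.1) — the regime where wavelength selection is genuinely useful;
  with weaker nuisance the simulated task becomes so easy that even an
  oracle informative-band subset cannot outperform the full spectrum.
* **Wet-chemistry fixtures** — `simulate_absorbance_readings` inverts the
  calibration line to produce replicate UV readings whose noise-free SAC
  maps back to the requested lignin content exactly.

Everything is bitwise deterministic under a fixed config seed.

**What passing tests show** — that the implemented arithmetic, transforms,
regression and selection behave correctly, and that under a realistic
mixture-plus-nuisance structure the pipeline recovers lignin content and the
planted lignin wavelengths. **What they do not show** — performance on real
roots: the simulator has no particle-size scattering physics, no band-shape
changes with moisture, no species identity, and its component library is a
stylized six-component reduction of real tissue chemistry.

## Problem sizes and numerical choices

Test and demonstration runs use the study-scale 74-sample/44-30-split
geometry with 25–100 repeats, and a 120-sample variant for the recovery
checks; these sizes keep every full run at desk scale on a single CPU.
Tie-breaks are deterministic everywhere (first minimum for nLV, fewer bands
then earlier run for CARS). Baseline solvers use sparse Cholesky-style
factorizations of the banded penalized system. Degenerate inputs (constant
spectra under SNV, zero ARS weights, exhausted PLS rank, zero observation
variance) raise or warn explicitly rather than returning silent NaNs.

## Known limitations

* The CARS inner RMSECV is selection-biased (see above); it is a ranking
  device, not an error estimate.
* `baseline_irls` is a generic robust-reweighting corrector; parameter-level
  parity with any specific published implementation is out of scope.
* MSC with the default set-mean reference is intentionally unstable for
  small validation sets — that instability is a property of the method the
  package is expected to exhibit, not a defect.
* The survey summary implements one quantile convention (linear
  interpolation); published tables using other conventions can differ in the
  quartiles for small n.
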