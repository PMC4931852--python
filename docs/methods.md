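# Methods

## The problem

Buccal swabs are the standard non-invasive specimen in forensic genetics,
but they are not a tissue: each swab is a mixture of buccal epithelial
cells and leukocytes in proportions that vary widely between donors and
harvesting procedures (epithelial fractions from roughly a quarter to over
ninety percent). DNA-methylation age clocks are calibrated per tissue, so a
blood-trained clock applied to a swab inherits an offset that scales with
the epithelial content. `swabage` implements the correction: estimate the
epithelial fraction from two cell-type-specific CpGs, then predict age as a
mixture of a blood clock and an epithelial clock weighted by that fraction.

## Models

All models are linear in β-values (fraction of methylated alleles, in
[0, 1]) at five pyrosequencing-assayed CpGs: three age-associated sites —
α (cg02228185, *ASPA*), β (cg25809905, *ITGA2B*), γ (a CpG upstream of
cg17861230, *PDE4C*; the assayed site is not on Illumina arrays, so the
registry carries an array alias) — and two cell-type-specific sites —
δ (cg07380416, *CD6*, hypomethylated in leukocytes) and ε (cg20837735,
*SERPINB5*, hypermethylated in leukocytes).

Frozen published predictors (coefficients stored at printed precision,
never re-derived; where two printings disagree the more precise one is
adopted and the discrepancy recorded in the model's `notes`):

- 3-CpG blood clock: `age = 38.0 − 26.4α − 23.7β + 164.7γ`
- 3-CpG swab clock: `age = 32.69 − 8.42α − 47.38β + 183.25γ`
- 1-CpG swab clock: `age = (γ − 0.0648)/0.0046` (a regression of β on age,
  inverted for prediction)
- Buccal-Cell-Signature:
  `ϐ [%] = (99.8δ + 1.92)/2 + (−98.12ε + 88.54)/2`
- 5-CpG mixture clock:
  `age = (1 − ϐ/100)·blood(α,β,γ) + (ϐ/100)·epithelial(α,β,γ)` with
  `epithelial = 2.6 − 11.0α − 15.6β + 181.7γ`.

ϐ is clamped into [0, 100] before weighting (it is a physical percentage;
the pre-clamp value is kept for diagnostics). Predicted ages are never
clamped — a negative prediction signals a calibration failure and is
reported as-is with a warning. Note the printed signature cannot actually
reach 0 or 100 for β in [0, 1]: its raw range is −3.83 to 95.13 %.

## Training

Each estimator is a model class whose `fit()` returns a results object with
the fitted clock, training MAD (mean absolute deviation of predicted from
chronological age, years — not the robust median statistic), squared
Pearson correlation, and the list of excluded samples with reasons.
Samples missing a required β or the age are excluded, never imputed.

- `AgeClockModel`: OLS of age on β at the chosen probes, with intercept.
- `OneCpGClockModel`: simple regression of β on age, then inverted; a
  zero fitted slope (age-independent CpG) is a failure, not a model.
- `CellSignatureModel`: two independent simple regressions of counted
  percent-epithelial on δ and on ε, averaged ½/½. Requires ≥3
  cytology-counted samples with variation in the counts.
- `EpithelialMixtureModel`: the two-stage plug-in estimation of the
  epithelial clock. With the blood clock and the cell signature held fixed,
  each sample contributes the residual `age_i − (1−w_i)·blood(x_i)`
  regressed on the scaled design `w_i·[1, α_i, β_i, γ_i]` with no free
  intercept, where `w_i = ϐ_i/100` uses the clamped signature output.
  Near-zero weights are retained (they carry ≈0 information; filtering
  would introduce a threshold for no benefit); if every weight is zero the
  epithelial clock is unidentifiable and the fit fails. No regularization
  anywhere — these are deliberately plain linear models.

Ordinary least squares is delegated to statsmodels; rank deficiency is
detected up front and reported with the offending constant column's name.

## Marker screening

`screen_markers` reproduces the three-criterion screen for cell-type
markers between two tissue β-matrices: (i) large |Δmean| between tissues,
(ii) low within-tissue variance (sum of the two sample variances, ddof=1),
(iii) no age correlation in a reference cohort (|Pearson r| < 0.05 by
default; an anti-correlation is equally disqualifying). The variance filter
keeps the lowest decile of variance sums among age-passing probes (the
original procedure gives no explicit cutoff; a quantile rule is the
declared deterministic substitute), then ranks by Δmean descending with
ties broken by smaller variance sum, then probe ID. Probes missing in more
than 20 % of samples of either tissue are dropped before statistics. The
ranking is invariant to sample and probe order.

A practical note baked into the synthetic defaults: the age veto is a
sample correlation, so its null sampling sd is 1/√n of the reference
cohort. At n = 656 (a typical public blood cohort) se(r) ≈ 0.039 and a
genuinely age-independent CpG is vetoed by chance ~20 % of the time. The
synthetic screening panel therefore defaults to a 3000-sample age
reference (se ≈ 0.018, the 0.05 veto ≈ 2.7 se above null), so that the
screen's behavior reflects the criteria rather than reference-size noise.

## Synthetic cohorts

The generator draws ages uniform on [1, 85] years and epithelial fractions
uniform on [24, 91] % (n = 55 by default, matching the training-cohort
design), builds per-cell-type β profiles — age-independent marker
baselines (δ: 0.02 leuko / 0.95 epi; ε: 0.92 leuko / 0.05 epi), age-linear
curves at the three age CpGs, and optional decoy CpGs with tissue-shared
baselines and donor-level scatter (sd uniform on [0.02, 0.20]) — mixes
them convexly at the sample's fraction, adds Gaussian β-noise (sd 0.02 by
default, clipped to [0, 1] with clip events counted in `matrix.meta`).
Everything is driven by per-purpose seeded substreams of one integer seed;
a separate `decoy_seed` lets several panels share decoy baselines.
A beta-distributed noise option exists for bounded realism; Gaussian is
the default because pyrosequencing scatter at mid-range β is symmetric
and small. The 11-sample calibration set spans counted epithelial
fractions 37–88 % (leukocyte fractions 12–63 %).

`reference_cell_types` does not pick tissue curves freely: it solves the
linear constraints under which the published 5-CpG mixture clock holds
*identically* on noise-free mixtures — the leukocyte γ curve makes the
blood branch exact, and the epithelial-minus-leukocyte differences Δ are
pinned (up to one free direction bounded by β ∈ [0, 1]) by requiring the
fraction-quadratic and fraction-linear terms of the model error to vanish,
with the signature's affine response to the true fraction folded in. A
noiseless synthetic cohort therefore satisfies the published model to
machine precision, which is what makes exact parameter-recovery tests
possible. The default leukocyte age slopes (α −0.0050, β −0.0040 /year)
additionally make the blood-vs-epithelial prediction gap grow with age
(≈ +2.5 years across the lifespan), emulating the observed pattern that
composition adjustment matters most in older donors.

What the generator does **not** emulate: batch and lab effects, assay
nonlinearity, non-uniform cohort age structure (an explicit age list can
be supplied), array-scale probe sets, and correlated noise between CpGs.
Passing tests demonstrate internal consistency of the estimation
machinery, not field performance on real swabs.

## Known limitations

- The two-stage epithelial estimation is statistically fragile at
  realistic measurement noise: the response residual contains the blood
  coefficients dotted with the β-noise (sd ≈ 0.02·||b|| ≈ 3.4 years, the γ
  term alone contributing 3.3), and the exact-consistency constraints cap
  the feasible tissue divergence at the age CpGs, so with 55 samples the
  epithelial coefficients — especially the intercept — carry standard
  errors far larger than 15 % of their magnitudes. Parameter recovery is
  exact at zero noise and degrades quickly with it; this mirrors the
  method's own caveat that the epithelial clock would be better estimated
  from purified epithelial cells or much larger cohorts.
- R² is affine-invariant and cannot certify calibration: a blood clock
  applied to swabs shows high R² together with a large offset. Read R²
  next to MAD and the mean signed error.
- Group comparisons use the classical equal-variance t-test by default
  (the original analysis does not state a Welch correction); Welch is
  available behind a flag.
- No confidence intervals for single predictions: the published models
  come without an error model, and inventing one here would suggest
  precision the assays do not warrant.

## Problem sizes in the test suite

Simulation-backed tests use the defaults above (n = 55 cohorts, 100 seeds
for recovery and screening replicates, 30 seeds for the stratified
improvement comparison, a 3000-sample screening age reference); the whole
suite runs in well under a minute on one CPU.
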