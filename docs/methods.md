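# Methods

## Model

The package models the probability of radiation-induced lung injury (RILI)
after breast irradiation with the Lyman–Kutcher–Burman (LKB) formulation.
A patient's inhomogeneous ipsilateral-lung dose distribution, represented
as a differential dose-volume histogram with partial volumes `v_i` at
doses `D_i`, is reduced to a single generalized equivalent uniform dose

    EUD(n) = (Σ_i v_i D_i^(1/n))^n ,

the power mean whose exponent is set by the volume-effect parameter `n`
(`n = 1`: mean lung dose, a fully parallel organ; `n → 0`: maximum dose, a
fully serial one). The complication probability is the probit response

    NTCP = Φ((EUD − TD50(1)) / (m · TD50(1))) ,

with `Φ` the standard normal CDF, `TD50(1)` the dose giving 50%
complications under uniform whole-organ irradiation, and `m` the relative
steepness. The historical effective-volume phrasing — a partial volume
`v_eff = Σ v_i (D_i/D_ref)^(1/n)` irradiated uniformly at a reference dose
`D_ref`, with tolerance `TD50(v) = TD50(1) v^(−n)` — is algebraically the
same model via `EUD = D_ref · v_eff^(n)`; the package exposes both and the
test suite verifies the identity to 1e-9 on random histograms. The EUD
form is primary because it needs no reference-dose choice.

Assumptions worth stating: doses are used as physical dose (no
linear-quadratic/EQD2 fractionation correction — typical for breast
series delivered at 2 Gy per fraction, and the convention behind the
shipped parameter presets); the outcome is binary any-grade injury
(RTOG grade ≥ 1); only the ipsilateral lung enters the model.

## DVH conventions

* Volumes are stored as fractions in [0, 1]; percent exists only at I/O
  boundaries. The default text dialect is CSV `dose_gy,volume_pct`,
  cumulative, header required; a `DvhDialect` toggles delimiter, units,
  header and mode.
* Cumulative → differential conversion assigns the mass between adjacent
  cumulative bins to their dose midpoint (standard histogram-reduction
  convention); the last bin keeps its cumulative tail at its own dose.
  This mapping is one-way (midpoints shift on every pass), which is why
  cohort bundles store DVHs differentially.
* Vx is read off the cumulative curve with linear interpolation, so
  sub-bin thresholds are meaningful; V(0) = 1 by definition and the curve
  is 0 beyond the last bin.
* Round-trip guarantees: cumulative↔differential conversions preserve the
  cumulative volumes and the mean dose to 1e-9; text round trips are
  bit-exact in the fraction dialect and within 1 ulp in the percent
  dialect (the ×100 / ÷100 pair is not exactly invertible in binary
  floating point — about a quarter of representable fractions are not hit
  by any `y/100`).
* EUD is evaluated in log space (log-sum-exp over
  `log v_i + (1/n) log D_i`): for `n < 0.1` and doses above 50 Gy the
  linear-space powers overflow. Zero-dose bins contribute zero, the
  continuity limit of `D^(1/n)` as `D → 0`.

## Maximum-likelihood fit

The objective is the Bernoulli log-likelihood of the binary outcomes
under per-patient NTCPs, with probabilities clipped to
`[1e-12, 1 − 1e-12]` so extreme trial parameters keep the objective
finite; the clipping constant is reported in the result. There is no
analytic gradient worth having (the EUD depends on `n` through a power
mean), so the optimiser uses central finite differences.

Search strategy, chosen for a likelihood whose `n`-direction is
notoriously flat:

* optimisation in `(log n, log m, log TD50)` over the box
  n, m ∈ [0.01, 5], TD50 ∈ [1, 100] Gy;
* safeguarded Newton ascent: Cholesky of the negated Hessian doubles as
  the negative-definiteness test, with steepest ascent as the fallback;
  step-halving enforces monotone improvement; steps are capped at 2 in
  log space;
* convergence when the gradient sup-norm drops below 1e-6 or the relative
  log-likelihood improvement below 1e-10;
* deterministic multi-start: an interior 3×3×3 lattice at the 25/50/75%
  quantiles of each log-range (the box corners are pathological start
  points) plus the classical whole-lung triple (0.87, 0.18, 24.5 Gy);
  ties within 1e-8 log-likelihood break toward smaller TD50, then smaller
  m, making refits bit-reproducible;
* `fixed_n` freezes the volume exponent and fits `(m, TD50)` only —
  useful when `n` is taken as a tissue constant.

Standard errors come from the inverse observed information (numerical
Hessian in natural parameters) and are flagged as asymptotic: at the
event counts of a single-institution breast cohort (~10 events) they are
not to be trusted. A near-singular information matrix (condition number
above 1e8, e.g. when every patient shares one DVH and `n` is
unidentifiable) is flagged rather than hidden.

## Statistical battery

* 2×2 chi-square defaults to the Yates continuity correction — on the
  chemotherapy-cycles table of the motivating 109-patient cohort the
  corrected form reproduces the published 5.825 exactly while the plain
  Pearson form gives 7.579, which pins down the convention used there.
* Two-sample t tests work from summary statistics (mean, SD, n) or raw
  samples, pooled or Welch.
* Logistic regression is IRLS with step-halving (monotone
  log-likelihood), convergence at score sup-norm < 1e-8, Wald odds-ratio
  CIs, and an explicit quasi-separation flag when a coefficient passes 15
  in absolute value. Collinearity among V5–V25 (they are deterministic
  functionals of one curve) is expected; it is reported through the
  information-matrix condition number, not "fixed".
* ROC curves place thresholds at midpoints between adjacent distinct
  scores plus ±∞ anchors, classify by `score ≥ cutoff`, and integrate by
  trapezoid — which makes the AUC exactly the Mann–Whitney pair statistic
  with ties counting one half (a property test checks this to 1e-12).
  The "best" cut-off maximises Youden's J, ties breaking toward higher
  specificity. The AUC interval is Hanley–McNeil, an approximation kept
  for comparability, not an inferential claim.
* Stratified incidence uses Fisher's exact test when any expected cell is
  below 5, otherwise the corrected chi-square.

## Synthetic cohorts

The generator emulates ipsilateral-lung DVHs of tangential breast IMRT as
a four-part mixture on a 0.5-Gy grid: a spared low-dose mode
(exponential, scale 1.2–2.8 Gy), a scatter/penumbra midrange (gamma,
mean 8.5–12.5 Gy), a linearly declining in-field shoulder from ~18 Gy up
toward the prescription, and a prescription peak (truncated normal at
~51 Gy) cut at a per-patient maximum near 55–56 Gy. Default mixture
fractions put cohort marginals where published breast-IMRT series put
them — V20 ≈ 26–30%, mean lung dose ≈ 15–17 Gy, maximum dose ≈ 55–56 Gy,
with the V25→V45 decline produced by the shoulder. Clinical covariates
(age, chemotherapy cycles, surgery type, stage) are drawn from marginal
distributions matching such series; outcomes are Bernoulli draws from
each patient's NTCP under a configurable true triple, optionally
log-odds-shifted for heavily chemotherapy-exposed patients. One
`numpy.random.Generator` seeded from the cohort specification drives
everything; the same
spec reproduces the same cohort bit for bit.

What the generator does **not** emulate: real per-patient correlation
between anatomy and plan quality, inter-planner variation, grade-specific
dose-response, contralateral/bilateral lung dosimetry, or measurement
noise in outcome ascertainment. Passing recovery tests therefore shows
the estimator is consistent under the model, not that the model is right
for any particular clinic's data.

A known tension in the motivating study's numbers, inherited knowingly:
its fitted triple (0.912, 0.437, 17.211 Gy) applied to its own dosimetric
marginals (mean lung dose 15–17 Gy, and EUD ≈ MLD at n ≈ 0.9) yields
NTCP ≈ 0.45, far above its observed 9.2% incidence — consistent with the
original partial volumes having been normalised to a larger reference
volume (e.g. bilateral lung) than the ipsilateral organ. This package
keeps the self-consistent ipsilateral-EUD formulation throughout, so
synthetic cohorts generated under that triple with realistic DVH
marginals have ~40–50% incidence, and the published per-patient NTCP
scale (cut-off 9.62%) is reproduced from its printed counts, not from
DVHs.

## Problem sizes and tolerances used in verification

Parameter recovery is exercised at 5,000 synthetic patients (seed 1):
TD50 recovers within 15%, m within 30%, n within 50% — bands that
reflect the flat `n`-ridge, on which `(n, m, TD50)` trade off while the
fitted risk ranking stays essentially exact (rank correlation of fitted
vs true NTCP > 0.996). A 30-patient, n-frozen fit is checked against an
exhaustive 200×200 grid maximiser to within one grid cell. Property
tests run on 100–1,000 random histograms/tables each. The identity
checks (EUD vs effective volume, EUD(1) vs mean dose, conversion round
trips) are held to 1e-9; the AUC/pair-counting and Φ symmetry identities
to 1e-12.

## Limitations

* No fractionation correction and no grade-stratified endpoints.
* No DICOM-RT ingestion: DVHs enter as two-column text.
* Hanley–McNeil is the only AUC variance offered (no DeLong), and no
  multiplicity adjustment is applied across the univariate battery.
* Asymptotic standard errors only; no profile likelihood or bootstrap.
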