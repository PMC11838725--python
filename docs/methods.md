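# Methods

## Outcome model and pairwise construction

Each subject contributes a right-censored history: observation time
`X = min(D, C)` (death time `D`, censoring time `C`), a death indicator,
and the times of nonfatal events before `X`.  The two-tier win rule
compares a pair over its shared window `t = min(Xᵢ, Xⱼ)`:

1. *Survival tier.*  If exactly one subject's death falls inside the
   window, the survivor wins; if both died, the later death wins; equal
   death times are an overall tie (the nonfatal tier is not entered).
2. *Nonfatal tier* (only when neither died inside the window).  The
   subject whose first nonfatal event is strictly later — or absent —
   wins; equal first-event times, or two event-free histories, tie.

Boundary convention: an event at exactly the shared-window end counts as
inside the window.  With `t = min(Xᵢ, Xⱼ)` an observed death always sits
on this boundary, so a strictly-interior reading would discard essentially
every death comparison; the inclusive convention is the operational
meaning of "shared observation window".  Between-subject time comparisons
remain strict, and exact between-subject ties at a tier yield a tie.  Ties
are not stored: the comparable-pair set ℛ holds, per pair, the win
indicator δᵢⱼ, the covariate difference zᵢⱼ, and the tier that decided it.

Duplicate nonfatal times within a subject are collapsed (only the first
event enters the comparison anyway).  Times are exact reals; no rounding
or unit conversion is applied.

## Penalized fitting

The PW model makes the pairwise win probability logistic in β′zᵢⱼ, so
the elastic-net objective is the penalized negative average pairwise
log-likelihood of a *no-intercept* logistic regression.  The intercept is
structurally forbidden: which pair member is labelled "i" is arbitrary, so
every quantity must be invariant to flipping `(δ, z_diff) → (1−δ,
−z_diff)`; an intercept would latch onto the nominal win prevalence, an
artifact of subject ordering.  For the same reason internal
standardization divides each z-difference column by its root mean square
*without centering* (centering would break the flip symmetry).
Coefficients are reported on the original covariate scale.  Exact parity
with any particular penalized-regression package is not a goal.

Numerics:

- Path solver: warm-started proximal Newton.  At each λ the iteratively
  reweighted quadratic (weights `p(1−p)` floored at 1e-5) is minimized by
  cyclic soft-threshold coordinate descent; outer iterations stop when the
  sup-norm coefficient change drops below `tol` (default 1e-7).  The inner
  CD tolerance is `tol/10`.  A numba-jitted kernel is used when numba is
  importable; a pure-Python fallback implements the same arithmetic.
- λ grid: 100 log-spaced values from the KKT bound λ_max (the smallest λ
  with an all-zero solution, computed on the standardized scale) down to
  `1e-3·λ_max`.  For α below 0.001 the α = 0.001 bound is used, since the
  ridge limit has no finite all-zero threshold.
- λ = 0 (unregularized) grid points are solved by Newton–Raphson on the
  estimating function.  Perfect separation is reported as an error, flagged
  either by the standardized coefficient norm crossing 30 during the
  iteration or by a converged root at which every pair margin is strictly
  positive (a certificate that the likelihood is unbounded).
- All pairs carry equal weight 1/|ℛ| (the time-constant weighting).
- Refitting at the CV-selected λ re-traverses the automatic grid down to
  that λ, so the refit coefficients match the CV path entry exactly.

## Cross-validation

Folds partition *subjects*, stratified on outcome status (died / alive
with a nonfatal event / event-free) so both tiers stay balanced; the same
three strata drive the train/test split.  For fold k the path is fitted on
pairs formed entirely outside the fold and validated on pairs formed
entirely inside it — cross-fold pairs are used by neither side, which is
the point: pairs sharing a subject are correlated, and pair-level CV
(implemented as `naive_pair_cv` purely as a cautionary demonstration)
overstates accuracy and keeps "improving" as λ shrinks.

The λ grid is computed once from the full training pair set and reused in
every fold so the per-fold curves share an x-axis.  The per-λ score is the
unweighted mean of fold concordances (folds without comparable validation
pairs are dropped with a warning rather than imputed at 0.5); λ_opt is the
maximizer, ties resolved to the largest λ (the sparsest model).  K
defaults to 10.

## Concordance

The generalized C-index scores a comparable pair as correct when the
winner has the strictly larger win score β′z, with half credit for exact
floating-point score ties.  Ties arise structurally (β = 0, identical
covariates); a tolerance would make the half-credit rule depend on noise,
so exact equality is deliberate.  Component indices restrict to
death-decided and nonfatal-decided pairs; an empty component is reported
as absent, never as 0.5.  The same evaluator scores the Cox benchmark
(linear predictor negated into a win score), keeping the comparison
like-for-like.

## Risk prediction

Variable importance is |coefficient on the standardized scale|, i.e.
|βⱼ|·scaleⱼ, sorted descending with name-order tie-breaks.  The risk-score
spectrum is cut at the j/L training quantiles (L defaults to 3,
tertiles); stratum index increases with risk and membership is
left-closed, so a score equal to a cut point joins the upper stratum.
Within strata, Kaplan–Meier curves (lifelines) estimate overall survival
(event = death) and event-free survival (event = earlier of first nonfatal
event and death); at tied times events precede censorings, the standard
product-limit convention.  The PW model has no baseline function, so these
curves are the package's route to absolute prognosis.

## Synthetic data

The generator emulates a two-endpoint trial population:

- Covariates: p = 20 standard normal components with AR(1) correlation
  ρ = 0.1 (corr(z_j, z_k) = ρ^|j−k|).
- Event times: (D, T) from a Gumbel–Hougaard copula with κ = 1.25
  (Kendall's τ = 1 − 1/κ = 20%, independent of z) and exponential margins
  with rates λ_D·e^{−β_D′z/κ} (λ_D = 0.1) and λ_H·e^{−β_H′z/κ}
  (λ_H = 1); positive coefficients are protective.  Sampling uses the
  positive-stable frailty construction with Chambers–Mallows–Stuck stable
  variates, which reproduces the joint survivor function exactly.
- Censoring: `C = min(Uniform[0.2, 4], Exponential(rate 0.02))` — an
  administrative cutoff and loss to follow-up; the exponential is read as
  rate 0.02 (mean 50), the only reading consistent with the intended
  observed-event rates.
- Effect scenarios: scenario 1 puts 0.5 on the first ten covariates for
  both endpoints; scenario 2 puts 0.75 on covariates 1–5 for death only
  and 0.75 on 6–10 for the nonfatal event only; a null preset has no
  effects.  Each subject carries at most one nonfatal event (T is a
  single time), although the data model accepts several.

At baseline (z = 0) the exact observed-event fractions under these laws
are death 0.180 (by quadrature of the censoring survivor against the
exponential death density), nonfatal ≈ 0.747 and composite ≈ 0.789.  The
generator targets a population with frequent nonfatal events and a
substantial minority of deaths; it does not emulate recurrent
hospitalizations, covariate-dependent censoring, non-proportional
win-loss odds or nonlinear effects, so passing tests demonstrate correct
mechanics under the generative model, not robustness to those violations.
Note the generative copula model satisfies the PW proportionality
assumption only approximately, so coefficient recovery is checked as
sign/ordering recovery, not as exact values.

Algebraic note: under the joint survivor function above, the marginal
hazard ratio per unit covariate is e^{−β/κ} (the dependence parameter
divides the linear predictor); the model is implemented literally as
stated rather than rescaling β.

## Simulation study driver

`run_sim_study` replicates the full workflow per dataset: stratified 80/20
split, 10-fold subject-level CV at α = 1, refit at λ_opt, selection =
nonzero coefficient, and overall/component concordance on the held-out
20%.  Replicate seeds derive from a single seed sequence, so studies are
reproducible end to end.  The default study size used in tests and in the
acceptance script is 100 replicates at n = 200, a deliberate desk-scale
choice that keeps each study a few minutes long while leaving Monte-Carlo
error on selection frequencies near 0.05.

The first-event Cox benchmark collapses each history to
min(death, first nonfatal, censoring), fits Coxnet (penalized partial
likelihood, l1 mixing floored at 0.01 since the implementation requires a
strictly positive lasso weight) on a path of its own KKT-derived grid, and
tunes λ on the same subject folds by Harrell's C of the linear predictor
on the fold's first-event view — the concordance-based criterion mirrors
the win-ratio tuning for a like-for-like comparison (a deviance-based
default would also be defensible).  Tie handling in the partial likelihood
follows the library default; simulated times are continuous, so ties have
measure zero.

## Known limitations

- Pairwise construction is O(n²) in memory and time; datasets beyond a
  few thousand subjects need chunked or subsampled handling upstream.
- No inference (standard errors, confidence intervals) is provided for
  either the regularized or the unregularized fit; the unregularized
  solver reports coefficients only.
- Only the two-tier first-event win rule is implemented: no
  recurrent-event frequency comparisons, no more than two tiers, no
  time-dependent (IPCW) concordance, and α is a fixed configuration
  value, not a tuned hyperparameter.
- The C-index shares Harrell's dependence on the censoring distribution
  of the test set.
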