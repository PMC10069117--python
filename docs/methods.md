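# Methods

## The problem

Low-dose multidrug combinations can kill cancer cells synergistically while
sparing non-malignant tissue, but the candidate space is combinatorially
large: even a modest panel of 7–11 drugs at two dose levels spans hundreds to
thousands of four-drug combinations, far beyond what a phenotypic viability
assay can screen exhaustively in a clinically relevant timeframe.  The
platform implemented here addresses this with design-of-experiments screening
plus response-surface modeling: a small, information-dense set of multidrug
conditions is assayed (ATP-based viability, % of untreated control), a
second-order polynomial is fitted to the readouts, drugs dominated by
antagonistic interactions are eliminated, and the process repeats on the
surviving drugs until a final dose-optimization round selects the optimized
drug combination (ODC).

## Response-surface model

Viability V (% of control) for one biological model (a cancer or a
non-cancer 3D co-culture) is modeled as

    V = β0 + Σi βi·xi + Σ{i<j} βij·xi·xj + Σi βii·xi²

where xi is the orthogonally coded dose score of drug i: screen levels
0 / 1 / 2 (absent, IC20/2, IC20) map to −1 / 0 / +1.  The recode keeps the
intercept and quadratic columns weakly correlated.  Since the response is
viability, a negative pairwise coefficient means the pair suppresses
viability beyond additivity (synergy); a positive one is antagonism.
Replicate readouts enter as independent observations; viabilities are
normalized per model to 100 × signal / mean(control signal) using the
design's embedded untreated rows.

The fit is ordinary least squares via QR factorization, with coefficient
standard errors from (XᵀX)⁻¹ and two-sided t tests.  A rank-deficient basis
raises an error naming the confounded terms (computed from the null space of
the design's model matrix).  When the residual variance is numerically zero
(noise-free data) p-values degenerate to 0/1 by coefficient magnitude at
1e−8, which makes noiseless support recovery exact.

## Screen designs

**First round (7 drugs, 50 conditions).**  An orthogonal-array composite
design: a 2^(7−2) resolution-IV regular fraction on levels {0,2} (32 runs;
defining words chosen as F = −ABCD, G = −ABDE so the fraction contains the
all-zero control run) stacked with the classical 18-run three-level
orthogonal array on levels {0,1,2}.  The array's seven three-level columns
are embedded through a fixed permutation selected by exhaustive search to
(i) avoid duplicating any non-control fraction run and (ii) minimize the
worst-case pairwise-coefficient variance — in a resolution-IV fraction three
alias pairs of two-factor interactions are separated only by the array
block, and the A-optimal assignment reduces their worst-case unit SE from
0.44 to 0.36.  The stacked design has full rank for all 36 model terms
(condition number ≈ 17).

**Later rounds (4–7 surviving drugs).**  The same composite structure scaled
down: a two-level block (full factorial up to 5 drugs, a resolution-≥V half
fraction for 6, the 32-run fraction for 7) stacked with the first n columns
of the 18-run array, deduplicated.  The array slice carries the half-dose
information the quadratic terms and the final dose choice need; all sizes
are verified full-rank for the complete quadratic model.

## Stepwise reduction and interaction calls

The full model is pruned by backward elimination: repeatedly drop the
least-significant term with p > α (default 0.05) and refit, under weak
heredity (a first-order term is kept while any interaction or quadratic
involving its drug remains).  Retained first-order and pairwise terms are
classified synergistic / antagonistic / additive-neutral by coefficient sign
and significance.

**Drug elimination** between rounds uses the *full* (unreduced) fit: on a
correlated composite design, backward elimination redistributes a dropped
term's effect into retained correlated columns and can fabricate strongly
significant phantom interactions, which is harmless for prediction but
poisonous for irreversible drug-elimination decisions.  Each drug's score is
the sum of its significant signed pairwise coefficients — its net
antagonistic burden in viability points — with pairwise significance
re-assessed under Benjamini–Hochberg control at 0.05 (the pairwise calls are
a family of C(n,2) simultaneous tests).  A drug is eliminated when the score
is positive or when it has no significant term at all; if fewer than four
drugs would survive, the lowest-scoring ones are retained with a warning.
A magnitude-weighted score rather than a call count prevents one decisive
synergy from being outvoted by marginal false-positive antagonisms.

## Selectivity and final selection

The therapeutic window is TW = V(non-cancer) − V(cancer) in percentage
points; positive TW means the combination spares the non-cancer model.  The
final round enumerates every four-drug candidate at levels {1,2} over the
surviving panel and selects the argmax of predicted TW (ties broken by lower
predicted cancer viability), or the argmin of predicted cancer viability
when no non-cancer screen exists.  Both the measured TW (condition means)
and the model-predicted TW are computed and labeled in the reports.  For
this selection the model is refitted on the pooled screens of every round
that used the identical design over the final panel (typically the last
two), which halves the prediction variance that drives the dose-level
choice; per-round models are reported individually.

## Adaptive-lasso sensitivity analysis

As an independent route over the same second-order basis, an adaptive lasso
is fitted: a pilot ridge regression (penalty by leave-one-out generalized
cross-validation) gives weights w_j = 1/|β̂_pilot,j|^γ (γ = 1, weights
capped at 1e8), the weighted L1 problem is solved by feature rescaling with
the penalty chosen by seeded 10-fold cross-validation, and a debiased OLS
refit on the selected support supplies coefficients and residual variance.
By construction the refit coincides exactly with the stepwise OLS model
whenever both select the same support.

Every candidate's viability is predicted under the selected model(s); with a
non-cancer model the predicted therapeutic window (PTW) is attached.  The
computed confidence interval (CCI) then selects all candidates statistically
undistinguishable from the best: the best candidate's criterion (max PTW or
min predicted cancer viability) receives a residual-bootstrap standard error
(1000 resamples, fixed seed; the selected support is held fixed across
resamples and only the OLS refit is repeated, since the SE of a single
predicted value is insensitive to re-running the cross-validated selection),
and the one-sided 95% bound is best ∓ z₀.₉₅·se with z₀.₉₅ = 1.6449 (a
t quantile is available by flag).  A zero SE degenerates the interval to
exact ties.  The selected set is summarized as a drug network (node weight =
fraction of in-CCI combinations containing the drug, edge weight = pair
fraction, exportable as GraphML) and a per-drug dose-level stacked-bar
table.

## Monotherapy dose–response and combination index

Monotherapy curves use the median-effect model fa/(1−fa) = (D/Dm)^m, fitted
by least squares on the linearized scale log(fa/(1−fa)) vs log D; fraction
affected is FA = 1 − treated/control ATP signal, clipped into [0,1] with a
log entry, and FA ∈ {0,1} points are excluded from the fit (their logit is
undefined).  ICx doses follow as Dx = Dm·(x/(100−x))^(1/m).  For a dosed
combination with observed fa, the Chou–Talalay combination index is the
mutually-exclusive form CI = Σi Di/Dxi(fa); CI < 1 synergistic, CI = 1
additive (tolerance 1e−6), CI > 1 antagonistic.  The mutually-nonexclusive
variant (with cross terms) is deliberately not implemented.

## Synthetic screens and what they do (not) show

The simulator generates two-model screens whose truth is a quadratic
polynomial in the *presence-scaled* doses u_i = level/2 ∈ {0, ½, 1}:

    V = 100 + Σi βi·ui + Σ βij·ui·uj + Σ βii·ui²

On this scale absent drugs vanish from every term, so a planted pairwise
coefficient acts only when both drugs are dosed — the pharmacological
meaning of synergy/antagonism — while the surface remains an exact member of
the quadratic family the engine fits in ±1 scores (the codings are affinely
equivalent).  Defaults, chosen to match the magnitudes the platform's
coefficient plots and combination indices report for real screens:

- 7 drugs, full-dose first-order effects −U(8, 16) viability points
  (monotherapy-scale effects at IC20-level dosing); the strongest effects
  are assigned to the synergy-pair drugs and the weakest to the
  antagonism-pair drugs,
- 2 planted synergies and 1 antagonism of magnitude ≈ ±12 points when both
  drugs are at full dose (deeply sub-additive combinations),
- mild quadratic curvature U(−2, 2),
- i.i.d. Gaussian replicate noise, sd 5 points, 3 replicates,
- non-cancer surface = 100 + 0.3 × (cancer effect part), so the optimal
  candidate coincides for the TW and the cancer-viability objectives.

The drawn effects are calibrated by one common rescale so the polynomial
stays within the physical range over the whole level grid, with a floor of
max(2, 3·noise_sd) percent: this keeps the most-dosed conditions clear of
the zero-truncation zone of the replicate noise, so readouts are effectively
Gaussian around the polynomial everywhere (readouts are still clipped at 0
with a log entry as a safety net).  The planted optimum is the exhaustive
argmin of the noiseless cancer surface over all four-drug candidates.

What passing tests show: the engine recovers coefficients, supports and the
planted optimum under plate-like noise on a screen whose truth is exactly
quadratic.  What they do not show: robustness to lack of fit (saturating or
biphasic dose–response, higher-order interactions), plate/batch effects,
non-Gaussian readout noise, or heteroscedasticity — real screens have all
of these, and the simulator deliberately omits them.

## Numerical choices and degenerate inputs

- Noise-free fits report σ² = 0 and magnitude-based 0/1 p-values (threshold
  1e−8).
- Adaptive-lasso support threshold 1e−8 on rescaled coefficients; an
  all-constant response short-circuits to the intercept-only model.
- Bootstrap SEs below 1e−10·max(1, |best|) are treated as exactly zero
  (perfect-fit degeneracy).
- Stepwise ties on p-values resolve by the first-encountered maximum in
  canonical term order; designs are byte-reproducible for identical panels.
- All randomness (simulation, cross-validation folds, bootstrap) flows
  through explicit integer seeds; there is no global random state.

## Monte-Carlo study sizes

The shipped studies use 100 random instances for the least-squares oracle
comparison, 500 screens for support retention (per method), 200 campaigns
for end-to-end recovery, 1000 screens for interval coverage, and 100–200
screens for the module-level elimination and CCI studies — sizes at which
the binomial uncertainty of each reported rate is ≈1–2 percentage points.

## Known limitations

- Elimination decisions remain greedy and irreversible; a drug lost to an
  unlucky round-1 screen cannot re-enter.
- The resolution-IV first-round fraction leaves three interaction alias
  pairs with ≈2.4× the variance of clean pairs even after the A-optimal
  array embedding; weak interactions on those columns are detected with
  reduced power.
- The CCI treats the best candidate's SE as common to all candidates
  (candidate-specific SEs are available by flag but not default).
- Search-round designs beyond 7 drugs are not provided; the 11-drug pool
  enters only through candidate enumeration, as in the screens this
  platform models.
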