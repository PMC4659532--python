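# Methods

This note records the statistical model, the numerical choices and the
limits of what the synthetic-data tests demonstrate.

## Dose-response models and likelihoods

**Continuous (micronucleus) data.** The response is the percentage of cells
carrying micronuclei per culture. The mean follows the 4-parameter
exponential model `y(x) = a[c − (c−1)exp(−b x^d)]` with `a > 0` the
background (% MN at dose 0), `b ≥ 0` the potency rate (units dose^−d),
`c > 0` the asymptotic fold-change over background and `d > 0` the shape
exponent. Errors are lognormal: log-responses are normal around the log
mean with per-compound standard deviation `s`. Lognormal errors match the
strictly positive, right-skewed spread of count proportions at low
background frequencies and make geometric means the natural dose-group
summary. Responses recorded as exactly 0% are replaced by half a count
(0.5 / cells scored, as a percentage) before the log transform; the
adjustment is warned about and configurable.

**Quantal (tumour-incidence) data.** The fraction of affected animals
follows the log-logistic model `y(x) = a + (1−a)/(1 + exp(−c ln(x/b)))`
with binomial errors; `a ∈ [0,1)` is background risk, `b` the dose at 50%
extra risk, `c` the slope against natural-log dose (the logarithm base only
rescales `c`; natural log is used). The dose-0 value is the continuity
limit `a`.

**Covariate (shared-shape) clustering.** Fitting many compounds jointly,
`a_i`, `b_i` (and `s_i`) are compound-specific while `(c, d)` (continuous)
or `c` (quantal) are shared. Replicate studies of one compound are pooled
(equal weight per observation), so each compound's benchmark dose reflects
the average over its replicate studies. The shared-shape model is nested in
the free-shape model, so its maximised log-likelihood can never exceed the
free fit's; the test suite checks this nesting on simulated clusters.

## Benchmark response and benchmark dose

The BMR is a 5% *increase* in the mean response for continuous data and 10%
extra risk `(y−a)/(1−a)` for quantal data — both conventional for these
endpoints, and only increases are considered since both endpoints rise with
genotoxic insult. BMDs invert in closed form:

- continuous: `BMD = [−ln((c−1−q)/(c−1)) / b]^{1/d}` for BMR `q`; infinite
  when `c ≤ 1+q` (the plateau never reaches the BMR) or `b = 0`. The
  infinity is a sentinel, not an error: it drives the unbounded-interval
  logic.
- quantal: `BMD = b · (q/(1−q))^{1/c}`.

Because shared shape makes fitted curves parallel against log dose, the
*ratio* of two compounds' BMDs is `(b_j/b_i)^{1/d}` — independent of the
BMR. Potency rankings therefore do not depend on the BMR choice, which the
suite verifies to machine tolerance.

## Optimisation

Parameters are fitted on transformed scales for positivity (`log a`,
`log b`, `c = 1 + e^γ`, `log d`, logit `a` for quantal backgrounds) with
L-BFGS-B under box bounds (`d ∈ [0.1, 10]` by default), multi-start
(default 10 starts: one heuristic start from control means and top-dose
fold-changes, the rest perturbed). The per-compound lognormal variance is
concentrated out in closed form, with a floor of 1e−12 so exactly-fitted
data keep a finite likelihood. A best-of-starts point that L-BFGS-B does
not flag as converged is polished (Nelder-Mead in low dimension, a longer
L-BFGS-B run otherwise) and accepted when the polish cannot improve the
log-likelihood beyond a 1e−6 relative change; otherwise the fit is marked
non-converged with a warning, and profiling refuses to run on it.

## Profile-likelihood confidence intervals

The BMD of one compound is made an explicit parameter by substituting
`b_i = −ln((c−1−q)/(c−1)) / t^d` (continuous; during profiling `c` is
parameterised as `1 + q + e^γ` since a finite BMD requires `c > 1+q`) or
`b_i = t((1−q)/q)^{1/c}` (quantal). For each candidate `t` all other
parameters are re-maximised. The two-sided interval at level 0.90 is the
set where the log-likelihood drop from the global maximum is at most
`χ²₁(0.90)/2 = 1.35277`; the level is configurable.

The search brackets outward from the MLE BMD (or from the profile's best
grid point when the MLE BMD is infinite) in multiplicative steps of 2 and
bisects each crossing in log dose to 1% relative precision. Profile
evaluations warm-start from the neighbouring point's optimum; any value
falling below the threshold — i.e. about to decide a bound — is re-solved
from cold starts with systematically varied shape values, because the
profile surface can switch between shape regimes (e.g. graded-curve vs
step-like fits) and a stalled optimiser would otherwise fake a crossing.
The suite compares the resulting bounds against a brute-force dense-grid
profile with full re-optimisation and requires 2% agreement.

**Unbounded intervals.** The upper bound is reported as infinite when the
profile stays above the threshold up to an operational ceiling of 1000 ×
the compound's maximum tested dose (configurable, recorded in the result).
Symmetrically, if the lower bound escapes below max dose / 10⁶ the interval
is declared two-sided unbounded: such data cannot even distinguish "very
potent" from "not potent", the result carries no usable potency, and the
compound is dropped from correlation analyses. A *finite-upper,
unbounded-lower* interval can arise when uniformly elevated treated
responses are compatible with an arbitrarily early step; it is classified
as unbounded (excluded) and flagged in the diagnostics rather than masked.

## Cross-system correlation and prediction

Each compound contributes a rectangle `[BMDL_x, BMDU_x] × [BMDL_y, BMDU_y]`
on log10–log10 axes. Proportionality between systems is a unity-slope
line, so the correlation is summarised by two parallel unity-slope lines
(two log10 intercepts). Two modes:

- **manual** intercepts, mirroring lines drawn by eye on a published plot;
- **fitted**: per doubly-finite pair the feasible offset range is
  `[log10 y_l − log10 x_u, log10 y_u − log10 x_l]`; intercepts are the
  empirical quantiles of the offset midpoints at the target coverage
  (default 0.95 — "most" of the intervals; the envelope min/max at
  coverage 1.0), expanded symmetrically until the target fraction of finite
  rectangles intersects the band. Degenerate bands are widened to a minimum
  width (default 0.1 log10 units). Achieved coverage is recorded. Pairs
  with an infinite bound on the x side join the report but not the fit.

Prediction maps an x interval `[L, U]` to
`(10^{lo} · L, 10^{hi} · U)` — lower line at the interval's lower end,
upper line at its upper end — so both the correlation scatter and the
x-interval width enter the predicted range. An infinite `U` propagates.
The Margin of Exposure of a predicted range against an exposure estimate
uses the conventional 10 000 threshold: *no concern* when even the lower
bound's MOE exceeds it, *concern* when even the upper bound's MOE falls
short, *inconclusive* otherwise.

The dashed reference box (lowest BMDL, largest finite BMDU per axis) is
emitted as plot metadata so intervals with infinite bounds are visible as
the ones crossing outside it.

## Cytotoxicity QC

Relative population doubling per concentration:
`PD = log2(final/initial)`, `RPD = 100 · mean PD(treated) / mean
PD(control)` (arithmetic mean across replicate cultures per arm);
concentrations with RPD < 45% are flagged excessively cytotoxic. The flag
annotates the data; flagged concentrations are *not* automatically removed
from BMD fitting.

## Synthetic data

The continuous generator emulates the MN assay design: per-compound
concentration series, quadruplicate solvent controls and duplicate treated
cultures, 1000 cells scored per culture, backgrounds around 0.5–2% MN.
Noise is two-layered — a lognormal latent mean per culture (geometric SD
default 1.2) followed by a binomial count of MN-positive cells — because
the observed response is a count proportion even though the analysis models
it as continuous lognormal; the generator deliberately exercises that
mismatch, and the near-nominal interval coverage observed in the suite
shows the lognormal analysis tolerates it at these cell counts. The
quantal generator draws binomial tumour counts (50 animals per dose group).
The correlated-systems generator draws true continuous BMDs log-uniformly,
sets true quantal BMDs proportional up to lognormal scatter (log10 SD
default 0.5), and scales each compound's dose series to its own true BMD,
emulating range-finding dose selection.

What the synthetic tests do **not** show: behaviour under toxicokinetics,
metabolic activation differences, inter-laboratory effects, dose-group
outliers, or model misspecification beyond the counting layer — real
assay data can violate the shared-shape and lognormal assumptions in ways
these generators do not produce.

## Problem sizes used in the checks

The simulation-based checks run at sizes chosen to exercise the full
pipeline while staying desk-scale: interval coverage over 200 simulated
single-compound studies (6 concentrations, 2 treated / 4 control cultures,
1000 cells); oracle agreement on a 2-compound cluster scored at 10⁵ cells
per culture so both bounds fall inside the tested dose range; end-to-end
correlation on 19 compounds with 0.5 log10 cross-system scatter; parameter
recovery on 10 pooled replicate studies at 10⁶ cells per culture.

## Known limitations

- Profile bounds located in numerically flat regions of the profile (far
  below the lowest tested dose) are ill-conditioned; their exact values
  depend on optimiser tolerances, though their order of magnitude does not.
- The variance floor (1e−12) makes likelihood values on exactly-fitted data
  floor-dependent; comparisons there are only meaningful against models
  sharing the floor.
- Single-compound fits leave the shape parameters weakly identified, which
  widens intervals and makes two-sided-unbounded outcomes more common than
  in clustered fits — an argument for the covariate approach, not against
  the implementation.
- No model averaging, bootstrap/Bayesian intervals, toxicokinetic
  adjustment, or formal estimation of prediction precision for the band.
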