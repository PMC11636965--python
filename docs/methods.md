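# Methods

## Model and hypothesis

A K-stage treatment regime d = (d_1, ..., d_K) is a sequence of rules,
each mapping a subject's accrued history h_k (prior treatments, response
status, covariates) to an option in the feasible subset Psi_k(h_k) of the
stage-k option set. For the potential event time T*(d) of a subject
following d, the hazard is lambda(u, d). Given a comparison set
D = {d^1, ..., d^D} (typically a SMART's embedded regimes), the null
hypothesis is equality of all D hazard functions at every u. The test is
a generalized score test in the spirit of the logrank test: a working
proportional-hazards structure lambda(u, d^j) = lambda_0(u) exp(beta_j)
(reference d^D) motivates a score vector evaluated at beta = 0; the
working model is a device only — no beta is ever estimated, and the test
is valid as a test of equality regardless of whether proportionality could
hold.

## Identification and weighting

The observed data per subject are kappa (decision points reached),
decision times T_1 = 0 < ... < T_kappa, stage covariate blocks,
treatments A_1..A_kappa, follow-up U and event indicator Delta. The
observed-data statistic identifies the potential-outcome score under the
standard sequential-randomization (guaranteed by design in a SMART),
consistency, positivity, and noninformative-censoring assumptions.
Censoring is further assumed independent of the evolving history, with
the possible exception of stage-1 treatment; under that assumption the
weight choice

    Omega(u, d) = C(u, d) I(U >= u) / pi(u, d)

makes the censoring survival function cancel, so no censoring model is
fitted. C(u, d) multiplies per-stage match indicators only over decisions
already reached by u, so a future mismatch does not disqualify a subject
before it happens; pi(u, d) multiplies the assignment probabilities of
the options *the regime assigns* (not those received) over reached
decisions. Both are right-continuous step functions changing only at a
subject's decision times, so evaluating them on the event-time grid is
exact (no quadrature error). Subjects with zero weight never have pi
evaluated, so unreachable strata need no rules.

## The statistic, its covariance, and rank

With dN_i(u), Y_i(u) the counting-process quantities (ties share a grid
point; at-risk is closed at u, so events precede censorings at tied
times), the pooled weighted hazard increment dL0(u) and score components
T^j are as in the README. The influence expansion

    T^j_i = sum_u Omega_i(u,d^j) M_i(u)
            - sum_{j'} sum_u Omega_i(u,d^{j'}) q(u,d^j) M_i(u),

with M_i(u) = dN_i(u) - dL0(u) Y_i(u) and q(u,d^j) regime j's share of
the pooled weighted risk set, makes the score a sum of asymptotically iid
terms; the plug-in version satisfies sum_i T^j_i = T^j exactly (the
subtracted part vanishes by the defining equation of dL0), which the test
suite asserts to 1e-8 relative. The covariance estimate is
Sigma = n^-1 sum_i T_i T_i'.

Shared-path regime sets make Sigma exactly singular. For the
response-stratified design with all 8 embedded regimes, the four regimes
sharing an initial arm satisfy one exact linear relation among their
weights (the two single-stratum rule changes commute), and the
per-subject influence rows of all D regimes sum to zero; together these
reduce the 7x7 covariance to rank 5. The 2x2 and responder-switch designs
have no such relation and give full rank 3. The statistic uses the
eigendecomposition pseudoinverse: eigenvalues above `rank_tolerance`
(default 1e-8) times the largest count toward the rank nu, and
Z = n^-1 T' Sigma^- T is referred to chi-square with nu degrees of
freedom. Rank 0 (e.g. a zero score) returns Z = 0, p = 1 with a warning.
The choice of reference regime is immaterial: relabeling changes T and
Sigma but leaves Z unchanged (asserted to 1e-6 relative).

## Truncation

Late event times have sparse, heavily weighted risk sets; the score
integral is truncated at L, by default the largest event time at which at
least 2% of subjects remain at risk (the midpoint of the customary 1-4%
rule of thumb), overridable by an explicit L or target fraction.

## Estimated propensities, residual adjustment, covariates

Although the randomization probabilities are known in a SMART, the test
based on stratified maximum-likelihood estimates (within-stratum sample
proportions of each feasible option) is asymptotically at least as
powerful, provided the estimation is accounted for: the per-subject
influence values are regressed (least squares, **no intercept**) on the
propensity score contributions — for the saturated stratified model, the
columns I(subject in stratum) {I(A_k = a) - omega_hat} per non-reference
option, which sum to zero at the fit — and the residuals replace the
influence values in Sigma. Because every regressor column sums to zero,
the residual column sums still equal T; an intercept would instead force
them to zero and destroy the statistic. Strata with a single feasible
option carry no parameter. The stratified fit requires every feasible
option observed at least once in every reached stratum; an empty cell is
a hard error naming the stratum (the ML estimate would sit on the
boundary and the weights would degenerate). Unreached strata retain the
design probabilities, which the weights never query. A per-stratum binary
logistic mode (statsmodels, Newton, gradient-norm check at 1e-8·n) serves
observational data; multinomial strata are supported in stratified mode
only.

Covariate adjustment adds centered history functions to the regression:
each stage-1 covariate as-is and each stage-k covariate multiplied by the
indicator of reaching stage k (0 imputed otherwise), all mean-centered;
the config can restrict to covariates thought strongly outcome-associated.
One honest caveat: with randomization independent of covariates and a
symmetric regime set, these raw history functions are asymptotically
uncorrelated with the influence columns (the weight has unit conditional
expectation given history, so the covariate-driven component of the
martingale residual enters all regimes' columns equally and cancels), so
the default adjustment is close to a no-op — harmless, but the observable
power gain is small. Larger gains would require regressors that interact
history functions with the assignment residuals, i.e. enlarging the
propensity-model score space; this is left as future work.

## Small-sample correction

Sandwich covariances understate variability at modest n, making the tests
anti-conservative. The implemented correction inflates Sigma by
n / (n - p_eff), where p_eff counts the score dimension (D - 1) plus the
residual-regression columns used; it strictly deflates Z, never changes
the rank, and vanishes as n grows. This is a deliberately simple
degrees-of-freedom accounting — the package's own choice, exposed as
`correction="dof"` with `"none"` available — and it is weaker than ideal:
at n = 250-375 it removes only part of the observed inflation (e.g.
roughly 0.058 -> 0.056 at n = 250 in the 2x2 null scenario), so corrected
rejection rates at small n sit slightly above the nominal 0.05 where a
sharper correction would sit at it. Alternatives can be hooked in at
`bias_correct`.

## The synthetic-data generator

The simulator generates subjects through latent phases separated by the
decision times: a piecewise-exponential event hazard whose phase-k rate
is base_rate · exp(linear predictor of the covariates observed by stage
k). Under a null configuration the hazard never depends on treatment, so
lambda(u, d) is identical across regimes *by construction* (verified
empirically by KS comparisons of directly sampled potential event times);
under an alternative the final-phase hazard of subjects starting on a
designated arm is multiplied by zeta (zeta = 1 recovers the null
exactly). Response status and intermediate covariates are disease
progression, so they are generated for every subject — including an
optional never-re-randomized control arm — while only subjects still
under follow-up reach the later randomizations; censoring is uniform on a
window, independent of everything.

Built-in scenarios (each with an `alt_*` twin):

| scenario | design (regimes) | covariate effects | censoring |
|---|---|---|---|
| `null_switch` | responder-switch (4) | none | 25-40% |
| `null_switch_cov` | responder-switch (4) | stages 1+2 | 25-40% |
| `null_twobytwo` | 2x2 re-randomization (4) | stages 1+2 | 30-45% |
| `null_control` | responder-switch + control (5) | stages 1+2 | 30-45% |
| `null_stratified` | response-stratified (8) | stages 1+2 | 30-40% |

Defaults: base rate 0.4 (0.5 for `null_switch`), decision-2 window
uniform (0.3, 0.9), censoring uniform (0.3, 4.2), responder probability
0.5, covariates one Bernoulli(0.5) and one standard normal at baseline
plus one standard normal intermediate, log-hazard coefficients 0.5 / 0.3
/ 0.4. These place roughly two-thirds of (non-control) subjects at the
second randomization — as in typical two-stage oncology SMARTs — which
keeps every randomization cell populated at the sample sizes studied, and
put the realized censoring inside each scenario's stated range. Per-
replicate RNG streams derive from (master seed, replicate index), so
Monte-Carlo runs are reproducible and independent of which test variants
are evaluated.

What the generator does **not** emulate: covariate-dependent or
history-dependent censoring, time-varying covariates between decisions,
regime rules depending on continuous covariates, and treatment effects
other than a proportional final-phase multiplier. Passing calibration
here therefore shows correct behavior under independent censoring and
discrete feasibility strata, not robustness beyond those assumptions.

## Problem sizes

The test suite checks covariance ranks over 20 seeds at n = 500 and runs
the null calibrations at 2000 Monte-Carlo replicates (MC SE about 0.005);
`scripts/acceptance.py` uses 5000 replicates (MC SE about 0.003) for the
n = 250 scenario and 2000 for the n = 375 and n = 500 scenarios. Power
comparisons use 150 replicates, enough for the 2-MC-SE qualitative
contrasts they assert.

## Known limitations

* Earlier martingale-based comparator statistics for two-stage designs
  are not implemented; only the influence-function-based test is provided.
* No estimation of hazard ratios or confidence intervals — the working
  proportional-hazards structure is a test device only.
* Weight functions for censoring depending on the post-baseline history
  are out of scope; the implemented weight assumes the cancellation form.
* User-supplied rule callables beyond discrete strata are accepted only
  through explicit rule tables; continuous-covariate rules are untested.
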