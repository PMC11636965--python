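# glogrank

Generalized logrank-type tests for comparing multistage treatment regimes
with a time-to-event outcome, from sequential multiple assignment
randomized trial (SMART) or observational data.

## Why

In a SMART, subjects are randomized at each of K decision points, with the
options at a later decision depending on evolving status (e.g. response to
the initial treatment). The design implies a set of *embedded regimes* —
complete treatment strategies of the form "give a initially; if response,
give b; else give c" — and a natural primary question: **do the survival
distributions that would result from following each regime differ?**

Classical logrank machinery does not apply directly: a single subject's
data can be consistent with several regimes at once ("shared paths"), and
the set of regimes a subject can still match changes over time. `glogrank`
implements a test of

    H0 : lambda(u, d^1) = ... = lambda(u, d^D)   for all u >= 0,

the equality of the hazard functions of the potential event times under
each regime d^j in a user-chosen comparison set, for any number of stages
and any regime set (all embedded regimes, or a pair for a focused
comparison).

## The statistic

For subject i, regime d and time u, let C_i(u,d) indicate that every
treatment received by u matches what d would have assigned, pi_i(u,d) be
the product of the assignment probabilities of the options d assigns over
decisions reached by u, and

    Omega_i(u,d) = C_i(u,d) I(U_i >= u) / pi_i(u,d)

be the inverse-probability weight that makes the subjects consistent with
d represent the whole population following d. Under censoring independent
of the evolving history (apart possibly from the initial treatment) the
censoring distribution cancels from this weight. With dN_i(u) and Y_i(u)
the usual counting-process event and at-risk indicators and

    dL0(u) = sum_ij Omega_i(u,d^j) dN_i(u) / sum_ij Omega_i(u,d^j) Y_i(u)

the pooled weighted Nelson–Aalen increment, the score vector has
components (j = 1..D-1, the last regime acting as reference)

    T^j = sum_i sum_{u <= L} Omega_i(u,d^j) {dN_i(u) - dL0(u) Y_i(u)},

with the integration truncated at a time L where a small fraction
(default 2%) of subjects remain at risk. The per-subject influence
expansion of T yields a sandwich covariance Sigma, and the test statistic

    Z = n^-1 T' Sigma^- T  ~  chi-square(rank(Sigma))   under H0,

where a generalized (eigendecomposition) inverse handles the exact
singularities that shared-path regime sets induce (e.g. the full set of 8
embedded regimes of a response-stratified two-stage design gives a 7x7
covariance of rank 5).

Estimating the (known) randomization probabilities by within-stratum
sample proportions and residualizing the influence contributions on the
propensity-model score — optionally together with centered baseline and
intermediate covariates — gives an asymptotically at-least-as-powerful
test, and a small-sample covariance correction counters the mild
anti-conservativeness of sandwich variances at modest n.

## Worked example

```python
from glogrank import (enumerate_embedded_regimes, get_scenario,
                      run_glogrank, simulate_dataset, TestOptions)

cfg = get_scenario("null_twobytwo")      # 2x2 re-randomization design
data = simulate_dataset(cfg, n=250, seed=1)
regimes = enumerate_embedded_regimes(data.design)
result = run_glogrank(data, regimes, TestOptions(correction="dof"))
print(f"Z = {result.statistic:.3f}, df = {result.df}, "
      f"p = {result.p_value:.3f}, L = {result.L:.2f}")
```

prints

```
Z = 2.057, df = 3, p = 0.561, L = 3.47
```

a statistic of 2.06 on 3 degrees of freedom (4 regimes compared, full-rank
covariance): no evidence against equal regime hazards — as expected, since
the scenario generates data under the null. The integration was truncated
at L = 3.47, the last event time with at least 2% of the sample at risk.

The same analysis from the shell:

```sh
glogrank simulate --scenario null_twobytwo --n 250 --seed 1 --out data.csv
glogrank test --data data.csv --config design.yaml --out result.json
glogrank regimes --config design.yaml       # list embedded regimes
glogrank calibrate --scenario null_twobytwo --n 250 --reps 1000 --seed 7
```

## Design configuration

A design is a YAML/JSON file: per stage its full option set, the
feasibility strata (each a discrete history classification), the feasible
subset and randomization probabilities per stratum. `key_features` names
the history features forming the stratum key: `a<j>` means the stage-j
treatment; any other name is a (discrete) stage covariate, e.g. a binary
`response` recorded in the stage-2 block (column `x2_response` in the
CSV).

```yaml
label: response-stratified
stages:
  - options: [0, 1]
    strata:
      - {key: [], feasible: [0, 1], probs: [0.5, 0.5]}
  - options: [2, 3, 4, 5]
    key_features: [a1, response]
    strata:
      - {key: [1, 1], feasible: [2, 5], probs: [0.5, 0.5]}
      - {key: [1, 0], feasible: [3, 5], probs: [0.5, 0.5]}
      - {key: [0, 1], feasible: [2, 4], probs: [0.5, 0.5]}
      - {key: [0, 0], feasible: [3, 4], probs: [0.5, 0.5]}
```

Data are wide CSV: `id, kappa, t1..tK, a1..aK, u, delta` plus covariate
columns `x<k>_<name>`, with stage-k fields blank for subjects who never
reached decision k.

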