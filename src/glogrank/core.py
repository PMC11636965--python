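"""The generalized logrank-type test for sets of multistage regimes.

The null hypothesis is equality of the hazard functions of the potential
event times under every regime in a user-chosen set D = (d^1, ..., d^D);
the last regime plays the role of reference.  For each subject, regime and
time u the machinery evaluates

* the consistency indicator C_i(u, d): 1 while every treatment the subject
  received by u matches what d would have assigned given the subject's
  history;
* the regime propensity pi_i(u, d): the product, over decisions reached by
  u, of the assignment probability of the option d assigns; and
* the inverse-probability weight Omega_i(u, d) = C_i(u, d) I(U_i >= u) /
  pi_i(u, d), which re-weights the subjects consistent with d to represent
  the whole population following d.  Under censoring that is independent of
  the evolving history (apart possibly from stage-1 treatment), the
  censoring survival function cancels from this weight, so no censoring
  model is needed.

From the weights, a pooled baseline-hazard increment dLambda0(u) (the
weighted Nelson-Aalen increment over all regimes), a (D-1)-vector score
T with components sum_i sum_u Omega_i(u, d^j) {dN_i(u) - dLambda0(u)
Y_i(u)}, a per-subject influence expansion whose columns sum exactly to T,
the sandwich covariance Sigma = n^-1 sum_i T_i T_i', and the statistic
Z = n^-1 T' Sigma^- T, referred to chi-square with df = rank(Sigma).
Sigma is singular by construction for some designs (shared-path regime
sets), hence the eigendecomposition pseudoinverse.

When assignment probabilities are estimated (or covariates are used to
sharpen the test), the influence terms are residualized on the propensity
score contributions and centered history functions before forming the
covariance; with the optional small-sample correction this gives the
bias-corrected statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .data import Dataset, SubjectRecord, choose_truncation, event_grid
from .design import Regime, SmartDesign
from .propensity import (
    PropensityModel,
    fit_logistic,
    fit_stratified,
    known_model,
    score_contributions,
)

__all__ = [
    "TestOptions",
    "TestResult",
    "consistency_indicator",
    "regime_propensity",
    "ipw_weight",
    "baseline_hazard_increments",
    "score_vector",
    "influence_matrix",
    "covariance",
    "residual_adjust",
    "bias_correct",
    "gscore_test",
    "history_covariate_matrix",
    "run_glogrank",
]


# ---------------------------------------------------------------------------
# definitional per-subject quantities (scalar path)


def _assigned_option(subject, regime, design, k):
    key = subject.stratum_key(design, k)
    stratum = design.stratum(k, key)
    rule = regime.rule_map.get((k, key))
    return rule, key, stratum


def consistency_indicator(
    subject: SubjectRecord, regime: Regime, design: SmartDesign, u: float
) -> int:
    """C(u, d): 1 iff every treatment received by time u matches the
    regime's rule; decisions not yet reached by u never break consistency."""
    for k in range(1, subject.kappa + 1):
        if subject.decision_times[k - 1] > u:
            continue
        rule, key, _ = _assigned_option(subject, regime, design, k)
        if rule is None:
            # stratum unreachable under the regime: consistency must have
            # broken at an earlier decision
            if all(
                subject.decision_times[kk - 1] > u
                or subject.treatments[kk - 1]
                == _assigned_option(subject, regime, design, kk)[0]
                for kk in range(1, k)
            ):
                raise KeyError(
                    f"regime {regime.label!r} has no rule for stage {k} "
                    f"stratum {key!r} of subject {subject.id}"
                )
            return 0
        if subject.treatments[k - 1] != rule:
            return 0
    return 1


def regime_propensity(
    subject: SubjectRecord,
    regime: Regime,
    design: SmartDesign,
    u: float,
    model: PropensityModel,
) -> float:
    """pi(u, d): product over decisions reached by u of the assignment
    probability of the option the regime assigns given the subject's
    history."""
    pi = 1.0
    for k in range(1, subject.kappa + 1):
        if subject.decision_times[k - 1] > u:
            continue
        rule, key, stratum = _assigned_option(subject, regime, design, k)
        if rule is None:
            continue  # irrelevant once inconsistent; C handles it
        w = model.omega(subject, k, rule)
        if w <= 0:
            raise ValueError(
                f"assignment probability 0 for stage {k} stratum {key!r} "
                f"option {rule!r} (positivity violation)"
            )
        pi *= w
    return pi


def ipw_weight(
    subject: SubjectRecord,
    regime: Regime,
    design: SmartDesign,
    u: float,
    model: PropensityModel,
) -> float:
    """Omega(u, d) = C(u, d) I(U >= u) / pi(u, d); 0 for subjects off the
    regime's path or no longer at risk (pi is then not evaluated)."""
    if subject.followup_time < u:
        return 0.0
    if consistency_indicator(subject, regime, design, u) == 0:
        return 0.0
    return 1.0 / regime_propensity(subject, regime, design, u, model)


# ---------------------------------------------------------------------------
# vectorized engine


def _omega_value(model, rec, k, key, stratum, option):
    if model.mode == "logistic" and (k, key) in model.logit:
        coefs, covs, modeled = model.logit[(k, key)]
        from .propensity import _design_row

        p = 1.0 / (1.0 + np.exp(-float(_design_row(rec, k, covs) @ coefs)))
        return p if option == modeled else 1.0 - p
    return model.tables[(k, key)][option]


class _Prepared:
    """Per-(subject, stage, regime) assignment data shared by all grid
    evaluations: decision times, break times of consistency, and cumulative
    log-propensities of the regime-assigned options."""

    def __init__(self, dataset: Dataset, regimes: Sequence[Regime],
                 model: PropensityModel):
        design = dataset.design
        n, D, K = dataset.n, len(regimes), design.K
        self.U = np.array(
            [r.followup_time for r in dataset.subjects], dtype=float
        )
        self.delta = np.array(
            [r.event for r in dataset.subjects], dtype=bool
        )
        self.T = np.full((n, K), np.inf)
        break_time = np.full((n, D), np.inf)
        logw = np.zeros((n, K, D))
        for i, rec in enumerate(dataset.subjects):
            for k in range(1, rec.kappa + 1):
                t_k = rec.decision_times[k - 1]
                self.T[i, k - 1] = t_k
                key = rec.stratum_key(design, k)
                stratum = design.stratum(k, key)
                for j, regime in enumerate(regimes):
                    rule = regime.rule_map.get((k, key))
                    if rule is None:
                        if break_time[i, j] == np.inf:
                            raise KeyError(
                                f"regime {regime.label!r} has no rule for "
                                f"stage {k} stratum {key!r} of subject "
                                f"{rec.id}"
                            )
                        continue
                    w = _omega_value(model, rec, k, key, stratum, rule)
                    if w <= 0:
                        raise ValueError(
                            f"assignment probability 0 at stage {k} "
                            f"stratum {key!r} option {rule!r}"
                        )
                    logw[i, k - 1, j] = np.log(w)
                    if (
                        rec.treatments[k - 1] != rule
                        and t_k < break_time[i, j]
                    ):
                        break_time[i, j] = t_k
        self.break_time = break_time
        # cumulative log pi over stages; index by number of reached stages
        self.cum_logw = np.concatenate(
            [np.zeros((n, 1, D)), np.cumsum(logw, axis=1)], axis=1
        )
        self.n, self.D, self.K = n, D, K

    def weights(self, grid: np.ndarray) -> np.ndarray:
        """Omega_i(u, d^j) on the grid: array (n, m, D)."""
        # log pi(i, u, j) = sum_k I(T_ik <= u) log omega_ikj
        reached = self.T[:, :, None] <= grid[None, None, :]  # (n, K, m)
        logw = self.cum_logw[:, 1:, :] - self.cum_logw[:, :-1, :]
        out = np.einsum("nkm,nkd->nmd", reached, logw)
        np.exp(np.negative(out, out=out), out=out)
        at_risk = self.U[:, None] >= grid[None, :]
        out *= at_risk[:, :, None]
        out *= grid[None, :, None] < self.break_time[:, None, :]
        return out

    def counting(self, grid: np.ndarray):
        """(dN, Y) on the grid, each (n, m)."""
        dN = (self.U[:, None] == grid[None, :]) & self.delta[:, None]
        Y = self.U[:, None] >= grid[None, :]
        return dN.astype(float), Y.astype(float)


@dataclass
class BaselineHazard:
    """Pooled weighted Nelson-Aalen increments dLambda0(u) on the event
    grid (0/0 risk sets contribute 0)."""

    grid: np.ndarray
    increments: np.ndarray


@dataclass
class ScoreVector:
    """Score components for regimes d^1..d^{D-1} against the reference
    d^D, truncated at L."""

    values: np.ndarray  # (D-1,)
    regimes: list[Regime]
    L: float


@dataclass
class InfluenceMatrix:
    """Per-subject influence contributions; column sums equal the score
    vector exactly."""

    values: np.ndarray  # (n, D-1)
    regimes: list[Regime]
    L: float
    adjusted: bool = False
    n_regressors: int = 0

    @property
    def score(self) -> np.ndarray:
        return self.values.sum(axis=0)


@dataclass
class CovarianceEstimate:
    matrix: np.ndarray
    rank: int
    rank_tolerance: float
    corrected: bool = False
    adjusted: bool = False
    eigvals: np.ndarray = field(default=None, repr=False)
    eigvecs: np.ndarray = field(default=None, repr=False)


@dataclass
class TestOptions:
    """Options of :func:`run_glogrank`.

    propensity: "known", "stratified" (ML sample proportions; the default,
    more powerful than plugging in known values once accounted for) or
    "logistic".  covariates: None, "all", or a list of covariate names to
    residual-adjust on.  correction: "none" or "dof" (multiply the
    covariance by n/(n - p_eff)).  L overrides the truncation rule;
    otherwise L is the largest event time with at least target_fraction of
    subjects still at risk.
    """

    __test__ = False  # not a pytest class, despite the name

    propensity: str = "stratified"
    covariates: Union[None, str, Sequence[str]] = None
    covariate_spec: Optional[dict] = None  # logistic-mode model covariates
    correction: str = "dof"
    L: Optional[float] = None
    target_fraction: float = 0.02
    rank_tolerance: float = 1e-8


@dataclass
class TestResult:
    __test__ = False  # not a pytest class, despite the name

    statistic: float
    df: int
    p_value: float
    score: ScoreVector
    covariance: CovarianceEstimate
    options: TestOptions
    n: int
    L: float
    regimes: list[Regime]
    diagnostics: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "statistic": self.statistic,
            "df": self.df,
            "p_value": self.p_value,
            "n": self.n,
            "L": self.L,
            "regimes": [r.label for r in self.regimes],
            "score": [float(v) for v in self.score.values],
            "covariance": self.covariance.matrix.tolist(),
            "rank_tolerance": self.covariance.rank_tolerance,
            "options": {
                "propensity": self.options.propensity,
                "covariates": (
                    list(self.options.covariates)
                    if isinstance(self.options.covariates, (list, tuple))
                    else self.options.covariates
                ),
                "correction": self.options.correction,
                "target_fraction": self.options.target_fraction,
            },
            "diagnostics": self.diagnostics,
        }


# ---------------------------------------------------------------------------
# pieces of the statistic


def _hazard_increments(Omega, dN, Y):
    num = np.einsum("imj,im->m", Omega, dN)
    den = np.einsum("imj,im->m", Omega, Y)
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return inc


def baseline_hazard_increments(
    dataset: Dataset,
    regimes: Sequence[Regime],
    model: PropensityModel,
    L: float = np.inf,
) -> BaselineHazard:
    """dLambda0(u) = sum_ij Omega dN / sum_ij Omega Y on the event grid.

    With a single regime and unit weights this is the Nelson-Aalen
    estimator; with equal randomization the constant inverse weights cancel
    and the pooled Nelson-Aalen increments are recovered.
    """
    grid = event_grid(dataset, L)
    prep = _Prepared(dataset, list(regimes), model)
    Omega = prep.weights(grid)
    dN, Y = prep.counting(grid)
    return BaselineHazard(grid=grid,
                          increments=_hazard_increments(Omega, dN, Y))


def _engine(dataset, regimes, model, L):
    grid = event_grid(dataset, L)
    prep = _Prepared(dataset, list(regimes), model)
    Omega = prep.weights(grid)
    dN, Y = prep.counting(grid)
    inc = _hazard_increments(Omega, dN, Y)
    M = dN - inc[None, :] * Y  # martingale-type residual increments
    term1 = np.einsum("imj,im->ij", Omega, M)  # all D columns
    risk = np.einsum("imj,im->mj", Omega, Y)
    pooled = risk.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        q = np.where(pooled[:, None] > 0,
                     risk / np.where(pooled > 0, pooled, 1.0)[:, None], 0.0)
    omnibus = (Omega.sum(axis=2) * M)  # (n, m): sum_j' Omega * M
    term2 = omnibus @ q  # (n, D)
    infl_full = term1 - term2
    return grid, infl_full, risk, prep


def score_vector(
    dataset: Dataset,
    regimes: Sequence[Regime],
    model: PropensityModel,
    L: float = np.inf,
) -> ScoreVector:
    """The (D-1)-vector of weighted observed-minus-expected event sums for
    regimes d^1..d^{D-1}, with d^D the reference."""
    regimes = list(regimes)
    if len(regimes) < 2:
        raise ValueError("need at least two regimes to compare")
    if len(set(regimes)) != len(regimes):
        raise ValueError("regimes in the comparison set must be distinct")
    grid = event_grid(dataset, L)
    prep = _Prepared(dataset, regimes, model)
    Omega = prep.weights(grid)
    dN, Y = prep.counting(grid)
    inc = _hazard_increments(Omega, dN, Y)
    M = dN - inc[None, :] * Y
    values = np.einsum("imj,im->j", Omega, M)[:-1]
    return ScoreVector(values=values, regimes=regimes, L=L)


def influence_matrix(
    dataset: Dataset,
    regimes: Sequence[Regime],
    model: PropensityModel,
    L: float = np.inf,
) -> InfluenceMatrix:
    """Per-subject iid-expansion terms of the score.

    Each subject's contribution subtracts, from its own weighted
    observed-minus-expected sum, the share q(u, d^j) of its pooled
    contribution, where q(u, d^j) is regime j's fraction of the pooled
    weighted risk set; the subtracted parts sum to zero over subjects, so
    the column sums reproduce the score exactly.
    """
    regimes = list(regimes)
    if len(regimes) < 2:
        raise ValueError("need at least two regimes to compare")
    _, infl_full, _, _ = _engine(dataset, regimes, model, L)
    return InfluenceMatrix(
        values=infl_full[:, :-1], regimes=regimes, L=L
    )


def covariance(
    influence: InfluenceMatrix, rank_tolerance: float = 1e-8
) -> CovarianceEstimate:
    """Sigma = n^-1 sum_i T_i T_i' with numerical rank: eigenvalues above
    rank_tolerance times the largest count toward the rank."""
    V = influence.values
    n = V.shape[0]
    Sigma = (V.T @ V) / n
    Sigma = (Sigma + Sigma.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(Sigma)
    lam_max = eigvals.max(initial=0.0)
    rank = (
        int((eigvals > rank_tolerance * lam_max).sum()) if lam_max > 0 else 0
    )
    return CovarianceEstimate(
        matrix=Sigma,
        rank=rank,
        rank_tolerance=rank_tolerance,
        adjusted=influence.adjusted,
        eigvals=eigvals,
        eigvecs=eigvecs,
    )


def residual_adjust(
    influence: InfluenceMatrix,
    regressors: np.ndarray,
    columns: Optional[Sequence[str]] = None,
) -> InfluenceMatrix:
    """Replace influence contributions by their residuals from a no-
    intercept least-squares fit on `regressors`.

    Regressor columns must sum to (numerically) zero — propensity score
    contributions do at the ML fit, and history functions are mean-centered
    by :func:`history_covariate_matrix` — so the residual column sums, and
    hence the score, are unchanged while the covariance shrinks.  Constant
    (zero-variance) columns are dropped; genuinely collinear columns are an
    error.
    """
    V = influence.values
    n = V.shape[0]
    X = np.asarray(regressors, dtype=float)
    if X.ndim != 2 or X.shape[0] != n:
        raise ValueError("regressor matrix must be n x p")
    names = list(columns) if columns is not None else [
        f"col{j}" for j in range(X.shape[1])
    ]
    keep = [
        j for j in range(X.shape[1])
        if np.ptp(X[:, j]) > 0
    ]
    X = X[:, keep]
    names = [names[j] for j in keep]
    if X.shape[1] == 0:
        return InfluenceMatrix(
            values=V.copy(), regimes=influence.regimes, L=influence.L,
            adjusted=True, n_regressors=0,
        )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # name the offending columns via pivoted QR
        from scipy.linalg import qr

        _, _, piv = qr(X, mode="economic", pivoting=True)
        bad = sorted(names[j] for j in piv[rank:])
        raise ValueError(
            f"regressor matrix rank deficient; collinear column(s): "
            f"{', '.join(bad)}"
        )
    beta, *_ = np.linalg.lstsq(X, V, rcond=None)
    resid = V - X @ beta
    return InfluenceMatrix(
        values=resid, regimes=influence.regimes, L=influence.L,
        adjusted=True, n_regressors=X.shape[1],
    )


def bias_correct(
    cov: CovarianceEstimate, n: int, p_eff: int
) -> CovarianceEstimate:
    """Degrees-of-freedom inflation n/(n - p_eff) of the covariance, where
    p_eff counts the score components plus any residual-regression columns;
    deflates the statistic, countering small-sample anti-conservativeness.
    """
    if n <= p_eff:
        raise ValueError(f"n={n} <= p_eff={p_eff}; correction undefined")
    factor = n / (n - p_eff)
    return CovarianceEstimate(
        matrix=cov.matrix * factor,
        rank=cov.rank,
        rank_tolerance=cov.rank_tolerance,
        corrected=True,
        adjusted=cov.adjusted,
        eigvals=cov.eigvals * factor,
        eigvecs=cov.eigvecs,
    )


def gscore_test(
    score: Union[ScoreVector, np.ndarray],
    cov: CovarianceEstimate,
    n: int,
) -> tuple[float, int, float]:
    """Z = n^-1 T' Sigma^- T with the eigendecomposition pseudoinverse at
    the covariance's rank; returns (statistic, df, p) with p the upper-tail
    chi-square probability at df = rank."""
    t = score.values if isinstance(score, ScoreVector) else np.asarray(score)
    if t.shape[0] != cov.matrix.shape[0]:
        raise ValueError("score / covariance dimension mismatch")
    if cov.rank == 0:
        warnings.warn("covariance has rank 0; statistic set to 0",
                      stacklevel=2)
        return 0.0, 0, 1.0
    eigvals, eigvecs = cov.eigvals, cov.eigvecs
    if eigvals is None:
        eigvals, eigvecs = np.linalg.eigh(cov.matrix)
    lam_max = eigvals.max()
    keep = eigvals > cov.rank_tolerance * lam_max
    proj = eigvecs[:, keep].T @ t
    z = float(proj @ (proj / eigvals[keep])) / n
    p = float(stats.chi2.sf(z, cov.rank))
    return z, cov.rank, p


def history_covariate_matrix(
    dataset: Dataset,
    names: Union[None, str, Sequence[str]] = "all",
) -> tuple[np.ndarray, list[str]]:
    """Mean-centered history functions for covariate adjustment.

    Stage-1 covariates enter as-is; each stage-k (k >= 2) covariate enters
    multiplied by the indicator of having reached stage k, with 0 imputed
    for subjects who did not.  `names` restricts to specific covariates
    (prefixed form ``x<k>_<name>`` or bare name).
    """
    K = dataset.design.K
    labels: list[str] = []
    for k in range(K):
        seen: list[str] = []
        for rec in dataset.subjects:
            if k < rec.kappa:
                for name in rec.covariates[k]:
                    if name not in seen:
                        seen.append(name)
        labels.extend(f"x{k + 1}_{nm}" for nm in seen)
    if names not in (None, "all"):
        wanted = set(names)
        labels = [
            lb for lb in labels
            if lb in wanted or lb.split("_", 1)[1] in wanted
        ]
        found = {lb for lb in labels} | {
            lb.split("_", 1)[1] for lb in labels
        }
        missing = wanted - found
        if missing:
            raise KeyError(
                f"covariate(s) not present in data: {sorted(missing)}"
            )
    cols = np.zeros((dataset.n, len(labels)))
    for j, lb in enumerate(labels):
        k_str, nm = lb.split("_", 1)
        k = int(k_str[1:])
        for i, rec in enumerate(dataset.subjects):
            if k <= rec.kappa and nm in rec.covariates[k - 1]:
                cols[i, j] = float(rec.covariates[k - 1][nm])
    cols -= cols.mean(axis=0, keepdims=True)
    return cols, labels


def run_glogrank(
    dataset: Dataset,
    regimes: Sequence[Regime],
    options: Optional[TestOptions] = None,
) -> TestResult:
    """Full pipeline: truncation, propensity fit, weights, score,
    influence expansion, optional residual adjustment and small-sample
    correction, generalized-inverse quadratic form."""
    options = options or TestOptions()
    regimes = list(regimes)
    design = dataset.design

    if options.L is not None:
        L = float(options.L)
    else:
        L = choose_truncation(dataset, options.target_fraction).L

    if options.propensity == "known":
        model = known_model(design)
    elif options.propensity == "stratified":
        model = fit_stratified(dataset, design)
    elif options.propensity == "logistic":
        model = fit_logistic(dataset, design, options.covariate_spec)
    else:
        raise ValueError(f"unknown propensity mode {options.propensity!r}")

    grid, infl_full, risk, prep = _engine(dataset, regimes, model, L)
    infl = InfluenceMatrix(values=infl_full[:, :-1], regimes=regimes, L=L)
    score = ScoreVector(values=infl.score, regimes=regimes, L=L)

    regressor_blocks, regressor_names = [], []
    if model.mode != "known":
        sm = score_contributions(model, dataset)
        if sm.values.shape[1]:
            regressor_blocks.append(sm.values)
            regressor_names.extend(sm.columns)
    if options.covariates is not None:
        X, labels = history_covariate_matrix(dataset, options.covariates)
        if X.shape[1]:
            regressor_blocks.append(X)
            regressor_names.extend(labels)

    if regressor_blocks:
        infl = residual_adjust(
            infl, np.column_stack(regressor_blocks), regressor_names
        )

    cov = covariance(infl, options.rank_tolerance)
    if options.correction == "dof":
        p_eff = (len(regimes) - 1) + infl.n_regressors
        cov = bias_correct(cov, dataset.n, p_eff)
    elif options.correction != "none":
        raise ValueError(f"unknown correction {options.correction!r}")

    z, df, p = gscore_test(score, cov, dataset.n)

    diagnostics = {
        "consistent_subjects": {
            r.label: int((prep.break_time[:, j] == np.inf).sum())
            for j, r in enumerate(regimes)
        },
        "weighted_at_risk": {
            "grid": grid.tolist(),
            **{
                r.label: risk[:, j].tolist()
                for j, r in enumerate(regimes)
            },
        },
        "n_regressors": infl.n_regressors,
    }
    return TestResult(
        statistic=z,
        df=df,
        p_value=p,
        score=score,
        covariance=cov,
        options=options,
        n=dataset.n,
        L=L,
        regimes=regimes,
        diagnostics=diagnostics,
    )
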