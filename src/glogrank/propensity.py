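"""Treatment-assignment probability models.

Three modes are supported:

* ``known`` — the design's randomization probabilities, used verbatim.
* ``stratified_ml`` — saturated maximum likelihood per feasibility stratum:
  the fitted probability of each feasible option is the sample proportion
  among subjects reaching the stratum.  Estimating the (known) probabilities
  this way, with the estimation accounted for downstream by residual
  adjustment, yields a more powerful test than plugging in the known values.
* ``logistic`` — per-stratum binary logistic regression on user-chosen
  covariates, for observational data where assignment probabilities are
  unknown.

All modes answer ``omega(subject, stage, option)``.  Fitted modes also
expose per-subject ML score contributions, which are the regressors of the
residual-adjustment step of the test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .data import Dataset, SubjectRecord
from .design import OptionLabel, SmartDesign


@dataclass
class ScoreMatrix:
    """Per-subject ML score contributions; columns sum to zero at the fit."""

    values: np.ndarray  # (n, p)
    columns: list[str]


@dataclass
class PropensityModel:
    mode: str  # "known" | "stratified_ml" | "logistic"
    design: SmartDesign
    tables: dict = field(default_factory=dict)
    # tables[(stage, key)] -> {option: prob}; in logistic mode
    # logit[(stage, key)] -> (coefs, covariate names, modeled option)
    logit: dict = field(default_factory=dict)
    fitted: bool = False
    param_count: int = 0

    def omega(
        self, subject: SubjectRecord, stage: int, option: OptionLabel
    ) -> float:
        """Probability the subject's stratum assigns `option` at `stage`."""
        if stage > subject.kappa:
            raise ValueError(
                f"subject {subject.id} did not reach stage {stage}"
            )
        key = subject.stratum_key(self.design, stage)
        stratum = self.design.stratum(stage, key)
        if option not in stratum.feasible:
            warnings.warn(
                f"option {option!r} infeasible at stage {stage} stratum "
                f"{key!r}; probability 0",
                stacklevel=2,
            )
            return 0.0
        if self.mode == "logistic" and (stage, key) in self.logit:
            coefs, covs, modeled = self.logit[(stage, key)]
            x = _design_row(subject, stage, covs)
            p = 1.0 / (1.0 + np.exp(-float(x @ coefs)))
            return p if option == modeled else 1.0 - p
        return self.tables[(stage, key)][option]


def known_model(design: SmartDesign) -> PropensityModel:
    """The design's randomization probabilities as a propensity model."""
    tables = {
        (s.stage, s.key): dict(s.probs)
        for stage_strata in design.strata
        for s in stage_strata
    }
    return PropensityModel(
        mode="known", design=design, tables=tables, fitted=True,
        param_count=0,
    )


def _stratum_members(dataset: Dataset):
    """Yield ((stage, key), stratum, [(subject index, treatment), ...]) for
    every stratum reached by at least one subject."""
    design = dataset.design
    groups: dict = {}
    for i, rec in enumerate(dataset.subjects):
        for k in range(1, rec.kappa + 1):
            key = rec.stratum_key(design, k)
            groups.setdefault((k, key), []).append(
                (i, rec.treatments[k - 1])
            )
    for (k, key), members in sorted(groups.items(),
                                    key=lambda kv: (kv[0][0],
                                                    repr(kv[0][1]))):
        yield (k, key), design.stratum(k, key), members


def fit_stratified(
    dataset: Dataset, design: Optional[SmartDesign] = None
) -> PropensityModel:
    """Stratified ML: fitted probabilities are within-stratum sample
    proportions of each feasible option.

    Every feasible option in every reached stratum must be assigned to at
    least one subject (otherwise the ML estimate sits on the boundary and
    the inverse weights are degenerate); strata reached by nobody retain
    the design probabilities, which the weights never query.
    """
    design = design or dataset.design
    model = known_model(design)
    model.mode = "stratified_ml"
    param_count = 0
    for (k, key), stratum, members in _stratum_members(dataset):
        n_here = len(members)
        counts = {a: 0 for a in stratum.feasible}
        for _, a in members:
            counts[a] += 1
        empty = [a for a, c in counts.items() if c == 0]
        if empty:
            raise ValueError(
                f"stage {k} stratum {key!r}: feasible option(s) "
                f"{empty} assigned to no subject ({n_here} in stratum); "
                f"stratified ML is degenerate"
            )
        model.tables[(k, key)] = {
            a: c / n_here for a, c in counts.items()
        }
        param_count += len(stratum.feasible) - 1
    model.param_count = param_count
    model.fitted = True
    return model


def _design_row(subject: SubjectRecord, stage: int, covs: Sequence[str]):
    """Intercept + named covariates, each taken from the most recent stage
    block defining it."""
    x = [1.0]
    for name in covs:
        for blk in reversed(subject.covariates[:stage]):
            if name in blk:
                x.append(float(blk[name]))
                break
        else:
            raise KeyError(
                f"covariate {name!r} missing for subject {subject.id} "
                f"by stage {stage}"
            )
    return np.asarray(x)


def fit_logistic(
    dataset: Dataset,
    design: Optional[SmartDesign] = None,
    covariate_spec: Optional[Mapping[int, Sequence[str]]] = None,
) -> PropensityModel:
    """Per-stratum logistic regression of assignment on covariates.

    ``covariate_spec`` maps stage -> covariate names entering the linear
    predictor at that stage (empty -> intercept only, equivalent to the
    stratified proportion).  Restricted to strata with exactly two feasible
    options; the first (sorted) option is modeled.
    """
    import statsmodels.api as sm

    design = design or dataset.design
    covariate_spec = dict(covariate_spec or {})
    model = known_model(design)
    model.mode = "logistic"
    param_count = 0
    for (k, key), stratum, members in _stratum_members(dataset):
        if len(stratum.feasible) == 1:
            continue
        if len(stratum.feasible) != 2:
            raise ValueError(
                f"stage {k} stratum {key!r} has {len(stratum.feasible)} "
                f"feasible options; logistic mode handles binary "
                f"randomizations only"
            )
        modeled = sorted(stratum.feasible, key=repr)[0]
        covs = list(covariate_spec.get(k, ()))
        X = np.vstack(
            [_design_row(dataset.subjects[i], k, covs) for i, _ in members]
        )
        y = np.array([1.0 if a == modeled else 0.0 for _, a in members])
        if y.min() == y.max():
            raise ValueError(
                f"stage {k} stratum {key!r}: all subjects received the "
                f"same option; logistic fit is degenerate"
            )
        if np.linalg.matrix_rank(X) < X.shape[1]:
            raise ValueError(
                f"stage {k} stratum {key!r}: design matrix rank deficient"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            try:
                res = sm.Logit(y, X).fit(disp=0, method="newton",
                                         tol=1e-10, maxiter=100)
            except Exception as exc:  # separation / non-convergence
                raise ValueError(
                    f"stage {k} stratum {key!r}: logistic fit failed "
                    f"({exc})"
                ) from exc
        grad = X.T @ (y - 1.0 / (1.0 + np.exp(-X @ res.params)))
        if np.linalg.norm(grad) > 1e-8 * max(1.0, len(y)):
            raise ValueError(
                f"stage {k} stratum {key!r}: logistic fit did not "
                f"converge (gradient norm {np.linalg.norm(grad):.2e})"
            )
        model.logit[(k, key)] = (res.params, covs, modeled)
        param_count += X.shape[1]
    model.param_count = param_count
    model.fitted = True
    return model


def score_contributions(
    model: PropensityModel, dataset: Dataset
) -> ScoreMatrix:
    """Per-subject score of the assignment-model loglikelihood at the fit.

    Stratified ML: one column per (stage, stratum, non-reference option)
    with entries I(subject in stratum) * {I(A = option) - omega_hat}; the
    last sorted feasible option is the reference.  Logistic: the usual
    Bernoulli score x * (y - p) per stratum coefficient.  Columns sum to
    zero by the ML first-order conditions.
    """
    if model.mode == "known":
        raise ValueError("known-probability model has no fitted parameters")
    if not model.fitted:
        raise ValueError("model is not fitted")
    n = dataset.n
    cols: list[str] = []
    vals: list[np.ndarray] = []
    for (k, key), stratum, members in _stratum_members(dataset):
        if len(stratum.feasible) < 2:
            continue
        options = sorted(stratum.feasible, key=repr)
        if model.mode == "stratified_ml":
            probs = model.tables[(k, key)]
            for a in options[:-1]:
                col = np.zeros(n)
                for i, a_i in members:
                    col[i] = (1.0 if a_i == a else 0.0) - probs[a]
                cols.append(f"s{k}:{key}:{a}")
                vals.append(col)
        else:
            coefs, covs, modeled = model.logit[(k, key)]
            for c_idx, cname in enumerate(["const"] + list(covs)):
                col = np.zeros(n)
                for i, a_i in members:
                    x = _design_row(dataset.subjects[i], k, covs)
                    p = 1.0 / (1.0 + np.exp(-float(x @ coefs)))
                    y = 1.0 if a_i == modeled else 0.0
                    col[i] = x[c_idx] * (y - p)
                cols.append(f"s{k}:{key}:{cname}")
                vals.append(col)
    values = (
        np.column_stack(vals) if vals else np.zeros((n, 0))
    )
    return ScoreMatrix(values=values, columns=cols)
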