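"""Synthetic SMART generator with known ground truth.

Subjects move through latent *phases* separated by the decision times: the
event hazard is piecewise exponential, with the phase-k rate a log-linear
function of the covariates observed by stage k.  Under a null scenario the
hazard never depends on treatment, so the regime-specific hazards
lambda(u, d) coincide for every embedded regime by construction.  Under an
alternative, the final-phase hazard of subjects whose initial treatment is
a designated arm is multiplied by zeta (zeta = 1 recovers the null), which
separates the regimes sharing that arm from the rest.

Censoring is drawn independently of everything (uniform on a window chosen
per scenario to land in the stated censoring range), matching the
noninformative, history-independent censoring under which the test's
weights need no censoring model.  Decision times, response status and
intermediate covariates are generated for every subject (they are disease
progression, not treatment), but only subjects still under follow-up and
outside a never-re-randomized control arm reach the later randomizations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np

from .core import TestOptions, run_glogrank
from .data import Dataset, SubjectRecord
from .design import (
    Regime,
    SmartDesign,
    responder_switch_design,
    response_stratified_design,
    two_by_two_design,
)

SeedLike = Union[int, np.random.SeedSequence, np.random.Generator]


def _rng(seed: SeedLike) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


@dataclass
class ScenarioConfig:
    """Generative model for a K-stage SMART scenario.

    ``baseline_covs`` / ``stage_covs`` list per-stage covariate
    distributions as (name, ("bernoulli", p) | ("normal", mu, sd)); stage-k
    blocks (k >= 2) typically include the binary ``response`` used by the
    design's feasibility strata.  ``phase_coefs[k]`` are log-linear hazard
    coefficients active from decision k on; ``windows[k]`` the uniform
    window for the gap between decisions k-1 and k; ``censor_window`` the
    uniform censoring support.  ``zeta`` multiplies the final-phase hazard
    of subjects starting on ``zeta_arm`` (1 = null); ``control_option`` is
    a stage-1 arm never re-randomized.
    """

    name: str
    design: SmartDesign
    base_rate: float
    baseline_covs: list = field(default_factory=list)
    stage_covs: dict = field(default_factory=dict)
    windows: dict = field(default_factory=dict)
    phase_coefs: dict = field(default_factory=dict)
    censor_window: tuple = (0.5, 4.0)
    zeta: float = 1.0
    zeta_arm: object = None
    control_option: object = None


def _draw(spec, n, rng):
    kind = spec[0]
    if kind == "bernoulli":
        return rng.binomial(1, spec[1], size=n).astype(float)
    if kind == "normal":
        return rng.normal(spec[1], spec[2], size=n)
    raise ValueError(f"unknown distribution {kind!r}")


def _phase_rates(config, covs, a1, n):
    """(n, K) per-phase hazard rates; phase k runs from decision k to
    decision k+1 (or infinity)."""
    K = config.design.K
    rates = np.empty((n, K))
    for k in range(1, K + 1):
        lin = np.zeros(n)
        for name, coef in config.phase_coefs.get(k, {}).items():
            lin += coef * covs[name]
        rates[:, k - 1] = config.base_rate * np.exp(lin)
    if config.zeta != 1.0 and config.zeta_arm is not None:
        mult = np.where(a1 == np.asarray(config.zeta_arm), config.zeta, 1.0)
        rates[:, K - 1] = rates[:, K - 1] * mult
    return rates


def _piecewise_exponential(rates, boundaries, rng):
    """Event times with hazard rates[:, k] on [boundaries[:, k],
    boundaries[:, k+1]); the last phase extends to infinity."""
    n, K = rates.shape
    e = rng.exponential(size=n)
    t = np.empty(n)
    remaining = e.copy()
    done = np.zeros(n, dtype=bool)
    for k in range(K):
        lo = boundaries[:, k]
        hi = boundaries[:, k + 1] if k + 1 < K else np.full(n, np.inf)
        width = hi - lo
        haz = rates[:, k] * width
        fits = ~done & (remaining <= haz)
        t[fits] = lo[fits] + remaining[fits] / rates[fits, k]
        done |= fits
        remaining = remaining - np.where(done, 0.0, haz)
    return t


def _feature_arrays(design, stage, a_cols, covs):
    feats = []
    for feat in design.key_features[stage - 1]:
        if feat.startswith("a") and feat[1:].isdigit():
            feats.append(a_cols[int(feat[1:]) - 1])
        else:
            feats.append(covs[feat])
    return feats


def simulate_dataset(
    config: ScenarioConfig, n: int, seed: SeedLike
) -> Dataset:
    """Generate n subjects; bit-reproducible for a given seed."""
    rng = _rng(seed)
    design = config.design
    K = design.K

    covs: dict[str, np.ndarray] = {}
    cov_stage: dict[str, int] = {}
    for name, spec in config.baseline_covs:
        covs[name] = _draw(spec, n, rng)
        cov_stage[name] = 1

    # decision-time boundaries (latent for everyone)
    boundaries = np.zeros((n, K))
    for k in range(2, K + 1):
        lo, hi = config.windows[k]
        boundaries[:, k - 1] = boundaries[:, k - 2] + rng.uniform(
            lo, hi, size=n
        )
        for name, spec in config.stage_covs.get(k, []):
            covs[name] = _draw(spec, n, rng)
            cov_stage[name] = k

    # stage-1 randomization (single baseline stratum)
    s1 = design.strata[0][0]
    opts1 = sorted(s1.feasible, key=repr)
    a1 = rng.choice(
        np.arange(len(opts1)), size=n, p=[s1.probs[o] for o in opts1]
    )
    a1 = np.array([opts1[i] for i in a1], dtype=object)

    rates = _phase_rates(config, covs, a1, n)
    t_event = _piecewise_exponential(rates, boundaries, rng)
    c_lo, c_hi = config.censor_window
    t_cens = rng.uniform(c_lo, c_hi, size=n)
    U = np.minimum(t_event, t_cens)
    delta = (t_event <= t_cens).astype(int)

    a_cols: list[np.ndarray] = [a1]
    kappa = np.ones(n, dtype=int)
    is_ctrl = (
        a1 == np.asarray(config.control_option)
        if config.control_option is not None
        else np.zeros(n, dtype=bool)
    )
    for k in range(2, K + 1):
        reach = (kappa == k - 1) & ~is_ctrl & (boundaries[:, k - 1] <= U)
        a_k = np.full(n, None, dtype=object)
        feats = _feature_arrays(design, k, a_cols, covs)
        for stratum in design.strata[k - 1]:
            in_s = reach.copy()
            for f_arr, val in zip(feats, stratum.key):
                in_s &= np.asarray(f_arr) == val
            idx = np.nonzero(in_s)[0]
            if idx.size == 0:
                continue
            opts = sorted(stratum.feasible, key=repr)
            pick = rng.choice(
                np.arange(len(opts)), size=idx.size,
                p=[stratum.probs[o] for o in opts],
            )
            a_k[idx] = [opts[i] for i in pick]
        assigned = np.array([a is not None for a in a_k])
        kappa[reach & assigned] = k
        a_cols.append(a_k)

    subjects = []
    for i in range(n):
        kap = int(kappa[i])
        times = tuple(float(boundaries[i, k]) for k in range(kap))
        trts = tuple(a_cols[k][i] for k in range(kap))
        blocks = []
        for k in range(1, kap + 1):
            blocks.append(
                {
                    name: float(covs[name][i])
                    for name, stage in cov_stage.items()
                    if stage == k
                }
            )
        subjects.append(
            SubjectRecord(
                id=i,
                kappa=kap,
                decision_times=times,
                treatments=trts,
                covariates=tuple(blocks),
                followup_time=float(U[i]),
                event=int(delta[i]),
            )
        )
    return Dataset(subjects=subjects, design=design)


def sample_potential_event_times(
    config: ScenarioConfig, regime: Regime, n: int, seed: SeedLike
) -> np.ndarray:
    """Uncensored draws of the potential event time T*(d) under `regime`,
    for checking that null scenarios put the same law on every regime."""
    rng = _rng(seed)
    design = config.design
    K = design.K
    covs: dict[str, np.ndarray] = {}
    for name, spec in config.baseline_covs:
        covs[name] = _draw(spec, n, rng)
    boundaries = np.zeros((n, K))
    for k in range(2, K + 1):
        lo, hi = config.windows[k]
        boundaries[:, k - 1] = boundaries[:, k - 2] + rng.uniform(
            lo, hi, size=n
        )
        for name, spec in config.stage_covs.get(k, []):
            covs[name] = _draw(spec, n, rng)
    a1 = np.full(n, regime.stage1_option(), dtype=object)
    rates = _phase_rates(config, covs, a1, n)
    return _piecewise_exponential(rates, boundaries, rng)


# ---------------------------------------------------------------------------
# built-in scenarios

_COV_BASE = [("x1b", ("bernoulli", 0.5)), ("x1c", ("normal", 0.0, 1.0))]
_COV_STAGE2 = [("response", ("bernoulli", 0.5)),
               ("x2c", ("normal", 0.0, 1.0))]
_RESP_ONLY = [("response", ("bernoulli", 0.5))]
_EFFECTS_1 = {"x1b": 0.5, "x1c": 0.3}
_EFFECTS_2 = {"x1b": 0.5, "x1c": 0.3, "x2c": 0.4}


def builtin_scenarios() -> dict[str, ScenarioConfig]:
    """Named generative scenarios.

    ``null_switch`` / ``null_switch_cov`` — responder-switch design (4
    embedded regimes), hazards free of treatment, without / with
    outcome-associated covariates; censoring in the 25-40% range.
    ``null_twobytwo`` — 2x2 re-randomization design with baseline and
    intermediate covariates in the hazard; censoring 30-45%.
    ``null_control`` — responder-switch design plus an up-front control arm
    (5 regimes).  ``null_stratified`` — response-stratified design (8
    embedded regimes).  ``alt_*`` — same generative processes with the
    final-phase hazard of the arm-1 regimes multiplied by zeta > 1.
    """
    # shared timing: second decision 0.3-0.9 time units after baseline and
    # uniform censoring on (0.3, 4.2), so that roughly two-thirds of
    # (non-control) subjects reach the second randomization, as in typical
    # two-stage oncology SMARTs, with censoring in the stated ranges
    window = {2: (0.3, 0.9)}
    censor = (0.3, 4.2)
    scenarios = {
        "null_switch": ScenarioConfig(
            name="null_switch",
            design=responder_switch_design(),
            base_rate=0.5,
            stage_covs={2: list(_RESP_ONLY)},
            windows=dict(window),
            censor_window=censor,
        ),
        "null_switch_cov": ScenarioConfig(
            name="null_switch_cov",
            design=responder_switch_design(),
            base_rate=0.4,
            baseline_covs=list(_COV_BASE),
            stage_covs={2: list(_COV_STAGE2)},
            windows=dict(window),
            phase_coefs={1: dict(_EFFECTS_1), 2: dict(_EFFECTS_2)},
            censor_window=censor,
        ),
        "null_twobytwo": ScenarioConfig(
            name="null_twobytwo",
            design=two_by_two_design(),
            base_rate=0.4,
            baseline_covs=list(_COV_BASE),
            stage_covs={2: list(_COV_STAGE2)},
            windows=dict(window),
            phase_coefs={1: dict(_EFFECTS_1), 2: dict(_EFFECTS_2)},
            censor_window=censor,
        ),
        "null_control": ScenarioConfig(
            name="null_control",
            design=responder_switch_design(control=True),
            base_rate=0.4,
            baseline_covs=list(_COV_BASE),
            stage_covs={2: list(_COV_STAGE2)},
            windows=dict(window),
            phase_coefs={1: dict(_EFFECTS_1), 2: dict(_EFFECTS_2)},
            censor_window=censor,
            control_option="ctrl",
        ),
        "null_stratified": ScenarioConfig(
            name="null_stratified",
            design=response_stratified_design(),
            base_rate=0.4,
            baseline_covs=list(_COV_BASE),
            stage_covs={2: list(_COV_STAGE2)},
            windows=dict(window),
            phase_coefs={1: dict(_EFFECTS_1), 2: dict(_EFFECTS_2)},
            censor_window=censor,
        ),
    }
    for name in list(scenarios):
        alt = replace(
            scenarios[name],
            name=name.replace("null", "alt"),
            zeta=2.5,
            zeta_arm=1,
        )
        scenarios[alt.name] = alt
    return scenarios


def get_scenario(name: str, zeta: Optional[float] = None) -> ScenarioConfig:
    """Look up a built-in scenario, optionally overriding zeta."""
    scenarios = builtin_scenarios()
    if name not in scenarios:
        raise KeyError(
            f"unknown scenario {name!r}; available: "
            f"{', '.join(sorted(scenarios))}"
        )
    config = scenarios[name]
    if zeta is not None:
        config = replace(config, zeta=zeta)
    return config


# ---------------------------------------------------------------------------
# Monte-Carlo operating characteristics


@dataclass
class SimulationReport:
    scenario: str
    n: int
    replicates: int
    level: float
    rejection_proportion: float
    mc_standard_error: float
    test_label: str = ""

    def to_dict(self) -> dict:
        return {
            "schema_version": 1,
            "scenario": self.scenario,
            "n": self.n,
            "replicates": self.replicates,
            "level": self.level,
            "rejection_proportion": self.rejection_proportion,
            "mc_standard_error": self.mc_standard_error,
            "test_label": self.test_label,
        }


def rejection_rates(
    config: ScenarioConfig,
    n: int,
    replicates: int,
    test_options: dict[str, TestOptions],
    level: float = 0.05,
    seed: int = 0,
    regimes: Optional[Sequence[Regime]] = None,
) -> dict[str, SimulationReport]:
    """Monte-Carlo rejection proportions of several test variants on the
    same stream of simulated datasets.

    Per-replicate RNG streams derive from (seed, replicate index), so the
    result is reproducible and independent of the variant set.
    """
    from .design import enumerate_embedded_regimes

    if replicates < 1:
        raise ValueError("need at least one replicate")
    regimes = (
        list(regimes)
        if regimes is not None
        else enumerate_embedded_regimes(config.design)
    )
    rejections = {label: 0 for label in test_options}
    for rep in range(replicates):
        ss = np.random.SeedSequence([int(seed) % (2**31), rep])
        dataset = simulate_dataset(config, n, np.random.default_rng(ss))
        for label, opts in test_options.items():
            result = run_glogrank(dataset, regimes, opts)
            if result.p_value <= level:
                rejections[label] += 1
    reports = {}
    for label, count in rejections.items():
        p_hat = count / replicates
        reports[label] = SimulationReport(
            scenario=config.name,
            n=n,
            replicates=replicates,
            level=level,
            rejection_proportion=p_hat,
            mc_standard_error=float(
                np.sqrt(p_hat * (1 - p_hat) / replicates)
            ),
            test_label=label,
        )
    return reports


def rejection_rate(
    config: ScenarioConfig,
    n: int,
    replicates: int,
    test_options: Optional[TestOptions] = None,
    level: float = 0.05,
    seed: int = 0,
    regimes: Optional[Sequence[Regime]] = None,
) -> SimulationReport:
    """Monte-Carlo rejection proportion of one test variant."""
    opts = test_options or TestOptions()
    return rejection_rates(
        config, n, replicates, {"test": opts}, level=level, seed=seed,
        regimes=regimes,
    )["test"]
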