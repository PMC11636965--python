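import numpy as np
import pytest

from glogrank import (
    Dataset,
    SubjectRecord,
    design_from_dict,
    enumerate_embedded_regimes,
    get_scenario,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def single_stage_design():
    """One decision, two arms, equal randomization."""
    return design_from_dict(
        {
            "stages": [
                {
                    "options": ["A", "B"],
                    "strata": [
                        {"key": [], "feasible": ["A", "B"],
                         "probs": [0.5, 0.5]}
                    ],
                }
            ]
        }
    )


@pytest.fixture(scope="session")
def hand_dataset(single_stage_design):
    """Four subjects, one decision: arm A events at 1 and 3, arm B an
    event at 2 and a censoring at 4."""
    rows = [("A", 1.0, 1), ("A", 3.0, 1), ("B", 2.0, 1), ("B", 4.0, 0)]
    subjects = [
        SubjectRecord(
            id=i, kappa=1, decision_times=(0.0,), treatments=(arm,),
            covariates=({},), followup_time=u, event=e,
        )
        for i, (arm, u, e) in enumerate(rows)
    ]
    return Dataset(subjects=subjects, design=single_stage_design)


def make_single_stage_dataset(design, n, seed, rate=1.0, c_hi=2.5):
    """Random single-stage survival data on `design`'s arms."""
    rng = np.random.default_rng(seed)
    s1 = design.strata[0][0]
    arms = rng.choice(sorted(s1.feasible, key=repr), n,
                      p=[s1.probs[o] for o in sorted(s1.feasible, key=repr)])
    t = rng.exponential(1.0 / rate, n).round(2)  # rounding makes ties
    t = np.maximum(t, 0.01)
    c = rng.uniform(0.2, c_hi, n)
    u = np.minimum(t, c)
    delta = (t <= c).astype(int)
    subjects = [
        SubjectRecord(
            id=i, kappa=1, decision_times=(0.0,), treatments=(arms[i],),
            covariates=({},), followup_time=float(u[i]),
            event=int(delta[i]),
        )
        for i in range(n)
    ]
    return Dataset(subjects=subjects, design=design)


@pytest.fixture(scope="session")
def twobytwo_dataset():
    cfg = get_scenario("null_twobytwo")
    return simulate_dataset(cfg, 250, 424)


@pytest.fixture(scope="session")
def twobytwo_regimes(twobytwo_dataset):
    return enumerate_embedded_regimes(twobytwo_dataset.design)
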