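"""SMART designs and embedded treatment regimes.

A sequential multiple assignment randomized trial (SMART) randomizes
subjects at each of K decision points, with the set of options available at
a decision point possibly depending on the subject's accrued history
(earlier treatments, response status).  The design is described here by, per
stage, the full option set ``A_k``, a finite list of *feasibility strata*
(discrete classifications of the history), and for each stratum the feasible
subset and its randomization probabilities.

A treatment regime is a rule table: one feasible option per (stage,
stratum).  The *embedded regimes* of a design are all regimes obtainable by
picking one feasible option in every stratum that the regime's own earlier
rules can reach.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from typing import Any, Hashable, Mapping, Sequence

import yaml

OptionLabel = Hashable
"""A treatment option is identified by an opaque hashable label (int or
str), unique within its stage's option set."""

_PRIOR_TRT = re.compile(r"^a(\d+)$")


@dataclass(frozen=True)
class Stratum:
    """One feasibility stratum of the history at a decision point.

    ``key`` is the discrete value of the declared key features (prior
    treatments ``a1..a{k-1}`` and/or discrete stage covariates) identifying
    subjects in this stratum; ``feasible`` is the nonempty feasible subset
    of the stage's option set; ``probs`` the randomization probabilities
    over ``feasible`` (strictly positive, summing to 1).
    """

    stage: int
    key: tuple
    feasible: tuple
    probs: Mapping[OptionLabel, float]

    def __post_init__(self):
        object.__setattr__(self, "feasible", tuple(self.feasible))
        object.__setattr__(self, "probs", dict(self.probs))


@dataclass
class SmartDesign:
    """A K-stage SMART design.

    Parameters
    ----------
    option_sets
        Per stage, the full treatment option set ``A_k``.
    strata
        Per stage, the list of feasibility strata (each a :class:`Stratum`).
    key_features
        Per stage, the names of the history features forming a stratum key,
        in order.  ``"a<j>"`` refers to the treatment received at stage j;
        any other name refers to a (discrete) stage covariate, looked up in
        the most recent stage block that defines it.  Stage 1 usually has
        no key features (a single all-histories stratum).
    """

    option_sets: list[tuple]
    strata: list[list[Stratum]]
    key_features: list[tuple[str, ...]]
    label: str = ""

    @property
    def K(self) -> int:
        return len(self.option_sets)

    def stratum(self, stage: int, key: tuple) -> Stratum:
        """The stratum with the given key at `stage` (1-based)."""
        for s in self.strata[stage - 1]:
            if s.key == tuple(key):
                return s
        raise KeyError(f"no stratum with key {key!r} at stage {stage}")

    def subject_key(
        self,
        stage: int,
        treatments: Sequence[OptionLabel],
        covariates: Sequence[Mapping[str, Any]],
    ) -> tuple:
        """Stratum key of a subject at `stage`, from prior treatments and
        the per-stage covariate blocks observed so far."""
        out = []
        for feat in self.key_features[stage - 1]:
            m = _PRIOR_TRT.match(feat)
            if m:
                j = int(m.group(1))
                if j >= stage or j > len(treatments):
                    raise KeyError(
                        f"feature {feat!r} not available at stage {stage}"
                    )
                out.append(treatments[j - 1])
            else:
                for blk in reversed(covariates[:stage]):
                    if feat in blk:
                        out.append(blk[feat])
                        break
                else:
                    raise KeyError(
                        f"covariate {feat!r} not found by stage {stage}"
                    )
        return tuple(out)


@dataclass(frozen=True)
class Regime:
    """A treatment regime: one feasible option per reachable (stage, key).

    ``rules`` maps ``(stage, stratum_key)`` to the assigned option.  Strata
    a regime's own earlier rules cannot reach carry no rule.  Two regimes
    are equal iff all rule outputs coincide.
    """

    rules: tuple  # sorted tuple of ((stage, key), option) pairs
    label: str = field(default="", compare=False)

    @classmethod
    def from_dict(cls, rules: Mapping, label: str = "") -> "Regime":
        items = tuple(sorted(rules.items(), key=lambda kv: repr(kv[0])))
        return cls(rules=items, label=label)

    @property
    def rule_map(self) -> dict:
        return dict(self.rules)

    def stage1_option(self) -> OptionLabel:
        for (stage, _key), opt in self.rules:
            if stage == 1:
                return opt
        raise ValueError("regime has no stage-1 rule")


def assigned_treatment(regime: Regime, stage: int, stratum: Stratum):
    """Option the regime assigns in `stratum`; None if the stratum is
    absorbed (empty feasible set, i.e. the event already occurred)."""
    if not stratum.feasible:
        return None
    try:
        return regime.rule_map[(stage, stratum.key)]
    except KeyError:
        raise KeyError(
            f"regime {regime.label!r} has no rule for stage {stage} "
            f"stratum {stratum.key!r}"
        ) from None


def validate_design(design: SmartDesign) -> list[str]:
    """Check design invariants; returns a list of violation messages
    (empty iff the design is well formed)."""
    report: list[str] = []
    if design.K < 1:
        report.append("design has no stages")
    for k, (options, strata) in enumerate(
        zip(design.option_sets, design.strata), start=1
    ):
        if len(set(options)) != len(options):
            report.append(f"stage {k}: duplicate option labels {options}")
        keys = [s.key for s in strata]
        if len(set(keys)) != len(keys):
            report.append(f"stage {k}: duplicate stratum keys")
        if not strata:
            report.append(f"stage {k}: no strata declared")
        for s in strata:
            where = f"stage {k} stratum {s.key!r}"
            if not s.feasible:
                report.append(f"{where}: empty feasible set")
                continue
            if len(set(s.feasible)) != len(s.feasible):
                report.append(f"{where}: duplicate feasible options")
            bad = [a for a in s.feasible if a not in options]
            if bad:
                report.append(
                    f"{where}: feasible options {bad} outside the stage "
                    f"option set"
                )
            if set(s.probs) != set(s.feasible):
                report.append(
                    f"{where}: probabilities keyed by "
                    f"{sorted(map(repr, s.probs))}, expected the feasible "
                    f"set"
                )
                continue
            if any(p <= 0 for p in s.probs.values()):
                report.append(f"{where}: nonpositive probability")
            total = sum(s.probs.values())
            if abs(total - 1.0) > 1e-9:
                report.append(
                    f"{where}: probabilities sum to {total:g} != 1"
                )
    return report


def _reachable_strata(design, stage, possible):
    """Strata at `stage` reachable given per-earlier-stage sets of
    possible treatments; covariate features never restrict reachability."""
    out = []
    for s in design.strata[stage - 1]:
        ok = True
        for feat, val in zip(design.key_features[stage - 1], s.key):
            m = _PRIOR_TRT.match(feat)
            if m and val not in possible[int(m.group(1))]:
                ok = False
                break
        if ok:
            out.append(s)
    return out


def enumerate_embedded_regimes(design: SmartDesign) -> list[Regime]:
    """All embedded regimes of the design, in a stable lexicographic order
    (stages, then declared stratum order, then sorted option labels).

    A regime assigns one feasible option per stratum that its own earlier
    rules can reach; strata keyed on prior treatments the regime never
    gives are skipped, so the count is the product of feasible-set sizes
    over reachable strata only.
    """
    problems = validate_design(design)
    if problems:
        raise ValueError("invalid design: " + "; ".join(problems))

    regimes: list[Regime] = []

    def recurse(stage, rules, possible):
        if stage > design.K:
            regimes.append(Regime.from_dict(dict(rules)))
            return
        strata = _reachable_strata(design, stage, possible)
        choice_sets = [sorted(s.feasible, key=repr) for s in strata]
        for combo in itertools.product(*choice_sets):
            new_rules = dict(rules)
            for s, opt in zip(strata, combo):
                new_rules[(stage, s.key)] = opt
            recurse(stage + 1, new_rules, {**possible, stage: set(combo)})

    recurse(1, {}, {})
    out = []
    for i, r in enumerate(regimes, start=1):
        stage1 = r.stage1_option()
        out.append(Regime(rules=r.rules, label=f"d{i}({stage1})"))
    return out


# ---------------------------------------------------------------------------
# config file I/O


def design_from_dict(cfg: Mapping) -> SmartDesign:
    """Build a design from the config mapping (see the README for the
    schema: top-level ``stages`` list; per stage ``options``, optional
    ``key_features``, and ``strata`` each with ``key``/``feasible``/
    ``probs``)."""
    stages = cfg["stages"]
    option_sets, strata, key_features = [], [], []
    for k, st in enumerate(stages, start=1):
        option_sets.append(tuple(st["options"]))
        key_features.append(tuple(st.get("key_features", ())))
        stage_strata = []
        for raw in st["strata"]:
            probs = raw["probs"]
            if isinstance(probs, Sequence) and not isinstance(probs, Mapping):
                probs = dict(zip(raw["feasible"], probs))
            stage_strata.append(
                Stratum(
                    stage=k,
                    key=tuple(raw.get("key", ())),
                    feasible=tuple(raw["feasible"]),
                    probs={k_: float(v) for k_, v in probs.items()},
                )
            )
        strata.append(stage_strata)
    return SmartDesign(
        option_sets=option_sets,
        strata=strata,
        key_features=key_features,
        label=str(cfg.get("label", "")),
    )


def load_design(path) -> SmartDesign:
    """Read a design config from a YAML or JSON file."""
    text = open(path).read()
    if str(path).endswith(".json"):
        cfg = json.loads(text)
    else:
        cfg = yaml.safe_load(text)
    return design_from_dict(cfg)


# ---------------------------------------------------------------------------
# built-in design templates used by the simulator and the docs


def two_by_two_design() -> SmartDesign:
    """Two-stage design where everyone reaching Decision 2 is randomized
    between the same two options: 2 initial x 2 follow-on = 4 embedded
    regimes (e.g. two consolidation therapies crossed with two maintenance
    therapies)."""
    return design_from_dict(
        {
            "label": "2x2",
            "stages": [
                {
                    "options": [0, 1],
                    "strata": [
                        {"key": [], "feasible": [0, 1], "probs": [0.5, 0.5]}
                    ],
                },
                {
                    "options": [0, 1],
                    "strata": [
                        {"key": [], "feasible": [0, 1], "probs": [0.5, 0.5]}
                    ],
                },
            ],
        }
    )


def responder_switch_design(control: bool = False) -> SmartDesign:
    """Two-arm design in which responders to the initial treatment are
    re-randomized to continue (0) or switch (1) and nonresponders continue;
    4 embedded regimes, or 5 with an up-front control arm that is never
    re-randomized."""
    a1 = [0, 1] + (["ctrl"] if control else [])
    p1 = 1.0 / len(a1)
    strata2 = []
    for arm in (0, 1):
        strata2.append(
            {
                "key": [arm, 1],
                "feasible": [0, 1],
                "probs": [0.5, 0.5],
            }
        )
        strata2.append({"key": [arm, 0], "feasible": [0], "probs": [1.0]})
    return design_from_dict(
        {
            "label": "responder-switch" + ("+control" if control else ""),
            "stages": [
                {
                    "options": a1,
                    "strata": [
                        {
                            "key": [],
                            "feasible": a1,
                            "probs": [p1] * len(a1),
                        }
                    ],
                },
                {
                    "options": [0, 1],
                    "key_features": ["a1", "response"],
                    "strata": strata2,
                },
            ],
        }
    )


def response_stratified_design() -> SmartDesign:
    """Two-stage design with second-stage feasible sets depending on both
    the initial treatment and response status (four strata of two options
    each, two reachable per arm); 8 embedded regimes."""
    return design_from_dict(
        {
            "label": "response-stratified",
            "stages": [
                {
                    "options": [0, 1],
                    "strata": [
                        {"key": [], "feasible": [0, 1], "probs": [0.5, 0.5]}
                    ],
                },
                {
                    "options": [2, 3, 4, 5],
                    "key_features": ["a1", "response"],
                    "strata": [
                        {"key": [1, 1], "feasible": [2, 5],
                         "probs": [0.5, 0.5]},
                        {"key": [1, 0], "feasible": [3, 5],
                         "probs": [0.5, 0.5]},
                        {"key": [0, 1], "feasible": [2, 4],
                         "probs": [0.5, 0.5]},
                        {"key": [0, 0], "feasible": [3, 4],
                         "probs": [0.5, 0.5]},
                    ],
                },
            ],
        }
    )
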