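"""Observed SMART data: subject records, CSV reading, validation, the
event-time grid and the truncation rule.

Each subject contributes the number of decision points reached (kappa), the
decision times T_1=0 < T_2 < ... <= U, per-stage covariate blocks, the
treatments received, the follow-up time U and the event indicator Delta.
Time is continuous in arbitrary but consistent units.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .design import Regime, SmartDesign, assigned_treatment


class DataError(ValueError):
    """Raised when input data cannot be interpreted as SMART records."""


@dataclass
class SubjectRecord:
    """One subject's observed data.

    ``decision_times`` has length kappa with first element 0;
    ``treatments`` the options received at each reached stage;
    ``covariates`` one mapping per reached stage (may be empty).
    """

    id: Any
    kappa: int
    decision_times: tuple
    treatments: tuple
    covariates: tuple
    followup_time: float
    event: int

    def stratum_key(self, design: SmartDesign, stage: int) -> tuple:
        return design.subject_key(stage, self.treatments, self.covariates)


@dataclass
class Dataset:
    """A collection of subjects under a common design."""

    subjects: list[SubjectRecord]
    design: SmartDesign

    @property
    def n(self) -> int:
        return len(self.subjects)

    def to_frame(self) -> pd.DataFrame:
        """Wide-format DataFrame (columns id, kappa, t1..tK, a1..aK, u,
        delta, x<k>_<name>); stage fields beyond kappa are missing."""
        K = self.design.K
        covnames: list[list[str]] = [[] for _ in range(K)]
        for rec in self.subjects:
            for k, blk in enumerate(rec.covariates):
                for name in blk:
                    if name not in covnames[k]:
                        covnames[k].append(name)
        rows = []
        for rec in self.subjects:
            row: dict[str, Any] = {"id": rec.id, "kappa": rec.kappa}
            for k in range(K):
                row[f"t{k + 1}"] = (
                    rec.decision_times[k] if k < rec.kappa else np.nan
                )
                row[f"a{k + 1}"] = (
                    rec.treatments[k] if k < rec.kappa else np.nan
                )
            for k in range(K):
                blk = rec.covariates[k] if k < rec.kappa else {}
                for name in covnames[k]:
                    row[f"x{k + 1}_{name}"] = blk.get(name, np.nan)
            row["u"] = rec.followup_time
            row["delta"] = rec.event
            rows.append(row)
        return pd.DataFrame(rows)


def write_dataset(dataset: Dataset, path) -> None:
    dataset.to_frame().to_csv(path, index=False)


def _coerce_option(val, options):
    """Match a CSV cell against a stage's option labels (CSV round-trips
    ints through floats/strings)."""
    for opt in options:
        if val == opt:
            return opt
        try:
            if float(val) == float(opt):
                return opt
        except (TypeError, ValueError):
            pass
        if str(val) == str(opt):
            return opt
    return val


def read_dataset(
    path,
    design: SmartDesign,
    schema: Optional[Mapping[str, str]] = None,
) -> Dataset:
    """Read a wide-layout CSV into a :class:`Dataset`.

    ``schema`` optionally renames the mandatory columns, mapping canonical
    names (``id``, ``kappa``, ``t1``..``tK``, ``a1``..``aK``, ``u``,
    ``delta``) to the file's column names.  Stage-k covariates are all
    columns named ``x<k>_<name>``.  Parse and consistency errors are
    collected and raised together with row numbers.
    """
    df = pd.read_csv(path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    K = design.K
    needed = ["kappa", "u", "delta"] + [f"t{k}" for k in range(1, K + 1)] + [
        f"a{k}" for k in range(1, K + 1)
    ]
    missing = [c for c in needed if c not in df.columns]
    if missing:
        raise DataError(f"missing mandatory column(s): {', '.join(missing)}")
    covcols: list[list[tuple[str, str]]] = [[] for _ in range(K)]
    for col in df.columns:
        for k in range(1, K + 1):
            pre = f"x{k}_"
            if col.startswith(pre):
                covcols[k - 1].append((col, col[len(pre):]))

    subjects, errors = [], []
    for idx, row in df.iterrows():
        rownum = idx + 2  # header is line 1
        try:
            kappa = int(row["kappa"])
            if not 1 <= kappa <= K:
                raise DataError(f"kappa={kappa} outside 1..{K}")
            times, trts, covs = [], [], []
            for k in range(1, K + 1):
                t, a = row[f"t{k}"], row[f"a{k}"]
                if k <= kappa:
                    if pd.isna(t) or pd.isna(a):
                        raise DataError(
                            f"stage {k} fields blank but kappa={kappa}"
                        )
                    times.append(float(t))
                    trts.append(
                        _coerce_option(a, design.option_sets[k - 1])
                    )
                    covs.append(
                        {
                            name: row[col]
                            for col, name in covcols[k - 1]
                            if not pd.isna(row[col])
                        }
                    )
                elif not (pd.isna(t) and pd.isna(a)):
                    raise DataError(
                        f"stage {k} fields populated but kappa={kappa}"
                    )
            u = float(row["u"])
            delta = int(row["delta"])
            if delta not in (0, 1):
                raise DataError(f"delta={delta} not in {{0,1}}")
            if times[0] != 0:
                raise DataError(f"t1={times[0]:g} != 0")
            for k in range(1, kappa):
                if not times[k - 1] < times[k]:
                    raise DataError("decision times not increasing")
            if times[-1] > u:
                raise DataError(
                    f"last decision time {times[-1]:g} exceeds u={u:g}"
                )
            subjects.append(
                SubjectRecord(
                    id=row.get("id", idx),
                    kappa=kappa,
                    decision_times=tuple(times),
                    treatments=tuple(trts),
                    covariates=tuple(covs),
                    followup_time=u,
                    event=delta,
                )
            )
        except (DataError, ValueError, TypeError) as exc:
            errors.append(f"row {rownum}: {exc}")
    if errors:
        raise DataError("; ".join(errors))
    return Dataset(subjects=subjects, design=design)


def validate_dataset(
    dataset: Dataset, regimes: Optional[Sequence[Regime]] = None
) -> list[str]:
    """Check record invariants and design feasibility; optionally flag
    regimes in `regimes` with no fully consistent subjects (a positivity
    diagnostic).  Returns a list of messages, empty when clean."""
    report = []
    design = dataset.design
    for rec in dataset.subjects:
        where = f"subject {rec.id}"
        if not 1 <= rec.kappa <= design.K:
            report.append(f"{where}: kappa={rec.kappa} outside 1..{design.K}")
            continue
        if rec.decision_times[0] != 0:
            report.append(f"{where}: first decision time is not 0")
        if any(
            b <= a
            for a, b in zip(rec.decision_times, rec.decision_times[1:])
        ):
            report.append(f"{where}: decision times not increasing")
        if rec.decision_times[-1] > rec.followup_time:
            report.append(f"{where}: decision time after follow-up time")
        if rec.event not in (0, 1):
            report.append(f"{where}: event indicator not 0/1")
        for k in range(1, rec.kappa + 1):
            try:
                key = rec.stratum_key(design, k)
                stratum = design.stratum(k, key)
            except KeyError as exc:
                report.append(f"{where}: {exc}")
                continue
            if rec.treatments[k - 1] not in stratum.feasible:
                report.append(
                    f"{where}: stage-{k} treatment "
                    f"{rec.treatments[k - 1]!r} not feasible in stratum "
                    f"{key!r}"
                )
    if regimes:
        for regime in regimes:
            n_cons = sum(
                1
                for rec in dataset.subjects
                if _fully_consistent(rec, regime, design)
            )
            if n_cons == 0:
                report.append(
                    f"warning: regime {regime.label!r} has no consistent "
                    f"subjects"
                )
    return report


def _fully_consistent(rec: SubjectRecord, regime: Regime, design) -> bool:
    for k in range(1, rec.kappa + 1):
        try:
            stratum = design.stratum(k, rec.stratum_key(design, k))
            assigned = assigned_treatment(regime, k, stratum)
        except KeyError:
            return False
        if assigned != rec.treatments[k - 1]:
            return False
    return True


def event_grid(dataset: Dataset, L: float = np.inf) -> np.ndarray:
    """Strictly increasing distinct event times <= L (ties share one grid
    point)."""
    if L <= 0:
        raise ValueError("truncation time L must be positive")
    u = np.array([r.followup_time for r in dataset.subjects], dtype=float)
    d = np.array([r.event for r in dataset.subjects], dtype=bool)
    times = np.unique(u[d & (u <= L)])
    if times.size == 0:
        raise DataError("no events before truncation time")
    return times


@dataclass
class TruncationChoice:
    """Chosen upper integration limit and the at-risk fraction there."""

    L: float
    at_risk_fraction: float


def choose_truncation(
    dataset: Dataset, target_fraction: float = 0.02
) -> TruncationChoice:
    """Largest observed event time at which at least ``target_fraction`` of
    subjects remain at risk.

    Sparse late risk sets can dominate the weighted score, so the score
    integral is truncated where a small fraction (by default 2%) of the
    sample is still at risk.
    """
    if not 0 < target_fraction < 1:
        raise ValueError("target_fraction must be in (0, 1)")
    if dataset.n == 0:
        raise DataError("empty dataset")
    u = np.array([r.followup_time for r in dataset.subjects], dtype=float)
    times = event_grid(dataset)
    at_risk = (u[None, :] >= times[:, None]).mean(axis=1)
    ok = np.nonzero(at_risk >= target_fraction)[0]
    if ok.size == 0:  # even the first event is too late; keep it anyway
        idx = 0
    else:
        idx = ok[-1]
    return TruncationChoice(L=float(times[idx]),
                            at_risk_fraction=float(at_risk[idx]))
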