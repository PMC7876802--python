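"""Shared domain types and tabular I/O.

The toolkit works with three tabular representations:

* a *long panel* of repeated biomarker measurements (one row per
  subject-exam, columns ``id,time,y,age,sex``);
* a *survival table* of right-censored follow-up (``id,time,event``);
* a *counting-process table* of half-open ``(start, stop]`` intervals with
  interval-constant covariates, the standard input format for Cox models
  with time-varying covariates.

Times are continuous years from study entry (t = 0 at the first exam).
Events sit at interval ``stop``; a subject is at risk at event time ``t``
iff it has a row with ``start < t <= stop``.  Subject ids are opaque
strings (numeric ids are stringified) so they survive CSV round-trips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LongPanel",
    "SurvivalRecord",
    "TrueLatentState",
    "CountingProcessTable",
    "FitResult",
    "read_long_panel",
    "write_long_panel",
    "read_survival",
    "write_survival",
    "read_counting_process",
    "write_counting_process",
    "validate_pairing",
]


class FormatError(ValueError):
    """A file did not have the expected columns or types."""


@dataclass
class LongPanel:
    """Longitudinal record for one subject.

    ``times`` are exam times t_ij in years (strictly increasing, first may
    be 0); ``values`` the observed log-scale biomarker Y_ij; ``age`` and
    ``sex`` (0 = male, 1 = female by default) are baseline covariates.
    """

    subject_id: str
    times: np.ndarray
    values: np.ndarray
    age: float
    sex: int

    def __post_init__(self) -> None:
        self.subject_id = str(self.subject_id)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if len(self.times) != len(self.values) or len(self.times) == 0:
            raise ValueError(
                f"subject {self.subject_id}: need equal, nonzero numbers of "
                f"times and values"
            )
        if np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"subject {self.subject_id}: measurement times must be "
                f"strictly increasing"
            )
        if self.sex not in (0, 1):
            raise ValueError(f"subject {self.subject_id}: sex must be 0 or 1")

    @property
    def m(self) -> int:
        """Number of measurements m_i."""
        return len(self.times)


@dataclass
class SurvivalRecord:
    """Observed follow-up: T_i = min(S_i, C_i) and event flag delta_i."""

    subject_id: str
    time: float
    event: int

    def __post_init__(self) -> None:
        self.subject_id = str(self.subject_id)
        self.time = float(self.time)
        self.event = int(self.event)
        if self.time <= 0:
            raise ValueError(f"subject {self.subject_id}: follow-up time must be > 0")
        if self.event not in (0, 1):
            raise ValueError(f"subject {self.subject_id}: event must be 0 or 1")


@dataclass
class TrueLatentState:
    """Generator-side truth for one subject (kept for testing/validation).

    ``S`` is the latent event time (may be ``inf`` when the cumulative
    hazard is bounded below -log M); ``C`` the latent censoring time; ``M``
    the uniform(0,1) survival draw.
    """

    subject_id: str
    U1: float
    U2: float
    M: float
    S: float
    C: float

    def __post_init__(self) -> None:
        self.subject_id = str(self.subject_id)
        if not (0.0 < self.M < 1.0):
            raise ValueError("M must lie strictly in (0, 1)")
        if self.S <= 0 or self.C <= 0:
            raise ValueError("latent times must be positive")


@dataclass
class CountingProcessTable:
    """(start, stop] interval rows with interval-constant covariates.

    ``data`` holds columns ``id, start, stop, status`` plus one column per
    covariate named in ``covariate_names`` (conventionally
    ``value, age, sex``).  Events occur at ``stop`` of rows with
    ``status == 1``; a subject's intervals are disjoint, ordered, and only
    its last row may carry the event.
    """

    data: pd.DataFrame
    covariate_names: tuple = ("value", "age", "sex")

    REQUIRED = ("id", "start", "stop", "status")

    def __post_init__(self) -> None:
        self.covariate_names = tuple(self.covariate_names)
        missing = [c for c in self.REQUIRED + self.covariate_names
                   if c not in self.data.columns]
        if missing:
            raise FormatError(f"counting-process table missing columns {missing}")
        self.data = self.data.reset_index(drop=True)
        self.data["id"] = self.data["id"].astype(str)

    def validate(self) -> None:
        df = self.data
        if len(df) == 0:
            return
        if not (df["start"] < df["stop"]).all():
            raise ValueError("every interval must satisfy start < stop")
        if not df["status"].isin([0, 1]).all():
            raise ValueError("status must be 0/1")
        for sid, grp in df.groupby("id", sort=False):
            g = grp.sort_values("start")
            if not np.array_equal(g.index.to_numpy(), grp.index.to_numpy()):
                raise ValueError(f"subject {sid}: intervals out of order")
            starts = g["start"].to_numpy()
            stops = g["stop"].to_numpy()
            if np.any(starts[1:] < stops[:-1] - 1e-12):
                raise ValueError(f"subject {sid}: overlapping intervals")
            status = g["status"].to_numpy()
            if status[:-1].any():
                raise ValueError(f"subject {sid}: status=1 before last row")

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class FitResult:
    """Common shape of estimation results.

    ``estimates`` and ``standard_errors`` are name-aligned; ``extra`` is a
    method-specific payload (information matrices, BLUPs, draws, ...).
    """

    estimates: dict
    standard_errors: dict
    loglik: float
    converged: bool
    iterations: int
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.estimates) != set(self.standard_errors):
            raise ValueError("estimate and standard-error names must coincide")
        if self.converged and any(se <= 0 for se in self.standard_errors.values()):
            raise ValueError("converged fit must have positive standard errors")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_PANEL_COLS = {"id": "id", "time": "time", "y": "y", "age": "age", "sex": "sex"}


def _read_csv(path, required: Sequence[str], column_map: Mapping[str, str]) -> pd.DataFrame:
    df = pd.read_csv(path, float_precision="round_trip")
    rename = {v: k for k, v in column_map.items() if v in df.columns}
    df = df.rename(columns=rename)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def _as_float(df: pd.DataFrame, cols: Sequence[str], path) -> pd.DataFrame:
    for c in cols:
        try:
            df[c] = pd.to_numeric(df[c], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[c], errors="coerce").isna() & df[c].notna()
            row = int(np.flatnonzero(bad.to_numpy())[0]) if bad.any() else -1
            raise FormatError(f"{path}: non-numeric value in column '{c}' at row {row}")
    return df


def read_long_panel(path, column_map: Mapping[str, str] | None = None) -> list[LongPanel]:
    """Read a long-format panel CSV into per-subject :class:`LongPanel`\\ s.

    ``column_map`` maps canonical names (id, time, y, age, sex) to the
    file's column names.  Rows may arrive in any order; panels come back
    sorted by subject, times ascending.
    """
    cmap = dict(_PANEL_COLS)
    if column_map:
        cmap.update(column_map)
    df = _read_csv(path, list(cmap), cmap)
    df = _as_float(df, ["time", "y", "age", "sex"], path)
    panels = []
    for sid, grp in df.groupby(df["id"].astype(str), sort=True):
        g = grp.sort_values("time")
        panels.append(
            LongPanel(
                subject_id=str(sid),
                times=g["time"].to_numpy(),
                values=g["y"].to_numpy(),
                age=float(g["age"].iloc[0]),
                sex=int(g["sex"].iloc[0]),
            )
        )
    return panels


def write_long_panel(panels: Sequence[LongPanel], path) -> None:
    rows = [
        {"id": p.subject_id, "time": t, "y": y, "age": p.age, "sex": p.sex}
        for p in panels
        for t, y in zip(p.times, p.values)
    ]
    pd.DataFrame(rows, columns=["id", "time", "y", "age", "sex"]).to_csv(
        path, index=False, float_format="%.17g"
    )


def read_survival(path, column_map: Mapping[str, str] | None = None) -> list[SurvivalRecord]:
    cmap = {"id": "id", "time": "time", "event": "event"}
    if column_map:
        cmap.update(column_map)
    df = _read_csv(path, list(cmap), cmap)
    df = _as_float(df, ["time", "event"], path)
    df = df.sort_values("id", key=lambda s: s.astype(str))
    return [
        SurvivalRecord(str(r.id), float(r.time), int(r.event))
        for r in df.itertuples(index=False)
    ]


def write_survival(records: Sequence[SurvivalRecord], path) -> None:
    pd.DataFrame(
        [{"id": r.subject_id, "time": r.time, "event": r.event} for r in records],
        columns=["id", "time", "event"],
    ).to_csv(path, index=False, float_format="%.17g")


def write_counting_process(table: CountingProcessTable, path) -> None:
    """Write a validated counting-process table; read-back equals input."""
    table.validate()
    cols = list(CountingProcessTable.REQUIRED) + list(table.covariate_names)
    table.data[cols].to_csv(path, index=False, float_format="%.17g")


def read_counting_process(path, covariate_names: Sequence[str] = ("value", "age", "sex")) -> CountingProcessTable:
    df = _read_csv(path, list(CountingProcessTable.REQUIRED) + list(covariate_names), {})
    df = _as_float(df, ["start", "stop", "status", *covariate_names], path)
    return CountingProcessTable(df, tuple(covariate_names))


def validate_pairing(panels: Sequence[LongPanel], survival: Sequence[SurvivalRecord]) -> None:
    """Check that no measurement time exceeds the paired follow-up time."""
    surv = {r.subject_id: r for r in survival}
    for p in panels:
        if p.subject_id not in surv:
            raise ValueError(f"subject {p.subject_id} has no survival record")
        T = surv[p.subject_id].time
        if p.times[-1] > T + 1e-12:
            raise ValueError(
                f"subject {p.subject_id}: measurement at t={p.times[-1]} "
                f"exceeds follow-up time {T}"
            )
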