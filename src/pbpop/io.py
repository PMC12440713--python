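"""Event-table dataset container and CSV dialect.

The on-disk format is a NONMEM-style rectangular CSV with columns
``ID, TIME, AMT, DV, EVID, MDV, WT, AGE, SEX``:

* ``EVID`` 1 = dose (AMT in mg, DV written as ``.``),
  ``EVID`` 0 = observation (DV in mg/L, AMT written as ``.``);
* ``MDV`` 1 marks a DV that must not enter estimation — dose rows, and
  observations flagged below the assay LLOQ;
* times in hours since first dose, decimal point, header required.

Within a subject, rows are sorted by time; an observation at the same
time as a dose precedes it (predose sampling convention).  Lines starting
with ``#`` are metadata comments (seed, config hash) and are skipped on
read, so a write/read round trip reproduces the table exactly.
"""

from __future__ import annotations

import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .model import DoseEvent, SubjectCovariates

__all__ = ["Observation", "SubjectRecord", "EventTable", "read_event_table", "write_event_table"]

COLUMNS = ["ID", "TIME", "AMT", "DV", "EVID", "MDV", "WT", "AGE", "SEX"]


@dataclass(frozen=True)
class Observation:
    time: float  # h since first dose
    conc: float  # mg/L
    below_lloq: bool = False


@dataclass
class SubjectRecord:
    """Covariates, dose history and observations for one dog."""

    id: int
    covariates: SubjectCovariates
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)

    @property
    def usable_observations(self) -> list[Observation]:
        """Observations entering estimation (above-LLOQ)."""
        return [o for o in self.observations if not o.below_lloq]


class EventTable:
    """A TDM dataset: a list of :class:`SubjectRecord` with CSV round trip."""

    def __init__(self, records: Sequence[SubjectRecord]):
        ids = [r.id for r in records]
        if len(set(ids)) != len(ids):
            raise ValueError("subject ids must be unique")
        self.records: list[SubjectRecord] = list(records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, EventTable):
            return NotImplemented
        return self.records == other.records

    @property
    def n_observations(self) -> int:
        return sum(len(r.observations) for r in self.records)

    @property
    def n_usable_observations(self) -> int:
        return sum(len(r.usable_observations) for r in self.records)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in self.records:
            c = rec.covariates
            events = [("obs", o.time, o) for o in rec.observations]
            events += [("dose", d.time, d) for d in rec.doses]
            # observations first at equal times (predose convention)
            events.sort(key=lambda e: (e[1], 0 if e[0] == "obs" else 1))
            for kind, t, ev in events:
                if kind == "dose":
                    rows.append((rec.id, t, ev.amount, np.nan, 1, 1, c.weight, c.age, c.sex))
                else:
                    rows.append(
                        (rec.id, t, np.nan, ev.conc, 0, 1 if ev.below_lloq else 0,
                         c.weight, c.age, c.sex)
                    )
        return pd.DataFrame(rows, columns=COLUMNS)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventTable":
        unknown = set(df.columns) - set(COLUMNS)
        if unknown:
            raise ValueError(f"unknown columns: {sorted(unknown)}")
        missing = set(COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"missing columns: {sorted(missing)}")
        records = []
        for sid, grp in df.groupby("ID", sort=True):
            times = grp["TIME"].to_numpy(float)
            if np.any(np.diff(times) < 0):
                raise ValueError(f"non-monotone times for subject {sid}")
            cov = SubjectCovariates(
                weight=float(grp["WT"].iloc[0]),
                age=float(grp["AGE"].iloc[0]),
                sex=int(grp["SEX"].iloc[0]),
            )
            doses, obs = [], []
            for i, row in grp.iterrows():
                evid = int(row["EVID"])
                if evid == 1:
                    if not np.isfinite(row["AMT"]) or row["AMT"] <= 0:
                        raise ValueError(f"row {i}: dose row needs positive AMT")
                    doses.append(DoseEvent(time=float(row["TIME"]), amount=float(row["AMT"])))
                elif evid == 0:
                    if not np.isfinite(row["DV"]):
                        continue  # missing DV, MDV honored
                    if row["DV"] < 0:
                        raise ValueError(f"row {i}: negative DV")
                    obs.append(
                        Observation(
                            time=float(row["TIME"]),
                            conc=float(row["DV"]),
                            below_lloq=bool(int(row["MDV"])),
                        )
                    )
                else:
                    raise ValueError(f"row {i}: unsupported EVID={evid}")
            records.append(SubjectRecord(id=int(sid), covariates=cov, doses=doses, observations=obs))
        return cls(records)

    # -- CSV dialect ------------------------------------------------------

    def write_csv(self, path: str | Path, metadata: dict | None = None) -> None:
        df = self.to_frame()
        buf = _io.StringIO()
        if metadata:
            items = " ".join(f"{k}={v}" for k, v in metadata.items())
            buf.write(f"# {items}\n")
        # repr() is the shortest exact decimal form: bit-exact round trip
        out = df.copy()
        for col in ("TIME", "AMT", "DV", "WT", "AGE"):
            out[col] = df[col].map(lambda v: "." if pd.isna(v) else repr(float(v)))
        for col in ("ID", "EVID", "MDV", "SEX"):
            out[col] = df[col].astype(int)
        out.to_csv(buf, index=False)
        Path(path).write_text(buf.getvalue())

    @classmethod
    def read_csv(cls, path: str | Path) -> "EventTable":
        df = pd.read_csv(path, comment="#", na_values=["."], float_precision="round_trip")
        return cls.from_frame(df)


def read_event_table(path: str | Path) -> EventTable:
    """Read and validate an event-table CSV (see module docstring)."""
    return EventTable.read_csv(path)


def write_event_table(table: EventTable, path: str | Path, metadata: dict | None = None) -> None:
    """Write an event table in the canonical CSV dialect."""
    table.write_csv(path, metadata=metadata)
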