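"""Event-record CSV I/O, run configuration and seed management.

The pharmacometric datasets follow the NONMEM event-record convention: one
row per dose or observation, with ``EVID`` distinguishing dose rows
(``EVID=1``, ``AMT`` set, ``DV`` missing) from observation rows (``EVID=0``,
``DV`` set) and ``MDV`` flagging missing observations.  Missing values are
written as ``"."``; both ``"."`` and empty cells are accepted on read.
Times are hours since each subject's first dose.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .pk_model import ConcObservation, DoseEvent

__all__ = [
    "SubjectCourse",
    "SchemaError",
    "DEFAULT_COLUMNS",
    "read_event_table",
    "write_event_table",
    "courses_to_frame",
    "read_logistic_table",
    "write_logistic_table",
    "spawn_rngs",
    "run_manifest",
]

log = logging.getLogger("graftrisk")

#: canonical column names; ``read_event_table`` accepts a ``column_map``
#: translating other headers onto these
DEFAULT_COLUMNS = {
    "id": "ID",
    "time": "TIME",
    "amt": "AMT",
    "dv": "DV",
    "evid": "EVID",
    "mdv": "MDV",
    "occasion": "OCC",
    "weight": "WT",
}

_MANDATORY = ("id", "time", "amt", "dv", "evid")


class SchemaError(ValueError):
    """A mandatory column is absent or a row violates the event-record rules."""


@dataclass
class SubjectCourse:
    """One subject's dosing and sampling course for a single drug.

    ``covariates`` holds subject-level values (age, sex, donor type, GFR
    class, donor age, diabetes flag, ...) preserved from unknown columns on
    read and consumed by the covariate machinery.
    """

    subject_id: str
    weight: float
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[ConcObservation] = field(default_factory=list)
    covariates: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.weight > 0:
            raise ValueError(f"subject {self.subject_id}: weight must be positive")


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

def read_event_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[SubjectCourse]:
    """Read a pharmacometric event-record CSV into subject courses.

    Unknown columns are carried along as subject-level covariates (their
    first value per subject).  Raises :class:`SchemaError` on a missing
    mandatory column and :class:`ValueError` on unsorted times.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path, na_values=["."], keep_default_na=True,
                     float_precision="round_trip")
    if df.empty:
        log.warning("event table %s is empty", path)
        return []
    for key in _MANDATORY:
        if cols[key] not in df.columns:
            raise SchemaError(f"mandatory column {cols[key]!r} ({key}) missing in {path}")
    known = {cols[k] for k in cols if cols[k] in df.columns}
    extra = [c for c in df.columns if c not in known]

    courses: list[SubjectCourse] = []
    for sid, grp in df.groupby(cols["id"], sort=False):
        times = grp[cols["time"]].to_numpy(float)
        if np.any(np.diff(times) < 0):
            raise ValueError(f"subject {sid}: times are not non-decreasing")
        wt = float(grp[cols["weight"]].iloc[0]) if cols["weight"] in grp else 70.0
        cov = {c: grp[c].iloc[0] for c in extra}
        course = SubjectCourse(subject_id=str(sid), weight=wt, covariates=cov)
        for _, row in grp.iterrows():
            evid = int(row[cols["evid"]])
            occ = str(row[cols["occasion"]]) if cols["occasion"] in grp and pd.notna(
                row.get(cols["occasion"])) else "W1"
            if evid == 1:
                course.doses.append(DoseEvent(str(sid), float(row[cols["time"]]),
                                              float(row[cols["amt"]])))
            elif evid == 0:
                mdv = int(row[cols["mdv"]]) if cols["mdv"] in grp and pd.notna(
                    row.get(cols["mdv"])) else 0
                if mdv == 0:
                    course.observations.append(
                        ConcObservation(str(sid), float(row[cols["time"]]),
                                        float(row[cols["dv"]]), occ))
            else:
                raise SchemaError(f"subject {sid}: unsupported EVID {evid}")
        courses.append(course)
    n_obs = sum(len(c.observations) for c in courses)
    log.info("read %d subjects, %d observations from %s", len(courses), n_obs, path)
    return courses


def courses_to_frame(courses: Sequence[SubjectCourse]) -> pd.DataFrame:
    """Flatten subject courses into an event-record DataFrame (write schema)."""
    rows = []
    for c in courses:
        events = [("dose", d.time, d) for d in c.doses] + [
            ("obs", o.time, o) for o in c.observations
        ]
        # doses precede observations at identical times (trough before dose is
        # expressed by obs strictly at the dose time being EVID=0 first); keep
        # stable time order with observations first at ties (pre-dose trough)
        events.sort(key=lambda e: (e[1], 0 if e[0] == "obs" else 1))
        for kind, t, ev in events:
            row = {
                "ID": c.subject_id,
                "TIME": t,
                "AMT": ev.amount if kind == "dose" else np.nan,
                "DV": ev.value if kind == "obs" else np.nan,
                "EVID": 1 if kind == "dose" else 0,
                "MDV": 1 if kind == "dose" else 0,
                "OCC": getattr(ev, "occasion", np.nan) if kind == "obs" else np.nan,
                "WT": c.weight,
            }
            row.update(c.covariates)
            rows.append(row)
    return pd.DataFrame(rows)


def _roundtrip_float(v) -> str:
    # shortest representation that parses back to the identical float
    return repr(float(v))


def write_event_table(courses: Sequence[SubjectCourse], path: str | Path) -> None:
    """Write subject courses as an event-record CSV ("." for missing)."""
    df = courses_to_frame(courses)
    df.to_csv(path, index=False, na_rep=".", float_format=_roundtrip_float)


# ---------------------------------------------------------------------------
# logistic visit table
# ---------------------------------------------------------------------------

_LOGISTIC_COLS = ["ID", "VISIT", "MIR155", "CXCL10", "AUC_TAC", "AUC_MPA",
                  "TROUGH_TAC", "TROUGH_MPA", "AR"]


def write_logistic_table(records: pd.DataFrame, path: str | Path) -> None:
    """Write the visit-level logistic dataset (S3-style column convention)."""
    records.to_csv(path, index=False, na_rep=".", float_format=_roundtrip_float,
                   columns=[c for c in _LOGISTIC_COLS if c in records.columns])


def read_logistic_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["."], float_precision="round_trip")
    missing = [c for c in ("ID", "VISIT", "AR") if c not in df.columns]
    if missing:
        raise SchemaError(f"logistic table missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# seeds and manifests
# ---------------------------------------------------------------------------

def spawn_rngs(seed: int, n: int) -> list[np.random.Generator]:
    """Derive ``n`` independent generators from one master seed."""
    ss = np.random.SeedSequence(seed)
    return [np.random.default_rng(child) for child in ss.spawn(n)]


def run_manifest(seed: int, config: Mapping | None = None, **extra) -> dict:
    """Machine-readable provenance record written next to every CLI output."""
    import graftrisk

    cfg_json = json.dumps(config, sort_keys=True, default=str) if config else ""
    return {
        "package": "graftrisk",
        "version": graftrisk.__version__,
        "seed": seed,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest()[:16],
        "numpy": np.__version__,
        **extra,
    }
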