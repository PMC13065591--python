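"""Relational data model for the five EHR documentation sources.

The package ingests five raw documentation tables plus two registries:

* ``patients``    — one row per patient (birth, optional death time)
* ``encounters``  — hospital stays, with admission/discharge times
* ``flowsheets``  — time-stamped ventilator-mode charting rows
* ``lda``         — Lines/Drains/Airways device records (placement/removal)
* ``anesthesia``  — intraoperative airway event log
* ``procedures``  — procedural records (intubations, tracheostomies)

All tables are plain :class:`pandas.DataFrame` objects bundled in a
:class:`SourceTables` dataclass.  Timestamps are timezone-naive
``datetime64[ns]`` in a single declared zone, canonically at minute
resolution; all interval arithmetic is done on the naive values directly,
which is equivalent to working in UTC.
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Closed location vocabulary; unknown tokens are mapped to "other".
LOCATIONS = (
    "perioperative",
    "ED",
    "NICU",
    "PICU",
    "cardiac_ICU",
    "adult_ICU",
    "ward",
    "other",
)

#: Default ventilator-mode vocabulary.  Editable via config: any token not in
#: either set is treated as unknown and ignored (but counted) by extraction.
INVASIVE_MODES = frozenset({"AC", "SIMV", "PRVC", "PS-invasive"})
NONINVASIVE_MODES = frozenset({"CPAP", "NIPPV", "nasal-IMV", "HFNC"})

TABLE_NAMES = ("patients", "encounters", "flowsheets", "lda", "anesthesia", "procedures")

#: Column layout per table; *_datetime columns are parsed as timestamps.
TABLE_COLUMNS: dict[str, list[str]] = {
    "patients": ["patient_id", "birth_datetime", "death_datetime"],
    "encounters": [
        "encounter_id",
        "patient_id",
        "admit_datetime",
        "discharge_datetime",
        "admit_location",
        "admitted_with_airway",
        "discharge_disposition",
    ],
    "flowsheets": ["encounter_id", "recorded_datetime", "vent_mode", "location"],
    "lda": ["encounter_id", "lda_type", "placement_datetime", "removal_datetime", "location"],
    "anesthesia": ["encounter_id", "event_type", "event_datetime", "location"],
    "procedures": ["encounter_id", "procedure_type", "procedure_datetime", "location"],
}

_BOOL_COLUMNS = {"encounters": ["admitted_with_airway"]}

#: Timestamp format used in CSV and SQLite storage (minute precision).
TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M"

#: Columns of the final analytic dataset, one row per ventilation episode.
EPISODE_COLUMNS = [
    "patient_id",
    "encounter_id",
    "episode_index",
    "intubation_datetime",
    "extubation_datetime",
    "intubation_location",
    "extubation_location",
    "termination",
    "new_tracheostomy_during_episode",
    "intubation_inferred",
    "extubation_inferred",
    "intubation_sources",
    "extubation_sources",
    "intubation_grade",
    "extubation_grade",
    "duration_hours",
    "age_years_at_intubation",
    "pediatric",
    "died_during_encounter",
    "reintubated_within_48h",
    "reintubated_2to7d",
    "reintubated_within_7d",
]

_EPISODE_DATETIME_COLUMNS = ["intubation_datetime", "extubation_datetime"]
_EPISODE_BOOL_COLUMNS = [
    "new_tracheostomy_during_episode",
    "intubation_inferred",
    "extubation_inferred",
    "reintubated_within_48h",
    "reintubated_2to7d",
    "reintubated_within_7d",
]


def normalize_location(value: object) -> str:
    """Map a raw location token onto the closed vocabulary."""
    if isinstance(value, str) and value in LOCATIONS:
        return value
    return "other"


def _datetime_columns(table: str) -> list[str]:
    return [c for c in TABLE_COLUMNS[table] if c.endswith("_datetime")]


def _empty_table(table: str) -> pd.DataFrame:
    df = pd.DataFrame({c: pd.Series(dtype="object") for c in TABLE_COLUMNS[table]})
    for c in _datetime_columns(table):
        df[c] = pd.Series(dtype="datetime64[ns]")
    return df


@dataclass
class SourceTables:
    """Bundle of the five documentation tables plus the two registries."""

    patients: pd.DataFrame = field(default_factory=lambda: _empty_table("patients"))
    encounters: pd.DataFrame = field(default_factory=lambda: _empty_table("encounters"))
    flowsheets: pd.DataFrame = field(default_factory=lambda: _empty_table("flowsheets"))
    lda: pd.DataFrame = field(default_factory=lambda: _empty_table("lda"))
    anesthesia: pd.DataFrame = field(default_factory=lambda: _empty_table("anesthesia"))
    procedures: pd.DataFrame = field(default_factory=lambda: _empty_table("procedures"))

    def tables(self) -> dict[str, pd.DataFrame]:
        return {name: getattr(self, name) for name in TABLE_NAMES}

    def row_counts(self) -> dict[str, int]:
        return {name: len(df) for name, df in self.tables().items()}

    def copy(self) -> "SourceTables":
        return SourceTables(**{name: df.copy() for name, df in self.tables().items()})

    def equals(self, other: "SourceTables") -> bool:
        return all(
            self.tables()[name].reset_index(drop=True).equals(
                other.tables()[name].reset_index(drop=True)
            )
            for name in TABLE_NAMES
        )


def _coerce_table(df: pd.DataFrame, table: str) -> pd.DataFrame:
    """Reorder columns, parse timestamps to minute resolution, coerce booleans."""
    missing = [c for c in TABLE_COLUMNS[table] if c not in df.columns]
    for c in missing:
        df[c] = pd.NA
    df = df[TABLE_COLUMNS[table]].copy()
    for c in _datetime_columns(table):
        df[c] = pd.to_datetime(df[c], errors="coerce", format="mixed").dt.floor("min")
    for c in _BOOL_COLUMNS.get(table, []):
        df[c] = df[c].map(
            lambda v: bool(v) if isinstance(v, (bool, np.bool_)) else str(v).strip().lower() in {"true", "1", "yes"}
        )
    return df


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_source_tables(path_or_db: str | Path, format: str = "csv-dir") -> SourceTables:
    """Read the six source tables from a CSV directory or a SQLite file.

    Unparseable timestamps are coerced to NaT here and routed to the
    validation reject list by :func:`validate_records`, never fatal.
    A missing table is fatal.
    """
    path = Path(path_or_db)
    if not path.exists():
        raise FileNotFoundError(f"input locator does not exist: {path}")
    raw: dict[str, pd.DataFrame] = {}
    if format == "csv-dir":
        for name in TABLE_NAMES:
            f = path / f"{name}.csv"
            if not f.exists():
                raise FileNotFoundError(f"required table missing: {f}")
            raw[name] = pd.read_csv(f, dtype="object", keep_default_na=True)
    elif format == "sqlite":
        with sqlite3.connect(path) as con:
            present = {
                r[0]
                for r in con.execute("SELECT name FROM sqlite_master WHERE type='table'")
            }
            for name in TABLE_NAMES:
                if name not in present:
                    raise FileNotFoundError(f"required table missing from {path}: {name}")
                raw[name] = pd.read_sql_query(f"SELECT * FROM {name}", con)
    else:
        raise ValueError(f"unknown format: {format!r}")

    tables = {name: _coerce_table(df, name) for name, df in raw.items()}
    st = SourceTables(**tables)
    for name, n in st.row_counts().items():
        logger.info("read %s: %d rows", name, n)
        if n == 0:
            logger.warning("table %s is empty", name)
    return st


def _serialize_table(df: pd.DataFrame, table: str) -> pd.DataFrame:
    out = df.copy()
    for c in _datetime_columns(table):
        out[c] = out[c].dt.strftime(TIMESTAMP_FORMAT)
    return out


def write_source_tables(tables: SourceTables, path_or_db: str | Path, format: str = "csv-dir") -> Path:
    """Write the six tables as RFC-4180 CSVs or a single SQLite database."""
    path = Path(path_or_db)
    if format == "csv-dir":
        path.mkdir(parents=True, exist_ok=True)
        for name, df in tables.tables().items():
            _serialize_table(df, name).to_csv(path / f"{name}.csv", index=False)
    elif format == "sqlite":
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.exists():
            path.unlink()
        with sqlite3.connect(path) as con:
            for name, df in tables.tables().items():
                _serialize_table(df, name).to_sql(name, con, index=False)
    else:
        raise ValueError(f"unknown format: {format!r}")
    return path


def write_analytic_dataset(episodes: pd.DataFrame, path: str | Path, format: str = "csv") -> Path:
    """Write the final analytic dataset (one row per episode), re-readable losslessly."""
    path = Path(path)
    out = episodes.copy()
    for c in EPISODE_COLUMNS:
        if c not in out.columns:
            out[c] = pd.NA
    out = out[EPISODE_COLUMNS]
    for c in _EPISODE_DATETIME_COLUMNS:
        out[c] = pd.to_datetime(out[c]).dt.strftime(TIMESTAMP_FORMAT)
    if format == "csv":
        path.parent.mkdir(parents=True, exist_ok=True)
        out.to_csv(path, index=False)
    elif format == "sqlite":
        path.parent.mkdir(parents=True, exist_ok=True)
        if path.exists():
            path.unlink()
        with sqlite3.connect(path) as con:
            out.to_sql("episodes", con, index=False)
    else:
        raise ValueError(f"unknown format: {format!r}")
    return path


def read_analytic_dataset(path: str | Path, format: str = "csv") -> pd.DataFrame:
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path)
    elif format == "sqlite":
        with sqlite3.connect(path) as con:
            df = pd.read_sql_query("SELECT * FROM episodes", con)
    else:
        raise ValueError(f"unknown format: {format!r}")
    for c in _EPISODE_DATETIME_COLUMNS:
        df[c] = pd.to_datetime(df[c], format="mixed")
    for c in _EPISODE_BOOL_COLUMNS:
        if df[c].dtype != bool:
            df[c] = df[c].map(lambda v: str(v).strip().lower() in {"true", "1"})
    return df


# ---------------------------------------------------------------------------
# Record-level validation
# ---------------------------------------------------------------------------

#: Events documented outside [admit - SLACK, discharge + SLACK] are invalid.
ENCOUNTER_WINDOW_SLACK = pd.Timedelta(hours=24)

REJECT_COLUMNS = ["table", "row_ref", "reason_code"]


@dataclass
class RejectReport:
    """Itemized list of records removed by validation, with reason codes."""

    rows: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=REJECT_COLUMNS)
    )

    @property
    def count(self) -> int:
        return len(self.rows)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(path, index=False)
        return path


def _reject(rejects: list, table: str, index: Iterable, reason: str) -> None:
    rejects.extend({"table": table, "row_ref": int(i), "reason_code": reason} for i in index)


def validate_records(tables: SourceTables) -> tuple[SourceTables, RejectReport]:
    """Partition each table into clean records and itemized rejects.

    Invalid means: NULL required timestamp, removal before placement,
    dangling foreign reference, or an event documented more than 24 h
    outside its encounter's admission-discharge window.  Validation never
    aborts; it always returns the clean subset plus the reject report, and
    is idempotent (a second pass rejects nothing).
    """
    t = tables.copy()
    rejects: list[dict] = []

    # Registries first so downstream foreign-key checks see the clean sets.
    pat = t.patients
    bad = pat.index[pat["patient_id"].isna() | pat["birth_datetime"].isna()]
    _reject(rejects, "patients", bad, "null_required_field")
    pat = pat.drop(index=bad)
    bad = pat.index[
        pat["death_datetime"].notna() & (pat["death_datetime"] < pat["birth_datetime"])
    ]
    _reject(rejects, "patients", bad, "negative_interval")
    pat = pat.drop(index=bad)
    bad = pat.index[pat["patient_id"].duplicated(keep="first")]
    _reject(rejects, "patients", bad, "duplicate_id")
    pat = pat.drop(index=bad)

    enc = t.encounters
    bad = enc.index[enc["encounter_id"].isna() | enc["admit_datetime"].isna()]
    _reject(rejects, "encounters", bad, "null_timestamp")
    enc = enc.drop(index=bad)
    bad = enc.index[~enc["patient_id"].isin(set(pat["patient_id"]))]
    _reject(rejects, "encounters", bad, "dangling_ref")
    enc = enc.drop(index=bad)
    bad = enc.index[
        enc["discharge_datetime"].notna() & (enc["discharge_datetime"] < enc["admit_datetime"])
    ]
    _reject(rejects, "encounters", bad, "negative_interval")
    enc = enc.drop(index=bad)
    bad = enc.index[enc["encounter_id"].duplicated(keep="first")]
    _reject(rejects, "encounters", bad, "duplicate_id")
    enc = enc.drop(index=bad)

    known_enc = set(enc["encounter_id"])
    lo = enc.set_index("encounter_id")["admit_datetime"] - ENCOUNTER_WINDOW_SLACK
    hi = enc.set_index("encounter_id")["discharge_datetime"] + ENCOUNTER_WINDOW_SLACK

    def window_ok(enc_ids: pd.Series, times: pd.Series) -> pd.Series:
        lower = enc_ids.map(lo)
        upper = enc_ids.map(hi)
        ok = times >= lower
        ok &= upper.isna() | (times <= upper)
        return ok

    def check_child(df: pd.DataFrame, table: str, time_cols: list[str], required: bool) -> pd.DataFrame:
        if required:
            null_mask = df[time_cols].isna().all(axis=1) if len(time_cols) > 1 else df[time_cols[0]].isna()
            bad = df.index[null_mask]
            _reject(rejects, table, bad, "null_timestamp")
            df = df.drop(index=bad)
        bad = df.index[~df["encounter_id"].isin(known_enc)]
        _reject(rejects, table, bad, "dangling_ref")
        df = df.drop(index=bad)
        out_of_window = pd.Series(False, index=df.index)
        for c in time_cols:
            present = df[c].notna()
            out_of_window |= present & ~window_ok(df["encounter_id"], df[c])
        bad = df.index[out_of_window]
        _reject(rejects, table, bad, "out_of_window")
        return df.drop(index=bad)

    fs = check_child(t.flowsheets, "flowsheets", ["recorded_datetime"], required=True)

    lda = t.lda
    # A device record must carry at least one endpoint timestamp.
    bad = lda.index[lda["placement_datetime"].isna() & lda["removal_datetime"].isna()]
    _reject(rejects, "lda", bad, "null_timestamp")
    lda = lda.drop(index=bad)
    bad = lda.index[
        lda["placement_datetime"].notna()
        & lda["removal_datetime"].notna()
        & (lda["removal_datetime"] < lda["placement_datetime"])
    ]
    _reject(rejects, "lda", bad, "negative_interval")
    lda = lda.drop(index=bad)
    lda = check_child(lda, "lda", ["placement_datetime", "removal_datetime"], required=False)

    an = check_child(t.anesthesia, "anesthesia", ["event_datetime"], required=True)
    proc = check_child(t.procedures, "procedures", ["procedure_datetime"], required=True)

    clean = SourceTables(
        patients=pat.reset_index(drop=True),
        encounters=enc.reset_index(drop=True),
        flowsheets=fs.reset_index(drop=True),
        lda=lda.reset_index(drop=True),
        anesthesia=an.reset_index(drop=True),
        procedures=proc.reset_index(drop=True),
    )
    report = RejectReport(pd.DataFrame(rejects, columns=REJECT_COLUMNS))
    if report.count:
        logger.info("validation rejected %d records", report.count)
    return clean, report
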