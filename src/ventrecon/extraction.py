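"""Per-source extraction of candidate airway events.

Each of the five documentation sources is converted into a uniform stream of
*candidate events* — one source's claim that an intubation or extubation
occurred at a timestamp.  These are the intermediate ("temporary") tables
between the raw EHR extracts and the reconciled episode dataset.

Candidate columns: ``encounter_id``, ``event_type`` (intubation|extubation),
``event_datetime``, ``source`` (flowsheet|lda|anesthesia|procedure|admission),
``location``, ``inferred`` (True only for admission/discharge fallback
inference), ``airway_kind`` (endotracheal|tracheostomy|unknown).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .schema import INVASIVE_MODES, NONINVASIVE_MODES, SourceTables, normalize_location

logger = logging.getLogger(__name__)

CANDIDATE_COLUMNS = [
    "encounter_id",
    "event_type",
    "event_datetime",
    "source",
    "location",
    "inferred",
    "airway_kind",
]

TRACH_EVENT_COLUMNS = ["encounter_id", "event_datetime", "source"]

#: Canonical-time source priority, best first.
SOURCE_PRIORITY = ("anesthesia", "lda", "flowsheet", "procedure", "admission")

DEFAULT_GAP_TOLERANCE_HOURS = 8.0


def empty_candidates() -> pd.DataFrame:
    df = pd.DataFrame(columns=CANDIDATE_COLUMNS)
    df["event_datetime"] = pd.Series(dtype="datetime64[ns]")
    df["inferred"] = pd.Series(dtype=bool)
    return df


def _candidates(rows: list[dict]) -> pd.DataFrame:
    if not rows:
        return empty_candidates()
    df = pd.DataFrame(rows, columns=CANDIDATE_COLUMNS)
    df["event_datetime"] = pd.to_datetime(df["event_datetime"])
    df["inferred"] = df["inferred"].astype(bool)
    return df


def extract_from_flowsheets(
    flowsheets: pd.DataFrame,
    invasive_vocab: frozenset[str] | set[str] = INVASIVE_MODES,
    noninvasive_vocab: frozenset[str] | set[str] = NONINVASIVE_MODES,
    gap_tolerance_hours: float = DEFAULT_GAP_TOLERANCE_HOURS,
) -> pd.DataFrame:
    """Segment invasive ventilator-mode rows into intervals and emit endpoints.

    Within an encounter, consecutive invasive-mode rows whose inter-row gap
    is at most ``gap_tolerance_hours`` form one invasive interval; the first
    row of an interval emits an intubation candidate, the last an extubation
    candidate.  Noninvasive modes (CPAP, NIPPV, nasal IMV, high-flow) never
    open or extend an interval; rows with a mode in neither vocabulary are
    ignored and counted in the log.
    """
    if flowsheets.empty:
        return empty_candidates()
    known = set(invasive_vocab) | set(noninvasive_vocab)
    unknown = ~flowsheets["vent_mode"].isin(known) & flowsheets["vent_mode"].notna()
    if unknown.any():
        logger.info("flowsheets: ignored %d rows with unknown vent_mode", int(unknown.sum()))
    rows = flowsheets[flowsheets["vent_mode"].isin(set(invasive_vocab))]
    if rows.empty:
        return empty_candidates()
    rows = rows.sort_values(["encounter_id", "recorded_datetime"], kind="mergesort")
    tol = pd.Timedelta(hours=gap_tolerance_hours)
    out: list[dict] = []
    for enc, grp in rows.groupby("encounter_id", sort=True):
        times = grp["recorded_datetime"].tolist()
        locs = grp["location"].tolist()
        start = 0
        for j in range(1, len(times) + 1):
            if j == len(times) or times[j] - times[j - 1] > tol:
                out.append(
                    {
                        "encounter_id": enc,
                        "event_type": "intubation",
                        "event_datetime": times[start],
                        "source": "flowsheet",
                        "location": normalize_location(locs[start]),
                        "inferred": False,
                        "airway_kind": "unknown",
                    }
                )
                out.append(
                    {
                        "encounter_id": enc,
                        "event_type": "extubation",
                        "event_datetime": times[j - 1],
                        "source": "flowsheet",
                        "location": normalize_location(locs[j - 1]),
                        "inferred": False,
                        "airway_kind": "unknown",
                    }
                )
                start = j
    return _candidates(out)


def extract_from_lda(lda: pd.DataFrame) -> pd.DataFrame:
    """Map device records to candidates: placement→intubation, removal→extubation.

    Endotracheal-tube records yield ``airway_kind='endotracheal'``;
    tracheostomy-tube records yield ``airway_kind='tracheostomy'``.  A record
    missing one endpoint emits only the present one; other device types emit
    nothing.
    """
    out: list[dict] = []
    for row in lda.itertuples(index=False):
        lda_type = str(row.lda_type).strip().lower()
        if "endotracheal" in lda_type or lda_type == "ett":
            kind = "endotracheal"
        elif "tracheostomy" in lda_type or lda_type == "trach":
            kind = "tracheostomy"
        else:
            continue
        loc = normalize_location(row.location)
        if pd.notna(row.placement_datetime):
            out.append(
                {
                    "encounter_id": row.encounter_id,
                    "event_type": "intubation",
                    "event_datetime": row.placement_datetime,
                    "source": "lda",
                    "location": loc,
                    "inferred": False,
                    "airway_kind": kind,
                }
            )
        if pd.notna(row.removal_datetime):
            out.append(
                {
                    "encounter_id": row.encounter_id,
                    "event_type": "extubation",
                    "event_datetime": row.removal_datetime,
                    "source": "lda",
                    "location": loc,
                    "inferred": False,
                    "airway_kind": kind,
                }
            )
    return _candidates(out)


def extract_from_anesthesia(anesthesia: pd.DataFrame) -> pd.DataFrame:
    """One-to-one mapping of typed anesthesia events to candidates."""
    out = [
        {
            "encounter_id": row.encounter_id,
            "event_type": row.event_type,
            "event_datetime": row.event_datetime,
            "source": "anesthesia",
            "location": normalize_location(row.location),
            "inferred": False,
            "airway_kind": "endotracheal",
        }
        for row in anesthesia.itertuples(index=False)
        if row.event_type in ("intubation", "extubation")
    ]
    return _candidates(out)


def extract_from_procedures(procedures: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Split procedures into intubation candidates and a tracheostomy stream.

    Tracheostomy procedures never emit extubation candidates; they are
    returned as a separate event stream consumed by episode pairing for
    termination classification.
    """
    cands: list[dict] = []
    trachs: list[dict] = []
    for row in procedures.itertuples(index=False):
        ptype = str(row.procedure_type).strip().lower()
        if ptype == "intubation":
            cands.append(
                {
                    "encounter_id": row.encounter_id,
                    "event_type": "intubation",
                    "event_datetime": row.procedure_datetime,
                    "source": "procedure",
                    "location": normalize_location(row.location),
                    "inferred": False,
                    "airway_kind": "endotracheal",
                }
            )
        elif ptype == "tracheostomy":
            trachs.append(
                {
                    "encounter_id": row.encounter_id,
                    "event_datetime": row.procedure_datetime,
                    "source": "procedure",
                }
            )
    trach_df = pd.DataFrame(trachs, columns=TRACH_EVENT_COLUMNS)
    if not trach_df.empty:
        trach_df["event_datetime"] = pd.to_datetime(trach_df["event_datetime"])
    return _candidates(cands), trach_df


def extract_from_admissions(encounters: pd.DataFrame, patients: pd.DataFrame) -> pd.DataFrame:
    """Fallback inference from admission/discharge/death timestamps.

    Encounters flagged as admitted with an airway in place emit an inferred
    intubation candidate at the admission time; patients who died during an
    encounter emit an inferred extubation candidate at min(death, discharge).
    These candidates carry ``inferred=True`` and act only as lowest-priority
    fallback downstream; they never count as documenting sources in grading.
    """
    out: list[dict] = []
    deaths = patients.set_index("patient_id")["death_datetime"]
    for row in encounters.itertuples(index=False):
        if bool(row.admitted_with_airway):
            out.append(
                {
                    "encounter_id": row.encounter_id,
                    "event_type": "intubation",
                    "event_datetime": row.admit_datetime,
                    "source": "admission",
                    "location": normalize_location(row.admit_location),
                    "inferred": True,
                    "airway_kind": "unknown",
                }
            )
        death = deaths.get(row.patient_id, pd.NaT)
        if pd.notna(death):
            hi = row.discharge_datetime if pd.notna(row.discharge_datetime) else death
            t = min(death, hi)
            if t >= row.admit_datetime:
                out.append(
                    {
                        "encounter_id": row.encounter_id,
                        "event_type": "extubation",
                        "event_datetime": t,
                        "source": "admission",
                        "location": normalize_location(row.admit_location),
                        "inferred": True,
                        "airway_kind": "unknown",
                    }
                )
    return _candidates(out)


@dataclass
class ExtractionResult:
    """All candidate streams from the five sources, plus tracheostomy events."""

    candidates: pd.DataFrame = field(default_factory=empty_candidates)
    tracheostomies: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=TRACH_EVENT_COLUMNS)
    )


def extract_all(
    tables: SourceTables,
    invasive_vocab: frozenset[str] | set[str] = INVASIVE_MODES,
    noninvasive_vocab: frozenset[str] | set[str] = NONINVASIVE_MODES,
    gap_tolerance_hours: float = DEFAULT_GAP_TOLERANCE_HOURS,
) -> ExtractionResult:
    """Run all five source extractors and concatenate their candidate streams."""
    fs = extract_from_flowsheets(
        tables.flowsheets, invasive_vocab, noninvasive_vocab, gap_tolerance_hours
    )
    ld = extract_from_lda(tables.lda)
    an = extract_from_anesthesia(tables.anesthesia)
    pr, trachs = extract_from_procedures(tables.procedures)
    ad = extract_from_admissions(tables.encounters, tables.patients)
    parts = [df for df in (fs, ld, an, pr, ad) if not df.empty]
    if parts:
        cands = pd.concat(parts, ignore_index=True)
    else:
        cands = empty_candidates()
    # LDA tracheostomy placements join the tracheostomy event stream; trach
    # candidates do not take part in endotracheal episode clustering.
    lda_trach = cands[
        (cands["airway_kind"] == "tracheostomy") & (cands["event_type"] == "intubation")
    ]
    if not lda_trach.empty:
        extra = lda_trach.rename(columns={})[["encounter_id", "event_datetime"]].copy()
        extra["source"] = "lda"
        trachs = pd.concat([trachs, extra], ignore_index=True)
    cands = cands[cands["airway_kind"] != "tracheostomy"].reset_index(drop=True)
    return ExtractionResult(candidates=cands, tracheostomies=trachs.reset_index(drop=True))
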