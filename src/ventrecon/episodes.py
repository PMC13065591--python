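"""Reconciliation of per-source candidate events into ventilation episodes.

Candidates claiming the same physical event are grouped by single-linkage
clustering in time (within an encounter and event type), each cluster gets
one canonical timestamp, and intubation/extubation clusters are paired in
time order into episodes — the rows of the final analytic dataset.

Canonical-time source priority: anesthesia > LDA > flowsheet > procedure >
admission.  Anesthesia events are charted to the minute; flowsheets are
interval-sampled; admission/discharge times are inference of last resort.

Unpaired intubations are closed by fallback: a tracheostomy event ends the
episode at the tracheostomy time, a death at the death time, a transfer-out
discharge at the discharge time (flagged inferred); otherwise the episode is
dropped and logged.  An extubation immediately followed by a reintubation
within ``min_episode_gap_minutes`` is treated as a charting artifact and the
two fragments are merged into one continuous episode.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from . import metrics as _metrics
from .extraction import (
    DEFAULT_GAP_TOLERANCE_HOURS,
    SOURCE_PRIORITY,
    ExtractionResult,
    empty_candidates,
    extract_all,
)
from .grading import DEFAULT_GRADING, GradingConfig, assign_grade
from .schema import EPISODE_COLUMNS, INVASIVE_MODES, NONINVASIVE_MODES, SourceTables, validate_records

logger = logging.getLogger(__name__)


@dataclass
class EventCluster:
    """Candidates from several sources judged to document one physical event."""

    encounter_id: str
    event_type: str
    members: pd.DataFrame
    canonical_datetime: pd.Timestamp
    location: str

    @property
    def sources_present(self) -> frozenset[str]:
        return frozenset(self.members["source"])

    @property
    def max_pairwise_gap_hours(self) -> float:
        t = self.members["event_datetime"]
        return float((t.max() - t.min()) / pd.Timedelta(hours=1))

    @property
    def inferred_only(self) -> bool:
        return bool(self.members["inferred"].astype(bool).all())


@dataclass(frozen=True)
class BuilderConfig:
    """Tunables of candidate matching and episode pairing."""

    #: Single-linkage threshold: candidates of the same encounter/event type
    #: closer than this are claims about the same event.  Aligned with the
    #: outer concordance bound of the grading scale.
    match_window_hours: float = 12.0
    #: Extubation→reintubation gaps shorter than this are charting artifacts.
    min_episode_gap_minutes: float = 30.0
    #: Flowsheet invasive-interval segmentation tolerance.
    gap_tolerance_hours: float = DEFAULT_GAP_TOLERANCE_HOURS
    invasive_vocab: frozenset[str] = INVASIVE_MODES
    noninvasive_vocab: frozenset[str] = NONINVASIVE_MODES
    grading: GradingConfig = DEFAULT_GRADING


DEFAULT_BUILDER = BuilderConfig()


def cluster_candidates(
    candidates: pd.DataFrame,
    match_window_hours: float = DEFAULT_BUILDER.match_window_hours,
    duplicate_split_hours: float = DEFAULT_GRADING.concordance_a_hours,
) -> list[EventCluster]:
    """Group candidates into per-event clusters by single-linkage in time.

    Within an encounter and event type, candidates sorted by time are split
    wherever the gap between neighbours exceeds ``match_window_hours``
    (single-linkage clustering on the line).  Because each source documents
    a physical event at most once, a cluster containing two candidates from
    the *same* source more than ``duplicate_split_hours`` apart must span
    two distinct events and is split at its largest internal gap (applied
    recursively).  The canonical time is the median time of the
    highest-priority source present; clusters are returned ordered by
    encounter and canonical time.
    """
    if candidates.empty:
        return []
    window = pd.Timedelta(hours=match_window_hours)
    split_tol = pd.Timedelta(hours=duplicate_split_hours)
    ordered = candidates.sort_values(
        ["encounter_id", "event_type", "event_datetime"], kind="mergesort"
    )
    clusters: list[EventCluster] = []
    for (enc, etype), grp in ordered.groupby(["encounter_id", "event_type"], sort=True):
        times = grp["event_datetime"].tolist()
        start = 0
        for j in range(1, len(times) + 1):
            if j == len(times) or times[j] - times[j - 1] > window:
                members = grp.iloc[start:j].reset_index(drop=True)
                for part in _split_same_source(members, split_tol):
                    clusters.append(_make_cluster(enc, etype, part))
                start = j
    clusters.sort(key=lambda c: (c.encounter_id, c.canonical_datetime, c.event_type))
    return clusters


def _split_same_source(members: pd.DataFrame, tol: pd.Timedelta) -> list[pd.DataFrame]:
    """Recursively split clusters with discordant same-source duplicates."""
    doc = members[~members["inferred"].astype(bool)]
    spread = doc.groupby("source")["event_datetime"].agg(lambda s: s.max() - s.min())
    if spread.empty or (spread <= tol).all():
        return [members]
    times = members["event_datetime"]
    gaps = times.diff()
    if len(members) < 2 or gaps.iloc[1:].max() <= pd.Timedelta(0):
        return [members]  # simultaneous duplicates: nothing to split on
    cut = int(gaps.iloc[1:].idxmax())
    left = members.iloc[:cut].reset_index(drop=True)
    right = members.iloc[cut:].reset_index(drop=True)
    return _split_same_source(left, tol) + _split_same_source(right, tol)


def _make_cluster(enc: str, etype: str, members: pd.DataFrame) -> EventCluster:
    for source in SOURCE_PRIORITY:
        sel = members[members["source"] == source]
        if not sel.empty:
            canonical = sel["event_datetime"].median().floor("min")
            nearest = (sel["event_datetime"] - canonical).abs().idxmin()
            location = sel.loc[nearest, "location"]
            break
    else:  # unknown source labels: fall back to the overall median
        canonical = members["event_datetime"].median().floor("min")
        location = members.iloc[0]["location"]
    return EventCluster(
        encounter_id=enc,
        event_type=etype,
        members=members,
        canonical_datetime=canonical,
        location=location,
    )


def _fallback_cluster(enc: str, when: pd.Timestamp, location: str) -> EventCluster:
    """Synthetic inferred-only extubation cluster for fallback closure."""
    members = pd.DataFrame(
        [
            {
                "encounter_id": enc,
                "event_type": "extubation",
                "event_datetime": when,
                "source": "admission",
                "location": location,
                "inferred": True,
                "airway_kind": "unknown",
            }
        ]
    )
    return EventCluster(enc, "extubation", members, when, location)


@dataclass
class _OpenEpisode:
    intubation: EventCluster


def pair_clusters(
    clusters: list[EventCluster],
    tracheostomies: pd.DataFrame,
    encounters: pd.DataFrame,
    patients: pd.DataFrame,
    config: BuilderConfig = DEFAULT_BUILDER,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pair clusters into episodes; returns (episodes, dropped-events log).

    Pairing alternates intubation→extubation in time order per encounter.
    Tracheostomy events, deaths and transfer-out discharges close otherwise
    unpaired intubations; remaining orphans are dropped and logged.
    """
    window = pd.Timedelta(hours=config.match_window_hours)
    a_band = pd.Timedelta(hours=config.grading.concordance_a_hours)
    min_gap = pd.Timedelta(minutes=config.min_episode_gap_minutes)

    enc_info = encounters.set_index("encounter_id")
    deaths = (
        encounters.merge(
            patients[["patient_id", "death_datetime"]], on="patient_id", how="left"
        )
        .set_index("encounter_id")["death_datetime"]
    )
    trach_by_enc: dict[str, list[pd.Timestamp]] = {}
    if not tracheostomies.empty:
        for enc, grp in tracheostomies.groupby("encounter_id"):
            trach_by_enc[enc] = sorted(grp["event_datetime"])

    episodes: list[dict] = []
    drops: list[dict] = []

    by_enc: dict[str, list[EventCluster]] = {}
    for c in clusters:
        by_enc.setdefault(c.encounter_id, []).append(c)

    for enc, encounter_clusters in by_enc.items():
        if enc not in enc_info.index:
            for c in encounter_clusters:
                drops.append(_drop(c, "unknown_encounter"))
            continue
        erow = enc_info.loc[enc]
        death = deaths.get(enc, pd.NaT)
        trachs = trach_by_enc.get(enc, [])
        pairs: list[tuple[EventCluster, EventCluster]] = []
        open_int: EventCluster | None = None

        def fallback_close(intub: EventCluster, before: pd.Timestamp | None) -> EventCluster | None:
            """Close an unpaired intubation via trach/death/transfer, or None."""
            t0 = intub.canonical_datetime
            cand_trachs = [t for t in trachs if t > t0 and (before is None or t < before)]
            if cand_trachs:
                return _fallback_cluster(enc, cand_trachs[0], intub.location)
            if pd.notna(death) and death > t0 and (before is None or death < before):
                return _fallback_cluster(enc, death, intub.location)
            if before is None:
                disposition = str(erow.get("discharge_disposition", "")).strip().lower()
                discharge = erow.get("discharge_datetime", pd.NaT)
                if disposition == "transfer" and pd.notna(discharge) and discharge > t0:
                    return _fallback_cluster(enc, discharge, intub.location)
            return None

        for c in encounter_clusters:
            if c.event_type == "intubation":
                if open_int is not None:
                    closer = fallback_close(open_int, before=c.canonical_datetime)
                    if closer is not None:
                        pairs.append((open_int, closer))
                    else:
                        drops.append(_drop(open_int, "unpaired_intubation"))
                    logger.warning(
                        "encounter %s: consecutive intubation clusters without extubation", enc
                    )
                open_int = c
            else:
                if open_int is None:
                    drops.append(_drop(c, "unpaired_extubation"))
                elif c.canonical_datetime <= open_int.canonical_datetime:
                    drops.append(_drop(c, "extubation_not_after_intubation"))
                else:
                    pairs.append((open_int, c))
                    open_int = None
        if open_int is not None:
            closer = fallback_close(open_int, before=None)
            if closer is not None:
                pairs.append((open_int, closer))
            else:
                drops.append(_drop(open_int, "unpaired_intubation"))

        # Merge charting artifacts: extubation→reintubation gaps < min gap.
        merged: list[tuple[EventCluster, EventCluster]] = []
        for pair in pairs:
            if (
                merged
                and pair[0].canonical_datetime - merged[-1][1].canonical_datetime < min_gap
            ):
                merged[-1] = (merged[-1][0], pair[1])
            else:
                merged.append(pair)

        for intub, extub in merged:
            t_int = intub.canonical_datetime
            t_ext = extub.canonical_datetime
            ep_trachs = [t for t in trachs if t_int < t <= t_ext + a_band]
            is_trach = any(t >= t_ext - window for t in ep_trachs)
            if is_trach:
                termination = "tracheostomy"
            elif pd.notna(death) and abs(death - t_ext) <= window:
                termination = "death"
            else:
                termination = "extubation"
            episodes.append(
                {
                    "patient_id": erow["patient_id"],
                    "encounter_id": enc,
                    "intubation_datetime": t_int,
                    "extubation_datetime": t_ext,
                    "intubation_location": intub.location,
                    "extubation_location": extub.location,
                    "termination": termination,
                    "new_tracheostomy_during_episode": bool(ep_trachs),
                    "intubation_inferred": intub.inferred_only,
                    "extubation_inferred": extub.inferred_only,
                    "intubation_sources": "|".join(sorted(intub.sources_present)),
                    "extubation_sources": "|".join(sorted(extub.sources_present)),
                    "intubation_grade": assign_grade(intub, config.grading).label,
                    "extubation_grade": assign_grade(extub, config.grading).label,
                }
            )

    episode_df = pd.DataFrame(episodes)
    if episode_df.empty:
        episode_df = pd.DataFrame(
            columns=[c for c in EPISODE_COLUMNS if c not in ("episode_index",)]
        )
    episode_df = episode_df.sort_values(
        ["patient_id", "intubation_datetime"], kind="mergesort"
    ).reset_index(drop=True)
    episode_df["episode_index"] = episode_df.groupby("patient_id").cumcount() + 1
    drop_df = pd.DataFrame(drops, columns=["encounter_id", "event_type", "canonical_datetime", "reason"])
    return episode_df, drop_df


def _drop(cluster: EventCluster, reason: str) -> dict:
    logger.info(
        "dropped %s cluster at %s (%s): %s",
        cluster.event_type,
        cluster.canonical_datetime,
        cluster.encounter_id,
        reason,
    )
    return {
        "encounter_id": cluster.encounter_id,
        "event_type": cluster.event_type,
        "canonical_datetime": cluster.canonical_datetime,
        "reason": reason,
    }


@dataclass
class BuildResult:
    """End-to-end pipeline output: episodes plus intermediate artifacts."""

    episodes: pd.DataFrame
    reject_report: "pd.DataFrame"
    candidates: pd.DataFrame = field(default_factory=empty_candidates)
    tracheostomies: pd.DataFrame = field(default_factory=pd.DataFrame)
    dropped_clusters: pd.DataFrame = field(default_factory=pd.DataFrame)


def build_episodes(tables: SourceTables, config: BuilderConfig = DEFAULT_BUILDER) -> BuildResult:
    """Full pipeline: validate → extract → cluster → pair → grade → metrics.

    Deterministic given input tables and config.  Returns the annotated
    analytic episode dataset along with the validation reject report,
    the candidate stream and the dropped-cluster log.
    """
    clean, report = validate_records(tables)
    extraction: ExtractionResult = extract_all(
        clean,
        invasive_vocab=config.invasive_vocab,
        noninvasive_vocab=config.noninvasive_vocab,
        gap_tolerance_hours=config.gap_tolerance_hours,
    )
    clusters = cluster_candidates(extraction.candidates, config.match_window_hours)
    episodes, dropped = pair_clusters(
        clusters, extraction.tracheostomies, clean.encounters, clean.patients, config
    )
    episodes = _metrics.compute_episode_metrics(episodes, clean.patients, clean.encounters)
    return BuildResult(
        episodes=episodes,
        reject_report=report.rows,
        candidates=extraction.candidates,
        tracheostomies=extraction.tracheostomies,
        dropped_clusters=dropped,
    )
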