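"""Synthetic EHR cohort generator.

Generates latent ground-truth ventilation episodes and renders them into the
five documentation source tables with configurable per-source documentation
probability and timestamp jitter.  The generator exists so every downstream
stage — extraction, episode reconciliation, grading, outcome metrics — can
be exercised and tested end-to-end without any real patient data.

Simulated phenomena, each behind a config switch: per-source missingness,
Gaussian timestamp jitter (truncated at ±24 h, minute-rounded), noninvasive
ventilation (CPAP/NIPPV) rows interleaved around the invasive interval,
transfers arriving with an endotracheal tube in place (no placement
documentation, admission flag only), in-hospital deaths (extubation
documentation dropped from a configurable subset of sources), tracheostomy
during the episode, and reintubation chained within the 48-h and 2-7-day
windows.  Default parameters emulate the documented cohort shape of a large
academic center: ~12% pediatric, 1.8% 48-h reintubation, 3.2% 7-day
reintubation, ~3% in-hospital death, rare tracheostomy, and a
perioperative-dominant location mix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .schema import INVASIVE_MODES, LOCATIONS, SourceTables, _empty_table

_EPOCH = pd.Timestamp("2024-01-01 00:00")
_MINUTE = pd.Timedelta(minutes=1)

GROUND_TRUTH_COLUMNS = [
    "patient_id",
    "encounter_id",
    "episode_index",
    "true_intubation",
    "true_extubation",
    "intubation_location",
    "extubation_location",
    "termination",
    "arrived_intubated",
]

_SOURCES = ("flowsheet", "lda", "anesthesia", "procedure")


class ScenarioConfig(BaseModel):
    """Full parameterisation of one synthetic cohort; the seed fixes the output."""

    model_config = ConfigDict(extra="forbid")

    n_patients: int = Field(default=500, ge=0)
    seed: int = 0

    # Cohort structure
    pediatric_fraction: float = Field(default=0.118, ge=0, le=1)
    reintubation_prob_48h: float = Field(default=0.018, ge=0, le=1)
    reintubation_prob_2to7d: float = Field(default=0.014, ge=0, le=1)
    p_arrive_intubated: float = Field(default=0.01, ge=0, le=1)
    p_death: float = Field(default=0.032, ge=0, le=1)
    p_tracheostomy: float = Field(default=0.0012, ge=0, le=1)
    p_noninvasive_interleave: float = Field(default=0.15, ge=0, le=1)
    mean_duration_hours_adult: float = Field(default=15.8, gt=0)
    mean_duration_hours_pediatric: float = Field(default=44.7, gt=0)
    duration_lognorm_sigma: float = Field(default=0.9, gt=0)
    location_mix: dict[str, float] = Field(
        default={
            "perioperative": 0.85,
            "ED": 0.03,
            "NICU": 0.02,
            "PICU": 0.01,
            "cardiac_ICU": 0.01,
            "adult_ICU": 0.05,
            "ward": 0.01,
            "other": 0.02,
        }
    )

    # Documentation process
    source_documentation_probs: dict[str, float] = Field(
        default={"flowsheet": 0.95, "lda": 0.95, "anesthesia": 0.75, "procedure": 0.40}
    )
    jitter_sd_minutes: dict[str, float] = Field(
        default={"flowsheet": 30.0, "lda": 10.0, "anesthesia": 2.0, "procedure": 60.0}
    )
    charting_interval_minutes: int = Field(default=60, ge=1)
    death_undocumented_sources: list[str] = Field(default=["lda", "anesthesia"])

    @model_validator(mode="after")
    def _check(self) -> "ScenarioConfig":
        if self.reintubation_prob_48h + self.reintubation_prob_2to7d > 1:
            raise ValueError("reintubation probabilities must sum to <= 1")
        if self.p_death + self.p_tracheostomy > 1:
            raise ValueError("p_death + p_tracheostomy must be <= 1")
        for name, d in (
            ("source_documentation_probs", self.source_documentation_probs),
            ("jitter_sd_minutes", self.jitter_sd_minutes),
        ):
            unknown = set(d) - set(_SOURCES)
            if unknown:
                raise ValueError(f"{name}: unknown sources {sorted(unknown)}")
            if any(v < 0 for v in d.values()):
                raise ValueError(f"{name}: values must be >= 0")
        if any(v > 1 for v in self.source_documentation_probs.values()):
            raise ValueError("documentation probabilities must be <= 1")
        if any(p < 0 for p in self.location_mix.values()) or sum(self.location_mix.values()) <= 0:
            raise ValueError("location_mix must be a nonnegative, non-degenerate weighting")
        unknown = set(self.location_mix) - set(LOCATIONS)
        if unknown:
            raise ValueError(f"location_mix: unknown locations {sorted(unknown)}")
        unknown = set(self.death_undocumented_sources) - set(_SOURCES)
        if unknown:
            raise ValueError(f"death_undocumented_sources: unknown sources {sorted(unknown)}")
        return self

    @classmethod
    def noise_free(cls, n_patients: int = 500, seed: int = 0, **overrides) -> "ScenarioConfig":
        """Fully documented, zero-jitter cohort with no special scenarios.

        Every event is documented by every applicable source at the true
        minute; the downstream pipeline should recover every episode with
        exact endpoints and uniformly best quality grades.
        """
        params = dict(
            n_patients=n_patients,
            seed=seed,
            reintubation_prob_48h=0.0,
            reintubation_prob_2to7d=0.0,
            p_arrive_intubated=0.0,
            p_death=0.0,
            p_tracheostomy=0.0,
            p_noninvasive_interleave=0.0,
            source_documentation_probs={s: 1.0 for s in _SOURCES},
            jitter_sd_minutes={s: 0.0 for s in _SOURCES},
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class _Episode:
    """Internal ground-truth episode during generation."""

    patient_id: str
    encounter_id: str
    episode_index: int
    intubation: pd.Timestamp
    extubation: pd.Timestamp
    intubation_location: str
    extubation_location: str
    termination: str
    arrived_intubated: bool


def _jitter(rng: np.random.Generator, t: pd.Timestamp, sd_minutes: float) -> pd.Timestamp:
    if sd_minutes <= 0:
        return t
    offset = float(np.clip(rng.normal(0.0, sd_minutes), -1440.0, 1440.0))
    return (t + pd.Timedelta(minutes=offset)).floor("min")


def _clamp(t: pd.Timestamp, lo: pd.Timestamp, hi: pd.Timestamp) -> pd.Timestamp:
    return min(max(t, lo), hi)


def generate_cohort(config: ScenarioConfig) -> tuple[pd.DataFrame, SourceTables]:
    """Generate ground-truth episodes and render them into the source tables.

    Returns the ground-truth episode table (one row per latent episode) and
    the populated :class:`SourceTables`.  Output is a pure function of the
    config, including its seed.
    """
    rng = np.random.default_rng(config.seed)
    loc_names = sorted(config.location_mix)
    loc_w = np.array([config.location_mix[k] for k in loc_names], dtype=float)
    loc_w = loc_w / loc_w.sum()
    p_doc = {s: config.source_documentation_probs.get(s, 1.0) for s in _SOURCES}
    sd = {s: config.jitter_sd_minutes.get(s, 0.0) for s in _SOURCES}
    interval = pd.Timedelta(minutes=config.charting_interval_minutes)
    invasive_modes = sorted(INVASIVE_MODES)

    patients, encounters = [], []
    flowsheets, lda, anesthesia, procedures = [], [], [], []
    truth: list[_Episode] = []

    def draw_duration(pediatric: bool) -> pd.Timedelta:
        mean = (
            config.mean_duration_hours_pediatric
            if pediatric
            else config.mean_duration_hours_adult
        )
        sigma = config.duration_lognorm_sigma
        mu = np.log(mean) - sigma**2 / 2.0
        hours = float(rng.lognormal(mu, sigma))
        return pd.Timedelta(minutes=max(120, round(hours * 60)))

    for i in range(config.n_patients):
        pid = f"P{i:06d}"
        eid = f"E{i:06d}"
        admit = (_EPOCH + pd.Timedelta(minutes=int(rng.integers(0, 365 * 1440)))).floor("min")
        pediatric = rng.random() < config.pediatric_fraction
        age_years = float(rng.uniform(0.0, 18.0)) if pediatric else float(rng.uniform(19.0, 90.0))
        birth = (admit - pd.Timedelta(days=age_years * 365.2425)).floor("min")
        arrived = rng.random() < config.p_arrive_intubated

        # Latent episode chain for this encounter.
        episodes: list[_Episode] = []
        intub = admit if arrived else admit + pd.Timedelta(minutes=int(rng.integers(60, 2880)))
        u = rng.random()
        if u < config.p_death:
            termination = "death"
        elif u < config.p_death + config.p_tracheostomy:
            termination = "tracheostomy"
        else:
            termination = "extubation"
        extub = intub + draw_duration(pediatric)
        loc_i = str(rng.choice(loc_names, p=loc_w))
        loc_e = loc_i if rng.random() < 0.8 else str(rng.choice(loc_names, p=loc_w))
        episodes.append(_Episode(pid, eid, 1, intub, extub, loc_i, loc_e, termination, arrived))

        if termination == "extubation":
            v = rng.random()
            gap = None
            if v < config.reintubation_prob_48h:
                gap = pd.Timedelta(minutes=int(rng.integers(60, 46 * 60)))
            elif v < config.reintubation_prob_48h + config.reintubation_prob_2to7d:
                gap = pd.Timedelta(minutes=int(rng.integers(49 * 60, 167 * 60)))
            if gap is not None:
                intub2 = extub + gap
                extub2 = intub2 + draw_duration(pediatric)
                loc2 = str(rng.choice(loc_names, p=loc_w))
                episodes.append(
                    _Episode(pid, eid, 2, intub2, extub2, loc2, loc2, "extubation", False)
                )

        last = episodes[-1]
        if last.termination == "death":
            death = last.extubation
            discharge = death
            disposition = "death"
        else:
            death = None
            discharge = last.extubation + pd.Timedelta(minutes=int(rng.integers(60, 4320)))
            disposition = "home"

        patients.append(
            {"patient_id": pid, "birth_datetime": birth, "death_datetime": death}
        )
        encounters.append(
            {
                "encounter_id": eid,
                "patient_id": pid,
                "admit_datetime": admit,
                "discharge_datetime": discharge,
                "admit_location": loc_i if arrived else "ED",
                "admitted_with_airway": arrived,
                "discharge_disposition": disposition,
            }
        )

        window_lo = admit - pd.Timedelta(hours=23)
        window_hi = discharge + pd.Timedelta(hours=23)

        def doc_time(t: pd.Timestamp, source: str) -> pd.Timestamp:
            return _clamp(_jitter(rng, t, sd[source]), window_lo, window_hi)

        for ep in episodes:
            drop_extubation_doc = (
                ep.termination == "death" and len(config.death_undocumented_sources) > 0
            )
            dropped = set(config.death_undocumented_sources) if drop_extubation_doc else set()

            # Flowsheet: invasive-mode rows from start to end at the charting
            # interval; documents the whole interval, including deaths.
            if rng.random() < p_doc["flowsheet"]:
                start = doc_time(ep.intubation, "flowsheet")
                end = doc_time(ep.extubation, "flowsheet")
                if "flowsheet" in dropped:
                    end = start
                if end < start:
                    end = start
                mode = str(rng.choice(invasive_modes))
                times = list(pd.date_range(start, end, freq=interval))
                if not times or times[-1] != end:
                    times.append(end)
                for k, t in enumerate(times):
                    flowsheets.append(
                        {
                            "encounter_id": eid,
                            "recorded_datetime": t,
                            "vent_mode": mode,
                            "location": ep.extubation_location
                            if k == len(times) - 1
                            else ep.intubation_location,
                        }
                    )
                if rng.random() < config.p_noninvasive_interleave:
                    niv_mode = str(rng.choice(["CPAP", "NIPPV"]))
                    for k in range(3, 0, -1):
                        t = start - k * interval
                        if t >= window_lo:
                            flowsheets.append(
                                {
                                    "encounter_id": eid,
                                    "recorded_datetime": t,
                                    "vent_mode": niv_mode,
                                    "location": ep.intubation_location,
                                }
                            )
                    for k in range(1, 4):
                        t = end + k * interval
                        if t <= window_hi:
                            flowsheets.append(
                                {
                                    "encounter_id": eid,
                                    "recorded_datetime": t,
                                    "vent_mode": niv_mode,
                                    "location": ep.extubation_location,
                                }
                            )

            # LDA: one endotracheal-tube record per episode.
            if rng.random() < p_doc["lda"]:
                placement = None if ep.arrived_intubated else doc_time(ep.intubation, "lda")
                removal = None if "lda" in dropped else doc_time(ep.extubation, "lda")
                if placement is not None and removal is not None and removal < placement:
                    removal = placement
                if placement is not None or removal is not None:
                    lda.append(
                        {
                            "encounter_id": eid,
                            "lda_type": "endotracheal tube",
                            "placement_datetime": placement,
                            "removal_datetime": removal,
                            "location": ep.intubation_location,
                        }
                    )

            # Anesthesia: minute-precise typed events.
            if not ep.arrived_intubated and rng.random() < p_doc["anesthesia"]:
                anesthesia.append(
                    {
                        "encounter_id": eid,
                        "event_type": "intubation",
                        "event_datetime": doc_time(ep.intubation, "anesthesia"),
                        "location": ep.intubation_location,
                    }
                )
            if "anesthesia" not in dropped and ep.termination == "extubation":
                if rng.random() < p_doc["anesthesia"]:
                    anesthesia.append(
                        {
                            "encounter_id": eid,
                            "event_type": "extubation",
                            "event_datetime": doc_time(ep.extubation, "anesthesia"),
                            "location": ep.extubation_location,
                        }
                    )

            # Procedures: intubation procedures probabilistically; tracheostomy
            # procedures always (procedure records are the authoritative trach
            # documentation in this simulation).
            if not ep.arrived_intubated and rng.random() < p_doc["procedure"]:
                procedures.append(
                    {
                        "encounter_id": eid,
                        "procedure_type": "intubation",
                        "procedure_datetime": doc_time(ep.intubation, "procedure"),
                        "location": ep.intubation_location,
                    }
                )
            if ep.termination == "tracheostomy":
                procedures.append(
                    {
                        "encounter_id": eid,
                        "procedure_type": "tracheostomy",
                        "procedure_datetime": doc_time(ep.extubation, "procedure"),
                        "location": ep.extubation_location,
                    }
                )
                if rng.random() < p_doc["lda"]:
                    lda.append(
                        {
                            "encounter_id": eid,
                            "lda_type": "tracheostomy tube",
                            "placement_datetime": doc_time(ep.extubation, "lda"),
                            "removal_datetime": None,
                            "location": ep.extubation_location,
                        }
                    )

        truth.extend(episodes)

    def frame(rows: list[dict], table: str) -> pd.DataFrame:
        if not rows:
            return _empty_table(table)
        df = pd.DataFrame(rows)
        for c in df.columns:
            if c.endswith("_datetime"):
                df[c] = pd.to_datetime(df[c]).dt.floor("min")
        return df

    tables = SourceTables(
        patients=frame(patients, "patients"),
        encounters=frame(encounters, "encounters"),
        flowsheets=frame(flowsheets, "flowsheets"),
        lda=frame(lda, "lda"),
        anesthesia=frame(anesthesia, "anesthesia"),
        procedures=frame(procedures, "procedures"),
    )

    gt = pd.DataFrame(
        [
            {
                "patient_id": e.patient_id,
                "encounter_id": e.encounter_id,
                "episode_index": e.episode_index,
                "true_intubation": e.intubation,
                "true_extubation": e.extubation,
                "intubation_location": e.intubation_location,
                "extubation_location": e.extubation_location,
                "termination": e.termination,
                "arrived_intubated": e.arrived_intubated,
            }
            for e in truth
        ],
        columns=GROUND_TRUTH_COLUMNS,
    )
    return gt, tables


def inject_invalid_records(
    tables: SourceTables, k: int, seed: int, target: str = "any"
) -> tuple[SourceTables, pd.DataFrame]:
    """Corrupt exactly ``k`` records so downstream validation rejects them.

    Corruption is a NULL required timestamp or a dangling encounter
    reference, chosen at random.  ``target="redundant"`` restricts
    corruption to interior flowsheet rows (never the first or last row of an
    encounter, never two adjacent rows), so the reconstructed episode set is
    provably unaffected by the rejected rows' absence.

    Returns the corrupted tables and a log of the corrupted positions
    (columns: table, row_ref, corruption).
    """
    if k < 0:
        raise ValueError("k must be >= 0")
    rng = np.random.default_rng(seed)
    out = tables.copy()
    if k == 0:
        return out, pd.DataFrame(columns=["table", "row_ref", "corruption"])

    if target == "redundant":
        # Interior rows of maximal invasive flowsheet runs (segmented at the
        # default 8-h gap tolerance) are redundant: their absence cannot move
        # a run endpoint, and with one corrupted row per non-adjacent pair the
        # residual inter-row gap stays within tolerance.
        fs = out.flowsheets
        invasive = fs[fs["vent_mode"].isin(INVASIVE_MODES)]
        order = invasive.sort_values(
            ["encounter_id", "recorded_datetime"], kind="mergesort"
        )
        gap_tol = pd.Timedelta(hours=8)
        flat: list[tuple[str, int, int]] = []  # (run key, position in run, df index)
        for enc, grp in order.groupby("encounter_id", sort=True):
            times = grp["recorded_datetime"].tolist()
            idx = grp.index.tolist()
            run_start = 0
            for j in range(1, len(idx) + 1):
                if j == len(idx) or times[j] - times[j - 1] > gap_tol:
                    run = idx[run_start:j]
                    for pos in range(1, len(run) - 1):
                        flat.append((f"{enc}:{run_start}", pos, run[pos]))
                    run_start = j
        if not flat:
            raise ValueError("no redundant flowsheet rows available to corrupt")
        perm = rng.permutation(len(flat))
        picked: list[tuple[str, int]] = []
        taken: dict[str, set[int]] = {}
        for j in perm:
            run_key, pos, df_idx = flat[j]
            s = taken.setdefault(run_key, set())
            if pos - 1 in s or pos + 1 in s or pos in s:
                continue
            s.add(pos)
            picked.append(("flowsheets", df_idx))
            if len(picked) == k:
                break
        if len(picked) < k:
            raise ValueError(f"only {len(picked)} non-adjacent interior flowsheet rows available")
    elif target == "any":
        pool = [
            (name, int(i))
            for name in ("flowsheets", "lda", "anesthesia", "procedures")
            for i in out.tables()[name].index
        ]
        if k > len(pool):
            raise ValueError(f"k={k} exceeds total corruptible rows ({len(pool)})")
        sel = rng.choice(len(pool), size=k, replace=False)
        picked = [pool[int(j)] for j in sorted(sel)]
    else:
        raise ValueError(f"unknown target mode: {target!r}")

    null_cols = {
        "flowsheets": ["recorded_datetime"],
        "lda": ["placement_datetime", "removal_datetime"],
        "anesthesia": ["event_datetime"],
        "procedures": ["procedure_datetime"],
    }
    log = []
    for name, idx in picked:
        df = out.tables()[name]
        if target == "redundant" or rng.random() < 0.5:
            for c in null_cols[name]:
                df.loc[idx, c] = pd.NaT
            corruption = "null_timestamp"
        else:
            df.loc[idx, "encounter_id"] = "E_DANGLING"
            corruption = "dangling_ref"
        log.append({"table": name, "row_ref": idx, "corruption": corruption})
    return out, pd.DataFrame(log, columns=["table", "row_ref", "corruption"])
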