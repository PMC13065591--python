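"""Episode- and cohort-level ventilation outcome metrics.

Annotates each reconciled episode with its duration, the patient's age at
intubation (pediatric means age <= 18 years), reintubation window flags and
death-during-encounter, then aggregates cohort summaries: extubation
failure (reintubation within 48 h of extubation), 7-day reintubation,
per-location durations and rates, tracheostomy and death counts.

Window conventions: "within 48 h" is a gap in (0, 48 h]; "2-7 days" is
(48 h, 168 h]; the two partition "within seven days".  Reintubation is
tracked per patient across encounters, so a readmission and reintubation
within the window still counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

HOURS_48 = pd.Timedelta(hours=48)
HOURS_168 = pd.Timedelta(hours=168)
DAYS_PER_YEAR = 365.2425
PEDIATRIC_MAX_AGE_YEARS = 18.0


def compute_episode_metrics(
    episodes: pd.DataFrame,
    patients: pd.DataFrame,
    encounters: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Annotate episodes with duration, age strata and reintubation flags.

    The next intubation of the *same patient* (any encounter) defines the
    reintubation gap from each episode's extubation.  Episodes of patients
    with no birth date get null age and pediatric flags (logged).
    """
    out = episodes.copy()
    if out.empty:
        for c in (
            "duration_hours",
            "age_years_at_intubation",
            "pediatric",
            "died_during_encounter",
            "reintubated_within_48h",
            "reintubated_2to7d",
            "reintubated_within_7d",
        ):
            out[c] = pd.Series(dtype=float if c.startswith(("duration", "age")) else object)
        return out

    out = out.sort_values(["patient_id", "intubation_datetime"], kind="mergesort").reset_index(
        drop=True
    )
    out["duration_hours"] = (
        out["extubation_datetime"] - out["intubation_datetime"]
    ) / pd.Timedelta(hours=1)

    pat = patients.set_index("patient_id")
    birth = out["patient_id"].map(pat["birth_datetime"])
    missing_birth = birth.isna()
    if missing_birth.any():
        logger.info("%d episodes lack a patient birth date", int(missing_birth.sum()))
    age_days = (out["intubation_datetime"] - birth).dt.total_seconds() / 86400.0
    out["age_years_at_intubation"] = age_days / DAYS_PER_YEAR
    out["pediatric"] = (out["age_years_at_intubation"] <= PEDIATRIC_MAX_AGE_YEARS).astype(
        "boolean"
    )
    out.loc[missing_birth, "pediatric"] = pd.NA

    death = out["patient_id"].map(pat["death_datetime"])
    if encounters is not None and not encounters.empty:
        enc = encounters.set_index("encounter_id")
        admit = out["encounter_id"].map(enc["admit_datetime"])
        discharge = out["encounter_id"].map(enc["discharge_datetime"])
        out["died_during_encounter"] = (
            death.notna() & (death >= admit) & (discharge.isna() | (death <= discharge))
        )
    else:
        out["died_during_encounter"] = death.notna()

    next_int = out.groupby("patient_id")["intubation_datetime"].shift(-1)
    gap = next_int - out["extubation_datetime"]
    has_next = gap.notna() & (gap > pd.Timedelta(0))
    out["reintubated_within_48h"] = has_next & (gap <= HOURS_48)
    out["reintubated_within_7d"] = has_next & (gap <= HOURS_168)
    out["reintubated_2to7d"] = out["reintubated_within_7d"] & ~out["reintubated_within_48h"]
    return out


def extubation_failure_rate(episodes: pd.DataFrame, denominator_policy: str = "episodes") -> float:
    """Rate of reintubation within 48 h of extubation.

    Policies:

    * ``"episodes"`` (default) — numerator: episodes reintubated within
      48 h; denominator: episodes terminated by a true extubation (death-
      and tracheostomy-terminated episodes cannot fail extubation).
    * ``"all_episodes"`` — denominator includes every episode.
    * ``"patients"`` — fraction of patients with at least one
      extubation-terminated episode who failed at least once.
    """
    if episodes.empty:
        logger.warning("extubation_failure_rate: empty episode set")
        return float("nan")
    if denominator_policy == "episodes":
        denom = episodes[episodes["termination"] == "extubation"]
        if denom.empty:
            logger.warning("extubation_failure_rate: empty denominator")
            return float("nan")
        return float(denom["reintubated_within_48h"].mean())
    if denominator_policy == "all_episodes":
        return float(episodes["reintubated_within_48h"].mean())
    if denominator_policy == "patients":
        eligible = episodes[episodes["termination"] == "extubation"]
        if eligible.empty:
            logger.warning("extubation_failure_rate: empty denominator")
            return float("nan")
        per_patient = eligible.groupby("patient_id")["reintubated_within_48h"].any()
        return float(per_patient.mean())
    raise ValueError(f"unknown denominator_policy: {denominator_policy!r}")


def reintubation_rate_7d(episodes: pd.DataFrame, denominator_policy: str = "episodes") -> float:
    """Rate of reintubation within seven days of extubation (same policies)."""
    if episodes.empty:
        return float("nan")
    if denominator_policy == "episodes":
        denom = episodes[episodes["termination"] == "extubation"]
        return float(denom["reintubated_within_7d"].mean()) if len(denom) else float("nan")
    if denominator_policy == "all_episodes":
        return float(episodes["reintubated_within_7d"].mean())
    if denominator_policy == "patients":
        eligible = episodes[episodes["termination"] == "extubation"]
        if eligible.empty:
            return float("nan")
        return float(eligible.groupby("patient_id")["reintubated_within_7d"].any().mean())
    raise ValueError(f"unknown denominator_policy: {denominator_policy!r}")


@dataclass
class CohortSummary:
    """Cohort-level metric table plus per-location breakdown."""

    n_episodes: int
    n_patients: int
    pediatric_fraction: float
    mean_duration_hours: float
    mean_duration_hours_pediatric: float
    mean_duration_hours_adult: float
    extubation_failure_rate_48h: float
    reintubation_rate_7d: float
    n_new_tracheostomies: int
    n_deaths: int
    per_location: pd.DataFrame = field(default_factory=pd.DataFrame)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            (k, getattr(self, k))
            for k in (
                "n_episodes",
                "n_patients",
                "pediatric_fraction",
                "mean_duration_hours",
                "mean_duration_hours_pediatric",
                "mean_duration_hours_adult",
                "extubation_failure_rate_48h",
                "reintubation_rate_7d",
                "n_new_tracheostomies",
                "n_deaths",
            )
        ]
        return pd.DataFrame(rows, columns=["metric", "value"])


def summarize_cohort(episodes: pd.DataFrame, denominator_policy: str = "episodes") -> CohortSummary:
    """Aggregate annotated episodes into a :class:`CohortSummary`.

    Permutation-invariant in episode order; stratum means are plain
    arithmetic means so the pooled mean equals the stratum-weighted mean.
    """
    if episodes.empty:
        return CohortSummary(0, 0, float("nan"), *[float("nan")] * 5, 0, 0)
    # Canonical row order makes the floating-point aggregates exactly
    # permutation-invariant.
    episodes = episodes.sort_values(
        ["patient_id", "intubation_datetime", "encounter_id"], kind="mergesort"
    ).reset_index(drop=True)
    ped = episodes["pediatric"].astype("boolean")
    per_location = (
        episodes.groupby("intubation_location")
        .agg(
            n_episodes=("duration_hours", "size"),
            mean_duration_hours=("duration_hours", "mean"),
            reintubation_rate_7d=("reintubated_within_7d", "mean"),
        )
        .sort_index()
    )
    return CohortSummary(
        n_episodes=int(len(episodes)),
        n_patients=int(episodes["patient_id"].nunique()),
        pediatric_fraction=float(ped.mean()) if ped.notna().any() else float("nan"),
        mean_duration_hours=float(episodes["duration_hours"].mean()),
        mean_duration_hours_pediatric=float(
            episodes.loc[ped.fillna(False), "duration_hours"].mean()
        ),
        mean_duration_hours_adult=float(
            episodes.loc[(~ped).fillna(False), "duration_hours"].mean()
        ),
        extubation_failure_rate_48h=extubation_failure_rate(episodes, denominator_policy),
        reintubation_rate_7d=reintubation_rate_7d(episodes, denominator_policy),
        n_new_tracheostomies=int(episodes["new_tracheostomy_during_episode"].sum()),
        n_deaths=int(
            episodes.groupby("patient_id")["died_during_encounter"].any().sum()
        ),
        per_location=per_location,
    )
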