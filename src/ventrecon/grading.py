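"""Data-quality grading of reconciled airway events.

Because no gold standard exists for intubation/extubation times in the EHR,
each reconciled event endpoint is graded on a two-part ordinal scale:

* **Score 1-3** — how many documentation sources corroborate the event.
  A source "matches" when its time lies within the concordance-A band
  (default 1 h) of the canonical event time.  Three or more matching
  sources → 1 (best), exactly two → 2, one or none → 3.
* **Concordance A-C** — the temporal spread across all documenting
  sources: every pair within 1 h → A; spread of more than 12 h → C;
  in between → B.  A single documenting source has zero spread → A.

The two parts combine into labels ``1A`` (best) … ``3C`` (worst).
Inferred admission/discharge candidates are products of fallback inference,
not documentation: they are excluded from both parts, and an endpoint that
rests solely on inference is graded 3C.

The exact numeric thresholds (three sources for score 1; the closed 1-h
A band; the open 12-h C boundary, so a spread of exactly 12 h is B) are
package conventions, configurable via :class:`GradingConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import total_ordering
from typing import TYPE_CHECKING

import numpy as np
import pandas as pd

if TYPE_CHECKING:  # pragma: no cover
    from .episodes import EventCluster

GRADE_LABELS = ["1A", "1B", "1C", "2A", "2B", "2C", "3A", "3B", "3C"]


@total_ordering
@dataclass(frozen=True)
class QualityGrade:
    """(score, concordance) pair; orders 1A (best) → 3C (worst)."""

    score: int
    concordance: str

    def __post_init__(self) -> None:
        if self.score not in (1, 2, 3):
            raise ValueError(f"score must be 1, 2 or 3, got {self.score}")
        if self.concordance not in ("A", "B", "C"):
            raise ValueError(f"concordance must be A, B or C, got {self.concordance}")

    @property
    def label(self) -> str:
        return f"{self.score}{self.concordance}"

    def __lt__(self, other: "QualityGrade") -> bool:
        return (self.score, self.concordance) < (other.score, other.concordance)

    @classmethod
    def from_label(cls, label: str) -> "QualityGrade":
        return cls(int(label[0]), label[1])


@dataclass(frozen=True)
class GradingConfig:
    """Thresholds of the grading scale.

    concordance_a_hours
        Closed upper bound of the A band (and of the "matching source"
        tolerance used by the score), in hours.
    concordance_c_hours
        Open lower bound of the C band, in hours: a pairwise spread
        strictly greater than this is C.
    score_one_min_sources / score_two_min_sources
        Minimum number of matching sources for score 1 / score 2.
    """

    concordance_a_hours: float = 1.0
    concordance_c_hours: float = 12.0
    score_one_min_sources: int = 3
    score_two_min_sources: int = 2

    def __post_init__(self) -> None:
        if not 0 < self.concordance_a_hours <= self.concordance_c_hours:
            raise ValueError("require 0 < concordance_a_hours <= concordance_c_hours")
        if not self.score_one_min_sources >= self.score_two_min_sources >= 1:
            raise ValueError("score thresholds must satisfy one >= two >= 1")


DEFAULT_GRADING = GradingConfig()


def _documented(cluster: "EventCluster") -> pd.DataFrame:
    m = cluster.members
    return m[~m["inferred"].astype(bool)]


def score_sources(cluster: "EventCluster", config: GradingConfig = DEFAULT_GRADING) -> int:
    """Count distinct non-inferred sources matching the canonical time.

    A source matches when at least one of its candidate times lies within
    ``concordance_a_hours`` of the cluster's canonical time.  Sources whose
    times are discordant still inform the concordance letter but do not
    corroborate the event.
    """
    doc = _documented(cluster)
    if doc.empty:
        return 3
    tol = pd.Timedelta(hours=config.concordance_a_hours)
    gap = (doc["event_datetime"] - cluster.canonical_datetime).abs()
    n = doc.loc[gap <= tol, "source"].nunique()
    if n >= config.score_one_min_sources:
        return 1
    if n >= config.score_two_min_sources:
        return 2
    return 3


def grade_concordance(cluster: "EventCluster", config: GradingConfig = DEFAULT_GRADING) -> str:
    """Grade the temporal spread of the non-inferred member times.

    The maximum pairwise gap g maps to: g <= A-band → "A";
    g <= C-bound → "B"; otherwise "C".  A singleton has g = 0 → "A";
    a cluster with no documented members at all grades "C".
    """
    doc = _documented(cluster)
    if doc.empty:
        return "C"
    times = doc["event_datetime"]
    g = times.max() - times.min()
    if g <= pd.Timedelta(hours=config.concordance_a_hours):
        return "A"
    if g <= pd.Timedelta(hours=config.concordance_c_hours):
        return "B"
    return "C"


def assign_grade(cluster: "EventCluster", config: GradingConfig = DEFAULT_GRADING) -> QualityGrade:
    """Combine score and concordance into the event's quality grade.

    An endpoint documented by no source (inference only) is graded 3C.
    """
    doc = _documented(cluster)
    if doc.empty:
        return QualityGrade(3, "C")
    return QualityGrade(score_sources(cluster, config), grade_concordance(cluster, config))


# ---------------------------------------------------------------------------
# Grade distributions (heat-map matrices)
# ---------------------------------------------------------------------------


def grade_distribution(
    episodes: pd.DataFrame,
    event_type: str,
    exclude_locations: set[str] | frozenset[str] = frozenset(),
) -> pd.DataFrame:
    """Location × grade matrix of event counts for one endpoint type.

    ``event_type`` selects the intubation or extubation endpoint of each
    episode.  Locations in ``exclude_locations`` (typically the dominant
    perioperative areas, which would otherwise swamp the distribution) are
    dropped.  Returns a DataFrame indexed by location with one column per
    grade label 1A..3C plus per-row fractions in columns ``frac_<label>``.
    """
    if event_type not in ("intubation", "extubation"):
        raise ValueError("event_type must be 'intubation' or 'extubation'")
    if episodes.empty:
        import logging

        logging.getLogger(__name__).warning("grade_distribution: empty episode set")
        return pd.DataFrame(columns=GRADE_LABELS + [f"frac_{g}" for g in GRADE_LABELS])
    loc_col = f"{event_type}_location"
    grade_col = f"{event_type}_grade"
    df = episodes[~episodes[loc_col].isin(set(exclude_locations))]
    counts = (
        df.groupby([loc_col, grade_col], sort=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=GRADE_LABELS, fill_value=0)
    )
    counts.index.name = "location"
    counts.columns.name = None
    totals = counts.sum(axis=1)
    fracs = counts.div(totals.replace(0, np.nan), axis=0)
    for g in GRADE_LABELS:
        counts[f"frac_{g}"] = fracs[g].fillna(0.0)
    return counts


def plot_grade_heatmap(distribution: pd.DataFrame, event_type: str, path=None):
    """Render a row-normalized location × grade heat map (fractions)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frac = distribution[[f"frac_{g}" for g in GRADE_LABELS]]
    fig, ax = plt.subplots(figsize=(8, max(2, 0.5 * len(frac) + 1.5)))
    im = ax.imshow(frac.to_numpy(), cmap="viridis", vmin=0, vmax=1, aspect="auto")
    ax.set_xticks(range(len(GRADE_LABELS)), GRADE_LABELS)
    ax.set_yticks(range(len(frac)), frac.index)
    ax.set_xlabel("quality grade")
    ax.set_title(f"{event_type} grade distribution (row fractions)")
    fig.colorbar(im, ax=ax, label="fraction of events")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
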