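"""Clustering, pairing and end-to-end episode reconstruction."""

import numpy as np
import pandas as pd
import pytest

from ventrecon.episodes import (
    BuilderConfig,
    build_episodes,
    cluster_candidates,
    pair_clusters,
)
from ventrecon.extraction import TRACH_EVENT_COLUMNS, empty_candidates
from ventrecon.synthetic import ScenarioConfig, generate_cohort

T0 = pd.Timestamp("2024-02-10 09:00")


def _cand(enc, etype, t, source, inferred=False, location="PICU"):
    return {
        "encounter_id": enc,
        "event_type": etype,
        "event_datetime": t,
        "source": source,
        "location": location,
        "inferred": inferred,
        "airway_kind": "endotracheal",
    }


def _cands(rows):
    df = pd.DataFrame(rows)
    df["event_datetime"] = pd.to_datetime(df["event_datetime"])
    return df


def _enc(enc="E1", pid="P1", admit=T0 - pd.Timedelta(hours=6), disposition="home", discharge=None):
    return pd.DataFrame(
        [
            {
                "encounter_id": enc,
                "patient_id": pid,
                "admit_datetime": admit,
                "discharge_datetime": discharge if discharge is not None else admit + pd.Timedelta(days=10),
                "admit_location": "ED",
                "admitted_with_airway": False,
                "discharge_disposition": disposition,
            }
        ]
    )


def _pat(pid="P1", death=pd.NaT):
    return pd.DataFrame(
        [{"patient_id": pid, "birth_datetime": pd.Timestamp("2000-01-01"), "death_datetime": death}]
    )


_NO_TRACH = pd.DataFrame(columns=TRACH_EVENT_COLUMNS)


class TestClusterCandidates:
    def test_nearby_candidates_form_one_cluster_with_priority_canonical(self):
        cands = _cands(
            [
                _cand("E1", "intubation", T0, "lda"),
                _cand("E1", "intubation", T0 + pd.Timedelta(minutes=20), "anesthesia"),
            ]
        )
        clusters = cluster_candidates(cands, match_window_hours=12)
        assert len(clusters) == 1
        assert clusters[0].canonical_datetime == T0 + pd.Timedelta(minutes=20)
        assert clusters[0].sources_present == {"lda", "anesthesia"}

    def test_distant_candidates_split(self):
        cands = _cands(
            [
                _cand("E1", "intubation", T0, "lda"),
                _cand("E1", "intubation", T0 + pd.Timedelta(hours=48), "lda"),
            ]
        )
        assert len(cluster_candidates(cands, match_window_hours=12)) == 2

    def test_singleton(self):
        cands = _cands([_cand("E1", "extubation", T0, "flowsheet")])
        (c,) = cluster_candidates(cands)
        assert c.canonical_datetime == T0
        assert c.max_pairwise_gap_hours == 0

    def test_same_source_duplicates_split_cluster(self):
        """Two LDA placements 5 h apart are two events even though
        single-linkage would chain them through the window."""
        cands = _cands(
            [
                _cand("E1", "intubation", T0, "lda"),
                _cand("E1", "intubation", T0 + pd.Timedelta(minutes=5), "anesthesia"),
                _cand("E1", "intubation", T0 + pd.Timedelta(hours=5), "lda"),
                _cand("E1", "intubation", T0 + pd.Timedelta(hours=5, minutes=3), "anesthesia"),
            ]
        )
        clusters = cluster_candidates(cands, match_window_hours=12)
        assert len(clusters) == 2
        assert all(len(c.members) == 2 for c in clusters)

    def test_event_types_never_mix(self):
        cands = _cands(
            [
                _cand("E1", "intubation", T0, "lda"),
                _cand("E1", "extubation", T0 + pd.Timedelta(minutes=10), "lda"),
            ]
        )
        assert len(cluster_candidates(cands)) == 2


class TestPairClusters:
    def _pair(self, cands, trachs=_NO_TRACH, encounters=None, patients=None):
        clusters = cluster_candidates(cands)
        return pair_clusters(
            clusters,
            trachs,
            encounters if encounters is not None else _enc(),
            patients if patients is not None else _pat(),
        )

    def test_alternation(self):
        h = pd.Timedelta(hours=1)
        cands = _cands(
            [
                _cand("E1", "intubation", T0, "lda"),
                _cand("E1", "extubation", T0 + 20 * h, "lda"),
                _cand("E1", "intubation", T0 + 60 * h, "lda"),
                _cand("E1", "extubation", T0 + 80 * h, "lda"),
            ]
        )
        episodes, drops = self._pair(cands)
        assert list(episodes.episode_index) == [1, 2]
        assert drops.empty

    def test_death_closes_open_intubation(self):
        death = T0 + pd.Timedelta(hours=30)
        episodes, _ = self._pair(
            _cands([_cand("E1", "intubation", T0, "lda")]),
            patients=_pat(death=death),
        )
        assert len(episodes) == 1
        ep = episodes.iloc[0]
        assert ep.termination == "death"
        assert ep.extubation_datetime == death
        assert ep.extubation_inferred

    def test_tracheostomy_closes_open_intubation(self):
        trach_t = T0 + pd.Timedelta(hours=72)
        trachs = pd.DataFrame(
            [{"encounter_id": "E1", "event_datetime": trach_t, "source": "procedure"}]
        )
        episodes, _ = self._pair(_cands([_cand("E1", "intubation", T0, "lda")]), trachs=trachs)
        ep = episodes.iloc[0]
        assert ep.termination == "tracheostomy"
        assert ep.extubation_datetime == trach_t
        assert ep.new_tracheostomy_during_episode

    def test_unpaired_intubation_dropped_without_fallback(self):
        episodes, drops = self._pair(_cands([_cand("E1", "intubation", T0, "lda")]))
        assert episodes.empty
        assert list(drops.reason) == ["unpaired_intubation"]

    def test_transfer_out_closes_at_discharge(self):
        discharge = T0 + pd.Timedelta(days=2)
        episodes, _ = self._pair(
            _cands([_cand("E1", "intubation", T0, "lda")]),
            encounters=_enc(disposition="transfer", discharge=discharge),
        )
        ep = episodes.iloc[0]
        assert ep.extubation_datetime == discharge
        assert ep.extubation_inferred

    def test_short_gap_fragments_merge(self):
        """Extubation then reintubation 10 min later is one charting
        artifact, not an extubation failure."""
        h = pd.Timedelta(hours=1)
        cands = _cands(
            [
                _cand("E1", "intubation", T0, "anesthesia"),
                _cand("E1", "extubation", T0 + 20 * h, "anesthesia"),
                _cand("E1", "intubation", T0 + 20 * h + pd.Timedelta(minutes=10), "lda"),
                _cand("E1", "extubation", T0 + 40 * h, "lda"),
            ]
        )
        episodes, _ = self._pair(cands)
        assert len(episodes) == 1
        ep = episodes.iloc[0]
        assert ep.intubation_datetime == T0
        assert ep.extubation_datetime == T0 + 40 * h

    def test_orphan_extubation_dropped(self):
        episodes, drops = self._pair(_cands([_cand("E1", "extubation", T0, "lda")]))
        assert episodes.empty
        assert list(drops.reason) == ["unpaired_extubation"]


class TestBuildEpisodes:
    def test_noise_free_recovery_exact(self, noise_free_build):
        """Every ground-truth episode is recovered with exact endpoints and
        no spurious episodes."""
        truth, result = noise_free_build
        ep = result.episodes
        assert len(ep) == len(truth)
        merged = truth.merge(
            ep, on=["patient_id", "episode_index"], how="inner", suffixes=("_true", "")
        )
        assert len(merged) == len(truth)
        assert (merged.true_intubation == merged.intubation_datetime).all()
        assert (merged.true_extubation == merged.extubation_datetime).all()
        assert (merged.intubation_location_true == merged.intubation_location).all()

    def test_empty_tables_empty_episodes(self):
        from ventrecon.schema import SourceTables

        result = build_episodes(SourceTables())
        assert result.episodes.empty
        assert result.reject_report.empty

    def test_input_order_invariance(self, noise_free_cohort):
        """Shuffling the raw rows of every source table leaves the episode
        set unchanged."""
        _, tables = noise_free_cohort
        baseline = build_episodes(tables).episodes
        shuffled = tables.copy()
        rng = np.random.default_rng(0)
        for name, df in shuffled.tables().items():
            perm = rng.permutation(len(df))
            setattr(shuffled, name, df.iloc[perm].reset_index(drop=True))
        again = build_episodes(shuffled).episodes
        pd.testing.assert_frame_equal(baseline, again)

    def test_no_overlap_and_positive_duration(self, noisy_build):
        _, result = noisy_build
        ep = result.episodes
        assert (ep.extubation_datetime > ep.intubation_datetime).all()
        s = ep.sort_values(["patient_id", "intubation_datetime"])
        prev_ext = s.groupby("patient_id")["extubation_datetime"].shift(1)
        overlap = prev_ext.notna() & (s["intubation_datetime"] < prev_ext)
        assert not overlap.any()

    def test_dropout_degrades_sensitivity_monotonically(self):
        """Recovery sensitivity is non-increasing as per-source
        documentation probability falls (p = 1.0 >= 0.8 >= 0.5)."""
        sens = []
        for p in (1.0, 0.8, 0.5):
            cfg = ScenarioConfig.noise_free(
                n_patients=150,
                seed=21,
                source_documentation_probs={s: p for s in ("flowsheet", "lda", "anesthesia", "procedure")},
            )
            truth, tables = generate_cohort(cfg)
            ep = build_episodes(tables).episodes
            merged = truth.merge(
                ep,
                on=["patient_id", "episode_index"],
                how="inner",
                suffixes=("_true", ""),
            )
            recovered = (
                (merged.true_intubation == merged.intubation_datetime)
                & (merged.true_extubation == merged.extubation_datetime)
            ).sum()
            sens.append(recovered / len(truth))
        assert sens[0] == 1.0
        assert sens[0] >= sens[1] >= sens[2]

    def test_termination_trach_implies_flag(self, noisy_build):
        _, result = noisy_build
        ep = result.episodes
        trach = ep[ep.termination == "tracheostomy"]
        assert trach.new_tracheostomy_during_episode.all()

    def test_reintubation_fraction_recovered(self):
        """A cohort simulated with 3.2% 7-day reintubation yields a recovered
        fraction within the binomial interval of the configured rate."""
        cfg = ScenarioConfig(n_patients=1500, seed=13)
        _, tables = generate_cohort(cfg)
        ep = build_episodes(tables).episodes
        from ventrecon.metrics import reintubation_rate_7d

        rate = reintubation_rate_7d(ep)
        p = cfg.reintubation_prob_48h + cfg.reintubation_prob_2to7d
        n = (ep.termination == "extubation").sum()
        half = 1.96 * np.sqrt(p * (1 - p) / n)
        assert p - half <= rate <= p + half
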