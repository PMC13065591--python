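"""Per-source candidate extraction, including the flowsheet interval rule."""

from datetime import datetime, timedelta

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ventrecon.extraction import (
    extract_all,
    extract_from_admissions,
    extract_from_anesthesia,
    extract_from_flowsheets,
    extract_from_lda,
    extract_from_procedures,
)
from ventrecon.schema import INVASIVE_MODES, NONINVASIVE_MODES

T0 = pd.Timestamp("2024-06-01 08:00")


def _fs(rows):
    return pd.DataFrame(
        [
            {"encounter_id": enc, "recorded_datetime": t, "vent_mode": mode, "location": "PICU"}
            for enc, t, mode in rows
        ]
    )


class TestFlowsheets:
    def test_single_invasive_interval(self):
        rows = _fs([("E1", T0 + pd.Timedelta(hours=h), "SIMV") for h in (0, 1, 2)])
        out = extract_from_flowsheets(rows, gap_tolerance_hours=8)
        assert len(out) == 2
        intub = out[out.event_type == "intubation"].iloc[0]
        extub = out[out.event_type == "extubation"].iloc[0]
        assert intub.event_datetime == T0
        assert extub.event_datetime == T0 + pd.Timedelta(hours=2)

    def test_noninvasive_rows_never_open_interval(self):
        rows = _fs([("E1", T0 + pd.Timedelta(hours=h), "CPAP") for h in range(4)])
        assert extract_from_flowsheets(rows).empty

    def test_gap_beyond_tolerance_splits_interval(self):
        rows = _fs(
            [("E1", T0, "AC"), ("E1", T0 + pd.Timedelta(hours=9), "AC")]
        )
        out = extract_from_flowsheets(rows, gap_tolerance_hours=8)
        assert len(out) == 4  # two singleton intervals

    def test_noninvasive_rows_do_not_bridge_gap(self):
        """A CPAP row inside a long gap does not extend the invasive run."""
        rows = _fs(
            [
                ("E1", T0, "AC"),
                ("E1", T0 + pd.Timedelta(hours=5), "CPAP"),
                ("E1", T0 + pd.Timedelta(hours=10), "AC"),
            ]
        )
        out = extract_from_flowsheets(rows, gap_tolerance_hours=8)
        assert len(out) == 4

    def test_unknown_mode_ignored(self):
        rows = _fs([("E1", T0, "mystery-mode"), ("E1", T0 + pd.Timedelta(hours=1), "AC")])
        out = extract_from_flowsheets(rows)
        assert len(out) == 2
        assert (out.event_datetime == T0 + pd.Timedelta(hours=1)).all()

    def test_empty_input(self):
        assert extract_from_flowsheets(_fs([])).empty

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.integers(min_value=0, max_value=200),  # hours offset
                st.sampled_from(sorted(INVASIVE_MODES) + sorted(NONINVASIVE_MODES) + ["unknown"]),
            ),
            max_size=50,
        )
    )
    def test_matches_brute_force_oracle(self, spec):
        """Interval endpoints equal an independent characterization: an
        invasive row starts a run iff no invasive row precedes it within
        tolerance, and ends one iff none follows within tolerance."""
        rows = _fs([("E1", T0 + pd.Timedelta(hours=h), m) for h, m in spec])
        tol = pd.Timedelta(hours=8)
        inv = sorted({T0 + pd.Timedelta(hours=h) for h, m in spec if m in INVASIVE_MODES})
        starts = {t for t in inv if not any(t - tol <= u < t for u in inv)}
        ends = {t for t in inv if not any(t < u <= t + tol for u in inv)}
        out = extract_from_flowsheets(rows, gap_tolerance_hours=8)
        got_starts = set(out.loc[out.event_type == "intubation", "event_datetime"])
        got_ends = set(out.loc[out.event_type == "extubation", "event_datetime"])
        assert got_starts == starts
        assert got_ends == ends


class TestLda:
    def _lda(self, **kw):
        row = {
            "encounter_id": "E1",
            "lda_type": "endotracheal tube",
            "placement_datetime": pd.NaT,
            "removal_datetime": pd.NaT,
            "location": "NICU",
        }
        row.update(kw)
        return pd.DataFrame([row])

    def test_both_endpoints(self):
        out = extract_from_lda(
            self._lda(placement_datetime=T0, removal_datetime=T0 + pd.Timedelta(hours=6))
        )
        assert list(out.event_type) == ["intubation", "extubation"]
        assert (out.airway_kind == "endotracheal").all()

    def test_placement_only(self):
        out = extract_from_lda(self._lda(placement_datetime=T0))
        assert list(out.event_type) == ["intubation"]

    def test_tracheostomy_tube_flagged(self):
        out = extract_from_lda(self._lda(lda_type="tracheostomy tube", placement_datetime=T0))
        assert (out.airway_kind == "tracheostomy").all()

    def test_other_devices_ignored(self):
        out = extract_from_lda(self._lda(lda_type="central line", placement_datetime=T0))
        assert out.empty


def test_anesthesia_one_to_one():
    events = pd.DataFrame(
        [
            {"encounter_id": "E1", "event_type": et, "event_datetime": T0 + pd.Timedelta(hours=i), "location": "perioperative"}
            for i, et in enumerate(["intubation", "extubation", "intubation"])
        ]
    )
    out = extract_from_anesthesia(events)
    assert len(out) == 3
    assert list(out.event_type) == ["intubation", "extubation", "intubation"]
    assert (out.source == "anesthesia").all()
    assert extract_from_anesthesia(events.iloc[0:0]).empty


class TestProcedures:
    def _proc(self, ptype):
        return pd.DataFrame(
            [{"encounter_id": "E1", "procedure_type": ptype, "procedure_datetime": T0, "location": "perioperative"}]
        )

    def test_tracheostomy_goes_to_separate_stream(self):
        cands, trachs = extract_from_procedures(self._proc("tracheostomy"))
        assert cands.empty
        assert len(trachs) == 1
        assert trachs.iloc[0].event_datetime == T0

    def test_intubation_procedure(self):
        cands, trachs = extract_from_procedures(self._proc("intubation"))
        assert list(cands.event_type) == ["intubation"]
        assert trachs.empty

    def test_other_emits_nothing(self):
        cands, trachs = extract_from_procedures(self._proc("appendectomy"))
        assert cands.empty and trachs.empty


class TestAdmissions:
    def _enc(self, **kw):
        row = {
            "encounter_id": "E1",
            "patient_id": "P1",
            "admit_datetime": T0,
            "discharge_datetime": T0 + pd.Timedelta(days=5),
            "admit_location": "ED",
            "admitted_with_airway": False,
            "discharge_disposition": "home",
        }
        row.update(kw)
        return pd.DataFrame([row])

    def _pat(self, death=pd.NaT):
        return pd.DataFrame(
            [{"patient_id": "P1", "birth_datetime": pd.Timestamp("1970-05-05"), "death_datetime": death}]
        )

    def test_airway_flag_emits_inferred_intubation(self):
        out = extract_from_admissions(self._enc(admitted_with_airway=True), self._pat())
        assert list(out.event_type) == ["intubation"]
        assert out.iloc[0].inferred
        assert out.iloc[0].event_datetime == T0

    def test_ordinary_encounter_emits_nothing(self):
        assert extract_from_admissions(self._enc(), self._pat()).empty

    def test_death_emits_inferred_extubation(self):
        death = T0 + pd.Timedelta(days=2)
        out = extract_from_admissions(self._enc(), self._pat(death=death))
        assert list(out.event_type) == ["extubation"]
        assert out.iloc[0].inferred
        assert out.iloc[0].event_datetime == death

    def test_death_capped_at_discharge(self):
        death = T0 + pd.Timedelta(days=30)
        out = extract_from_admissions(self._enc(), self._pat(death=death))
        assert out.iloc[0].event_datetime == T0 + pd.Timedelta(days=5)


def test_candidates_lie_within_encounter_window(noisy_cohort):
    """Every extracted candidate is documented within 24 h of its encounter."""
    from ventrecon.schema import validate_records

    _, tables = noisy_cohort
    clean, _ = validate_records(tables)
    result = extract_all(clean)
    enc = clean.encounters.set_index("encounter_id")
    lo = result.candidates["encounter_id"].map(enc["admit_datetime"]) - pd.Timedelta(hours=24)
    hi = result.candidates["encounter_id"].map(enc["discharge_datetime"]) + pd.Timedelta(hours=24)
    assert (result.candidates["event_datetime"] >= lo).all()
    assert ((result.candidates["event_datetime"] <= hi) | hi.isna()).all()


def test_fully_documented_candidate_count(noise_free_cohort):
    """Noise-free fully documented cohort: candidate count equals the number
    of documenting sources summed over events (4 per intubation: flowsheet,
    LDA, anesthesia, procedure; 3 per extubation)."""
    truth, tables = noise_free_cohort
    result = extract_all(tables)
    n = len(truth)
    assert (result.candidates.event_type == "intubation").sum() == 4 * n
    assert (result.candidates.event_type == "extubation").sum() == 3 * n
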