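"""Fate classification, turnover arithmetic, survival and zone logic."""

import numpy as np
import pandas as pd
import pytest

from spinedyn import (
    AnalysisConfig,
    EventKind,
    SimulationConfig,
    Zone,
    assign_zone,
    classify_interval_events,
    classify_study_events,
    dendrospinogram_table,
    simulate_study,
    survival_fraction,
    turnover_summary,
    turnover_table,
)
from .conftest import make_segment
from spinedyn.model import StudyDataset


def kinds_of(events):
    return {ev.spine_id: ev.kind for ev in events}


class TestClassification:
    def test_interval_zero_fates(self, three_session_segment):
        k = kinds_of(classify_interval_events(three_session_segment, 0))
        assert k["sp01"] == EventKind.SURVIVED_OLD
        assert k["sp02"] == EventKind.ELIMINATED
        assert k["sp03"] == EventKind.FORMED
        assert k["sp04"] == EventKind.FORMED
        assert k["sp05"] == EventKind.SURVIVED_OLD
        assert "sp06" not in k                    # absent at both sessions

    def test_new_cohort_tracked_into_next_interval(self, three_session_segment):
        k = kinds_of(classify_interval_events(three_session_segment, 1))
        assert k["sp03"] == EventKind.SURVIVED_NEW   # formed in (s1,s2), kept at s3
        assert k["sp04"] == EventKind.ELIMINATED
        assert k["sp01"] == EventKind.SURVIVED_OLD
        assert k["sp06"] == EventKind.FORMED

    def test_interval_out_of_range(self, three_session_segment):
        with pytest.raises(IndexError):
            classify_interval_events(three_session_segment, 2)

    def test_nn_event_distance(self):
        seg = make_segment([
            ("a", 10.0, None, (0, 1)), ("b", 13.0, None, (0, 1)),
            ("c", 30.0, None, (0, 1)), ("d", 5.0, None, (1, 1)),
        ], labels=("s1", "s2"))
        ev = {e.spine_id: e for e in classify_interval_events(seg, 0)}
        assert ev["a"].nn_event_dist_um == pytest.approx(3.0)
        assert ev["b"].nn_event_dist_um == pytest.approx(3.0)
        assert ev["c"].nn_event_dist_um == pytest.approx(17.0)
        assert ev["d"].nn_event_dist_um is None      # lone survivor event


class TestTurnover:
    def test_rate_arithmetic(self):
        seg = make_segment(
            [(f"e{i}", 1.0 + i, None, (1, 0)) for i in range(3)]
            + [(f"s{i}", 10.0 + i, None, (1, 1)) for i in range(7)]
            + [(f"f{i}", 40.0 + i, None, (0, 1)) for i in range(2)],
            labels=("s1", "s2"))
        ts = turnover_summary(classify_interval_events(seg, 0), n_start=10)
        assert ts.formation_pct == pytest.approx(20.0)
        assert ts.elimination_pct == pytest.approx(30.0)
        assert ts.form_elim_ratio == pytest.approx(2 / 3)
        assert ts.n_start - ts.n_eliminated + ts.n_formed == 9

    def test_no_events_flags(self):
        seg = make_segment([("a", 1.0, None, (1, 1))], labels=("s1", "s2"))
        ts = turnover_summary(classify_interval_events(seg, 0), n_start=1)
        assert ts.form_elim_ratio is None
        assert ts.survival_old == 1.0
        empty = turnover_summary([], n_start=0)
        assert empty.formation_pct is None and empty.elimination_pct is None

    def test_animal_level_is_unweighted_mean(self):
        segs = [
            make_segment([(f"s{i}", 1.0 + i, None, (1, 1)) for i in range(10)]
                         + [("f", 30.0, None, (0, 1))],
                         segment_id="g1", labels=("s1", "s2")),           # 1/10 formed
            make_segment([(f"s{i}", 1.0 + i, None, (1, 1)) for i in range(10)]
                         + [(f"f{i}", 30.0 + i, None, (0, 1)) for i in range(3)],
                         segment_id="g2", labels=("s1", "s2")),           # 3/10 formed
        ]
        study = StudyDataset(segs, segs[0].sessions)
        t = turnover_table(study)
        animal = t[(t.unit == "animal") & (t.interval == 0)].iloc[0]
        assert animal["formation_pct"] == pytest.approx(20.0)   # not 10*(10/20)+30*(10/20)


class TestSurvival:
    def test_fractions(self, three_session_segment):
        # pre-existing at s2: sp01, sp03, sp04, sp05 -> sp01, sp03 persist
        assert survival_fraction(three_session_segment, "pre_existing", 1) == pytest.approx(0.5)
        # new at s2: sp03, sp04 -> sp03 persists
        assert survival_fraction(three_session_segment, "new", 1) == pytest.approx(0.5)

    def test_constant_presence_survives_fully(self):
        seg = make_segment([("a", 1.0, None, (1, 1, 1)), ("b", 5.0, None, (1, 1, 1))])
        assert survival_fraction(seg, "pre_existing", 0) == 1.0
        assert survival_fraction(seg, "new", 1) is None     # empty cohort flagged

    def test_new_cohort_needs_preceding_interval(self, three_session_segment):
        with pytest.raises(ValueError):
            survival_fraction(three_session_segment, "new", 0)


class TestZones:
    @pytest.mark.parametrize("dist, zone", [
        (10.0, Zone.PROXIMAL), (40.0, Zone.INTERMEDIATE), (150.0, Zone.DISTAL),
        (80.0, Zone.UNASSIGNED_60_100),
        (25.0, Zone.INTERMEDIATE), (60.0, Zone.INTERMEDIATE),   # inclusive bounds
        (24.999, Zone.PROXIMAL), (100.0, Zone.UNASSIGNED_60_100),
    ])
    def test_assignment(self, dist, zone):
        assert assign_zone(dist) is zone

    def test_missing_and_negative(self):
        assert assign_zone(None) is Zone.NO_PLAQUE
        assert assign_zone(None, missing_to_distal=True) is Zone.DISTAL
        with pytest.raises(ValueError):
            assign_zone(-1.0)

    def test_zones_partition_events(self):
        cfg = SimulationConfig(n_animals=3, segments_per_animal=5, seed=11,
                               plaque_field=__import__("spinedyn").PlaqueField())
        study, _ = simulate_study(cfg)
        events = classify_study_events(study)
        with_dist = [ev for ev in events if ev.dist_plaque_um is not None]
        by_zone = sum(ev.zone in (Zone.PROXIMAL, Zone.INTERMEDIATE,
                                  Zone.UNASSIGNED_60_100, Zone.DISTAL)
                      for ev in with_dist)
        assert by_zone == len(with_dist) == len(events)


class TestDendrospinogram:
    def test_rows_and_zone_binning(self, three_session_segment):
        events = classify_study_events(
            StudyDataset([three_session_segment], three_session_segment.sessions))
        df = dendrospinogram_table(events)
        assert len(df) == len(events) == 10
        assert set(df["interval"].unique()) == {0, 1}
        sp = df[df.spine_id == "sp01"].iloc[0]
        assert sp["zone"] == "proximal"
        assert df[df.spine_id == "sp03"].iloc[0]["zone"] == "distal"

    def test_no_plaque_distances_warns_empty(self):
        seg = make_segment([("a", 1.0, None, (1, 0)), ("b", 5.0, None, (0, 1))],
                           labels=("s1", "s2"))
        events = classify_interval_events(seg, 0)
        with pytest.warns(UserWarning):
            df = dendrospinogram_table(events)
        assert len(df) == 0


def test_conservation_on_simulated_study():
    """n_present(t+1) = n_present(t) - eliminated + formed, per segment/interval."""
    cfg = SimulationConfig(n_animals=3, segments_per_animal=4, seed=5,
                           p_restore=0.4, clustering_strength=0.5)
    study, _ = simulate_study(cfg)
    for seg in study.segments:
        for i in range(study.sessions.n_intervals):
            ev = classify_interval_events(seg, i)
            n_formed = sum(e.kind == EventKind.FORMED for e in ev)
            n_elim = sum(e.kind == EventKind.ELIMINATED for e in ev)
            assert seg.n_present(i + 1) == seg.n_present(i) - n_elim + n_formed


def test_rate_estimates_unbiased():
    """Estimated formation/elimination rates recover the generative rates."""
    cfg = SimulationConfig(n_animals=1, segments_per_animal=150, seed=21,
                           n_sessions=3, p_elim_base=0.10, p_form_base=0.10)
    study, _ = simulate_study(cfg)
    t = turnover_table(study)
    seg_rows = t[t.unit == "segment"]
    assert seg_rows["elimination_pct"].mean() == pytest.approx(10.0, abs=1.0)
    assert seg_rows["formation_pct"].mean() == pytest.approx(10.0, abs=1.0)
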