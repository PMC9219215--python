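"""Restored-vs-de-novo matching and the random re-placement null."""

import numpy as np
import pytest

from spinedyn import (
    AnalysisConfig,
    SimulationConfig,
    match_restorations,
    restoration_null,
    restored_vs_de_novo_summary,
    simulate_study,
)
from spinedyn.restoration import MatchedPair, RestorationMatching, restoration_table
from .conftest import make_segment


def seg_with(lost_positions, new_positions, extra=()):
    """3-session segment: given spines lost in (s1,s2) and formed in (s2,s3)."""
    spines = [(f"lost{i}", p, None, (1, 0, 0)) for i, p in enumerate(lost_positions)]
    spines += [(f"new{i}", p, None, (0, 0, 1)) for i, p in enumerate(new_positions)]
    spines += [(f"bg{i}", p, None, (1, 1, 1)) for i, p in enumerate(extra)]
    return make_segment(spines)


class TestMatching:
    def test_close_reappearance_is_restored(self):
        m = match_restorations(seg_with([10.0], [10.5]), 0, 1)
        assert m.n_restored == 1 and m.n_de_novo == 0
        assert m.pairs[0].distance_um == pytest.approx(0.5)

    def test_exactly_two_um_is_de_novo(self):
        m = match_restorations(seg_with([10.0], [12.0]), 0, 1)
        assert m.n_restored == 0 and m.n_de_novo == 1   # strict < 2 um

    def test_greedy_one_to_one(self):
        m = match_restorations(seg_with([10.0, 11.0], [10.4]), 0, 1)
        assert len(m.pairs) == 1
        assert m.pairs[0].lost_spine_id == "lost0"      # 10 <-> 10.4 is nearest
        assert m.pairs[0].restored
        assert m.unmatched_lost == ["lost1"]
        assert m.n_lost == 2 and m.n_reappeared == 1

    def test_unmatched_new_is_de_novo(self):
        m = match_restorations(seg_with([10.0], [10.5, 30.0]), 0, 1)
        assert m.n_reappeared == 2
        assert m.n_restored == 1 and m.n_de_novo == 1
        assert m.unmatched_new == ["new1"]

    def test_optimal_vs_greedy_can_differ(self):
        # nearest pair first: greedy takes (11, 10.6) then (10, 9.5);
        # optimal can never do worse on total distance
        seg = seg_with([10.0, 11.0], [9.5, 10.6])
        greedy = match_restorations(seg, 0, 1, method="greedy")
        optimal = match_restorations(seg, 0, 1, method="optimal")
        assert {(p.lost_spine_id, p.new_spine_id) for p in greedy.pairs} == \
            {("lost1", "new1"), ("lost0", "new0")}
        total_g = sum(p.distance_um for p in greedy.pairs)
        total_o = sum(p.distance_um for p in optimal.pairs)
        assert total_o <= total_g

    def test_interval_order_enforced(self):
        with pytest.raises(ValueError):
            match_restorations(seg_with([10.0], [10.5]), 1, 1)

    def test_counts_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            lost = rng.uniform(0, 80, rng.integers(0, 5))
            new = rng.uniform(0, 80, rng.integers(0, 5))
            m = match_restorations(seg_with(lost, new), 0, 1)
            assert m.n_restored + m.n_de_novo == m.n_reappeared == len(new)
            assert m.n_lost == len(lost)


class TestNull:
    def test_analytic_reference_instance(self):
        """Lost at 10, candidates {9, 10.5, 30, 50}: positions 9 and 10.5
        are < 2 um away -> null restored probability exactly 2/4."""
        m = match_restorations(seg_with([10.0], [10.5]), 0, 1)
        res = restoration_null(m, [9.0, 10.5, 30.0, 50.0], n_perm=10_000, seed=4)
        assert abs(res.null_mean - 0.5) <= 3 * max(res.null_sem, 1e-12)

    def test_all_candidates_within_threshold(self):
        m = match_restorations(seg_with([10.0], [10.5]), 0, 1)
        res = restoration_null(m, [9.0, 10.5, 11.0], n_perm=2000, seed=4,
                               threshold_um=50.0)
        assert res.null_mean == 1.0

    def test_deterministic_given_seed(self):
        m = match_restorations(seg_with([10.0, 20.0], [10.5, 40.0]), 0, 1)
        cand = [5.0, 10.5, 19.0, 40.0, 60.0]
        assert restoration_null(m, cand, seed=11) == restoration_null(m, cand, seed=11)

    def test_analytic_invariant_random_instances(self):
        """Null mean equals the mean over reappeared spines of the
        fraction of candidate positions within threshold."""
        rng = np.random.default_rng(5)
        for trial in range(5):
            lost = rng.uniform(0, 80, 3)
            new = rng.uniform(0, 80, 3)
            cand = rng.uniform(0, 80, 20)
            m = match_restorations(seg_with(lost, new), 0, 1)
            res = restoration_null(m, cand, n_perm=10_000, seed=trial)
            analytic = np.mean([
                np.mean(np.abs(cand - p.lost_position_um) < m.threshold_um)
                for p in m.pairs]) * len(m.pairs) / m.n_reappeared
            assert abs(res.null_mean - analytic) <= 3 * max(res.null_sem, 1e-12)

    def test_no_candidates_raises(self):
        m = match_restorations(seg_with([10.0], [10.5]), 0, 1)
        with pytest.raises(ValueError):
            restoration_null(m, [], seed=0)


class TestStudySummary:
    def test_proportions_sum_to_one(self):
        cfg = SimulationConfig(n_animals=3, segments_per_animal=4, seed=29,
                               p_restore=0.5)
        study, _ = simulate_study(cfg)
        summary = restored_vs_de_novo_summary(study)
        prop_cols = [c for c in summary.columns if c.startswith("prop_")]
        totals = summary[prop_cols].sum(axis=1)
        assert np.allclose(totals, 1.0)

    def test_restoration_rate_recovers_generator(self):
        """Median observed restored proportion rises with p_restore."""
        medians = []
        ana = AnalysisConfig(n_perm_restore=200, seed=0)
        for p in (0.0, 0.25, 0.5):
            cfg = SimulationConfig(n_animals=1, segments_per_animal=60, seed=37,
                                   p_elim_base=0.15, p_restore=p)
            study, _ = simulate_study(cfg)
            t = restoration_table(study, ana)
            t = t[t.n_reappeared > 0]
            medians.append(float(t.observed_restored_prop.mean()))
        assert medians[0] < medians[1] < medians[2]

    def test_needs_three_sessions(self):
        cfg = SimulationConfig(n_animals=1, segments_per_animal=1, seed=1, n_sessions=2)
        study, _ = simulate_study(cfg)
        with pytest.raises(ValueError):
            restored_vs_de_novo_summary(study)
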