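"""Cluster detection and the randomized-placement null, against the
brute-force enumeration oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from spinedyn import (
    AnalysisConfig,
    EventKind,
    SimulationConfig,
    Zone,
    cluster_test_by_zone,
    clustered_proportion,
    detect_clusters,
    exhaustive_null,
    permutation_null,
    pooled_permutation_null,
    simulate_study,
)
from spinedyn.model import Verdict


class TestDetection:
    @pytest.mark.parametrize("positions, n_clusters, clustered", [
        ([10.0, 13.0], 1, 2),            # spacing 3 <= 5
        ([10.0, 15.0], 1, 2),            # boundary: <= 5 um is inclusive
        ([10.0, 16.0], 0, 0),            # spacing 6 breaks the chain
        ([10.0, 13.0, 17.0, 40.0], 1, 3),  # chain of 3, singleton excluded
        ([1.0, 2.0, 3.0, 4.0], 1, 4),
        ([], 0, 0),
    ])
    def test_examples(self, positions, n_clusters, clustered):
        clusters = detect_clusters(positions)
        assert len(clusters) == n_clusters
        assert sum(len(c) for c in clusters) == clustered

    def test_order_invariance(self):
        a = detect_clusters([40.0, 10.0, 13.0, 17.0])
        b = detect_clusters([10.0, 13.0, 17.0, 40.0])
        assert sorted(map(len, a)) == sorted(map(len, b))

    @pytest.mark.parametrize("positions, expected", [
        ([10.0, 13.0, 30.0], 2 / 3),
        ([0.0, 10.0, 20.0, 30.0], 0.0),
        ([1.0, 2.0, 3.0, 4.5], 1.0),
    ])
    def test_clustered_proportion(self, positions, expected):
        assert clustered_proportion(positions) == pytest.approx(expected)

    def test_min_size_three(self):
        assert clustered_proportion([0.0, 3.0, 30.0, 33.0, 36.0], min_size=3) \
            == pytest.approx(3 / 5)


class TestExhaustiveOracle:
    def test_reference_instance(self):
        """Anchor at 0 (partner over {3,10,20}) and at 3 (over {0,10,20}):
        2 clustered placements of 6 -> exactly 1/3."""
        assert exhaustive_null([0.0, 3.0], [0.0, 3.0, 10.0, 20.0]) \
            == pytest.approx(1 / 3)

    def test_all_candidates_within_window(self):
        assert exhaustive_null([0.0, 2.0], [0.0, 1.0, 2.0, 3.0, 4.0]) == 1.0

    def test_hand_enumerated_sparse_instance(self):
        # candidates {0, 3, 20, 40}: clustered placements are exactly the
        # {0,3} pairs -> per anchor 1 of 3 assignments (anchors 0 and 3),
        # 0 of 3 (anchors placed alone far away are impossible: events
        # observed at 0 and 20) -> anchors are 0 and 20:
        # anchor 0: partners {3,20,40} -> clustered only with 3 -> 1/3 of mass
        # anchor 20: partners {0,3,40} -> none within 5 -> 0
        # mean = (1/3 + 0) / 2 * 1.0 ... enumerate explicitly:
        vals = []
        for anchor, rest in ((0.0, [3.0, 20.0, 40.0]), (20.0, [0.0, 3.0, 40.0])):
            for p in rest:
                vals.append(clustered_proportion([anchor, p]))
        assert exhaustive_null([0.0, 20.0], [0.0, 3.0, 20.0, 40.0]) \
            == pytest.approx(np.mean(vals)) == pytest.approx(1 / 6)

    def test_combinatorial_bound(self):
        with pytest.raises(ValueError, match="placements"):
            exhaustive_null(list(range(10)), list(range(60)),
                            max_placements=1000)


class TestPermutationNull:
    def test_matches_oracle_on_reference_instance(self):
        res = permutation_null([0.0, 3.0], [0.0, 3.0, 10.0, 20.0],
                               n_perm=30_000, seed=2)
        assert res.observed_prop == 1.0
        assert abs(res.null_mean - 1 / 3) <= 3 * res.null_sem

    def test_single_event_undefined(self):
        assert permutation_null([5.0], [0.0, 5.0, 10.0], seed=0) is None

    def test_candidates_fewer_than_events(self):
        with pytest.raises(ValueError):
            permutation_null([0.0, 3.0, 5.0], [0.0, 3.0], seed=0)

    def test_deterministic_given_seed(self):
        a = permutation_null([0.0, 3.0, 9.0], [0.0, 3.0, 9.0, 15.0, 30.0],
                             n_perm=5000, seed=7)
        b = permutation_null([0.0, 3.0, 9.0], [0.0, 3.0, 9.0, 15.0, 30.0],
                             n_perm=5000, seed=7)
        assert a == b

    def test_replicates_bounded(self):
        res = permutation_null([0.0, 3.0], [0.0, 3.0, 4.0, 4.5],
                               n_perm=2000, seed=1)
        assert 0.0 <= res.null_mean <= 1.0
        assert res.ci_low <= res.null_mean <= res.ci_high

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.data())
    def test_oracle_equivalence_random_small_instances(self, data):
        """Monte-Carlo null mean agrees with full enumeration on random
        instances with <= 8 candidates and 2-3 dynamic events."""
        n_cand = data.draw(st.integers(4, 8))
        n_ev = data.draw(st.integers(2, 3))
        seed = data.draw(st.integers(0, 10_000))
        rng = np.random.default_rng(seed)
        cand = np.sort(rng.uniform(0.0, 40.0, n_cand))
        cand += np.arange(n_cand) * 1e-3          # enforce distinct sites
        ev = rng.choice(cand, n_ev, replace=False)
        exact = exhaustive_null(ev, cand)
        res = permutation_null(ev, cand, n_perm=30_000, seed=seed + 1)
        tol = max(3 * res.null_sem, 1e-12)
        assert abs(res.null_mean - exact) <= tol

    def test_anchor_symmetry(self):
        """With all-distinct spacings, cycling the anchor changes the null
        mean only within Monte-Carlo error of any single-anchor null."""
        import itertools
        cand = np.array([0.0, 4.0, 11.0, 19.0, 26.0, 37.0])
        ev = np.array([0.0, 4.0, 19.0])
        full = permutation_null(ev, cand, n_perm=30_000, seed=3)
        single_anchor_means = []
        for a in ev:
            rest = cand[np.abs(cand - a) > 1e-9]
            vals = [clustered_proportion(np.r_[a, combo])
                    for combo in itertools.combinations(rest, len(ev) - 1)]
            single_anchor_means.append(np.mean(vals))
        # the rotating-anchor estimate sits between the single-anchor means
        lo, hi = min(single_anchor_means), max(single_anchor_means)
        assert lo - 3 * full.null_sem <= full.null_mean <= hi + 3 * full.null_sem
        assert abs(full.null_mean - np.mean(single_anchor_means)) <= 3 * full.null_sem


class TestPooled:
    def test_single_group_matches_plain_test(self):
        ev = [0.0, 3.0]
        cand = [0.0, 3.0, 10.0, 20.0]
        pooled = pooled_permutation_null([(ev, cand)], n_perm=20_000, seed=5)
        plain = permutation_null(ev, cand, n_perm=20_000, seed=5)
        assert pooled.observed_prop == plain.observed_prop
        assert abs(pooled.null_mean - plain.null_mean) <= \
            3 * (pooled.null_sem + plain.null_sem)

    def test_lone_event_group_dilutes_only(self):
        groups = [([0.0, 3.0], [0.0, 3.0, 10.0, 20.0]), ([7.0], [2.0, 7.0, 30.0])]
        res = pooled_permutation_null(groups, n_perm=10_000, seed=5)
        assert res.n_dynamic == 3
        assert res.observed_prop == pytest.approx(2 / 3)
        # the lone event can never cluster: null mean = (2/3) * pairwise null
        assert abs(res.null_mean - (2 / 3) * (1 / 3)) <= 3 * res.null_sem


def test_cluster_test_by_zone_smoke():
    cfg = SimulationConfig(n_animals=2, segments_per_animal=4, seed=19,
                           n_sessions=2, p_form_base=0.3, clustering_strength=0.6)
    study, _ = simulate_study(cfg)
    ana = AnalysisConfig(n_perm_cluster=2000, seed=19)
    per_seg, per_animal = cluster_test_by_zone(study, EventKind.FORMED, ana)
    assert len(per_seg) > 0
    assert set(per_seg.verdict) <= {v.value for v in Verdict}
    assert len(per_animal) == 2 * study.sessions.n_intervals
    assert (per_animal.pooled_null_mean <= 1).all()


def test_empty_zone_gives_empty_result():
    cfg = SimulationConfig(n_animals=1, segments_per_animal=2, seed=23, n_sessions=2)
    study, _ = simulate_study(cfg)      # no plaque field -> no zoned events
    ana = AnalysisConfig(n_perm_cluster=500, seed=1)
    per_seg, per_animal = cluster_test_by_zone(study, EventKind.FORMED, ana,
                                               zone=Zone.PROXIMAL)
    assert len(per_seg) == 0 and len(per_animal) == 0
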