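"""Stay-probability, MB-index, place-memory and correlation analyses."""

import numpy as np
import pytest

from dualsys.agent import TrialRecord
from dualsys.analysis import (
    association_z,
    compare_correlations,
    mb_index,
    place_memory_score,
    stay_probabilities,
    stay_trials,
)


def record(choice, reward, common):
    return TrialRecord(
        trial=0, steps=2, reward=float(reward), terminal=True, final_state=0,
        visited=np.zeros(1, dtype=np.int32), mean_psr=0.5, start_psr=0.5,
        mean_omega_mf=0.0, mean_abs_rpe=0.0, choice1=choice, stage2=1,
        common=bool(common),
    )


def synth_records(rng, n, stay_rule):
    """Generate records where each choice follows ``stay_rule(prev)``."""
    recs = [record(rng.integers(2), rng.integers(2), rng.random() < 0.7)]
    for _ in range(n - 1):
        prev = recs[-1]
        stay_p = stay_rule(prev)
        c = prev.choice1 if rng.random() < stay_p else 1 - prev.choice1
        recs.append(record(c, rng.integers(2), rng.random() < 0.7))
    return recs


class TestStayProbabilities:
    def test_always_repeat_gives_ones(self, rng):
        recs = synth_records(rng, 200, lambda prev: 1.0)
        assert np.allclose(stay_probabilities(recs).as_array(), 1.0)

    def test_always_alternate_gives_zeros(self, rng):
        recs = synth_records(rng, 200, lambda prev: 0.0)
        assert np.allclose(stay_probabilities(recs).as_array(), 0.0)

    def test_uniform_random_near_half(self):
        rng = np.random.default_rng(8)
        recs = synth_records(rng, 4000, lambda prev: 0.5)
        assert np.allclose(stay_probabilities(recs).as_array(), 0.5, atol=0.05)

    def test_matches_independent_tabulation(self, rng):
        """Dual-route check: vectorized table versus a plain loop."""
        recs = synth_records(rng, 500, lambda p: 0.3 + 0.4 * p.reward)
        table = stay_probabilities(recs)
        cells = {(True, True): [], (True, False): [], (False, True): [], (False, False): []}
        for prev, cur in zip(recs[:-1], recs[1:]):
            cells[(prev.reward > 0, prev.common)].append(cur.choice1 == prev.choice1)
        assert table.rewarded_common == pytest.approx(np.mean(cells[(True, True)]))
        assert table.unrewarded_rare == pytest.approx(np.mean(cells[(False, False)]))

    def test_empty_records_raise(self):
        with pytest.raises(ValueError):
            stay_probabilities([record(0, 1, True)])


class TestMBIndex:
    def test_pure_mb_chooser_positive_interaction(self):
        # transition-aware rule: stay after rewarded-common/unrewarded-rare
        rng = np.random.default_rng(3)

        def rule(prev):
            mb_stay = (prev.reward > 0) == prev.common
            return 0.85 if mb_stay else 0.15

        recs = synth_records(rng, 600, rule)
        assert mb_index(recs) > 0.5

    def test_pure_mf_chooser_no_interaction(self):
        rng = np.random.default_rng(4)
        recs = synth_records(rng, 600, lambda p: 0.8 if p.reward > 0 else 0.3)
        mb, mf = mb_index(recs, return_mf=True)
        assert abs(mb) < 0.25
        assert mf > 0.5

    def test_constant_chooser_excluded(self, rng):
        recs = synth_records(rng, 100, lambda p: 1.0)
        assert np.isnan(mb_index(recs))

    def test_too_few_trials_excluded(self, rng):
        recs = synth_records(rng, 5, lambda p: 0.5)
        assert np.isnan(mb_index(recs))


class TestPlaceMemoryScore:
    def test_perfect_memory_zero_distance(self):
        centers = np.array([[float(i), 0.0] for i in range(5)])
        vmap = np.array([0.0, 0.0, 1.0, 0.0, 0.0])
        assert place_memory_score(vmap, centers, np.array([[2.0, 0.0]])) == 0.0

    def test_random_maps_match_geometric_oracle(self):
        """Uniformly random argmax: mean distance equals the Monte-Carlo
        mean distance from a uniform grid point to the reference point."""
        rng = np.random.default_rng(9)
        xs, ys = np.meshgrid(np.arange(10.0), np.arange(10.0))
        centers = np.column_stack([xs.ravel(), ys.ravel()])
        target = np.array([4.0, 4.0])
        maps = rng.random((400, 100))
        score = place_memory_score(maps, centers, np.tile(target, (400, 1)))
        oracle = np.linalg.norm(centers - target, axis=1).mean()
        assert score == pytest.approx(oracle, rel=0.05)

    def test_flat_map_uses_centroid_tiebreak(self):
        centers = np.array([[0.0, 0.0], [2.0, 0.0], [4.0, 0.0]])
        score = place_memory_score(np.zeros(3), centers, np.array([[0.0, 0.0]]))
        assert score == pytest.approx(2.0)  # centroid cell is (2, 0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            place_memory_score(np.zeros((2, 4)), np.zeros((4, 2)), np.zeros((3, 2)))


class TestCorrelationStatistics:
    def test_association_z_is_fisher_transform(self, rng):
        x = rng.normal(size=30)
        y = 0.8 * x + 0.6 * rng.normal(size=30)
        r, z, p = association_z(x, y)
        assert z == pytest.approx(np.arctanh(r))
        assert 0 <= p <= 1

    def test_equal_correlations_zero_difference(self):
        z, p = compare_correlations(0.5, 20, 0.5, 25)
        assert z == 0.0 and p == pytest.approx(1.0)

    def test_p_decreasing_in_z(self):
        ps = [compare_correlations(r, 20, 0.0, 20)[1] for r in (0.2, 0.5, 0.8)]
        assert ps[0] > ps[1] > ps[2]

    def test_matches_permutation_oracle(self):
        """Fisher z difference test versus a label-permutation oracle."""
        rng = np.random.default_rng(12)
        n = 20
        x1 = rng.normal(size=n)
        y1 = 0.8 * x1 + 0.4 * rng.normal(size=n)
        x2, y2 = rng.normal(size=n), rng.normal(size=n)
        r1 = np.corrcoef(x1, y1)[0, 1]
        r2 = np.corrcoef(x2, y2)[0, 1]
        z, p = compare_correlations(r1, n, r2, n)
        xs, ys = np.concatenate([x1, x2]), np.concatenate([y1, y2])
        diffs = []
        for _ in range(2000):
            idx = rng.permutation(2 * n)
            a, b = idx[:n], idx[n:]
            diffs.append(
                np.arctanh(np.corrcoef(xs[a], ys[a])[0, 1])
                - np.arctanh(np.corrcoef(xs[b], ys[b])[0, 1])
            )
        observed = np.arctanh(r1) - np.arctanh(r2)
        p_perm = np.mean(np.abs(diffs) >= abs(observed))
        # both agree the difference is significant, at compatible levels
        assert p < 0.05 and p_perm < 0.05

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            compare_correlations(1.0, 20, 0.0, 20)
        with pytest.raises(ValueError):
            compare_correlations(0.5, 3, 0.0, 20)

    def test_association_needs_pairs(self):
        with pytest.raises(ValueError):
            association_z([1, 2], [1, 2])
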