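import numpy as np
import pytest

from isletdx import (EHOParams, DOAParams, eho_select, doa_select,
                     eho_update_position, eho_best_update, eho_worst_replace,
                     doa_forces, doa_step, feature_pvalues)
from isletdx.reduction import ReducedMatrix
from isletdx.selection import eho_optimize, doa_optimize
from tests.conftest import two_class_labels


class TestEHOUpdates:
    def test_alpha_zero_no_move(self, rng):
        y = rng.normal(size=4)
        np.testing.assert_array_equal(
            eho_update_position(y, rng.normal(size=4), 0.0, rng), y)

    def test_at_best_no_move(self, rng):
        y = rng.normal(size=4)
        np.testing.assert_array_equal(eho_update_position(y, y, 0.7, rng), y)

    def test_follower_arithmetic(self):
        class FixedRng:
            def random(self):
                return 1.0
        out = eho_update_position(np.array([0.0]), np.array([2.0]), 0.5,
                                  FixedRng())
        assert out[0] == 1.0

    def test_best_update_is_scaled_centre(self):
        pos = np.array([[2.0, 4.0], [2.0, 4.0]])
        np.testing.assert_array_equal(eho_best_update(pos, 1.0), [2.0, 4.0])
        np.testing.assert_array_equal(eho_best_update(pos, 0.5), [1.0, 2.0])

    def test_worst_replace_literal_then_clamped(self):
        class FixedRng:
            def __init__(self, v):
                self.v = v
            def random(self):
                return self.v
        assert eho_worst_replace(0.0, 1.0, FixedRng(0.0)) == 0.0
        # rand = 1 gives y_max + 1 before the clamp, y_max after
        assert eho_worst_replace(0.0, 1.0, FixedRng(1.0)) == 1.0

    def test_worst_replace_always_in_bounds(self, rng):
        vals = [eho_worst_replace(-1.0, 2.0, rng) for _ in range(10_000)]
        assert min(vals) >= -1.0 and max(vals) <= 2.0


class TestDOAForces:
    def test_empty_neighborhood_conventions(self):
        pos = np.array([[0.0, 0.0], [10.0, 10.0]])
        vel = np.array([[1.0, 2.0], [0.0, 0.0]])
        p = DOAParams(neighborhood_radius=1.0)
        se, ag, co, h, d = doa_forces(0, pos, vel, np.zeros(2), np.ones(2), p)
        np.testing.assert_array_equal(se, 0)
        np.testing.assert_array_equal(ag, vel[0])
        np.testing.assert_array_equal(co, 0)

    def test_fly_at_food_has_zero_attraction(self):
        pos = np.array([[0.5, 0.5], [0.2, 0.2]])
        vel = np.zeros_like(pos)
        se, ag, co, h, d = doa_forces(0, pos, vel, pos[0].copy(),
                                      np.zeros(2), DOAParams())
        np.testing.assert_array_equal(h, 0)

    def test_symmetric_neighbors_cancel_separation(self):
        pos = np.array([[0.0, 0.0], [1.0, 1.0], [-1.0, -1.0]])
        vel = np.zeros_like(pos)
        se, *_ = doa_forces(0, pos, vel, np.zeros(2), np.zeros(2),
                            DOAParams())
        np.testing.assert_allclose(se, 0, atol=1e-12)

    def test_literal_vs_canonical_enemy_term(self):
        pos = np.array([[0.2, 0.2], [0.8, 0.8]])
        vel = np.zeros_like(pos)
        enemy = np.array([1.0, 1.0])
        *_, d_lit = doa_forces(0, pos, vel, np.zeros(2), enemy,
                               DOAParams(da_literal_enemy=True))
        *_, d_can = doa_forces(0, pos, vel, np.zeros(2), enemy,
                               DOAParams(da_literal_enemy=False))
        np.testing.assert_allclose(d_lit, enemy + pos[0])
        np.testing.assert_allclose(d_can, enemy - pos[0])


class TestDOAStep:
    def test_pure_inertia(self, rng):
        p = DOAParams(s_weight=(0, 0), a_weight=(0, 0), c_weight=(0, 0),
                      h_weight=(0, 0), d_weight=(0, 0), inertia=(1.0, 1.0),
                      step_clamp=10.0, bounds=(-100, 100))
        pos = np.zeros((2, 3))
        vel = np.full((2, 3), 0.25)
        doa_step(pos, vel, np.zeros(3), np.zeros(3), p, 0.0, rng)
        np.testing.assert_allclose(vel, 0.25)
        np.testing.assert_allclose(pos, 0.25)

    def test_all_zero_weights_freeze_swarm(self, rng):
        p = DOAParams(s_weight=(0, 0), a_weight=(0, 0), c_weight=(0, 0),
                      h_weight=(0, 0), d_weight=(0, 0), inertia=(0.0, 0.0))
        pos = np.full((3, 4), 0.5)
        vel = np.zeros((3, 4))
        doa_step(pos, vel, np.zeros(4), np.zeros(4), p, 0.5, rng)
        np.testing.assert_array_equal(vel, 0)
        np.testing.assert_array_equal(pos, 0.5)

    def test_sphere_best_trace_monotone_and_converges(self):
        ratios = []
        for seed in range(10):
            res = doa_optimize(lambda v: float((v ** 2).sum()), 10,
                               DOAParams(bounds=(-5, 5), seed=seed),
                               maximize=False)
            assert all(b <= a + 1e-12 for a, b in zip(res.trace, res.trace[1:]))
            rng = np.random.default_rng(seed)
            init = rng.uniform(-5, 5, (20, 10))
            ratios.append(res.best_fitness / np.median((init ** 2).sum(1)))
        assert np.median(ratios) < 0.01


def planted_block(rng, n_features=60, n_informative=6):
    """Reduced-matrix block with a few strongly separated features."""
    y = two_class_labels(20, 50)
    vals = rng.normal(size=(n_features, 70))
    vals[:n_informative, :20] += 3.0
    rm = ReducedMatrix([f"f{i}" for i in range(n_features)],
                       list(y.sample_ids), vals, "dct")
    return rm, y, set(range(n_informative))


class TestSelectors:
    @pytest.mark.parametrize("select,params", [
        (eho_select, EHOParams(seed=0, iterations=150)),
        (doa_select, DOAParams(seed=0, iterations=150)),
    ])
    def test_mask_size_determinism_and_enrichment(self, rng, select, params):
        rm, y, informative = planted_block(rng)
        mask = select(rm, y, 10, params)
        assert len(mask.selected) == 10
        assert mask.selected == sorted(mask.selected)
        again = select(rm, y, 10, params)
        assert mask.selected == again.selected
        hits = len(informative & set(mask.selected))
        assert hits >= 4      # ~1 expected for a random 10-of-60 subset

    def test_single_class_rejected(self, rng):
        rm, y, _ = planted_block(rng)
        from isletdx.data import LabelVector
        y1 = LabelVector(y.sample_ids, ["diabetic"] * len(y))
        with pytest.raises(ValueError):
            eho_select(rm, y1, 5, EHOParams(iterations=5))

    def test_positions_stay_in_bounds(self):
        seen = []
        def probe(v):
            seen.append(v.copy())
            return float(v.sum())
        eho_optimize(probe, 8, EHOParams(seed=1, iterations=50))
        arr = np.array(seen)
        assert arr.min() >= 0.0 and arr.max() <= 1.0


class TestFeaturePvalues:
    def test_identical_groups_give_p_one(self):
        vals = np.tile(np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0]), (2, 1))
        y = two_class_labels(3, 3)
        rm = ReducedMatrix(["f0", "f1"], list(y.sample_ids), vals, "dct")
        p, summary = feature_pvalues(rm, y)
        np.testing.assert_allclose(p, 1.0)
        assert summary == 1.0

    def test_separated_groups_significant(self, rng):
        y = two_class_labels(30, 30)
        vals = np.hstack([rng.normal(5, 1, (3, 30)), rng.normal(0, 1, (3, 30))])
        rm = ReducedMatrix(["a", "b", "c"], list(y.sample_ids), vals, "dct")
        _, summary = feature_pvalues(rm, y)
        assert summary < 1e-6

    def test_matches_scipy_welch_per_feature(self, rng):
        from scipy import stats
        y = two_class_labels(8, 12)
        vals = rng.normal(size=(5, 20))
        rm = ReducedMatrix([f"f{i}" for i in range(5)], list(y.sample_ids),
                           vals, "dct")
        p, _ = feature_pvalues(rm, y)
        ref = stats.ttest_ind(vals[:, :8], vals[:, 8:], axis=1,
                              equal_var=False).pvalue
        np.testing.assert_allclose(p, ref)
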