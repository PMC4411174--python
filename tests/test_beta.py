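"""Dissimilarity metrics and the Raup-Crick null model, including the
exhaustive enumeration oracle and the null-model calibration property."""

from itertools import combinations

import numpy as np
import pytest

from regiondiv.beta import (RCConfig, bray_curtis, bray_curtis_matrix,
                            classify_rc_pair, compare_rc_matrices, jaccard,
                            jaccard_matrix, raup_crick, rc_exhaustive)
from regiondiv.simulate import TruthConfig, simulate_metacommunity
from regiondiv.types import OTUTable


class TestJaccard:
    def test_partial_overlap(self):
        a = np.array([1, 1, 0])
        b = np.array([0, 1, 1])
        assert jaccard(a, b) == pytest.approx(1 - 1 / 3)

    def test_identical_zero(self):
        a = np.array([2, 0, 5])
        assert jaccard(a, a) == 0.0

    def test_disjoint_one(self):
        assert jaccard(np.array([1, 0]), np.array([0, 3])) == 1.0

    def test_both_empty_defined_zero(self):
        assert jaccard(np.zeros(4), np.zeros(4)) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError):
            jaccard(np.array([1]), np.array([1, 2]))


class TestBrayCurtis:
    @pytest.mark.parametrize("a,b,expected", [
        ((5, 5), (5, 5), 0.0),
        ((10, 0), (0, 10), 1.0),
        ((6, 2), (2, 2), 1 / 3),
    ])
    def test_examples(self, a, b, expected):
        assert bray_curtis(np.array(a), np.array(b)) == pytest.approx(expected)

    def test_both_empty_is_error(self):
        with pytest.raises(ValueError):
            bray_curtis(np.zeros(3), np.zeros(3))


class TestMatrixForms:
    def test_metric_axioms_on_random_tables(self, rng):
        counts = rng.integers(0, 8, size=(6, 12))
        counts[:, 0] = 1  # no empty samples
        t = OTUTable([f"s{i}" for i in range(6)],
                     [f"o{j}" for j in range(12)], counts)
        for mat in (jaccard_matrix(t), bray_curtis_matrix(t)):
            assert np.allclose(np.diag(mat.values), 0.0)
            assert np.allclose(mat.values, mat.values.T)
            assert (mat.values >= 0).all() and (mat.values <= 1).all()

    def test_matrix_matches_pairwise_function(self, small_table):
        mat = jaccard_matrix(small_table)
        expected = jaccard(small_table.counts[0], small_table.counts[1])
        assert mat.pair("s1", "s2") == pytest.approx(expected)


def _table(presence):
    presence = np.asarray(presence, dtype=int)
    return OTUTable([f"s{i}" for i in range(presence.shape[0])],
                    [f"o{j}" for j in range(presence.shape[1])], presence)


class TestRaupCrick:
    def test_forced_ties_give_zero(self):
        # both samples contain the whole pool: null always ties observed
        t = _table(np.ones((2, 6)))
        rc = raup_crick(t, RCConfig(n_iterations=500, seed=1))
        assert rc.values[0, 1] == 0.0

    def test_bounds_and_symmetry(self, rng):
        presence = rng.random((5, 10)) < 0.5
        presence[:, 0] = True
        t = _table(presence)
        rc = raup_crick(t, RCConfig(n_iterations=300, seed=2))
        assert np.allclose(rc.values, rc.values.T)
        assert (rc.values >= -1).all() and (rc.values <= 1).all()

    def test_empty_sample_rejected(self):
        t = _table([[1, 1, 0], [0, 0, 0]])
        with pytest.raises(ValueError, match="empty"):
            raup_crick(t, RCConfig(n_iterations=10, seed=0))

    def test_share_sample_draws_mode_agrees(self, rng):
        presence = rng.random((5, 10)) < 0.5
        presence[:, 0] = True
        t = _table(presence)
        a = raup_crick(t, RCConfig(n_iterations=4000, seed=3))
        b = raup_crick(t, RCConfig(n_iterations=4000, seed=4,
                                   share_sample_draws=True))
        assert np.allclose(b.values, b.values.T)
        # same law, independent seeds: values agree to Monte-Carlo error
        assert np.abs(a.values - b.values).max() < 0.12

    def test_disjoint_samples_match_hypergeometric_tail(self):
        # gamma = 20, alpha = 5 and 5, SS_obs = 0
        presence = np.zeros((2, 20), dtype=int)
        presence[0, :5] = 1
        presence[1, 5:10] = 1
        presence = np.vstack([presence, np.ones((1, 20), dtype=int)])
        t = _table(presence)
        cfg = RCConfig(n_iterations=10000, weighting="uniform", seed=5)
        rc = raup_crick(t, cfg)
        from scipy.stats import hypergeom
        dist = hypergeom(20, 5, 5)
        p_exact = dist.sf(0) + 0.5 * dist.pmf(0)
        p_mc = (rc.values[0, 1] + 1) / 2
        se = np.sqrt(p_exact * (1 - p_exact) / 10000)
        assert abs(p_mc - p_exact) < 3 * se


class TestExhaustiveOracle:
    def test_exact_enumeration_gamma4(self):
        # gamma=4, alpha=2,2, SS_obs=1: enumerate all 36 subset pairs
        presence = np.array([[1, 1, 0, 0],
                             [0, 1, 1, 0],
                             [1, 1, 1, 1]])
        t = _table(presence)
        rc = rc_exhaustive(t)
        pool = range(4)
        obs = 1
        gt = ties = total = 0
        for a in combinations(pool, 2):
            for b in combinations(pool, 2):
                shared = len(set(a) & set(b))
                total += 1
                gt += shared > obs
                ties += shared == obs
        p = (gt + 0.5 * ties) / total
        assert rc.values[0, 1] == pytest.approx(2 * p - 1)

    def test_maximal_sharing_p_at_most_half(self):
        presence = np.array([[1, 1, 0, 0, 0],
                             [1, 1, 1, 0, 0],
                             [1, 1, 1, 1, 1]])
        t = _table(presence)
        rc = rc_exhaustive(t)
        assert (rc.values[0, 1] + 1) / 2 <= 0.5

    def test_no_sharing_p_above_half(self):
        presence = np.array([[1, 1, 0, 0],
                             [0, 0, 1, 1],
                             [1, 1, 1, 1]])
        t = _table(presence)
        rc = rc_exhaustive(t)
        assert (rc.values[0, 1] + 1) / 2 > 0.5

    def test_large_pool_rejected(self):
        t = _table(np.ones((2, 40)))
        with pytest.raises(ValueError, match="too large"):
            rc_exhaustive(t)


class TestClassification:
    @pytest.mark.parametrize("rc1,rc2,expected", [
        (-0.99, -0.99, "a"),
        (0.0, 0.5, "a"),
        (0.99, 0.99, "a"),
        (-0.99, 0.0, "b"),
        (0.0, -0.99, "b"),
        (0.99, 0.0, "c"),
        (-0.99, 0.99, "d"),
    ])
    def test_categories(self, rc1, rc2, expected):
        assert classify_rc_pair(rc1, rc2, band=0.975) == expected

    def test_band_validated(self):
        with pytest.raises(ValueError):
            classify_rc_pair(0.0, 0.0, band=1.2)

    def test_rc_range_validated(self):
        with pytest.raises(ValueError):
            classify_rc_pair(1.5, 0.0)

    def test_counts_sum_to_pairs(self, rng):
        presence = rng.random((8, 15)) < 0.5
        presence[:, 0] = True
        t = _table(presence)
        rc1 = raup_crick(t, RCConfig(n_iterations=200, seed=6))
        rc2 = raup_crick(t, RCConfig(n_iterations=200, seed=7))
        comp = compare_rc_matrices(rc1, rc2)
        assert sum(comp.counts.values()) == 8 * 7 // 2


class TestNullCalibration:
    def test_exchangeable_lakes_significant_fraction_near_alpha(self):
        # identical assembly process in every lake: |RC| >= 0.975 should
        # occur for roughly 5% of pairs
        sig, total = 0, 0
        for seed in range(3):
            meta = simulate_metacommunity(TruthConfig(
                n_species=120, n_lakes=12, niche_breadth=None, seed=seed))
            counts = (meta.abundances * 600).astype(int)
            keep = counts.sum(axis=1) > 0
            t = OTUTable([f"s{i}" for i in range(keep.sum())],
                         meta.species_ids, counts[keep])
            rc = raup_crick(t, RCConfig(n_iterations=1000, seed=seed,
                                        share_sample_draws=True))
            vals = rc.condensed()
            sig += (np.abs(vals) >= 0.975).sum()
            total += vals.size
        frac = sig / total
        assert 0.005 <= frac <= 0.12
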