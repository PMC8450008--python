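"""Annotation recovery, Bray-Curtis, Mantel versus exhaustive enumeration,
and OLS versus the closed-form normal equations."""

from __future__ import annotations

from itertools import combinations, permutations
from math import factorial

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats
from skbio import DistanceMatrix
from skbio.stats.distance import mantel as skbio_mantel

from struoforge.evaluate import (
    AbundanceProfile,
    annotation_recovery,
    bray_curtis,
    bray_curtis_matrix,
    mantel,
    ols_r2,
)
from struoforge.fixtures import synth_profiles


def ann_table(pairs):
    return pd.DataFrame(pairs, columns=["gene_id", "uniref90_id"])


class TestRecovery:
    def test_identical_tables_give_full_recovery(self):
        truth = ann_table([(f"g{i}", f"U{i}") for i in range(10)])
        assert annotation_recovery(truth, truth) == (100.0, 100.0)

    def test_empty_test_table_gives_zero(self):
        truth = ann_table([(f"g{i}", f"U{i}") for i in range(10)])
        assert annotation_recovery(truth, ann_table([])) == (0.0, 0.0)

    def test_partial_recovery_counts(self):
        truth = ann_table([(f"g{i}", f"U{i}") for i in range(10)])
        # 8 genes annotated, 6 with the truth id
        rows = [(f"g{i}", f"U{i}") for i in range(6)]
        rows += [(f"g{i}", "U_wrong") for i in range(6, 8)]
        assert annotation_recovery(truth, ann_table(rows)) == (80.0, 60.0)

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            annotation_recovery(ann_table([]), ann_table([("g", "U")]))

    def test_gene_map_redirects_identity(self):
        truth = ann_table([("t1", "UA"), ("t2", "UB")])
        test = ann_table([("x1", "UA"), ("x2", "UA")])
        pa, pc = annotation_recovery(truth, test, {"x1": "t1", "x2": "t2"})
        assert (pa, pc) == (100.0, 50.0)


class TestBrayCurtis:
    def test_identical_profiles_have_zero_distance(self):
        p = AbundanceProfile("a", {"x": 3, "y": 2})
        assert bray_curtis(p, p) == 0.0

    def test_disjoint_taxa_have_distance_one(self):
        assert bray_curtis(
            AbundanceProfile("a", {"x": 5}), AbundanceProfile("b", {"y": 2})
        ) == 1.0

    def test_hand_computed_value(self):
        p = AbundanceProfile("a", {"t1": 2, "t2": 1})
        q = AbundanceProfile("b", {"t1": 1, "t2": 3})
        assert bray_curtis(p, q) == pytest.approx(3 / 7)

    def test_symmetry_and_range_on_random_profiles(self):
        rng = np.random.default_rng(0)
        profiles = synth_profiles(6, 15, 0.5, seed=3)
        for p, q in combinations(profiles, 2):
            d = bray_curtis(p, q)
            assert 0.0 <= d <= 1.0
            assert d == pytest.approx(bray_curtis(q, p))

    def test_all_zero_profiles_rejected(self):
        z = AbundanceProfile("a", {"x": 0.0})
        with pytest.raises(ValueError):
            bray_curtis(z, z)


def _random_dm(rng, n, ids):
    m = rng.uniform(0.1, 1.0, size=(n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0)
    return DistanceMatrix(m, ids)


class TestMantel:
    def test_self_comparison_gives_rho_one(self):
        rng = np.random.default_rng(1)
        d = _random_dm(rng, 5, list("abcde"))
        rho, p = mantel(d, d, n_perm=99, seed=0)
        assert rho == pytest.approx(1.0)
        assert p == pytest.approx(1 / 100, abs=0.05)

    def test_exhaustive_p_matches_bruteforce_enumeration(self):
        rng = np.random.default_rng(2)
        ids = list("abcd")
        d1, d2 = _random_dm(rng, 4, ids), _random_dm(rng, 4, ids)
        rho, p = mantel(d1, d2, exhaustive=True)
        # independent oracle: enumerate all 24 joint relabelings of d2
        iu = np.triu_indices(4, k=1)
        x = d1.data[iu]
        rhos = [
            sp_stats.pearsonr(x, d2.data[np.ix_(perm, perm)][iu])[0]
            for perm in permutations(range(4))
        ]
        expected = sum(r >= rho - 1e-12 for r in rhos) / factorial(4)
        assert p == pytest.approx(expected)

    def test_same_seed_reproduces_result(self):
        rng = np.random.default_rng(3)
        ids = [f"s{i}" for i in range(6)]
        d1, d2 = _random_dm(rng, 6, ids), _random_dm(rng, 6, ids)
        assert mantel(d1, d2, seed=7) == mantel(d1, d2, seed=7)

    def test_p_value_bounds(self):
        rng = np.random.default_rng(4)
        ids = [f"s{i}" for i in range(5)]
        d1, d2 = _random_dm(rng, 5, ids), _random_dm(rng, 5, ids)
        _, p = mantel(d1, d2, n_perm=999, seed=0)
        assert 1 / 1000 <= p <= 1.0

    def test_rho_invariant_under_joint_relabeling(self):
        rng = np.random.default_rng(5)
        ids = [f"s{i}" for i in range(5)]
        d1, d2 = _random_dm(rng, 5, ids), _random_dm(rng, 5, ids)
        rho, _ = mantel(d1, d2, n_perm=9, seed=0)
        perm = [3, 1, 4, 0, 2]
        pids = [ids[i] for i in perm]
        d1p = DistanceMatrix(d1.data[np.ix_(perm, perm)], pids)
        d2p = DistanceMatrix(d2.data[np.ix_(perm, perm)], pids)
        rho_p, _ = mantel(d1p, d2p, n_perm=9, seed=0)
        assert rho_p == pytest.approx(rho)

    def test_agrees_with_skbio_statistic(self):
        rng = np.random.default_rng(6)
        ids = [f"s{i}" for i in range(7)]
        d1, d2 = _random_dm(rng, 7, ids), _random_dm(rng, 7, ids)
        rho, _ = mantel(d1, d2, n_perm=9, seed=0)
        rho_skbio = skbio_mantel(d1, d2, method="pearson", permutations=0)[0]
        assert rho == pytest.approx(float(rho_skbio))

    def test_mismatched_ids_and_tiny_n_rejected(self):
        rng = np.random.default_rng(7)
        d1 = _random_dm(rng, 3, list("abc"))
        d2 = _random_dm(rng, 3, list("abd"))
        with pytest.raises(ValueError, match="ids"):
            mantel(d1, d2)


class TestOLS:
    def test_exact_line_recovered(self):
        x = [0.0, 1.0, 2.0, 3.0]
        y = [1.0, 3.0, 5.0, 7.0]
        slope, intercept, r2 = ols_r2(x, y)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_constant_y_gives_zero_r2(self):
        slope, intercept, r2 = ols_r2([0, 1, 2, 3], [5, 5, 5, 5])
        assert slope == pytest.approx(0.0)
        assert r2 == pytest.approx(0.0)

    def test_matches_normal_equation_oracle(self):
        x = np.array([0.3, 1.1, 2.7, 3.3, 4.9])
        y = np.array([1.2, 0.7, 3.5, 2.9, 5.1])
        # closed form: beta = (X'X)^-1 X'y
        X = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2_oracle = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
        slope, intercept, r2 = ols_r2(x, y)
        assert abs(intercept - beta[0]) < 1e-10
        assert abs(slope - beta[1]) < 1e-10
        assert abs(r2 - r2_oracle) < 1e-10

    def test_constant_x_rejected(self):
        with pytest.raises(ValueError):
            ols_r2([2, 2, 2], [1, 2, 3])


def test_bray_curtis_matrix_is_valid_distance_matrix():
    profiles = synth_profiles(5, 10, 0.2, seed=9)
    dm = bray_curtis_matrix(profiles)
    assert list(dm.ids) == [p.sample_id for p in profiles]
    assert np.allclose(dm.data, dm.data.T)
    assert np.all(np.diag(dm.data) == 0)
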