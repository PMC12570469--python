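"""Richness, rarefaction, Mann-Whitney, Bray-Curtis, NMDS, PERMANOVA."""
import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.spatial.distance import pdist, squareform

from virotu import diversity, simulate


def occ_frame(matrix, samples):
    return pd.DataFrame(
        np.asarray(matrix, dtype=bool),
        index=[f"v{i}" for i in range(len(matrix))],
        columns=samples,
    )


class TestRichness:
    def test_all_false_gives_zeros(self, design24):
        occ = occ_frame(np.zeros((5, 24)), design24["sample_id"])
        out = diversity.richness(occ, design24)
        assert (out["richness"] == 0).all()

    def test_identity_matrix_counts_one_per_sample(self):
        design = simulate.generate_design(1)
        occ = occ_frame(np.eye(6), design["sample_id"])
        out = diversity.richness(occ, design)
        assert (out["richness"] == 1).all()

    def test_matches_brute_force_column_sums(self, design24, rng):
        M = rng.random((40, 24)) < 0.3
        occ = occ_frame(M, design24["sample_id"])
        out = diversity.richness(occ, design24).set_index("sample_id")["richness"]
        for j, s in enumerate(design24["sample_id"]):
            assert out[s] == M[:, j].sum()

    def test_unknown_sample_is_an_error(self, design24):
        occ = occ_frame(np.zeros((2, 1)), ["not_a_sample"])
        with pytest.raises(ValueError, match="not in design"):
            diversity.richness(occ, design24)


class TestRarefaction:
    def test_single_sample_curve_is_its_richness(self):
        occ = occ_frame([[1], [1], [0]], ["s1"])
        curve = diversity.rarefaction(occ, n_permutations=10, seed=0)
        assert curve.mean_richness.tolist() == [2.0]

    def test_disjoint_samples_give_linear_curve(self):
        occ = occ_frame(np.eye(4), [f"s{i}" for i in range(4)])
        curve = diversity.rarefaction(occ, n_permutations=20, seed=1)
        assert np.allclose(curve.mean_richness, [1, 2, 3, 4])
        assert (curve.per_permutation == np.arange(1, 5)).all()

    def test_mean_curve_matches_exhaustive_enumeration(self, rng):
        # 4 samples: enumerate all 24 orderings for the exact mean curve
        M = rng.random((12, 4)) < 0.4
        occ = occ_frame(M, [f"s{i}" for i in range(4)])
        exact = np.zeros(4)
        orders = list(itertools.permutations(range(4)))
        for order in orders:
            seen = np.zeros(12, bool)
            for k, j in enumerate(order):
                seen |= M[:, j]
                exact[k] += seen.sum()
        exact /= len(orders)
        curve = diversity.rarefaction(occ, n_permutations=300, seed=2)
        se = curve.per_permutation.std(axis=0, ddof=1) / math.sqrt(curve.n_permutations)
        assert np.all(np.abs(curve.mean_richness - exact) <= 3 * se + 1e-9)

    def test_mean_curve_non_decreasing_with_total_richness_endpoint(self, default_occ):
        curve = diversity.rarefaction(default_occ, n_permutations=30, seed=3)
        assert (np.diff(curve.mean_richness) >= -1e-12).all()
        assert curve.mean_richness[-1] == default_occ.any(axis=1).sum()


def _mw_exact_oracle(a, b):
    """Two-sided exact Mann-Whitney p by enumerating all group assignments."""
    pooled = np.concatenate([a, b])
    n_a = len(a)
    ranks = pd.Series(pooled).rank().to_numpy()

    def u_stat(idx):
        r = ranks[list(idx)].sum()
        return r - n_a * (n_a + 1) / 2

    u_obs = u_stat(range(n_a))
    us = [u_stat(c) for c in itertools.combinations(range(len(pooled)), n_a)]
    us = np.asarray(us)
    cdf = (us <= u_obs + 1e-12).mean()
    sf = (us >= u_obs - 1e-12).mean()
    return min(1.0, 2 * min(cdf, sf))


class TestMannWhitney:
    def test_complete_separation_exact_p(self):
        res = diversity.mann_whitney([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.method == "exact"
        assert res.U == 0
        assert res.p_value == pytest.approx(2 / 70)

    def test_identical_groups_give_p_one(self):
        res = diversity.mann_whitney([3, 1, 4, 1], [3, 1, 4, 1])
        assert res.p_value == pytest.approx(1.0)

    def test_exact_branch_matches_enumeration_oracle(self, rng):
        for _ in range(5):
            vals = rng.choice(100, size=9, replace=False).astype(float)
            a, b = vals[:4], vals[4:]
            res = diversity.mann_whitney(a, b)
            assert res.method == "exact"
            assert res.p_value == pytest.approx(_mw_exact_oracle(a, b))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            diversity.mann_whitney([], [1, 2])


class TestPairwiseMannWhitney:
    def test_all_cell_pairs_reported(self, design24, rng):
        rich = pd.DataFrame(
            {
                "sample_id": design24["sample_id"],
                "phenotype": design24["phenotype"],
                "compartment": design24["compartment"],
                "richness": rng.integers(10, 100, size=24),
            }
        )
        out = diversity.pairwise_mann_whitney(rich, holm=True)
        assert len(out) == 15  # C(6,2) cell pairs
        assert (out["p_holm"] >= out["p_value"] - 1e-12).all()


class TestBrayCurtis:
    def test_identical_columns_are_zero(self):
        ab = pd.DataFrame({"s1": [1.0, 2.0], "s2": [1.0, 2.0]})
        assert diversity.bray_curtis(ab).loc["s1", "s2"] == 0.0

    def test_disjoint_support_is_one(self):
        ab = pd.DataFrame({"s1": [5.0, 0.0], "s2": [0.0, 3.0]})
        assert diversity.bray_curtis(ab).loc["s1", "s2"] == 1.0

    def test_hand_computed_value(self):
        ab = pd.DataFrame({"x": [2.0, 2.0], "y": [1.0, 3.0]})
        assert diversity.bray_curtis(ab).loc["x", "y"] == pytest.approx(0.25)

    def test_all_zero_pair_reported_as_zero_with_warning(self):
        ab = pd.DataFrame({"s1": [0.0, 0.0], "s2": [0.0, 0.0], "s3": [1.0, 1.0]})
        with pytest.warns(RuntimeWarning, match="all-zero"):
            D = diversity.bray_curtis(ab)
        assert D.loc["s1", "s2"] == 0.0
        assert D.loc["s1", "s3"] == 1.0

    @given(st.integers(0, 2**31 - 1))
    def test_bounds_symmetry_and_scaling_invariance(self, seed):
        rng = np.random.default_rng(seed)
        ab = pd.DataFrame(rng.random((6, 4)) * rng.integers(1, 100))
        D = diversity.bray_curtis(ab)
        V = D.to_numpy()
        assert ((V >= -1e-12) & (V <= 1 + 1e-12)).all()
        assert np.allclose(V, V.T) and np.allclose(np.diag(V), 0)
        D2 = diversity.bray_curtis(ab * 7.5)  # joint scaling of all columns
        assert np.allclose(V, D2.to_numpy())


class TestNmds:
    def planted(self, n=9, seed=5):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(n, 2))
        return pd.DataFrame(squareform(pdist(X)), index=range(n), columns=range(n))

    def test_realizable_configuration_reaches_near_zero_stress(self):
        res = diversity.nmds(self.planted(), k=2, n_restarts=8, seed=0)
        assert res.stress < 0.01

    def test_two_samples_have_zero_stress(self):
        D = pd.DataFrame([[0.0, 0.4], [0.4, 0.0]], index=["a", "b"], columns=["a", "b"])
        res = diversity.nmds(D, seed=1)
        assert res.stress == pytest.approx(0.0, abs=1e-12)

    def test_stress_history_never_increases(self):
        res = diversity.nmds(self.planted(seed=7), n_restarts=3, seed=2)
        assert (np.diff(res.stress_history) <= 1e-12).all()

    def test_non_symmetric_input_rejected(self):
        D = pd.DataFrame([[0.0, 1.0], [0.5, 0.0]])
        with pytest.raises(ValueError, match="symmetric"):
            diversity.nmds(D)

    def test_agrees_with_sklearn_smacof_on_fixture(self):
        from sklearn.manifold import smacof

        D = self.planted(seed=11)
        mine = diversity.nmds(D, n_restarts=8, seed=3)
        _, sk_stress = smacof(
            D.to_numpy(), metric=False, n_components=2, n_init=8, random_state=3,
            normalized_stress=True,
        )
        assert mine.stress == pytest.approx(sk_stress, abs=0.02)


class TestPermanova:
    def clusters(self, sep, seed=0, n=6):
        rng = np.random.default_rng(seed)
        Y = np.vstack([rng.normal(0, 1, (n, 3)), rng.normal(sep, 1, (n, 3))])
        D = pd.DataFrame(squareform(pdist(Y)))
        return D, ["a"] * n + ["b"] * n

    def test_separated_clusters_reach_minimum_p(self):
        # only permutations recreating the observed partition can match F_obs
        # (sampling probability 2*6!*6!/12! ~ 0.002), so p sits at the
        # attainable floor of the permutation distribution
        D, labels = self.clusters(10)
        res = diversity.permanova(D, labels, n_permutations=999, seed=4)
        assert 1 / 1000 <= res.p_value <= 8 / 1000
        assert res.r_squared > 0.9

    def test_p_bounded_below_by_permutation_count(self):
        D, labels = self.clusters(10)
        res = diversity.permanova(D, labels, n_permutations=9, seed=5)
        assert res.p_value >= 1 / 10

    def test_statistic_matches_skbio(self):
        skbio = pytest.importorskip("skbio")
        D, labels = self.clusters(2, seed=6)
        res = diversity.permanova(D, labels, n_permutations=99, seed=7)
        dm = skbio.DistanceMatrix(D.to_numpy(), ids=[str(i) for i in range(12)])
        sk = skbio.stats.distance.permanova(dm, grouping=labels, permutations=9)
        assert res.pseudo_f == pytest.approx(sk["test statistic"])

    def test_exact_enumeration_matches_independent_oracle(self):
        rng = np.random.default_rng(8)
        Y = rng.normal(size=(5, 2))
        D = squareform(pdist(Y))
        labels = ["a", "a", "b", "b", "b"]
        res = diversity.permanova(pd.DataFrame(D), labels, method="exact")

        def f_stat(lab):
            lab = np.asarray(lab)
            n = len(lab)
            sst = (D**2)[np.triu_indices(n, 1)].sum() / n
            ssw = 0.0
            for g in np.unique(lab):
                idx = np.flatnonzero(lab == g)
                ssw += (D**2)[np.ix_(idx, idx)].sum() / (2 * len(idx))
            return ((sst - ssw) / 1) / (ssw / 3)

        f_obs = f_stat(labels)
        labels_arr = np.asarray(labels)
        fs = [
            f_stat(labels_arr[list(p)])
            for p in itertools.permutations(range(5))
        ]
        expected_p = np.mean([f >= f_obs - 1e-12 for f in fs])
        assert res.p_value == pytest.approx(expected_p)

    def test_single_viable_group_rejected(self):
        D = pd.DataFrame(squareform(pdist(np.random.default_rng(0).normal(size=(4, 2)))))
        with pytest.raises(ValueError):
            diversity.permanova(D, ["a", "b", "b", "b"], n_permutations=99)
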