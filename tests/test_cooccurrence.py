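"""Sharing classes, the richness-conserving null model, and chi-square tests."""
import math

import numpy as np
import pandas as pd
import pytest

from virotu import cooccurrence, simulate
from virotu.cooccurrence import (
    _null_replicate_occurrence,
    chi_square_gof,
    classify_compartment_sharing,
    classify_phenotype_sharing,
    exact_null_expectations,
    multi_sample_filter,
    null_model,
)


def occ_frame(matrix, samples):
    return pd.DataFrame(
        np.asarray(matrix, dtype=bool),
        index=[f"v{i}" for i in range(len(matrix))],
        columns=samples,
    )


class TestMultiSampleFilter:
    def test_boundary_at_two_samples(self, design24):
        occ = occ_frame(
            [[1] + [0] * 23, [1, 1] + [0] * 22, [1, 1, 1] + [0] * 21],
            design24["sample_id"],
        )
        kept = multi_sample_filter(occ)
        assert list(kept.index) == ["v1", "v2"]

    def test_matches_brute_force(self, design24, rng):
        M = rng.random((60, 24)) < 0.1
        occ = occ_frame(M, design24["sample_id"])
        kept = set(multi_sample_filter(occ).index)
        brute = {f"v{i}" for i in range(60) if M[i].sum() >= 2}
        assert kept == brute


class TestClassification:
    def test_two_short_samples_is_short_only(self, design24):
        cols = design24["sample_id"]
        row = [s.startswith("short_bulk") for s in cols]
        occ = occ_frame([row], cols)
        counts = classify_phenotype_sharing(occ, design24)
        assert counts["short-only"] == 1 and counts.sum() == 1

    def test_one_short_one_tall_is_both(self, design24):
        cols = list(design24["sample_id"])
        row = [s in ("short_bulk_r1", "tall_root_r2") for s in cols]
        occ = occ_frame([row], cols)
        counts = classify_phenotype_sharing(occ, design24)
        assert counts["both-phenotypes"] == 1

    def test_rhizosphere_and_root_class(self, design24):
        cols = list(design24["sample_id"])
        row = [s in ("short_rhizosphere_r1", "tall_root_r1") for s in cols]
        occ = occ_frame([row], cols)
        counts = classify_compartment_sharing(occ, design24)
        assert counts["rhizosphere+root"] == 1

    def test_all_three_compartments(self, design24):
        cols = list(design24["sample_id"])
        row = [s in ("short_bulk_r1", "short_rhizosphere_r1", "short_root_r1") for s in cols]
        occ = occ_frame([row], cols)
        assert classify_compartment_sharing(occ, design24)["all-three"] == 1

    def test_matches_brute_force_set_computation(self, design24, rng):
        M = rng.random((80, 24)) < 0.15
        occ = multi_sample_filter(occ_frame(M, design24["sample_id"]))
        pheno = classify_phenotype_sharing(occ, design24)
        comp = classify_compartment_sharing(occ, design24)
        labels = design24.set_index("sample_id")
        brute_p = {k: 0 for k in pheno.index}
        brute_c = {k: 0 for k in comp.index}
        from virotu.design import compartment_class, phenotype_class

        for _, row in occ.iterrows():
            samples = row.index[row]
            brute_p[phenotype_class(set(labels.loc[samples, "phenotype"]))] += 1
            brute_c[compartment_class(set(labels.loc[samples, "compartment"]))] += 1
        assert pheno.to_dict() == brute_p
        assert comp.to_dict() == brute_c

    def test_classification_partitions_n_multi(self, design24, default_occ):
        res = cooccurrence.sharing_class_counts(default_occ, design24)
        assert res.phenotype.sum() == res.n_multi
        assert res.compartment.sum() == res.n_multi


class TestNullModel:
    def two_sample_design(self):
        d = simulate.generate_design(1)
        return d[d["sample_id"].isin(["short_bulk_r1", "tall_bulk_r1"])].reset_index(drop=True)

    def test_replicates_conserve_sample_richness(self, design24, rng):
        rich = rng.integers(0, 20, size=24)
        for _ in range(20):
            M = _null_replicate_occurrence(rng, 50, rich, "per_sample", None)
            assert (M.sum(axis=0) == rich).all()

    def test_per_cell_mode_conserves_richness_without_within_cell_repeats(self, design24, rng):
        rich = rng.integers(0, 5, size=24)
        cells = (design24["phenotype"] + "|" + design24["compartment"]).to_numpy()
        _, cell = np.unique(cells, return_inverse=True)
        M = _null_replicate_occurrence(rng, 100, rich, "per_cell", cell)
        assert (M.sum(axis=0) == rich).all()
        for c in np.unique(cell):
            sub = M[:, cell == c]
            assert sub.sum(axis=1).max() <= 1  # no vOTU twice within a cell

    def test_collision_free_limit_yields_no_multi_sample_votus(self):
        design = self.two_sample_design()
        occ = occ_frame([[1, 0], [0, 1]], design["sample_id"])
        res = null_model(
            occ, design, "phenotype", n_replicates=200, seed=1, catalog_size=100_000
        )
        assert res.replicate_counts.to_numpy().sum() <= 1  # collisions vanishingly rare

    def test_shared_probability_matches_closed_form(self):
        # 2 samples, catalog 3, richness 1 each: P(shared vOTU) = 1/3
        design = self.two_sample_design()
        occ = occ_frame([[1, 0], [0, 1], [0, 0]], design["sample_id"])
        res = null_model(occ, design, "phenotype", n_replicates=10_000, seed=2, catalog_size=3)
        shared = res.replicate_counts.sum(axis=1).to_numpy()
        se = shared.std(ddof=1) / math.sqrt(len(shared))
        assert abs(shared.mean() - 1 / 3) < 3 * se

    def test_monte_carlo_matches_exact_enumeration(self):
        design = simulate.generate_design(1)
        rich = {s: r for s, r in zip(design["sample_id"], [1, 2, 1, 0, 1, 0])}
        catalog = 4
        occ = occ_frame(np.zeros((catalog, 6)), design["sample_id"])
        M = occ.to_numpy()
        M[0, 0] = M[0, 1] = M[1, 1] = M[2, 2] = M[3, 4] = True
        occ = occ_frame(M, design["sample_id"])
        for classification in ("phenotype", "compartment"):
            exact = exact_null_expectations(rich, catalog, design, classification)
            res = null_model(
                occ, design, classification, n_replicates=10_000, seed=3, catalog_size=catalog
            )
            counts = res.replicate_counts.to_numpy()
            se = counts.std(axis=0, ddof=1) / math.sqrt(counts.shape[0])
            diff = np.abs(counts.mean(axis=0) - exact.expected_counts.to_numpy())
            assert np.all(diff <= 3 * se + 1e-9)

    def test_richness_exceeding_catalog_rejected(self):
        design = self.two_sample_design()
        occ = occ_frame(np.ones((5, 2)), design["sample_id"])
        with pytest.raises(ValueError, match="catalog"):
            null_model(occ, design, "phenotype", n_replicates=10, catalog_size=3)

    def test_zero_replicates_rejected(self, design24, default_occ):
        with pytest.raises(ValueError):
            null_model(default_occ, design24, "phenotype", n_replicates=0)


class TestExactNullExpectations:
    def test_two_samples_richness_one_catalog_three(self):
        design = simulate.generate_design(1)
        d2 = design[design["sample_id"].isin(["short_bulk_r1", "tall_bulk_r1"])].reset_index(
            drop=True
        )
        res = exact_null_expectations(
            {"short_bulk_r1": 1, "tall_bulk_r1": 1}, 3, d2, "phenotype"
        )
        assert res.expected_n_multi == pytest.approx(1 / 3)
        assert res.proportions["both-phenotypes"] == pytest.approx(1.0)

    def test_single_sample_design_is_always_empty(self):
        design = simulate.generate_design(1).iloc[[0]].reset_index(drop=True)
        res = exact_null_expectations({"short_bulk_r1": 2}, 5, design, "phenotype")
        assert res.expected_n_multi == 0.0

    def test_symmetric_design_gives_symmetric_phenotype_proportions(self):
        design = simulate.generate_design(1)
        rich = {s: 1 for s in design["sample_id"]}
        res = exact_null_expectations(rich, 3, design, "phenotype")
        assert res.proportions["short-only"] == pytest.approx(res.proportions["tall-only"])

    def test_combinatorial_guard_refuses_large_instances(self, design24):
        rich = {s: 10 for s in design24["sample_id"]}
        with pytest.raises(ValueError, match="refusing"):
            exact_null_expectations(rich, 100, design24, "phenotype")


class TestChiSquareGof:
    def test_observed_proportional_to_expected_is_null(self):
        res = chi_square_gof([20, 30, 50], [0.2, 0.3, 0.5])
        assert res.chi2 == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_statistic(self):
        res = chi_square_gof([10, 20, 30], [1 / 3, 1 / 3, 1 / 3])
        assert res.chi2 == pytest.approx(10.0)
        assert res.df == 2

    def test_expected_zero_with_observed_zero_dropped_from_df(self):
        res = chi_square_gof([10, 10, 0], [0.5, 0.5, 0.0])
        assert res.df == 1
        assert not res.infinite

    def test_expected_zero_with_observed_positive_flagged_infinite(self):
        res = chi_square_gof([10, 10, 5], [0.5, 0.5, 0.0])
        assert res.infinite and math.isinf(res.chi2) and res.p_value == 0.0

    def test_small_expected_counts_warn(self):
        with pytest.warns(RuntimeWarning, match="below 5"):
            chi_square_gof([3, 4], [0.5, 0.5])

    def test_rejects_proportions_not_summing_to_one(self):
        with pytest.raises(ValueError):
            chi_square_gof([5, 5], [0.7, 0.7])
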