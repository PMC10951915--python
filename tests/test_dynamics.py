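"""Normalization, clustering, correlation, and ranking of temporal profiles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from embryoprot import (
    aggregate_isoform_tpm,
    co_cluster_orthologs,
    expressed_flags,
    fold_change,
    kmeans_profiles,
    median_normalize,
    rna_protein_correlation,
    stage_transition_ranking,
    sum_to_one,
)
from embryoprot.dynamics import ProfileSet
from embryoprot.errors import (
    InvalidInputError,
    InvalidParameterError,
)
from embryoprot.io import ExpressionMatrix
from embryoprot.orthology import OrthologMap


def matrix_from(values, columns=None, modality="protein_relative"):
    arr = np.asarray(values, dtype=float)
    columns = columns or [f"s{i + 1}" for i in range(arr.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(arr, columns=columns,
                     index=[f"g{i + 1}" for i in range(arr.shape[0])]),
        modality=modality,
    )


class TestMedianNormalize:
    def test_hand_computed_scale_factors(self):
        # column medians [1, 2, 4]; grand median of all 9 values is 2
        m = matrix_from([[0.5, 1, 2], [1, 2, 4], [2, 4, 8]])
        out = median_normalize(m)
        np.testing.assert_allclose(out.values.median(axis=0), [2, 2, 2])
        np.testing.assert_allclose(
            out.values.to_numpy()[1], [2, 2, 2],  # row at column medians
        )

    def test_equal_medians_unchanged(self):
        m = matrix_from([[1, 1], [2, 2], [3, 3]])
        out = median_normalize(m)
        np.testing.assert_allclose(out.values.to_numpy(), m.values.to_numpy())

    def test_single_column_unchanged(self):
        m = matrix_from([[1], [2], [3]])
        np.testing.assert_allclose(
            median_normalize(m).values.to_numpy(), m.values.to_numpy(),
        )

    def test_all_zero_column_rejected_naming_stage(self):
        m = matrix_from([[1, 0], [2, 0]])
        with pytest.raises(InvalidInputError, match="s2"):
            median_normalize(m)

    def test_column_medians_equalized_after_rescaled_input(self, rng):
        m = matrix_from(10.0 ** rng.uniform(0, 3, size=(40, 6)))
        rescaled = ExpressionMatrix(
            m.values * rng.uniform(0.1, 10, 6), modality=m.modality,
        )
        out = median_normalize(rescaled)
        medians = out.values.median(axis=0).to_numpy()
        np.testing.assert_allclose(medians, medians[0])


class TestSumToOne:
    def test_constant_profile_over_eight_stages(self):
        ps = sum_to_one(matrix_from([[3.0] * 8]))
        np.testing.assert_allclose(ps.values.to_numpy(), 0.125)

    def test_zeros_preserved(self):
        ps = sum_to_one(matrix_from([[2, 0, 2]]))
        np.testing.assert_allclose(ps.values.to_numpy()[0], [0.5, 0, 0.5])

    def test_all_zero_row_dropped(self):
        ps = sum_to_one(matrix_from([[1, 1], [0, 0]]))
        assert list(ps.values.index) == ["g1"]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_rows_sum_to_one_and_idempotence(self, seed):
        rng = np.random.default_rng(seed)
        m = matrix_from(rng.uniform(0, 5, size=(12, 6)) + 1e-3)
        once = sum_to_one(m)
        assert np.allclose(once.values.sum(axis=1), 1.0, atol=1e-9)
        twice = sum_to_one(once)
        np.testing.assert_allclose(
            twice.values.to_numpy(), once.values.to_numpy(), atol=1e-12,
        )


class TestRnaProteinCorrelation:
    def test_identical_and_reversed_profiles(self):
        rna = sum_to_one(matrix_from([[1, 2, 3], [1, 2, 3]]))
        prot = sum_to_one(matrix_from([[1, 2, 3], [3, 2, 1]]))
        records, median_r = rna_protein_correlation(rna, prot)
        by_id = records.set_index("rna_id")["r"]
        assert by_id["g1"] == pytest.approx(1.0)
        assert by_id["g2"] == pytest.approx(-1.0)
        assert median_r == pytest.approx(0.0, abs=1e-12)

    def test_target_correlation_recovered_in_simulation(self, rng):
        # bivariate normal profiles with rho = 0.5, n = 2000 pairs
        n, stages, rho = 2000, 8, 0.5
        shared = rng.normal(size=(n, stages))
        x = shared
        y = rho * shared + np.sqrt(1 - rho**2) * rng.normal(size=(n, stages))
        rna = ProfileSet(pd.DataFrame(
            x - x.min() + 0.1, index=[f"g{i}" for i in range(n)],
        ))
        prot = ProfileSet(pd.DataFrame(
            y - y.min() + 0.1, index=[f"g{i}" for i in range(n)],
        ))
        _, median_r = rna_protein_correlation(rna, prot)
        assert abs(median_r - rho) < 0.05

    def test_independent_profiles_center_on_zero(self, rng):
        n = 2000
        rna = ProfileSet(pd.DataFrame(
            rng.uniform(0, 1, size=(n, 8)), index=[f"g{i}" for i in range(n)],
        ))
        prot = ProfileSet(pd.DataFrame(
            rng.uniform(0, 1, size=(n, 8)), index=[f"g{i}" for i in range(n)],
        ))
        _, median_r = rna_protein_correlation(rna, prot)
        assert abs(median_r) < 0.05

    def test_zero_variance_pairs_excluded(self):
        rna = ProfileSet(pd.DataFrame([[1.0, 1.0, 1.0], [1, 2, 3]],
                                      index=["g1", "g2"]))
        prot = ProfileSet(pd.DataFrame([[1.0, 2.0, 3.0], [1, 2, 3]],
                                       index=["g1", "g2"]))
        records, _ = rna_protein_correlation(rna, prot)
        assert list(records["rna_id"]) == ["g2"]


class TestKmeans:
    def test_two_separated_groups_recovered(self, rng):
        up = np.linspace(0.0, 1.0, 8) + rng.normal(0, 0.01, size=(30, 8))
        down = np.linspace(1.0, 0.0, 8) + rng.normal(0, 0.01, size=(20, 8))
        profiles = ProfileSet(pd.DataFrame(
            np.vstack([up, down]), index=[f"g{i}" for i in range(50)],
        ))
        model = kmeans_profiles(profiles, k=2, n_restarts=20, seed=1)
        labels = model.assignments
        assert labels.iloc[:30].nunique() == 1
        assert labels.iloc[30:].nunique() == 1
        assert labels.iloc[0] != labels.iloc[-1]
        # cluster 0 is the larger group
        assert labels.iloc[0] == 0

    def test_k_equals_n_gives_zero_within_ss(self, rng):
        profiles = ProfileSet(pd.DataFrame(
            rng.uniform(size=(6, 4)), index=[f"g{i}" for i in range(6)],
        ))
        model = kmeans_profiles(profiles, k=6, n_restarts=5, seed=0)
        assert model.total_within_ss == pytest.approx(0.0, abs=1e-12)

    def test_best_of_restarts_no_worse_than_single_restart(self, rng):
        profiles = ProfileSet(pd.DataFrame(
            rng.uniform(size=(40, 6)), index=[f"g{i}" for i in range(40)],
        ))
        multi = kmeans_profiles(profiles, k=4, n_restarts=30, seed=3)
        single = kmeans_profiles(profiles, k=4, n_restarts=1, seed=3)
        assert multi.total_within_ss <= single.total_within_ss + 1e-9

    def test_reproducible_and_k_monotone(self, rng):
        profiles = ProfileSet(pd.DataFrame(
            rng.uniform(size=(30, 5)), index=[f"g{i}" for i in range(30)],
        ))
        a = kmeans_profiles(profiles, k=3, n_restarts=10, seed=7)
        b = kmeans_profiles(profiles, k=3, n_restarts=10, seed=7)
        pd.testing.assert_series_equal(a.assignments, b.assignments)
        assert a.total_within_ss == b.total_within_ss
        more = kmeans_profiles(profiles, k=5, n_restarts=10, seed=7)
        assert more.total_within_ss <= a.total_within_ss + 1e-9

    def test_k_larger_than_entities_rejected(self, rng):
        profiles = ProfileSet(pd.DataFrame(
            rng.uniform(size=(3, 4)), index=["a", "b", "c"],
        ))
        with pytest.raises(InvalidParameterError):
            kmeans_profiles(profiles, k=4)


class TestCoClusterOrthologs:
    def _pair_profiles(self, rng, n_per_group=15):
        up = np.linspace(0.05, 0.3, 8)
        down = up[::-1]
        rows_a, rows_b, pairs = [], [], []
        for i in range(2 * n_per_group):
            base = up if i < n_per_group else down
            noise = rng.normal(0, 0.002, 8)
            rows_a.append(base + noise)
            rows_b.append(base + noise)
            pairs.append((f"a{i}", f"b{i}"))
        ids_a = [p[0] for p in pairs]
        ids_b = [p[1] for p in pairs]
        pa = sum_to_one(matrix_from(rows_a))
        pb = sum_to_one(matrix_from(rows_b))
        pa.values.index = ids_a
        pb.values.index = ids_b
        return pa, pb, OrthologMap.from_pairs(pairs), n_per_group

    def test_two_temporal_programs_recovered(self, rng):
        pa, pb, omap, n = self._pair_profiles(rng)
        model = co_cluster_orthologs(pa, pb, omap, k=2, n_restarts=20, seed=2)
        labels = model.assignments
        assert labels.iloc[:n].nunique() == 1
        assert labels.iloc[n:].nunique() == 1
        assert set(labels) == {0, 1}

    def test_k1_centroid_is_mean_concatenated_profile(self, rng):
        pa, pb, omap, _ = self._pair_profiles(rng)
        model = co_cluster_orthologs(pa, pb, omap, k=1, n_restarts=3, seed=0)
        expected = np.concatenate([
            pa.values.to_numpy().mean(axis=0), pb.values.to_numpy().mean(axis=0),
        ])
        np.testing.assert_allclose(
            model.centroids.iloc[0].to_numpy(), expected, atol=1e-12,
        )

    def test_empty_map_rejected(self, rng):
        pa, pb, _, _ = self._pair_profiles(rng)
        with pytest.raises(InvalidParameterError):
            co_cluster_orthologs(pa, pb, OrthologMap.from_pairs([]), k=2)

    def test_requires_sum_to_one_profiles(self, rng):
        pa, pb, omap, _ = self._pair_profiles(rng)
        raw = ProfileSet(pa.values * 2, normalization="raw")
        with pytest.raises(InvalidParameterError):
            co_cluster_orthologs(raw, pb, omap, k=2)


class TestFoldChange:
    def test_worked_examples(self, small_matrix):
        fc = fold_change(small_matrix, "larva", "unfE")
        assert fc.loc["g1", "FC"] == pytest.approx(4.0)
        assert fc.loc["g1", "log2FC"] == pytest.approx(2.0)

    def test_equal_values_give_unity(self):
        m = matrix_from([[2.0, 2.0]])
        fc = fold_change(m, "s1", "s2")
        assert fc.loc["g1", "FC"] == 1.0 and fc.loc["g1", "log2FC"] == 0.0

    def test_swap_inverts(self, small_matrix, rng):
        fwd = fold_change(small_matrix, "larva", "unfE")["FC"]
        rev = fold_change(small_matrix, "unfE", "larva")["FC"]
        np.testing.assert_allclose(fwd * rev, 1.0)

    def test_unknown_stage_rejected(self, small_matrix):
        with pytest.raises(InvalidParameterError):
            fold_change(small_matrix, "larva", "juvenile")


class TestStageTransitionRanking:
    def test_doubling_entity_ranks_first(self):
        m = matrix_from([[1, 1, 1], [1, 2, 2], [1, 1, 1]])
        ranks = stage_transition_ranking(sum_to_one_free(m))
        top = ranks[("s1", "s2")].iloc[0]
        assert top["entity_id"] == "g2"

    def test_flat_matrix_ties_in_id_order(self):
        m = matrix_from([[1, 1], [1, 1], [1, 1]])
        tbl = stage_transition_ranking(sum_to_one_free(m))[("s1", "s2")]
        assert list(tbl["entity_id"]) == ["g1", "g2", "g3"]

    def test_scores_match_brute_force(self, rng):
        vals = rng.uniform(0, 10, size=(20, 5))
        vals[vals < 1] = 0.0
        m = matrix_from(vals)
        eps = vals[vals > 0].min() * 0.5
        result = stage_transition_ranking(sum_to_one_free(m))
        for j, key in enumerate(result):
            tbl = result[key].set_index("entity_id")
            for i in range(20):
                expected = abs(np.log2((vals[i, j + 1] + eps) / (vals[i, j] + eps)))
                assert tbl.loc[f"g{i + 1}", "abs_log2_ratio"] == pytest.approx(expected)


def sum_to_one_free(matrix):
    """Wrap a matrix as a raw ProfileSet without renormalizing."""
    return ProfileSet(matrix.values, normalization="raw")


class TestTpmHelpers:
    def test_isoform_tpms_summed(self):
        m = matrix_from([[3, 1], [7, 2], [5, 5]], modality="rna_tpm")
        gene = aggregate_isoform_tpm(
            m, {"g1": "G", "g2": "G", "g3": "H"},
        )
        assert gene.values.loc["G"].tolist() == [10, 3]
        assert gene.values.loc["H"].tolist() == [5, 5]

    def test_column_sums_preserved(self, rng):
        vals = rng.uniform(0, 50, size=(30, 4))
        m = matrix_from(vals, modality="rna_tpm")
        mapping = {f"g{i + 1}": f"G{i % 7}" for i in range(30)}
        gene = aggregate_isoform_tpm(m, mapping)
        np.testing.assert_allclose(
            gene.values.sum(axis=0), m.values.sum(axis=0),
        )

    def test_unmapped_transcript_rejected(self):
        m = matrix_from([[1, 2]], modality="rna_tpm")
        with pytest.raises(InvalidInputError, match="g1"):
            aggregate_isoform_tpm(m, {})

    def test_expressed_threshold_inclusive_and_missing_false(self):
        df = pd.DataFrame(
            {"s1": [2.0, 1.999, np.nan]}, index=["a", "b", "c"],
        )
        m = ExpressionMatrix(df, modality="rna_tpm")
        flags = expressed_flags(m, threshold=2.0)
        assert flags.loc["a", "s1"] and not flags.loc["b", "s1"]
        assert not flags.loc["c", "s1"]

    def test_threshold_zero_flags_all_nonmissing(self):
        m = matrix_from([[0.0, 0.5]], modality="rna_tpm")
        assert expressed_flags(m, threshold=0.0).all(axis=None)
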