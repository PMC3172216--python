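"""Centroid construction, sample scoring, subset contrast, concordance,
clustering, and signature overlap."""

import math

import numpy as np
import pandas as pd
import pytest

from persig import (
    Centroid,
    GeneSignature,
    InputError,
    build_centroid,
    cluster_samples,
    compare_subsets,
    concordance_fractions,
    overlap_signatures,
    score_samples,
)

from conftest import make_dataset


def signature_from(genes_weights):
    entries = pd.DataFrame(
        {
            "direction": [int(np.sign(w)) for w in genes_weights.values()],
            "weight": list(genes_weights.values()),
        },
        index=list(genes_weights),
    )
    return GeneSignature("sig", entries)


SIG3 = signature_from({"GA": 1.0, "GB": -1.0, "GC": 2.0})


def cohort_from(columns, genes=("GA", "GB", "GC"), subset=None):
    values = {k: list(v) for k, v in columns.items()}
    df = pd.DataFrame(values, index=list(genes), dtype=float)
    ann = None
    if subset is not None:
        ann = pd.DataFrame({"subset": subset}, index=df.columns)
    from persig import ExpressionDataset

    return ExpressionDataset(df, "log-ratio", ann)


class TestBuildCentroid:
    def test_full_coverage(self):
        cohort = cohort_from({"s1": [0.1, 0.2, 0.3], "s2": [0.0, 0.1, 0.2]})
        cent = build_centroid(SIG3, cohort)
        assert cent.coverage == 1.0
        np.testing.assert_allclose(cent.values, [1.0, -1.0, 2.0])

    def test_sign_mode_unit_weights(self):
        cohort = cohort_from({"s1": [0.1, 0.2, 0.3], "s2": [0.4, 0.2, 0.1]})
        cent = build_centroid(SIG3, cohort, weighting="sign")
        assert set(np.abs(cent.values)) == {1.0}

    def test_partial_coverage_reported(self):
        cohort = cohort_from({"s1": [0.1, 0.3], "s2": [0.2, 0.1]}, genes=("GA", "GC"))
        cent = build_centroid(SIG3, cohort)
        assert cent.coverage == pytest.approx(2 / 3)
        assert cent.genes == ["GA", "GC"]

    def test_too_few_matches_rejected(self):
        cohort = cohort_from({"s1": [0.1], "s2": [0.2]}, genes=("GA",))
        with pytest.raises(InputError, match="matched"):
            build_centroid(SIG3, cohort)

    def test_duplicate_rows_collapsed_by_iqr(self):
        values = pd.DataFrame(
            [[0.0, 1.0, 2.0, 3.0], [0.0, 10.0, 20.0, 30.0], [1.0, 1.0, 1.5, 1.2]],
            index=["GA", "GA", "GB"],
            columns=["s1", "s2", "s3", "s4"],
        )
        from persig import score_samples as _  # noqa: F401
        from persig.projection import _collapse_by_iqr

        collapsed = _collapse_by_iqr(values)
        assert list(collapsed.index) == ["GA", "GB"]
        assert collapsed.loc["GA", "s4"] == 30.0


class TestScoreSamples:
    def test_proportional_column_scores_one(self):
        cent = Centroid(["GA", "GB", "GC"], np.array([1.0, -1.0, 2.0]), 1.0)
        cohort = cohort_from({"s1": [0.5, -0.5, 1.0], "s2": [3.0, 1.0, 2.0]})
        out = score_samples(cent, cohort, center_genes=False)
        assert out.loc["s1", "score"] == pytest.approx(1.0)

    def test_negated_column_scores_minus_one(self):
        cent = Centroid(["GA", "GB", "GC"], np.array([1.0, -1.0, 2.0]), 1.0)
        cohort = cohort_from({"s1": [-1.0, 1.0, -2.0], "s2": [0.0, 0.2, 0.1]})
        out = score_samples(cent, cohort, center_genes=False)
        assert out.loc["s1", "score"] == pytest.approx(-1.0)

    def test_hand_pearson(self):
        cent = Centroid(["GA", "GB", "GC"], np.array([1.0, -1.0, 2.0]), 1.0)
        cohort = cohort_from({"s1": [0.0, 1.0, 2.0], "s2": [1.0, 0.0, 1.0]})
        out = score_samples(cent, cohort, center_genes=False)
        assert out.loc["s1", "score"] == pytest.approx(3 / math.sqrt(84), abs=1e-10)

    def test_affine_invariance_of_scores(self, rng):
        cent = Centroid(
            [f"G{i}" for i in range(20)], rng.standard_normal(20), 1.0
        )
        base = rng.standard_normal(20)
        cohort = cohort_from(
            {"plain": base, "scaled": 3.5 * base + 2.0},
            genes=[f"G{i}" for i in range(20)],
        )
        out = score_samples(cent, cohort, center_genes=False)
        assert out.loc["plain", "score"] == pytest.approx(
            out.loc["scaled", "score"], abs=1e-12
        )

    def test_na_genes_dropped_pairwise(self):
        cent = Centroid(["GA", "GB", "GC"], np.array([1.0, -1.0, 2.0]), 1.0)
        cohort = cohort_from({"s1": [0.5, np.nan, 1.0], "s2": [1.0, 2.0, 3.0]})
        out = score_samples(cent, cohort, center_genes=False)
        assert out.loc["s1", "n_genes_used"] == 2
        assert np.isfinite(out.loc["s1", "score"])

    def test_undefined_score_is_na(self):
        cent = Centroid(["GA", "GB", "GC"], np.array([1.0, -1.0, 2.0]), 1.0)
        cohort = cohort_from({"s1": [np.nan, np.nan, 1.0], "s2": [1.0, 2.0, 3.0]})
        out = score_samples(cent, cohort, center_genes=False)
        assert np.isnan(out.loc["s1", "score"])


class TestCompareSubsets:
    def test_identical_distributions_zero_difference(self):
        scores = pd.Series([0.1, 0.2, 0.1, 0.2], index=list("abcd"))
        labels = pd.Series(["t", "t", "r", "r"], index=list("abcd"))
        res = compare_subsets(scores, labels, target_subsets=("t",))
        assert res.difference == pytest.approx(0.0)

    def test_hand_welch(self):
        scores = pd.Series([0.1, 0.3, -0.2, 0.0], index=list("abcd"))
        labels = pd.Series(["t", "t", "r", "r"], index=list("abcd"))
        res = compare_subsets(scores, labels, target_subsets=("t",))
        assert res.target_mean == pytest.approx(0.2)
        assert res.rest_mean == pytest.approx(-0.1)
        assert res.t_stat == pytest.approx(0.3 / math.sqrt(0.02 / 2 + 0.02 / 2),
                                           abs=1e-4)

    def test_zero_variance_underflows_to_minimum_p(self):
        # exactly representable values so the group SDs are exactly zero
        scores = pd.Series([0.25, 0.25, 0.25, -0.125, -0.125, -0.125],
                           index=list("abcdef"))
        labels = pd.Series(["t"] * 3 + ["r"] * 3, index=list("abcdef"))
        res = compare_subsets(scores, labels, target_subsets=("t",))
        assert res.difference == pytest.approx(0.375)
        assert res.target_sd == 0.0 and res.rest_sd == 0.0
        assert 0 < res.p_value <= 1e-300

    def test_degenerate_group_rejected(self):
        scores = pd.Series([0.1, 0.2, 0.3], index=list("abc"))
        labels = pd.Series(["t", "r", "r"], index=list("abc"))
        with pytest.raises(InputError):
            compare_subsets(scores, labels, target_subsets=("t",))


class TestConcordance:
    def test_noise_free_target_subset_fully_concordant(self):
        sig = signature_from({"GA": 1.5, "GB": -1.2})
        cohort = cohort_from(
            {"d1": [2.0, -2.0], "d2": [2.0, -2.0], "o1": [0.0, 0.0],
             "o2": [0.0, 0.0], "o3": [0.0, 0.0]},
            genes=("GA", "GB"),
            subset=["diffuse", "diffuse", "other", "other", "other"],
        )
        frac = concordance_fractions(sig, cohort)
        assert frac["diffuse"] == 1.0

    def test_hand_sign_count(self):
        sig = signature_from({f"G{i}": 1.0 for i in range(5)})
        # subset means (+, -, +, +, -) after centering -> 3/5 concordant
        cols = {
            "a": [1.0, -1.0, 1.0, 1.0, -1.0],
            "b": [1.0, -1.0, 1.0, 1.0, -1.0],
            "o1": [0.0] * 5,
            "o2": [0.0] * 5,
            "o3": [0.0] * 5,
        }
        cohort = cohort_from(cols, genes=[f"G{i}" for i in range(5)],
                             subset=["s", "s", "o", "o", "o"])
        frac = concordance_fractions(sig, cohort)
        assert frac["s"] == pytest.approx(3 / 5)

    def test_zero_means_not_concordant_under_strict_sign_rule(self):
        sig = signature_from({"GA": 1.0, "GB": 1.0})
        cohort = cohort_from(
            {"a": [0.0, 0.0], "b": [0.0, 0.0], "c": [0.0, 0.0]},
            genes=("GA", "GB"), subset=["s", "s", "o"],
        )
        frac = concordance_fractions(sig, cohort, center_genes=False)
        assert frac["s"] == 0.0

    def test_null_band_excludes_small_shifts(self):
        sig = signature_from({"GA": 1.0, "GB": 1.0})
        cohort = cohort_from(
            {"a": [0.2, 2.0], "b": [0.2, 2.0], "c": [0.0, 0.0],
             "d": [0.0, 0.0], "e": [0.0, 0.0]},
            genes=("GA", "GB"), subset=["s", "s", "o", "o", "o"],
        )
        assert concordance_fractions(sig, cohort)["s"] == 1.0
        assert concordance_fractions(sig, cohort, null_band=0.5)["s"] == 0.5


class TestClusterSamples:
    def test_identical_samples_merge_at_zero(self):
        cohort = cohort_from(
            {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0], "c": [3.0, 1.0, 2.0]}
        )
        tree = cluster_samples(cohort, center_genes=False)
        assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_sample_merges_at_two(self):
        base = [1.0, 2.0, 3.0, 1.5]
        cohort = cohort_from(
            {"a": base, "b": base, "c": [-x for x in base]},
            genes=[f"G{i}" for i in range(4)],
        )
        tree = cluster_samples(cohort, center_genes=False)
        assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert tree.linkage[1, 2] == pytest.approx(2.0, abs=1e-12)

    def test_permutation_leaves_merge_heights_unchanged(self, rng):
        data = rng.standard_normal((10, 6))
        genes = [f"G{i}" for i in range(10)]
        cols = [f"s{j}" for j in range(6)]
        c1 = cohort_from({c: data[:, j] for j, c in enumerate(cols)}, genes=genes)
        perm = [3, 0, 5, 1, 4, 2]
        c2 = cohort_from({cols[j]: data[:, j] for j in perm}, genes=genes)
        t1 = cluster_samples(c1, center_genes=False)
        t2 = cluster_samples(c2, center_genes=False)
        np.testing.assert_allclose(
            np.sort(t1.linkage[:, 2]), np.sort(t2.linkage[:, 2]), atol=1e-12
        )

    def test_constant_sample_rejected_by_name(self):
        cohort = cohort_from(
            {"a": [1.0, 2.0, 3.0], "flat": [5.0, 5.0, 5.0], "c": [0.0, 1.0, 0.5]}
        )
        with pytest.raises(InputError, match="flat"):
            cluster_samples(cohort, center_genes=False)

    def test_newick_contains_all_leaves(self):
        cohort = cohort_from(
            {"a": [1.0, 2.0, 3.0], "b": [1.1, 2.0, 2.9], "c": [3.0, 1.0, 2.0]}
        )
        nwk = cluster_samples(cohort, center_genes=False).to_newick()
        assert nwk.endswith(";")
        for leaf in ("a", "b", "c"):
            assert leaf in nwk


class TestOverlapSignatures:
    def test_identical_signatures(self):
        sig = signature_from({"GA": 1.0, "GB": -1.0})
        rep = overlap_signatures(sig, sig)
        assert rep.intersection == 2
        assert rep.discordant == 0

    def test_disjoint_signatures(self):
        a = signature_from({"GA": 1.0})
        b = signature_from({"GB": 1.0})
        # pad to >=1 entries each; intersection empty
        rep = overlap_signatures(a, b)
        assert rep.intersection == 0
        assert rep.only_a == ["GA"] and rep.only_b == ["GB"]

    def test_hand_partition(self):
        a = signature_from({"G1": 1.0, "G2": 1.0, "G3": -1.0})
        b = signature_from({"G2": 1.0, "G3": 1.0, "G4": -1.0})
        rep = overlap_signatures(a, b)
        assert rep.intersection == 2
        assert rep.concordant_up == 1 and rep.concordant_up_genes == ["G2"]
        assert rep.discordant == 1 and rep.discordant_genes == ["G3"]
        assert rep.concordant_down == 0

    def test_partition_counts_sum_to_intersection(self, late_results):
        sig48 = late_results.derive_signature(name="48h")
        sig_loose = late_results.derive_signature(fdr=0.05, fold=1.5, name="loose")
        rep = overlap_signatures(sig48, sig_loose)
        assert (
            rep.concordant_up + rep.concordant_down + rep.discordant
            == rep.intersection
        )
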