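"""TPM normalization, enrichment calls, clustering and PCA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from pollenmir.expression import (call_enrichment, kmeans_profiles,
                                  pca_samples, to_tpm)

LIBS = ["UNM", "BCP", "TCP", "callus", "leaf", "root"]


def _mat(rows, index=None):
    return pd.DataFrame(rows, columns=LIBS,
                        index=index or [f"m{i}" for i in range(len(rows))])


class TestTpm:
    def test_basic_formula(self):
        counts = _mat([[100, 10, 0, 0, 0, 0]])
        totals = pd.Series([1_000_000, 2_000_000, 1, 1, 1, 1], index=LIBS)
        tpm = to_tpm(counts, totals)
        assert tpm.iloc[0, 0] == 100.0
        assert tpm.iloc[0, 1] == 5.0
        assert tpm.iloc[0, 2] == 0.0

    def test_library_conservation(self):
        rng = np.random.default_rng(0)
        counts = _mat(rng.integers(0, 50, size=(40, 6)))
        totals = counts.sum(axis=0)
        tpm = to_tpm(counts, totals)
        assert np.allclose(tpm.sum(axis=0), 1e6)

    @given(st.integers(1, 1000))
    def test_scale_invariance(self, factor):
        counts = _mat([[3, 5, 8, 2, 0, 7]])
        totals = pd.Series([100, 200, 300, 400, 500, 600], index=LIBS)
        a = to_tpm(counts, totals)
        b = to_tpm(counts * factor, totals * factor)
        assert np.allclose(a, b)

    def test_negative_counts_fail(self):
        with pytest.raises(ValueError):
            to_tpm(_mat([[-1, 0, 0, 0, 0, 0]]),
                   pd.Series(1, index=LIBS))


def _pop_sd(x):
    x = np.asarray(x, dtype=float)
    return np.sqrt(np.mean((x - x.mean()) ** 2))


class TestEnrichment:
    def test_flat_profile_never_enriched(self):
        calls = call_enrichment(_mat([[100] * 6]), "sample")
        assert (calls["zscore"] == 0).all()
        assert not calls["enriched"].any()

    def test_strong_single_sample(self):
        prof = [1000, 10, 10, 10, 10, 10]
        calls = call_enrichment(_mat([prof]), "sample")
        row = calls[calls["target"] == "UNM"].iloc[0]
        assert row["ratio"] == pytest.approx(100.0)
        assert row["zscore"] == pytest.approx((1000 - np.mean(prof))
                                              / _pop_sd(prof))
        assert row["enriched"]

    def test_ratio_without_zscore_not_enriched(self):
        # high ratio but a spread-out background keeps the Z-score low
        prof = [40, 30, 1, 1, 1, 1]
        calls = call_enrichment(_mat([prof]), "sample")
        row = calls[calls["target"] == "UNM"].iloc[0]
        assert row["ratio"] == pytest.approx(40 / np.mean(prof[1:]))
        assert row["ratio"] > 2
        assert row["zscore"] == pytest.approx((40 - np.mean(prof))
                                              / _pop_sd(prof))
        assert row["zscore"] < 2
        assert not row["enriched"]

    def test_stage_specific_zscore_constant(self):
        # one sample holds all mass: z = 5/sqrt(5) regardless of amplitude
        for amp in (10, 1234):
            calls = call_enrichment(_mat([[amp, 0, 0, 0, 0, 0]]), "sample")
            row = calls[calls["target"] == "UNM"].iloc[0]
            assert row["zscore"] == pytest.approx(np.sqrt(5))
            assert row["enriched"]

    def test_group_scope_pollen(self):
        prof = [900, 150, 100, 3, 3, 3]
        calls = call_enrichment(_mat([prof]), "group")
        row = calls[calls["target"] == "pollen"].iloc[0]
        assert row["ratio"] == pytest.approx(np.mean(prof[:3]) / 3.0)
        assert row["zscore"] == pytest.approx((900 - np.mean(prof))
                                              / _pop_sd(prof))
        assert row["enriched"]
        other = calls[calls["target"] == "sporophyte"].iloc[0]
        assert not other["enriched"]

    def test_all_zero_row_no_failure(self):
        calls = call_enrichment(_mat([[0] * 6]), "sample")
        assert not calls["enriched"].any()

    def test_unknown_scope(self):
        with pytest.raises(ValueError):
            call_enrichment(_mat([[1] * 6]), "tissue")


class TestKMeans:
    def test_identical_profiles_one_cluster(self):
        tpm = _mat([[10, 20, 30, 10, 20, 30]] * 3)
        asg, cent = kmeans_profiles(tpm, k=1, seed=0)
        assert (asg["cluster"] == 0).all()
        assert np.allclose(cent.iloc[0], np.log2(np.array(
            [10, 20, 30, 10, 20, 30]) + 1))

    def test_separated_groups_recovered(self):
        rng = np.random.default_rng(1)
        lo = rng.uniform(0, 2, size=(10, 6))
        hi = rng.uniform(500, 600, size=(10, 6))
        tpm = _mat(np.vstack([lo, hi]))
        asg, _ = kmeans_profiles(tpm, k=2, seed=0)
        labels = asg["cluster"].to_numpy()
        assert len(set(labels[:10])) == 1
        assert len(set(labels[10:])) == 1
        assert labels[0] != labels[10]

    def test_deterministic_for_fixed_seed(self):
        rng = np.random.default_rng(2)
        tpm = _mat(rng.uniform(0, 100, size=(30, 6)))
        a, _ = kmeans_profiles(tpm, k=4, seed=9)
        b, _ = kmeans_profiles(tpm, k=4, seed=9)
        assert (a["cluster"] == b["cluster"]).all()

    def test_k_exceeding_rows_fails(self):
        with pytest.raises(ValueError):
            kmeans_profiles(_mat([[1] * 6] * 3), k=4)


class TestPca:
    def test_rank_one_matrix(self):
        base = np.array([1, 2, 3, 4, 5, 6], dtype=float)
        tpm = _mat([2.0 ** (i * base) - 1 for i in (1, 2, 3)])
        res = pca_samples(tpm)
        assert res.explained_variance.iloc[0] == pytest.approx(1.0)

    def test_group_structure_separates_on_pc1(self):
        rng = np.random.default_rng(3)
        rows = []
        for _ in range(30):
            p = rng.uniform(200, 400)
            s = rng.uniform(1, 5)
            rows.append([p, p, p, s, s, s] + rng.uniform(0, 1, 6))
        res = pca_samples(_mat(rows))
        pc1 = res.sample_scores["PC1"]
        assert len(set(np.sign(pc1[LIBS[:3]]))) == 1
        assert np.sign(pc1["UNM"]) != np.sign(pc1["callus"])

    def test_explained_fractions_sum_to_one(self):
        rng = np.random.default_rng(4)
        res = pca_samples(_mat(rng.uniform(0, 500, size=(25, 6))))
        assert res.explained_variance.sum() == pytest.approx(1.0)

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(5)
        tpm = _mat(rng.uniform(0, 500, size=(20, 6)))
        res1 = pca_samples(tpm)
        res2 = pca_samples(tpm.iloc[rng.permutation(20)])
        assert np.allclose(res1.explained_variance, res2.explained_variance)

    def test_matches_covariance_eigendecomposition(self):
        rng = np.random.default_rng(6)
        tpm = _mat(rng.uniform(0, 500, size=(15, 6)))
        res = pca_samples(tpm)
        x = np.log2(tpm.to_numpy().T + 1)
        x = x - x.mean(axis=0)
        evals = np.sort(np.linalg.eigvalsh(np.cov(x.T, bias=False)))[::-1]
        evals = evals[evals > 1e-10]
        assert np.allclose(res.explained_variance,
                           evals[:len(res.explained_variance)] / evals.sum(),
                           atol=1e-8)

    def test_constant_matrix_fails(self):
        with pytest.raises(ValueError):
            pca_samples(_mat([[5] * 6] * 4))
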