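"""TPM, z-scores, NB differential testing, BH and temporal K-means."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

from regengrn.expression_temporal import (
    bh_adjust,
    compute_tpm,
    kmeans_temporal,
    log_zscore,
    nb_differential,
)
from regengrn.synthetic_data import SimulationConfig, _nb_draw, make_sample_table


def _counts_frame(array, samples):
    return pd.DataFrame(
        np.asarray(array),
        index=[f"f{i}" for i in range(len(array))],
        columns=list(samples.sample_ids),
    )


SAMPLES = make_sample_table(SimulationConfig.small())


class TestTpm:
    def test_hand_computed_two_transcripts(self):
        counts = pd.DataFrame({"s1": [10, 10]}, index=["a", "b"])
        lengths = pd.Series([1000.0, 2000.0], index=["a", "b"])
        tpm = compute_tpm(counts, lengths)
        # rates 0.01 and 0.005 -> 2/3 and 1/3 of a million
        np.testing.assert_allclose(tpm["s1"], [666666.666667, 333333.333333], rtol=1e-9)

    def test_single_transcript_gets_full_million(self):
        tpm = compute_tpm(
            pd.DataFrame({"s1": [7]}, index=["a"]), pd.Series([123.0], index=["a"])
        )
        assert tpm.iloc[0, 0] == pytest.approx(1e6)

    def test_equal_counts_equal_lengths_split_evenly(self):
        n = 8
        counts = pd.DataFrame({"s1": [5] * n}, index=[f"t{i}" for i in range(n)])
        lengths = pd.Series([500.0] * n, index=counts.index)
        np.testing.assert_allclose(compute_tpm(counts, lengths)["s1"], 1e6 / n)

    def test_columns_sum_to_one_million(self, small_bundle):
        _, b = small_bundle
        tpm = compute_tpm(b["counts"], b["effective_lengths"])
        np.testing.assert_allclose(tpm.sum(axis=0), 1e6, rtol=1e-6)

    def test_subsetting_requires_renormalization(self, small_bundle):
        """Column sums are NOT conserved after row subsetting."""
        _, b = small_bundle
        tpm = compute_tpm(b["counts"], b["effective_lengths"])
        sub = tpm.iloc[:50]
        assert (np.abs(sub.sum(axis=0) - 1e6) > 1).all()

    def test_all_zero_sample_is_error(self):
        counts = pd.DataFrame({"s1": [0, 0]}, index=["a", "b"])
        with pytest.raises(ValueError):
            compute_tpm(counts, pd.Series([1.0, 1.0], index=["a", "b"]))


class TestZscore:
    def test_simple_row(self):
        # log2(tpm+1) = [1, 2, 3] -> z = [-1, 0, 1] with sample SD
        tpm = pd.DataFrame({"s1": [1.0], "s2": [3.0], "s3": [7.0]}, index=["a"])
        z = log_zscore(tpm)
        np.testing.assert_allclose(z.z.loc["a"], [-1, 0, 1])

    def test_constant_row_flagged(self):
        tpm = pd.DataFrame({"s1": [2.0, 1.0], "s2": [2.0, 5.0]}, index=["a", "b"])
        z = log_zscore(tpm)
        assert z.flagged_constant == ["a"]
        assert list(z.z.index) == ["b"]

    def test_rows_sum_to_zero_unit_sd(self, small_bundle):
        _, b = small_bundle
        tpm = compute_tpm(b["counts"], b["effective_lengths"])
        z = log_zscore(tpm)
        np.testing.assert_allclose(z.z.mean(axis=1), 0, atol=1e-9)
        np.testing.assert_allclose(z.z.std(axis=1, ddof=1), 1, atol=1e-9)


def brute_force_bh(p):
    """Literal step-up: q_i = min over p_(j) >= p_(i) of p_(j) * m / j."""
    p = np.asarray(p, float)
    m = len(p)
    sorted_p = np.sort(p, kind="mergesort")
    q = np.empty(m)
    for i in range(m):
        vals = [sorted_p[j] * m / (j + 1) for j in range(m) if sorted_p[j] >= p[i]]
        q[i] = min(1.0, min(vals))
    return q


class TestBH:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_single_and_saturated(self):
        np.testing.assert_allclose(bh_adjust([0.2]), [0.2])
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 60))
            np.testing.assert_allclose(bh_adjust(p), brute_force_bh(p), atol=1e-12)


class TestNbDifferential:
    def test_identical_counts_are_null(self):
        counts = _counts_frame(np.full((5, 15), 40), SAMPLES)
        de = nb_differential(counts, SAMPLES)
        t = de.table
        for tp in (2, 4, 7, 12):
            np.testing.assert_allclose(t[f"log2fc_{tp}"], 0.0)
            assert (t[f"wald_p_{tp}"] > 0.9).all()
        assert (t["lrt_p"] > 0.9).all()

    def test_null_lrt_p_values_approximately_uniform(self):
        rng = np.random.default_rng(42)
        mu = rng.lognormal(np.log(200), 1.0, size=500)[:, None] * np.ones((1, 15))
        counts = _counts_frame(_nb_draw(rng, mu, 0.1), SAMPLES)
        de = nb_differential(counts, SAMPLES)
        p = de.table.loc[de.table["tested"], "lrt_p"].to_numpy()
        assert kstest(p, "uniform").pvalue > 0.01

    def test_planted_fourfold_change_detected(self):
        rng = np.random.default_rng(7)
        mu = np.full((100, 15), 50.0)
        at2 = np.asarray(SAMPLES.timepoints_dpi) == 2
        mu[:, at2] *= 4
        counts = _counts_frame(_nb_draw(rng, mu, 0.1), SAMPLES)
        de = nb_differential(counts, SAMPLES)
        frac = (de.table["wald_p_2"] < 0.05).mean()
        assert frac >= 0.8

    def test_low_count_features_not_tested(self):
        X = np.full((3, 15), 20)
        X[0] = 0
        counts = _counts_frame(X, SAMPLES)
        counts.iloc[0, 0] = 5  # total 5 < 10
        de = nb_differential(counts, SAMPLES)
        assert not de.table["tested"].iloc[0]
        assert np.isnan(de.table["lrt_p"].iloc[0])

    def test_single_replicate_group_rejected(self):
        from regengrn.io_formats import SampleTable

        st_bad = SampleTable(("a", "b", "c"), (0, 0, 2), (1, 2, 1))
        counts = pd.DataFrame(
            np.full((3, 3), 10), index=list("xyz"), columns=["a", "b", "c"]
        )
        with pytest.raises(ValueError):
            nb_differential(counts, st_bad)

    def test_q_not_below_p(self, small_bundle):
        _, b = small_bundle
        de = nb_differential(b["counts"], b["samples"])
        t = de.table[de.table["tested"]]
        assert (t["lrt_q"] >= t["lrt_p"] - 1e-12).all()
        assert (t["wald_q_2"] >= t["wald_p_2"] - 1e-12).all()


class TestKmeans:
    def test_separable_two_clusters_recovered_exactly(self):
        rng = np.random.default_rng(0)
        a = np.tile([1.0, 1, -1, -1, 0], (20, 1)) + rng.normal(0, 0.05, (20, 5))
        b = np.tile([-1.0, -1, 1, 1, 0], (15, 1)) + rng.normal(0, 0.05, (15, 5))
        X = pd.DataFrame(np.vstack([a, b]))
        res = kmeans_temporal(X, K=2, seed=1, n_restarts=5)
        labels = res.assignment.to_numpy()
        assert len(set(labels[:20])) == 1 and len(set(labels[20:])) == 1
        assert labels[0] != labels[-1]

    def test_deterministic_given_seed(self, small_bundle):
        _, b = small_bundle
        tpm = compute_tpm(b["counts"], b["effective_lengths"])
        z = log_zscore(tpm)
        r1 = kmeans_temporal(z, K=7, seed=11)
        r2 = kmeans_temporal(z, K=7, seed=11)
        assert r1.assignment.equals(r2.assignment)
        assert r1.within_ss == r2.within_ss

    def test_within_ss_matches_definition_and_no_empty_cluster(self, small_bundle):
        _, b = small_bundle
        tpm = compute_tpm(b["counts"], b["effective_lengths"])
        z = log_zscore(tpm)
        res = kmeans_temporal(z, K=7, seed=3)
        X = z.z.to_numpy()
        d = ((X - res.centroids[res.assignment.to_numpy()]) ** 2).sum()
        assert res.within_ss == pytest.approx(d)
        assert set(res.assignment) == set(range(7))

    def test_k_validation(self):
        X = pd.DataFrame(np.zeros((5, 3)))
        with pytest.raises(ValueError):
            kmeans_temporal(X, K=1)
        with pytest.raises(ValueError):
            kmeans_temporal(X, K=9)
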