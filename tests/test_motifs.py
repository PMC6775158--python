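"""PWM construction, scanning, enrichment and co-occurrence."""

import math

import numpy as np
import pandas as pd
import pytest

from regengrn.io_formats import MotifMatrix
from regengrn.motif_engine import (
    build_hit_matrix,
    cooccurrence_network,
    estimate_background,
    motif_enrichment,
    pfm_to_pwm,
    scan_sequence,
)
from regengrn.synthetic_data import _revcomp

UNIFORM = np.full(4, 0.25)


def _pfm(counts, motif_id="M1"):
    return MotifMatrix(motif_id, "TF", np.asarray(counts, float))


class TestPfmToPwm:
    def test_hand_computed_column(self):
        # A=100 of 100, uniform bg, pseudocount 1:
        # log2(((100+0.25)/101)/0.25) = 1.9892 bits
        counts = np.zeros((4, 4))
        counts[0, :] = 100
        pwm = pfm_to_pwm(_pfm(counts), UNIFORM, pseudocount=1.0)
        expected = math.log2(((100 + 0.25) / 101) / 0.25)
        np.testing.assert_allclose(pwm.log_odds[0], expected, rtol=1e-12)

    def test_background_proportional_counts_give_zero(self):
        counts = np.tile(np.array([10.0, 20.0, 30.0, 40.0])[:, None], (1, 5))
        bg = np.array([0.1, 0.2, 0.3, 0.4])
        pwm = pfm_to_pwm(_pfm(counts), bg, pseudocount=1.0)
        np.testing.assert_allclose(pwm.log_odds, 0.0, atol=1e-12)

    def test_zero_count_without_pseudocount_rejected(self):
        counts = np.zeros((4, 4))
        counts[0, :] = 100
        with pytest.raises(ValueError):
            pfm_to_pwm(_pfm(counts), UNIFORM, pseudocount=0.0)

    def test_max_score_is_column_max_sum(self):
        counts = np.eye(4)[:, [0, 1, 2, 3]] * 50 + 1
        pwm = pfm_to_pwm(_pfm(counts), UNIFORM)
        np.testing.assert_allclose(pwm.max_score, pwm.log_odds.max(axis=0).sum())


def brute_force_scan(pwm, seq, frac):
    """Per-window python scorer, both strands."""
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    L = pwm.length
    thr = frac * pwm.max_score
    out = []
    for strand, lo in (("+", pwm.log_odds), ("-", pwm.reverse_complement().log_odds)):
        for off in range(len(seq) - L + 1):
            window = seq[off : off + L]
            if "N" in window:
                continue
            score = sum(lo[idx[b], j] for j, b in enumerate(window))
            if score >= thr:
                out.append((off, strand, score))
    return sorted(out)


class TestScan:
    def _pwm(self, rng, L=9):
        dominant = rng.integers(0, 4, L)
        counts = np.full((4, L), 5.0)
        counts[dominant, np.arange(L)] = 85.0
        return pfm_to_pwm(_pfm(counts), UNIFORM)

    def test_planted_consensus_found_at_offset(self, rng):
        pwm = self._pwm(rng)
        consensus = "".join("ACGT"[i] for i in pwm.log_odds.argmax(axis=0))
        seq = "".join(rng.choice(list("ACGT"), 100))
        seq = seq[:37] + consensus + seq[37 + len(consensus):]
        hits = scan_sequence(pwm, seq)
        assert any(h.offset == 37 and h.strand == "+" for h in hits)

    def test_reverse_complement_found_on_minus_strand(self, rng):
        pwm = self._pwm(rng)
        consensus = "".join("ACGT"[i] for i in pwm.log_odds.argmax(axis=0))
        seq = "A" * 40 + _revcomp(consensus) + "C" * 40
        hits = scan_sequence(pwm, seq)
        assert any(h.offset == 40 and h.strand == "-" for h in hits)

    def test_short_sequence_yields_empty(self, rng):
        pwm = self._pwm(rng)
        assert scan_sequence(pwm, "ACG") == []

    def test_n_windows_never_hit(self, rng):
        pwm = self._pwm(rng)
        consensus = "".join("ACGT"[i] for i in pwm.log_odds.argmax(axis=0))
        broken = consensus[:4] + "N" + consensus[5:]
        assert all(h.offset != 0 for h in scan_sequence(pwm, broken + "ACGTACGT"))

    def test_matches_brute_force_scorer(self, rng):
        """Exhaustive equivalence on random sequences at a permissive threshold."""
        for _ in range(5):
            pwm = self._pwm(rng, L=int(rng.integers(8, 13)))
            for _ in range(10):
                seq = "".join(rng.choice(list("ACGTN"), 200, p=[0.24] * 4 + [0.04]))
                hits = scan_sequence(pwm, seq, threshold_fraction=0.5)
                got = sorted((h.offset, h.strand, h.score) for h in hits)
                expected = brute_force_scan(pwm, seq, 0.5)
                assert len(got) == len(expected)
                for g, e in zip(got, expected):
                    assert g[:2] == e[:2]
                    assert g[2] == pytest.approx(e[2], abs=1e-9)

    def test_strand_symmetry(self, rng):
        """Scanning seq with the PWM mirrors scanning revcomp(seq) with the
        revcomp PWM."""
        pwm = self._pwm(rng)
        seq = "".join(rng.choice(list("ACGT"), 150))
        fwd = scan_sequence(pwm, seq, threshold_fraction=0.5)
        rc = scan_sequence(pwm.reverse_complement(), _revcomp(seq), threshold_fraction=0.5)
        L, n = pwm.length, len(seq)
        # revcomping both sequence and motif preserves the matching strand;
        # only offsets mirror
        mirrored = sorted(
            (n - L - h.offset, h.strand, round(h.score, 9)) for h in rc
        )
        assert mirrored == sorted((h.offset, h.strand, round(h.score, 9)) for h in fwd)

    def test_invalid_alphabet_rejected(self, rng):
        pwm = self._pwm(rng)
        with pytest.raises(ValueError):
            scan_sequence(pwm, "ACGTXACGTACGT")


class TestHitMatrix:
    def test_planted_motifs_all_detected(self, small_bundle):
        """With the generator's verbatim planting every planted (peaklet,
        motif) pair must be a hit."""
        _, b = small_bundle
        bg = estimate_background([r.sequence for r in b["genome"]])
        pwms = [pfm_to_pwm(m, bg) for m in b["motifs"]]
        hm = build_hit_matrix(b["peaklets"], b["genome"], pwms)
        for pid, mid, _off, _strand in b["truth"].planted_hits:
            assert hm.matrix.loc[pid, mid]

    def test_empty_pwm_list(self, small_bundle):
        _, b = small_bundle
        hm = build_hit_matrix(b["peaklets"][:5], b["genome"], [])
        assert hm.matrix.shape == (5, 0)

    def test_peaklet_outside_genome_is_error(self, small_bundle, rng):
        from regengrn.chromatin_accessibility import build_peaklets

        _, b = small_bundle
        bad = build_peaklets([("chrX", 1000, 1e-12)], {"chrX": 10_000})
        bg = np.full(4, 0.25)
        pwms = [pfm_to_pwm(b["motifs"][0], bg)]
        with pytest.raises(ValueError):
            build_hit_matrix(bad, b["genome"], pwms)


def brute_force_hypergeom_tail(k, n, K, N):
    """P(X >= k) for X ~ Hypergeom(N population, K successes, n draws)."""
    total = 0.0
    for i in range(k, min(n, K) + 1):
        total += (
            math.comb(K, i) * math.comb(N - K, n - i) / math.comb(N, n)
        )
    return total


class TestEnrichment:
    def test_matches_hypergeometric_oracle(self):
        # foreground within a 40-peaklet universe, 10 hits total, 5 in fore
        ids = [f"p{i}" for i in range(40)]
        hits = pd.DataFrame({"M": [i < 5 or (10 <= i < 15) for i in range(40)]}, index=ids)
        fore = ids[:10]
        res = motif_enrichment(fore, ids, hits)
        expected = brute_force_hypergeom_tail(5, 10, 10, 40)
        assert res.iloc[0]["p"] == pytest.approx(expected, abs=1e-10)

    def test_foreground_equals_background_is_null(self):
        ids = [f"p{i}" for i in range(20)]
        hits = pd.DataFrame({"M": [i < 8 for i in range(20)]}, index=ids)
        res = motif_enrichment(ids, ids, hits)
        assert res.iloc[0]["p"] == pytest.approx(1.0)

    def test_empty_foreground_rejected(self):
        hits = pd.DataFrame({"M": [True]}, index=["p0"])
        with pytest.raises(ValueError):
            motif_enrichment([], ["p0"], hits)

    def test_planted_motif_enriched_decoys_not(self, small_bundle):
        from regengrn.chromatin_accessibility import annotate_peaklets

        _, b = small_bundle
        bg = estimate_background([r.sequence for r in b["genome"]])
        pwms = [pfm_to_pwm(m, bg) for m in b["motifs"]]
        hm = build_hit_matrix(b["peaklets"], b["genome"], pwms)
        truth = b["truth"]
        ann = annotate_peaklets(b["peaklets"], b["genes"])
        cluster0 = {
            g for g, c in truth.cluster_of_gene.items() if c == 0
        }
        fore = list(ann.index[ann["nearest_gene"].isin(cluster0)])
        back = list(ann.index.difference(fore))
        res = motif_enrichment(fore, back, hm).set_index("motif_id")
        planted = truth.motif_of_cluster[0]
        assert res.loc[planted, "enriched"]
        decoys = [m.motif_id for m in b["motifs"][7:]]
        assert not res.loc[decoys, "enriched"].any()


def brute_force_cooccurrence(M):
    rows = []
    cols = list(M.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1:]:
            both = int((M[a] & M[b]).sum())
            union = int((M[a] | M[b]).sum())
            if both:
                rows.append((a, b, both, both / union))
    return rows


class TestCooccurrence:
    def test_identical_columns_jaccard_one(self):
        M = pd.DataFrame({"a": [1, 1, 0], "b": [1, 1, 0]}, dtype=bool)
        (edge,) = cooccurrence_network(M).itertuples(index=False)
        assert edge.shared_fraction == 1.0 and edge.shared_peaklets == 2

    def test_disjoint_columns_no_edge(self):
        M = pd.DataFrame({"a": [1, 0], "b": [0, 1]}, dtype=bool)
        assert len(cooccurrence_network(M)) == 0

    def test_matches_brute_force_random_matrices(self, rng):
        M = pd.DataFrame(
            rng.random((200, 20)) < 0.2,
            columns=[f"m{i}" for i in range(20)],
        )
        got = cooccurrence_network(M)
        expected = brute_force_cooccurrence(M)
        assert len(got) == len(expected)
        for row, exp in zip(got.itertuples(index=False), expected):
            assert (row.motif_a, row.motif_b, row.shared_peaklets) == exp[:3]
            assert row.shared_fraction == pytest.approx(exp[3], abs=1e-12)

    def test_min_denominator_option(self):
        M = pd.DataFrame({"a": [1, 1, 1, 0], "b": [1, 0, 0, 1]}, dtype=bool)
        jac = cooccurrence_network(M).iloc[0]["shared_fraction"]
        mn = cooccurrence_network(M, denominator="min").iloc[0]["shared_fraction"]
        assert jac == pytest.approx(1 / 4)
        assert mn == pytest.approx(1 / 2)
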