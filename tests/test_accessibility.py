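"""Peaklet construction, overlap counting, DA testing and annotation."""

import numpy as np
import pandas as pd
import pytest

from regengrn.chromatin_accessibility import (
    annotate_peaklets,
    build_peaklets,
    count_overlaps,
    differential_accessibility,
    genomic_distribution,
)
from regengrn.io_formats import GeneModel, GenomicInterval
from regengrn.synthetic_data import SimulationConfig, simulate_peaklet_counts

CHROMS = {"chr1": 10_000, "chr2": 200_000}


class TestBuildPeaklets:
    def test_500bp_window_around_summit(self):
        (p,) = build_peaklets([("chr2", 1000, 1e-12)], CHROMS)
        assert (p.interval.start, p.interval.end) == (750, 1250)
        assert not p.clipped

    def test_edge_clipping(self):
        (p,) = build_peaklets([("chr1", 100, 1e-12)], CHROMS)
        assert (p.interval.start, p.interval.end) == (0, 350)
        assert p.clipped

    def test_weak_summit_dropped(self):
        assert build_peaklets([("chr1", 1000, 1e-9)], CHROMS) == []
        assert len(build_peaklets([("chr1", 1000, 1e-11)], CHROMS)) == 1

    def test_ids_follow_sort_order_and_no_merging(self):
        pks = build_peaklets(
            [("chr2", 5000, 1e-12), ("chr1", 900, 1e-12), ("chr2", 5100, 1e-12)],
            CHROMS,
        )
        assert [p.peaklet_id for p in pks] == [
            "peaklet_00000",
            "peaklet_00001",
            "peaklet_00002",
        ]
        assert pks[0].interval.chrom == "chr1"
        # overlapping windows from nearby summits are kept distinct
        assert pks[1].interval.overlap_bp(pks[2].interval) > 0

    def test_odd_width_rejected(self):
        with pytest.raises(ValueError):
            build_peaklets([], CHROMS, width=501)


class TestCountOverlaps:
    def _peaklet(self):
        return build_peaklets([("chr2", 1000, 1e-12)], CHROMS)

    def test_half_open_no_overlap(self):
        reads = {"s": pd.DataFrame({"chrom": ["chr2"], "start": [700], "end": [750]})}
        m = count_overlaps(reads, self._peaklet())
        assert m.iloc[0, 0] == 0

    def test_single_bp_overlap_counts(self):
        reads = {"s": pd.DataFrame({"chrom": ["chr2"], "start": [749], "end": [800]})}
        assert count_overlaps(reads, self._peaklet()).iloc[0, 0] == 1

    def test_read_spanning_two_peaklets_counts_in_both(self):
        pks = build_peaklets(
            [("chr2", 1000, 1e-12), ("chr2", 1500, 1e-12)], CHROMS
        )
        reads = {"s": pd.DataFrame({"chrom": ["chr2"], "start": [1240], "end": [1260]})}
        m = count_overlaps(reads, pks)
        assert m["s"].tolist() == [1, 1]

    def test_matches_brute_force_on_random_fixture(self, rng):
        pks = build_peaklets(
            [("chr2", int(pos), 1e-12) for pos in rng.integers(300, 199_000, 60)],
            CHROMS,
        )
        reads = pd.DataFrame(
            {
                "chrom": "chr2",
                "start": rng.integers(0, 199_900, 500),
            }
        )
        reads["end"] = reads["start"] + 100
        m = count_overlaps({"s": reads}, pks)
        for p in pks:
            expected = (
                (reads["start"] < p.interval.end) & (reads["end"] > p.interval.start)
            ).sum()
            assert m.loc[p.peaklet_id, "s"] == expected


class TestDifferentialAccessibility:
    def test_planted_open_peaklets_called_with_direction(self, rng):
        cfg = SimulationConfig.small(seed=0)
        counts, samples = simulate_peaklet_counts(300, 20, cfg, rng)
        res = differential_accessibility(counts, samples)
        called_open = set(
            res.calls.loc[
                (res.calls["direction"] == "open") & (res.calls["timepoint"] == 2),
                "peaklet_id",
            ]
        )
        planted = {f"pk{i:05d}" for i in range(20)}
        assert len(called_open & planted) / 20 >= 0.8
        false_calls = set(res.calls["peaklet_id"]) - planted
        assert len(false_calls) / 280 <= 0.07

    def test_all_equal_counts_yield_no_calls(self):
        cfg = SimulationConfig.small(seed=0)
        counts, samples = simulate_peaklet_counts(50, 0, cfg, np.random.default_rng(1))
        counts.iloc[:, :] = 30
        res = differential_accessibility(counts, samples)
        assert len(res.calls) == 0


def _gene(gid, chrom, start, end, strand, exons=(), utr5=()):
    return GeneModel(
        gene_id=gid,
        transcript_ids=(f"{gid}.t1",),
        interval=GenomicInterval(chrom, start, end, strand),
        exons=tuple(GenomicInterval(chrom, s, e, strand) for s, e in exons),
        utr5=tuple(GenomicInterval(chrom, s, e, strand) for s, e in utr5),
    )


def brute_force_annotation(peaklets, genes, proximal=1000, distal=100_000, exon_bp=50):
    """O(genes x peaklets) reference scan."""
    rows = {}
    genes = sorted(genes, key=lambda g: g.gene_id)
    for p in peaklets:
        c = p.interval.center
        best_gene, best_d = None, None
        for g in genes:
            if g.interval.chrom != p.interval.chrom:
                continue
            d = abs(c - g.tss)
            if best_d is None or d < best_d:
                best_gene, best_d = g.gene_id, d
        max_ov = 0
        any_exon = any_utr = any_genic = False
        for g in genes:
            for ex in g.exons:
                ov = p.interval.overlap_bp(ex)
                if ov > 0:
                    any_exon = True
                max_ov = max(max_ov, ov)
            for u in g.utr5:
                if p.interval.overlap_bp(u) > 0:
                    any_utr = True
            if p.interval.overlap_bp(g.interval) > 0:
                any_genic = True
        genic = (
            "5'UTR" if any_utr else "exon" if any_exon else
            "intron" if any_genic else "intergenic"
        )
        if max_ov > exon_bp:
            loc = "unassigned"
        elif best_d is None:
            loc = "unassigned"
        elif best_d <= proximal:
            loc = "proximal"
        elif best_d < distal:
            loc = "distal"
        else:
            loc = "unassigned"
        rows[p.peaklet_id] = (loc, genic, best_gene, best_d)
    return rows


class TestAnnotation:
    def test_proximal_distal_unassigned_windows(self):
        genes = [_gene("g1", "chr2", 10_000, 12_000, "+", exons=[(10_000, 10_400)])]
        pks = build_peaklets(
            [("chr2", 9_500, 1e-12), ("chr2", 60_000, 1e-12), ("chr2", 199_000, 1e-12)],
            CHROMS,
        )
        ann = annotate_peaklets(pks, genes)
        assert list(ann["location_class"]) == ["proximal", "distal", "unassigned"]

    def test_exonic_overlap_excluded_from_location_but_classified(self):
        genes = [_gene("g1", "chr2", 10_000, 12_000, "+", exons=[(10_000, 10_400)])]
        (pk,) = build_peaklets([("chr2", 10_200, 1e-12)], CHROMS)
        ann = annotate_peaklets(pks := [pk], genes)
        assert ann.iloc[0]["location_class"] == "unassigned"
        assert ann.iloc[0]["unassigned_reason"] == "exonic"
        assert ann.iloc[0]["genic_class"] == "exon"

    def test_matches_brute_force_on_random_fixture(self, rng):
        chroms = {"chrA": 500_000, "chrB": 500_000}
        genes = []
        for i in range(50):
            chrom = "chrA" if i % 2 == 0 else "chrB"
            start = int(rng.integers(0, 480_000))
            end = start + int(rng.integers(500, 5000))
            strand = "+" if rng.random() < 0.5 else "-"
            exons = [(start, min(start + 300, end))]
            utr5 = [(start, min(start + 80, end))] if rng.random() < 0.5 else []
            genes.append(_gene(f"g{i:02d}", chrom, start, end, strand, exons, utr5))
        summits = [
            ("chrA" if rng.random() < 0.5 else "chrB", int(rng.integers(0, 500_000)), 1e-12)
            for _ in range(1000)
        ]
        pks = build_peaklets(summits, chroms)
        ann = annotate_peaklets(pks, genes)
        oracle = brute_force_annotation(pks, genes)
        for pid, (loc, genic, gene, dist) in oracle.items():
            row = ann.loc[pid]
            assert row["location_class"] == loc, pid
            assert row["genic_class"] == genic, pid
            assert row["nearest_gene"] == gene, pid
            assert row["tss_distance"] == dist, pid


class TestGenomicDistribution:
    def test_fractions_sum_to_one_per_axis(self, small_bundle):
        _, b = small_bundle
        ann = annotate_peaklets(b["peaklets"], b["genes"])
        dist = genomic_distribution(ann)
        for axis, grp in dist.groupby("axis"):
            assert grp["fraction"].sum() == pytest.approx(1.0)

    def test_all_intergenic(self):
        pks = build_peaklets([("chr2", 1000, 1e-12)], CHROMS)
        ann = annotate_peaklets(pks, [])
        dist = genomic_distribution(ann)
        g = dist[dist["axis"] == "genic_class"]
        assert g.iloc[0]["class"] == "intergenic" and g.iloc[0]["fraction"] == 1.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            genomic_distribution(pd.DataFrame(columns=["genic_class", "location_class"]))
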