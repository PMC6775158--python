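#!/usr/bin/env python
"""Motif scanning of peaklets, per-cluster enrichment and co-occurrence.

Scans every peaklet sequence with the motif library (log-odds PWMs,
hit = 80% of max score, both strands), then for the first temporal cluster
reports Fisher-exact enrichment of each motif in that cluster's
proximal/distal peaklets and the pairwise co-occurrence network of
enriched motifs. Writes hit_matrix.tsv, motif_hits.tsv, enrichment.tsv and
cooccurrence_edges.tsv under results/motifs/.
"""

import argparse
from pathlib import Path

import pandas as pd

from regengrn.chromatin_accessibility import build_peaklets
from regengrn.io_formats import read_fasta, read_jaspar
from regengrn.motif_engine import (
    build_hit_matrix,
    cooccurrence_network,
    estimate_background,
    motif_enrichment,
    pfm_to_pwm,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--expression", type=Path, default=Path("results/expression"))
    ap.add_argument("--atac", type=Path, default=Path("results/atac"))
    ap.add_argument("--outdir", type=Path, default=Path("results/motifs"))
    ap.add_argument("--threshold", type=float, default=0.8)
    ap.add_argument("--cluster", type=int, default=0)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genome = read_fasta(args.data / "genome.fa")
    seqs = {r.id: r.sequence for r in genome}
    chrom_lengths = {r.id: len(s) for r, s in zip(genome, seqs.values())}
    summits = pd.read_csv(args.data / "summits.tsv", sep="\t")
    peaklets = build_peaklets(
        list(zip(summits["chrom"], summits["pos"], summits["p_value"])), chrom_lengths
    )
    pfms = read_jaspar(args.data / "motifs.jaspar")
    background = estimate_background(
        seqs[p.interval.chrom][p.interval.start : p.interval.end] for p in peaklets
    )
    print("background base frequencies (A,C,G,T):", background.round(4).tolist())
    pwms = [pfm_to_pwm(m, background, threshold_fraction=args.threshold) for m in pfms]
    hm = build_hit_matrix(peaklets, seqs, pwms)
    print(f"{len(hm.hits)} motif hits across {int(hm.matrix.any(axis=1).sum())} "
          f"of {len(peaklets)} peaklets")

    ann = pd.read_csv(args.atac / "peaklet_annotation.tsv", sep="\t", index_col=0)
    clusters = pd.read_csv(args.expression / "clusters.tsv", sep="\t", index_col=0)
    # transcript ids are <gene>.t1 in the simulated annotation
    gene_cluster = {tid.rsplit(".", 1)[0]: c for tid, c in clusters["cluster"].items()}
    cluster_genes = {g for g, c in gene_cluster.items() if c == args.cluster}
    usable = ann[ann["location_class"].isin(["proximal", "distal"])]
    fore = list(usable.index[usable["nearest_gene"].isin(cluster_genes)])
    back = list(usable.index.difference(fore))
    enr = motif_enrichment(fore, back, hm)
    n_enr = int(enr["enriched"].sum())
    print(f"cluster {args.cluster}: {n_enr} of {len(enr)} motifs enriched "
          f"in its {len(fore)} proximal/distal peaklets")

    edges = cooccurrence_network(
        hm, enriched_motifs=list(enr.loc[enr["enriched"], "motif_id"]) or None,
        peaklet_subset=fore or None,
    )
    print(f"co-occurrence network: {len(edges)} edges")

    hm.matrix.astype(int).rename_axis("peaklet_id").to_csv(
        args.outdir / "hit_matrix.tsv", sep="\t"
    )
    pd.DataFrame(
        [(h.peaklet_id, h.motif_id, h.offset, h.strand, h.score) for h in hm.hits],
        columns=["peaklet_id", "motif_id", "offset", "strand", "score"],
    ).to_csv(args.outdir / "motif_hits.tsv", sep="\t", index=False)
    enr.to_csv(args.outdir / "enrichment.tsv", sep="\t", index=False)
    edges.to_csv(args.outdir / "cooccurrence_edges.tsv", sep="\t", index=False)
    print(f"wrote results to {args.outdir}")


if __name__ == "__main__":
    main()
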