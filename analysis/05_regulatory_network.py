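#!/usr/bin/env python
"""TF selection, DA-proximity ranking, target inference, gene-set check.

Cross-references the TF catalog with differential expression, ranks the
selected TFs by distance from their TSS to the nearest differentially
accessible peaklet, infers TF->target edges from motif hits in target
peaklets, and runs a hypergeometric gene-set check of the top TF's targets
against the recovered temporal clusters. Writes tf_records.tsv,
tf_da_proximity.tsv, tf_target_edges.tsv, stage_enrichment.tsv and
target_geneset_enrichment.tsv under results/network/.
"""

import argparse
from pathlib import Path

import pandas as pd

from regengrn.chromatin_accessibility import (
    annotate_peaklets,
    build_peaklets,
    differential_accessibility,
)
from regengrn.expression_temporal import (
    compute_tpm,
    kmeans_temporal,
    log_zscore,
    nb_differential,
)
from regengrn.io_formats import read_fasta, read_gff_genes, read_jaspar
from regengrn.motif_engine import HitMatrix, MotifHit
from regengrn.pipeline import _read_samples
from regengrn.regulatory_network import (
    cluster_stage_enrichment,
    geneset_enrichment,
    infer_tf_targets,
    rank_tfs_by_da_proximity,
    select_regeneration_tfs,
    transcript_gene_map,
)


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--motifs", type=Path, default=Path("results/motifs"))
    ap.add_argument("--outdir", type=Path, default=Path("results/network"))
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--fdr", type=float, default=0.05)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genes = read_gff_genes(args.data / "genes.gff3")
    genome = read_fasta(args.data / "genome.fa")
    chrom_lengths = {r.id: len(r.sequence) for r in genome}
    samples = _read_samples(args.data / "samples.tsv")
    counts = pd.read_csv(args.data / "counts.tsv", sep="\t", index_col=0)
    lengths = pd.read_csv(
        args.data / "effective_lengths.tsv", sep="\t", index_col=0
    ).iloc[:, 0]
    summits = pd.read_csv(args.data / "summits.tsv", sep="\t")
    tf_catalog = pd.read_csv(args.data / "tf_catalog.tsv", sep="\t")
    pfms = read_jaspar(args.data / "motifs.jaspar")

    # recompute DE + clustering (deterministic, matches driver 02)
    de = nb_differential(counts, samples)
    z = log_zscore(compute_tpm(counts, lengths), de.significant(args.fdr, "lrt"))
    clustering = kmeans_temporal(z, K=7, seed=args.seed)

    peaklets = build_peaklets(
        list(zip(summits["chrom"], summits["pos"], summits["p_value"])), chrom_lengths
    )
    ann = annotate_peaklets(peaklets, genes)
    from regengrn.chromatin_accessibility import count_overlaps

    reads = {
        bed.stem: pd.read_csv(bed, sep="\t", header=None, usecols=[0, 1, 2],
                              names=["chrom", "start", "end"])
        for bed in sorted((args.data / "reads").glob("*.bed"))
    }
    acc = count_overlaps(reads, peaklets)[list(samples.sample_ids)]
    da = differential_accessibility(acc, samples, fdr=args.fdr)

    matrix = pd.read_csv(args.motifs / "hit_matrix.tsv", sep="\t", index_col=0).astype(bool)
    hits_df = pd.read_csv(args.motifs / "motif_hits.tsv", sep="\t")
    hm = HitMatrix(
        matrix=matrix,
        hits=[MotifHit(*row) for row in hits_df.itertuples(index=False)],
    )

    tfs, without_motif = select_regeneration_tfs(
        de, tf_catalog, pfms, clustering, genes, fdr=args.fdr
    )
    print(f"{len(tfs)} differentially expressed TFs with motifs selected "
          f"({len(without_motif)} significant catalog TFs lack a motif)")

    stage = cluster_stage_enrichment(clustering, ann, hm, tfs, genes, de)
    prox = rank_tfs_by_da_proximity(tfs, da.differential_ids, peaklets, genes)
    top = prox.iloc[0]
    print(f"TF nearest to differential accessibility: {top['gene_id']} "
          f"({top['min_distance_to_da_peaklet']:.0f} bp from a DA peaklet center)")

    top_tf = next(tf for tf in tfs if tf.gene_id == top["gene_id"])
    edges = []
    for tf in tfs:
        edges += infer_tf_targets(tf, clustering, ann, hm, genes, de)
    print(f"inferred {len(edges)} TF->target edges across {len(tfs)} TFs")

    # generic gene-set check: the top TF's targets against recovered clusters
    t2g = transcript_gene_map(genes)
    genesets = {
        f"cluster_{k}": sorted({t2g[t] for t in clustering.members(k)})
        for k in range(clustering.K)
    }
    universe = sorted({t2g[t] for t in de.table.index if t in t2g})
    targets = [e.target_gene_id for e in edges if e.tf_gene_id == top_tf.gene_id]
    gs = geneset_enrichment(targets, genesets, universe)
    best = gs.sort_values("p").iloc[0]
    print(f"targets of {top_tf.gene_id} are most enriched in {best['set_id']} "
          f"(p = {best['p']:.2e})")

    pd.DataFrame(
        [
            {"gene_id": tf.gene_id, "family": tf.family,
             "motif_id": tf.motif_id or "", "peak_cluster": tf.peak_cluster}
            for tf in tfs + without_motif
        ]
    ).to_csv(args.outdir / "tf_records.tsv", sep="\t", index=False)
    stage.to_csv(args.outdir / "stage_enrichment.tsv", sep="\t", index=False)
    prox.to_csv(args.outdir / "tf_da_proximity.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"tf_gene_id": e.tf_gene_id, "target_gene_id": e.target_gene_id,
             "n_evidence_peaklets": len({ev[0] for ev in e.evidence})}
            for e in edges
        ]
    ).to_csv(args.outdir / "tf_target_edges.tsv", sep="\t", index=False)
    gs.to_csv(args.outdir / "target_geneset_enrichment.tsv", sep="\t", index=False)
    print(f"wrote results to {args.outdir}")


if __name__ == "__main__":
    main()
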