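#!/usr/bin/env python
"""Peaklets, accessibility counting, differential accessibility, annotation.

Builds 500 bp peaklets from summits with p < 1e-10, counts overlapping
reads per sample, tests each timepoint against 0 dpi, and annotates each
peaklet as proximal/distal/unassigned relative to the nearest TSS. Writes
peaklets.bed, da_results.tsv, da_calls.tsv, peaklet_annotation.tsv and
genomic_distribution.tsv under results/atac/.
"""

import argparse
from pathlib import Path

import pandas as pd

from regengrn.chromatin_accessibility import (
    annotate_peaklets,
    build_peaklets,
    count_overlaps,
    differential_accessibility,
    genomic_distribution,
)
from regengrn.io_formats import read_fasta, read_gff_genes
from regengrn.pipeline import _read_samples


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/atac"))
    ap.add_argument("--fdr", type=float, default=0.05)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    genome = read_fasta(args.data / "genome.fa")
    chrom_lengths = {r.id: len(r.sequence) for r in genome}
    genes = read_gff_genes(args.data / "genes.gff3")
    samples = _read_samples(args.data / "samples.tsv")
    summits = pd.read_csv(args.data / "summits.tsv", sep="\t")

    peaklets = build_peaklets(
        list(zip(summits["chrom"], summits["pos"], summits["p_value"])), chrom_lengths
    )
    n_clipped = sum(p.clipped for p in peaklets)
    print(f"{len(peaklets)} peaklets retained from {len(summits)} summits "
          f"({n_clipped} clipped at chromosome edges)")

    reads = {
        bed.stem: pd.read_csv(bed, sep="\t", header=None, usecols=[0, 1, 2],
                              names=["chrom", "start", "end"])
        for bed in sorted((args.data / "reads").glob("*.bed"))
    }
    counts = count_overlaps(reads, peaklets)[list(samples.sample_ids)]
    da = differential_accessibility(counts, samples, fdr=args.fdr)
    by_tp = da.calls.groupby(["timepoint", "direction"]).size()
    print(f"{len(da.differential_ids)} differentially accessible peaklets "
          f"at FDR < {args.fdr}:")
    print(by_tp.to_string())

    ann = annotate_peaklets(peaklets, genes)
    dist = genomic_distribution(ann)
    print(dist.to_string(index=False))

    with open(args.outdir / "peaklets.bed", "w") as fh:
        for p in peaklets:
            iv = p.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peaklet_id}\t0\t.\n")
    da.table.rename_axis("peaklet_id").to_csv(args.outdir / "da_results.tsv", sep="\t")
    da.calls.to_csv(args.outdir / "da_calls.tsv", sep="\t", index=False)
    ann.to_csv(args.outdir / "peaklet_annotation.tsv", sep="\t")
    dist.to_csv(args.outdir / "genomic_distribution.tsv", sep="\t", index=False)
    print(f"wrote results to {args.outdir}")


if __name__ == "__main__":
    main()
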