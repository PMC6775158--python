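#!/usr/bin/env python
"""Differential expression vs 0 dpi and temporal K-means clustering.

Reads the counts/lengths/design written by 01, tests each post-injury
timepoint against baseline (NB Wald + LRT, BH-adjusted), standardizes
log2(TPM+1) profiles of the significant transcripts and clusters them into
K=7 temporal groups. Writes de_results.tsv, zscores.tsv and clusters.tsv
under results/expression/.
"""

import argparse
from pathlib import Path

import pandas as pd

from regengrn.expression_temporal import (
    compute_tpm,
    kmeans_temporal,
    log_zscore,
    nb_differential,
)
from regengrn.pipeline import _read_samples


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--data", type=Path, default=Path("results/data"))
    ap.add_argument("--outdir", type=Path, default=Path("results/expression"))
    ap.add_argument("--k", type=int, default=7)
    ap.add_argument("--fdr", type=float, default=0.05)
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()
    args.outdir.mkdir(parents=True, exist_ok=True)

    counts = pd.read_csv(args.data / "counts.tsv", sep="\t", index_col=0)
    lengths = pd.read_csv(
        args.data / "effective_lengths.tsv", sep="\t", index_col=0
    ).iloc[:, 0]
    samples = _read_samples(args.data / "samples.tsv")

    de = nb_differential(counts, samples)
    de_ids = de.significant(fdr=args.fdr, test="lrt")
    print(f"{len(de_ids)} of {int(de.table['tested'].sum())} tested transcripts "
          f"differentially expressed at LRT FDR < {args.fdr}")

    z = log_zscore(compute_tpm(counts, lengths), de_ids)
    clustering = kmeans_temporal(z, K=args.k, seed=args.seed)
    sizes = clustering.assignment.value_counts().sort_index()
    print(f"K-means (K={args.k}) cluster sizes: {sizes.tolist()} "
          f"(within-SS {clustering.within_ss:.1f})")

    de.table.rename_axis("transcript_id").to_csv(args.outdir / "de_results.tsv", sep="\t")
    z.z.rename_axis("transcript_id").to_csv(args.outdir / "zscores.tsv", sep="\t")
    clustering.assignment.rename_axis("transcript_id").to_frame().to_csv(
        args.outdir / "clusters.tsv", sep="\t"
    )
    print(f"wrote results to {args.outdir}")


if __name__ == "__main__":
    main()
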