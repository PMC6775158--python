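"""Regeneration-associated transcription factors and TF->target inference.

TFs are selected by cross-referencing differential expression with a TF
catalog (gene -> family -> motif id): a catalog gene is retained when at
least one of its transcripts passes the time-factor LRT at the configured
FDR and it has a usable motif. Selected TFs are assigned to the temporal
cluster of their most significant transcript, ranked by the distance from
their TSS to the nearest differentially accessible peaklet, and linked to
putative target genes through motif hits in the targets' proximal/distal
peaklets, requiring temporally compatible cluster membership.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .expression_temporal import (
    DifferentialExpressionResult,
    TemporalClustering,
    bh_adjust,
)
from .io_formats import GeneModel
from .motif_engine import HitMatrix, motif_enrichment

__all__ = [
    "TFRecord",
    "TargetEdge",
    "select_regeneration_tfs",
    "cluster_stage_enrichment",
    "rank_tfs_by_da_proximity",
    "infer_tf_targets",
    "geneset_enrichment",
    "transcript_gene_map",
    "gene_cluster_map",
]


@dataclass(frozen=True)
class TFRecord:
    gene_id: str
    transcript_ids: tuple
    family: str
    motif_id: str | None
    peak_cluster: int


@dataclass(frozen=True)
class TargetEdge:
    tf_gene_id: str
    target_gene_id: str
    evidence: tuple  # (peaklet_id, location_class, offset, strand)


def transcript_gene_map(genes) -> dict:
    return {tid: g.gene_id for g in genes for tid in g.transcript_ids}


def gene_cluster_map(
    clustering: TemporalClustering,
    genes,
    de_results: DifferentialExpressionResult | None = None,
) -> dict:
    """Gene -> cluster of its most significant clustered transcript."""
    t2g = transcript_gene_map(genes)
    best: dict[str, tuple] = {}
    for tid, cl in clustering.assignment.items():
        gid = t2g.get(tid)
        if gid is None:
            continue
        if de_results is not None and tid in de_results.table.index:
            key = de_results.table.loc[tid, "lrt_q"]
            key = np.inf if pd.isna(key) else float(key)
        else:
            key = 0.0
        if gid not in best or key < best[gid][0]:
            best[gid] = (key, int(cl))
    return {gid: cl for gid, (_k, cl) in best.items()}


def select_regeneration_tfs(
    de_results: DifferentialExpressionResult,
    tf_catalog: pd.DataFrame,
    motif_db,
    clustering: TemporalClustering,
    genes,
    fdr: float = 0.05,
):
    """Catalog TFs passing the global LRT, split by motif availability.

    Returns ``(tf_records, without_motif)``: TFs with a catalog motif that
    also exists in the motif library become :class:`TFRecord`; significant
    catalog TFs lacking a motif are reported separately and excluded from
    motif-based stages.
    """
    if len(tf_catalog) == 0:
        raise ValueError("empty TF catalog")
    motif_ids = {
        m if isinstance(m, str) else m.motif_id for m in motif_db
    }
    t2g = transcript_gene_map(genes)
    gene_transcripts: dict[str, list] = {}
    for tid, gid in t2g.items():
        gene_transcripts.setdefault(gid, []).append(tid)
    g2c = gene_cluster_map(clustering, genes, de_results)
    table = de_results.table
    records, without_motif = [], []
    for _, row in tf_catalog.iterrows():
        gid = row["gene_id"]
        tids = [t for t in gene_transcripts.get(gid, []) if t in table.index]
        if not tids:
            continue
        qs = table.loc[tids, "lrt_q"]
        if not (qs < fdr).any():
            continue
        motif_id = row.get("motif_id") or None
        if isinstance(motif_id, float) and np.isnan(motif_id):
            motif_id = None
        if motif_id and motif_id not in motif_ids:
            motif_id = None
        cluster = g2c.get(gid)
        if cluster is None:
            continue  # significant but none of its transcripts were clustered
        rec = TFRecord(
            gene_id=gid,
            transcript_ids=tuple(tids),
            family=str(row.get("family", "")),
            motif_id=motif_id,
            peak_cluster=cluster,
        )
        (records if motif_id else without_motif).append(rec)
    return records, without_motif


def cluster_stage_enrichment(
    clustering: TemporalClustering,
    annotations: pd.DataFrame,
    hit_matrix: HitMatrix,
    tfs,
    genes,
    de_results: DifferentialExpressionResult | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-cluster proximal/distal enrichment of temporally matched TF motifs.

    For each cluster and compartment, the foreground is that cluster's
    genes' proximal (resp. distal) peaklets and the background is every
    other annotated peaklet; each of the cluster's TF motifs is tested by
    Fisher exact with BH across that motif family.
    """
    g2c = gene_cluster_map(clustering, genes, de_results)
    ann = annotations[annotations["location_class"].isin(["proximal", "distal"])]
    rows = []
    clusters = sorted({tf.peak_cluster for tf in tfs})
    for c in clusters:
        cluster_genes = {g for g, cl in g2c.items() if cl == c}
        motifs = [tf.motif_id for tf in tfs if tf.peak_cluster == c and tf.motif_id]
        if not motifs:
            continue
        for compartment in ("proximal", "distal"):
            in_comp = ann[ann["location_class"] == compartment]
            fore = list(in_comp.index[in_comp["nearest_gene"].isin(cluster_genes)])
            back = list(ann.index.difference(fore))
            if not fore:
                continue
            res = motif_enrichment(
                fore, back, hit_matrix.matrix[motifs], alpha=alpha
            )
            for _, r in res.iterrows():
                rows.append(
                    {
                        "cluster": c,
                        "compartment": compartment,
                        "motif_id": r["motif_id"],
                        "n_hit_peaklets": r["foreground_hits"],
                        "n_peaklets": r["foreground_size"],
                        "odds_ratio": r["odds_ratio"],
                        "p": r["p"],
                        "q": r["q"],
                        "enriched": bool(r["enriched"]),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "cluster",
            "compartment",
            "motif_id",
            "n_hit_peaklets",
            "n_peaklets",
            "odds_ratio",
            "p",
            "q",
            "enriched",
        ],
    )


def rank_tfs_by_da_proximity(
    tfs, da_peaklet_ids, peaklets, genes, flag_bp: int = 100_000
) -> pd.DataFrame:
    """Rank TF genes by min |TSS - DA peaklet center|, ascending.

    TFs on chromosomes without differentially accessible peaklets get
    infinite distance; TFs within ``flag_bp`` are flagged.
    """
    da_set = set(da_peaklet_ids)
    centers: dict[str, list] = {}
    ids_by_chrom: dict[str, list] = {}
    for p in peaklets:
        if p.peaklet_id in da_set:
            centers.setdefault(p.interval.chrom, []).append(p.interval.center)
            ids_by_chrom.setdefault(p.interval.chrom, []).append(p.peaklet_id)
    gene_by_id = {g.gene_id: g for g in genes}
    rows = []
    for tf in tfs:
        g = gene_by_id[tf.gene_id]
        chrom = g.interval.chrom
        if chrom in centers:
            d = np.abs(np.asarray(centers[chrom]) - g.tss)
            dmin = int(d.min())
            flanking = sorted(
                pid for pid, dd in zip(ids_by_chrom[chrom], d) if dd <= flag_bp
            )
        else:
            dmin, flanking = np.inf, []
        rows.append(
            {
                "gene_id": tf.gene_id,
                "min_distance_to_da_peaklet": dmin,
                "within_flag_window": dmin <= flag_bp,
                "flanking_da_peaklet_ids": ",".join(flanking),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["min_distance_to_da_peaklet", "gene_id"], kind="mergesort"
    )
    return out.reset_index(drop=True)


def infer_tf_targets(
    tf: TFRecord,
    clustering: TemporalClustering,
    annotations: pd.DataFrame,
    hit_matrix: HitMatrix,
    genes,
    de_results: DifferentialExpressionResult | None = None,
    de_fdr: float = 0.05,
    compatibility: str = "same",
) -> list:
    """Putative targets of one TF via motif hits in the targets' peaklets.

    A gene is a target when (a) at least one of its proximal or distal
    peaklets contains a hit of the TF's motif and (b) the gene is
    differentially expressed with a temporally compatible cluster
    (``same``: identical cluster; ``same-or-adjacent``: +/- 1).
    Evidence records every supporting (peaklet, location, offset, strand).
    """
    if tf.motif_id is None:
        raise ValueError(f"TF {tf.gene_id} has no motif")
    if compatibility not in ("same", "same-or-adjacent"):
        raise ValueError("compatibility must be 'same' or 'same-or-adjacent'")
    g2c = gene_cluster_map(clustering, genes, de_results)
    if de_results is not None:
        de_ok_transcripts = set(de_results.significant(fdr=de_fdr, test="lrt"))
        t2g = transcript_gene_map(genes)
        de_genes = {t2g[t] for t in de_ok_transcripts if t in t2g}
    else:
        de_genes = set(g2c)

    hits_by_peaklet: dict[str, list] = {}
    for h in hit_matrix.hits:
        if h.motif_id == tf.motif_id:
            hits_by_peaklet.setdefault(h.peaklet_id, []).append(h)

    usable = annotations[annotations["location_class"].isin(["proximal", "distal"])]
    edges = []
    for gid, sub in usable.groupby("nearest_gene"):
        cluster = g2c.get(gid)
        if cluster is None or gid not in de_genes:
            continue
        if compatibility == "same":
            if cluster != tf.peak_cluster:
                continue
        elif abs(cluster - tf.peak_cluster) > 1:
            continue
        evidence = []
        for pid, row in sub.iterrows():
            for h in hits_by_peaklet.get(pid, []):
                evidence.append((pid, row["location_class"], h.offset, h.strand))
        if evidence:
            edges.append(
                TargetEdge(
                    tf_gene_id=tf.gene_id,
                    target_gene_id=gid,
                    evidence=tuple(sorted(evidence)),
                )
            )
    edges.sort(key=lambda e: e.target_gene_id)
    return edges


def geneset_enrichment(target_genes, genesets: dict, universe) -> pd.DataFrame:
    """Hypergeometric upper-tail enrichment of targets in each gene set."""
    universe = set(universe)
    targets = set(target_genes) & universe
    N, n = len(universe), len(targets)
    rows = []
    for set_id, members in genesets.items():
        members = set(members)
        if len(members) > N:
            raise ValueError(f"gene set {set_id!r} larger than universe")
        K = len(members & universe)
        k = len(members & targets)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append(
            {"set_id": set_id, "overlap": k, "set_size": K, "universe_size": N, "p": p}
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["q"] = bh_adjust(out["p"].to_numpy())
    return out
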