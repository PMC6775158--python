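"""End-to-end orchestration: simulate -> expression -> atac -> motifs -> network.

Every stage reads and writes plain TSV/BED/FASTA/GFF3/JASPAR files so that
reruns with an identical config and seed are byte-identical. ``run_all``
returns (and writes) a manifest recording the seed, input digests, output
paths and summary counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .chromatin_accessibility import (
    annotate_peaklets,
    build_peaklets,
    count_overlaps,
    differential_accessibility,
    genomic_distribution,
)
from .expression_temporal import (
    compute_tpm,
    kmeans_temporal,
    log_zscore,
    nb_differential,
)
from .io_formats import SampleTable, read_fasta, read_gff_genes, read_jaspar
from .motif_engine import build_hit_matrix, estimate_background, pfm_to_pwm
from .regulatory_network import (
    cluster_stage_enrichment,
    infer_tf_targets,
    rank_tfs_by_da_proximity,
    select_regeneration_tfs,
)
from .synthetic_data import SimulationConfig, simulate_all

log = logging.getLogger("regengrn")

__all__ = ["PipelineConfig", "PipelineError", "run_all"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    workdir: str = "regengrn_run"
    seed: int = 0
    # inputs (populated automatically when simulate is set)
    counts: str | None = None
    effective_lengths: str | None = None
    samples: str | None = None
    summits: str | None = None
    reads_dir: str | None = None
    genome: str | None = None
    genes_gff: str | None = None
    jaspar: str | None = None
    tf_catalog: str | None = None
    # thresholds
    de_fdr: float = 0.05
    da_fdr: float = 0.05
    peak_pcut: float = 1e-10
    peaklet_width: int = 500
    proximal_bp: int = 1000
    distal_bp: int = 100_000
    exon_overlap_bp: int = 50
    motif_threshold: float = 0.8
    K: int = 7
    kmeans_restarts: int = 10
    target_compatibility: str = "same"
    simulate: SimulationConfig | None = None

    def __post_init__(self):
        if self.proximal_bp >= self.distal_bp:
            raise ValueError("proximal_bp must be < distal_bp")
        for name in ("de_fdr", "da_fdr", "peak_pcut", "motif_threshold"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _read_samples(path) -> SampleTable:
    df = pd.read_csv(path, sep="\t")
    return SampleTable(
        tuple(df["sample_id"]),
        tuple(int(t) for t in df["timepoint_dpi"]),
        tuple(int(r) for r in df["replicate"]),
    )


def run_all(config: PipelineConfig) -> dict:
    """Execute all stages in order; any failure aborts naming the stage."""
    t0 = time.time()
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "inputs": {},
        "outputs": {},
        "counts": {},
    }

    if config.simulate is not None:
        stage = "simulate"
        try:
            log.info("stage %s", stage)
            indir = workdir / "inputs"
            simulate_all(config.simulate, outdir=indir)
            config.counts = str(indir / "counts.tsv")
            config.effective_lengths = str(indir / "effective_lengths.tsv")
            config.samples = str(indir / "samples.tsv")
            config.summits = str(indir / "summits.tsv")
            config.reads_dir = str(indir / "reads")
            config.genome = str(indir / "genome.fa")
            config.genes_gff = str(indir / "genes.gff3")
            config.jaspar = str(indir / "motifs.jaspar")
            config.tf_catalog = str(indir / "tf_catalog.tsv")
        except Exception as exc:  # noqa: BLE001 - stage-tagged abort
            raise PipelineError(stage, exc) from exc

    for name in (
        "counts",
        "effective_lengths",
        "samples",
        "summits",
        "genes_gff",
        "jaspar",
        "tf_catalog",
    ):
        path = getattr(config, name)
        if path is not None and Path(path).exists():
            manifest["inputs"][name] = _digest(path)

    # ----------------------------------------------------------------- expression
    stage = "expression"
    try:
        log.info("stage %s", stage)
        counts = pd.read_csv(config.counts, sep="\t", index_col=0)
        eff_len = pd.read_csv(config.effective_lengths, sep="\t", index_col=0).iloc[:, 0]
        samples = _read_samples(config.samples)
        tpm = compute_tpm(counts, eff_len)
        de = nb_differential(counts, samples)
        de_ids = de.significant(fdr=config.de_fdr, test="lrt")
        if len(de_ids) < config.K:
            raise ValueError(
                f"only {len(de_ids)} differentially expressed transcripts; "
                f"cannot cluster into K={config.K}"
            )
        zmat = log_zscore(tpm, de_ids)
        clustering = kmeans_temporal(
            zmat, K=config.K, seed=config.seed, n_restarts=config.kmeans_restarts
        )
        de_path = workdir / "de_results.tsv"
        de.table.rename_axis("transcript_id").to_csv(de_path, sep="\t")
        z_path = workdir / "zscores.tsv"
        zmat.z.rename_axis("transcript_id").to_csv(z_path, sep="\t")
        cl_path = workdir / "clusters.tsv"
        clustering.assignment.rename_axis("transcript_id").to_frame().to_csv(
            cl_path, sep="\t"
        )
        manifest["outputs"].update(
            de_results=str(de_path), zscores=str(z_path), clusters=str(cl_path)
        )
        manifest["counts"]["n_de_transcripts"] = int(len(de_ids))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ----------------------------------------------------------------- atac
    stage = "atac"
    try:
        log.info("stage %s", stage)
        genes = read_gff_genes(config.genes_gff)
        summits_df = pd.read_csv(config.summits, sep="\t")
        if config.genome is None or not Path(config.genome).exists():
            raise FileNotFoundError(f"genome FASTA not found: {config.genome}")
        genome = read_fasta(config.genome)
        chrom_lengths = {rec.id: len(rec.sequence) for rec in genome}
        peaklets = build_peaklets(
            list(zip(summits_df["chrom"], summits_df["pos"], summits_df["p_value"])),
            chrom_lengths,
            width=config.peaklet_width,
            p_cut=config.peak_pcut,
        )
        reads_by_sample = {}
        for bed in sorted(Path(config.reads_dir).glob("*.bed")):
            reads_by_sample[bed.stem] = pd.read_csv(
                bed,
                sep="\t",
                header=None,
                usecols=[0, 1, 2],
                names=["chrom", "start", "end"],
            )
        acc_counts = count_overlaps(reads_by_sample, peaklets)
        acc_counts = acc_counts[list(samples.sample_ids)]
        da = differential_accessibility(acc_counts, samples, fdr=config.da_fdr)
        annotations = annotate_peaklets(
            peaklets,
            genes,
            proximal_bp=config.proximal_bp,
            distal_bp=config.distal_bp,
            exon_overlap_bp=config.exon_overlap_bp,
        )
        distribution = genomic_distribution(annotations)
        pk_path = workdir / "peaklets.bed"
        with open(pk_path, "w") as fh:
            for p in peaklets:
                iv = p.interval
                fh.write(
                    f"{iv.chrom}\t{iv.start}\t{iv.end}\t{p.peaklet_id}\t0\t.\n"
                )
        ann_path = workdir / "peaklet_annotation.tsv"
        annotations.to_csv(ann_path, sep="\t")
        da_path = workdir / "da_results.tsv"
        da.table.rename_axis("peaklet_id").to_csv(da_path, sep="\t")
        calls_path = workdir / "da_calls.tsv"
        da.calls.to_csv(calls_path, sep="\t", index=False)
        dist_path = workdir / "genomic_distribution.tsv"
        distribution.to_csv(dist_path, sep="\t", index=False)
        manifest["outputs"].update(
            peaklets=str(pk_path),
            annotation=str(ann_path),
            da_results=str(da_path),
            da_calls=str(calls_path),
            genomic_distribution=str(dist_path),
        )
        manifest["counts"]["n_peaklets"] = len(peaklets)
        manifest["counts"]["n_da_peaklets"] = len(da.differential_ids)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ----------------------------------------------------------------- motifs
    stage = "motifs"
    try:
        log.info("stage %s", stage)
        pfms = read_jaspar(config.jaspar)
        seqs = {rec.id: rec.sequence for rec in genome}
        peaklet_seqs = [
            seqs[p.interval.chrom][p.interval.start : p.interval.end] for p in peaklets
        ]
        background = estimate_background(peaklet_seqs)
        pwms = [
            pfm_to_pwm(m, background, threshold_fraction=config.motif_threshold)
            for m in pfms
        ]
        hit_matrix = build_hit_matrix(peaklets, seqs, pwms)
        hm_path = workdir / "hit_matrix.tsv"
        hit_matrix.matrix.astype(int).rename_axis("peaklet_id").to_csv(
            hm_path, sep="\t"
        )
        hits_path = workdir / "motif_hits.tsv"
        pd.DataFrame(
            [
                (h.peaklet_id, h.motif_id, h.offset, h.strand, h.score)
                for h in hit_matrix.hits
            ],
            columns=["peaklet_id", "motif_id", "offset", "strand", "score"],
        ).to_csv(hits_path, sep="\t", index=False)
        manifest["outputs"].update(hit_matrix=str(hm_path), motif_hits=str(hits_path))
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    # ----------------------------------------------------------------- network
    stage = "network"
    try:
        log.info("stage %s", stage)
        tf_catalog = pd.read_csv(config.tf_catalog, sep="\t")
        tfs, tfs_without_motif = select_regeneration_tfs(
            de, tf_catalog, pfms, clustering, genes, fdr=config.de_fdr
        )
        stage_enr = cluster_stage_enrichment(
            clustering, annotations, hit_matrix, tfs, genes, de
        )
        proximity = rank_tfs_by_da_proximity(
            tfs, da.differential_ids, peaklets, genes, flag_bp=config.distal_bp
        )
        edge_rows = []
        for tf in tfs:
            for e in infer_tf_targets(
                tf,
                clustering,
                annotations,
                hit_matrix,
                genes,
                de,
                de_fdr=config.de_fdr,
                compatibility=config.target_compatibility,
            ):
                edge_rows.append(
                    {
                        "tf_gene_id": e.tf_gene_id,
                        "target_gene_id": e.target_gene_id,
                        "n_evidence_peaklets": len({ev[0] for ev in e.evidence}),
                        "evidence": ";".join(
                            f"{pid}:{loc}:{off}:{strand}"
                            for pid, loc, off, strand in e.evidence
                        ),
                    }
                )
        tf_path = workdir / "tf_records.tsv"
        pd.DataFrame(
            [
                {
                    "gene_id": tf.gene_id,
                    "family": tf.family,
                    "motif_id": tf.motif_id or "",
                    "peak_cluster": tf.peak_cluster,
                }
                for tf in tfs + tfs_without_motif
            ]
        ).to_csv(tf_path, sep="\t", index=False)
        enr_path = workdir / "cluster_stage_enrichment.tsv"
        stage_enr.to_csv(enr_path, sep="\t", index=False)
        prox_path = workdir / "tf_da_proximity.tsv"
        proximity.to_csv(prox_path, sep="\t", index=False)
        edges_path = workdir / "tf_target_edges.tsv"
        pd.DataFrame(
            edge_rows,
            columns=["tf_gene_id", "target_gene_id", "n_evidence_peaklets", "evidence"],
        ).to_csv(edges_path, sep="\t", index=False)
        manifest["outputs"].update(
            tf_records=str(tf_path),
            cluster_stage_enrichment=str(enr_path),
            tf_da_proximity=str(prox_path),
            tf_target_edges=str(edges_path),
        )
        manifest["counts"]["n_tfs"] = len(tfs)
        manifest["counts"]["n_edges"] = len(edge_rows)
    except Exception as exc:
        raise PipelineError(stage, exc) from exc

    manifest["elapsed_s"] = round(time.time() - t0, 2)
    with open(workdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
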