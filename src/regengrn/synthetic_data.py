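"""Synthetic optic-nerve-regeneration dataset with known ground truth.

Emulates the statistical structure the downstream analysis assumes:

* a small genome with regularly spaced, non-overlapping two-exon genes;
* transcript counts over a 0/2/4/7/12 days-post-injury (dpi) time course
  with seven planted temporal archetypes (early/mid/late up, early/mid/late
  down, down-then-late-up) plus flat "null" genes;
* accessible-chromatin summits near every gene (one proximal, 1-3 distal),
  with negative-binomial read counts that are stable for most peaklets and
  differentially accessible for a small planted fraction -- opening at
  2 dpi or closing at 12 dpi;
* one designated regulator (TF) gene per temporal cluster whose motif
  consensus is written verbatim into the peaklets of cluster-matched genes;
* a "jun-like" cluster-1 TF flanked by differentially open peaklets at
  2 dpi, giving the proximity-ranking stage a known answer.

All outputs are a pure function of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    BASES,
    GeneModel,
    GenomicInterval,
    MotifMatrix,
    SampleTable,
    SequenceRecord,
    write_fasta,
    write_gff_genes,
    write_jaspar,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "ClusterAssignment",
    "ARCHETYPE_NAMES",
    "archetype_profiles",
    "simulate_genome_and_annotation",
    "simulate_motif_library",
    "assign_clusters",
    "simulate_expression",
    "simulate_accessibility",
    "simulate_peaklet_counts",
    "simulate_all",
    "write_truth",
    "read_truth",
]

TIMEPOINTS = (0, 2, 4, 7, 12)

# log2 fold-change shapes over (0, 2, 4, 7, 12) dpi, in units of the
# planted effect size; index order defines the cluster index (0-based).
ARCHETYPE_NAMES = (
    "early-up",
    "mid-up",
    "late-up",
    "early-down",
    "mid-down",
    "late-down",
    "down-late-up",
)

_ARCHETYPE_SHAPES = np.array(
    [
        [0.0, 1.0, 1 / 3, 0.0, 0.0],  # early-up: peak at 2 dpi
        [0.0, 1 / 3, 1.0, 1 / 3, 0.0],  # mid-up: peak at 4 dpi
        [0.0, 0.0, 0.0, 0.5, 1.0],  # late-up: peak at 12 dpi
        [0.0, -1.0, -1.0, -1.0, -1.0],  # early-down
        [0.0, 0.0, -1.0, -1.0, -1.0],  # mid-down
        [0.0, 0.0, 0.0, -0.5, -1.0],  # late-down
        [0.0, -1.0, -1.0, -0.5, 0.5],  # down-then-late-up
    ]
)


def archetype_profiles(de_log2fc: float, n_clusters: int = 7) -> np.ndarray:
    """log2 fold-change profiles (n_clusters x 5) scaled by the effect size."""
    if n_clusters > len(ARCHETYPE_NAMES):
        raise ValueError(f"at most {len(ARCHETYPE_NAMES)} archetypes available")
    return de_log2fc * _ARCHETYPE_SHAPES[:n_clusters]


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chroms: int = 4
    chrom_length: int = 6_000_000
    n_genes: int = 2000
    n_motifs: int = 12
    n_clusters: int = 7
    timepoints: tuple = TIMEPOINTS
    replicates: int = 3
    nb_dispersion: float = 0.1
    de_log2fc: float = 2.0
    frac_da_peaklets: float = 0.05
    motif_plant_rate: float = 0.9
    frac_de_genes: float = 0.35
    accessibility_mean: float = 50.0
    expression_baseline_mean: float = 200.0
    read_length: int = 100
    gene_length: int = 2000

    def __post_init__(self):
        if self.n_clusters < 2:
            raise ValueError("n_clusters must be >= 2")
        if self.n_clusters > self.n_motifs:
            raise ValueError("need at least one motif per cluster")
        if self.chrom_length <= 10 * self.n_genes / self.n_chroms * 1000:
            raise ValueError(
                "chrom_length too small: genes cannot be placed without overlap "
                f"(need > {10 * self.n_genes / self.n_chroms * 1000:.0f} bp)"
            )
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if not 0 <= self.frac_da_peaklets <= 1:
            raise ValueError("frac_da_peaklets must be in [0, 1]")
        if not 0 <= self.motif_plant_rate <= 1:
            raise ValueError("motif_plant_rate must be in [0, 1]")

    @classmethod
    def small(cls, seed: int = 0, **overrides) -> "SimulationConfig":
        """Reduced problem size for the chromatin/motif/network stages."""
        kw = dict(seed=seed, n_chroms=3, chrom_length=1_200_000, n_genes=300)
        kw.update(overrides)
        return cls(**kw)


@dataclass
class ClusterAssignment:
    """Planted archetype per gene plus the designated per-cluster regulator."""

    cluster_of_gene: dict  # gene_id -> int cluster index or None
    tf_gene_of_cluster: dict  # cluster index -> gene_id
    motif_of_cluster: dict  # cluster index -> motif_id


@dataclass
class GroundTruth:
    cluster_of_gene: dict = field(default_factory=dict)
    tf_gene_of_cluster: dict = field(default_factory=dict)
    motif_of_cluster: dict = field(default_factory=dict)
    da_peaklets: list = field(default_factory=list)  # (peaklet_id, direction, dpi)
    planted_hits: list = field(default_factory=list)  # (peaklet_id, motif_id, offset, strand)
    true_edges: list = field(default_factory=list)  # (tf_gene_id, target_gene_id)


def _rng(config: SimulationConfig, stream: str) -> np.random.Generator:
    """Independent, named substream so stages stay reproducible in isolation."""
    import zlib

    ss = np.random.SeedSequence([config.seed, zlib.crc32(stream.encode()) % (2**31)])
    return np.random.default_rng(ss)


def _nb_draw(rng, mean, dispersion):
    mean = np.asarray(mean, dtype=float)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


# ---------------------------------------------------------------------------
# Genome + annotation


def simulate_genome_and_annotation(config: SimulationConfig):
    """Uniform-ACGT chromosomes with evenly slotted two-exon genes.

    Genes alternate strands, never overlap, and each carries one transcript,
    two exons and a strand-aware 5'UTR.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    base_lookup = np.frombuffer(b"ACGT", dtype="S1")
    chroms = []
    for ci in range(config.n_chroms):
        idx = rng.integers(0, 4, size=config.chrom_length)
        seq = base_lookup[idx].tobytes().decode()
        chroms.append(SequenceRecord(f"chr{ci + 1}", seq))

    n_per = [config.n_genes // config.n_chroms] * config.n_chroms
    for i in range(config.n_genes % config.n_chroms):
        n_per[i] += 1
    glen = config.gene_length
    genes = []
    gi = 0
    for ci, n_here in enumerate(n_per):
        if n_here == 0:
            continue
        slot = config.chrom_length // n_here
        # each slot must hold the gene body plus the farthest distal summit
        # (<= 4.25 kb beyond the TSS) with its 250 bp peaklet flank
        if slot < glen + 9700:
            raise ValueError("genes cannot be placed without overlap")
        for k in range(n_here):
            jitter = int(rng.integers(-300, 301))
            start = k * slot + slot // 2 - glen // 2 + jitter
            end = start + glen
            strand = "+" if gi % 2 == 0 else "-"
            gid = f"g{gi:04d}"
            iv = GenomicInterval(chroms[ci].id, start, end, strand)
            exon1 = GenomicInterval(chroms[ci].id, start, start + 400, strand)
            exon2 = GenomicInterval(chroms[ci].id, end - 400, end, strand)
            if strand == "+":
                utr = GenomicInterval(chroms[ci].id, start, start + 100, strand)
            else:
                utr = GenomicInterval(chroms[ci].id, end - 100, end, strand)
            genes.append(
                GeneModel(
                    gene_id=gid,
                    transcript_ids=(f"{gid}.t1",),
                    interval=iv,
                    exons=(exon1, exon2),
                    utr5=(utr,),
                )
            )
            gi += 1
    return chroms, genes


# ---------------------------------------------------------------------------
# Motifs


def simulate_motif_library(config: SimulationConfig):
    """Random informative PFMs: one dominant base (0.85) per column, counts 100."""
    rng = _rng(config, "motifs")
    motifs = []
    for mi in range(config.n_motifs):
        L = int(rng.integers(8, 13))
        dominant = rng.integers(0, 4, size=L)
        counts = np.full((4, L), 5.0)
        counts[dominant, np.arange(L)] = 85.0
        # columns sum to 100 (85 + 3*5)
        motifs.append(MotifMatrix(f"M{mi + 1:03d}", f"TF{mi + 1}", counts))
    return motifs


# ---------------------------------------------------------------------------
# Cluster / regulator assignment


def assign_clusters(genes: Sequence[GeneModel], config: SimulationConfig) -> ClusterAssignment:
    """Assign archetypes to a fraction of genes and pick one TF gene per cluster."""
    rng = _rng(config, "clusters")
    gene_ids = [g.gene_id for g in genes]
    n_de = int(round(config.frac_de_genes * len(gene_ids)))
    n_de = max(n_de, config.n_clusters)
    de_ids = list(rng.choice(gene_ids, size=n_de, replace=False))
    cluster_of_gene = {gid: None for gid in gene_ids}
    for i, gid in enumerate(de_ids):
        cluster_of_gene[gid] = i % config.n_clusters
    tf_gene_of_cluster = {}
    for c in range(config.n_clusters):
        members = [gid for gid in de_ids if cluster_of_gene[gid] == c]
        tf_gene_of_cluster[c] = members[int(rng.integers(0, len(members)))]
    motif_of_cluster = {c: f"M{c + 1:03d}" for c in range(config.n_clusters)}
    return ClusterAssignment(cluster_of_gene, tf_gene_of_cluster, motif_of_cluster)


def make_sample_table(config: SimulationConfig) -> SampleTable:
    ids, tps, reps = [], [], []
    for t in config.timepoints:
        for r in range(1, config.replicates + 1):
            ids.append(f"s{t:02d}dpi_r{r}")
            tps.append(t)
            reps.append(r)
    return SampleTable(tuple(ids), tuple(tps), tuple(reps))


# ---------------------------------------------------------------------------
# Expression


def simulate_expression(
    genes: Sequence[GeneModel],
    config: SimulationConfig,
    assignment: ClusterAssignment | None = None,
):
    """Transcript counts over the time course with planted archetype profiles.

    Returns ``(counts DataFrame, effective lengths Series, SampleTable,
    GroundTruth fragment)``. Counts are negative binomial around
    ``baseline * 2**profile[t]``.
    """
    if assignment is None:
        assignment = assign_clusters(genes, config)
    rng = _rng(config, "expression")
    samples = make_sample_table(config)
    profiles = archetype_profiles(config.de_log2fc, config.n_clusters)
    tp_index = {t: i for i, t in enumerate(TIMEPOINTS)}

    transcript_ids, rows, lengths = [], [], []
    for g in genes:
        tid = g.transcript_ids[0]
        transcript_ids.append(tid)
        baseline = rng.lognormal(np.log(config.expression_baseline_mean), 1.0)
        c = assignment.cluster_of_gene[g.gene_id]
        lfc = profiles[c] if c is not None else np.zeros(len(TIMEPOINTS))
        mu = np.array(
            [baseline * 2.0 ** lfc[tp_index[t]] for t in samples.timepoints_dpi]
        )
        rows.append(_nb_draw(rng, mu, config.nb_dispersion))
        lengths.append(int(rng.integers(500, 2501)))

    counts = pd.DataFrame(
        np.array(rows), index=transcript_ids, columns=list(samples.sample_ids)
    )
    eff_len = pd.Series(lengths, index=transcript_ids, name="effective_length", dtype=float)
    truth = GroundTruth(
        cluster_of_gene=dict(assignment.cluster_of_gene),
        tf_gene_of_cluster=dict(assignment.tf_gene_of_cluster),
        motif_of_cluster=dict(assignment.motif_of_cluster),
    )
    return counts, eff_len, samples, truth


# ---------------------------------------------------------------------------
# Accessibility


def simulate_accessibility(
    genome: Sequence[SequenceRecord],
    genes: Sequence[GeneModel],
    motifs: Sequence[MotifMatrix],
    assignment: ClusterAssignment,
    config: SimulationConfig,
    emit_reads: bool = True,
):
    """Summits, peaklet counts, optional per-sample read intervals, truth.

    Every gene gets one proximal summit (300-700 bp upstream of its TSS)
    and 1-3 distal summits (2.4-4.0 kb from the TSS). A planted fraction of
    peaklets is differentially accessible: opening (counts x 2**de_log2fc)
    at 2 dpi or closing at 12 dpi. The cluster-1 regulator gene is flanked
    by three differentially open peaklets at 2 dpi (one promoter-proximal,
    two distal), mirroring an immediate-early activation pattern. Motif
    consensus sequences of each cluster's regulator are written into the
    genome inside peaklets of cluster-matched genes at ``motif_plant_rate``.

    Returns ``(summits DataFrame, peaklets, counts DataFrame,
    reads_by_sample, genome_out, GroundTruth fragment)``.
    """
    from .chromatin_accessibility import build_peaklets

    rng = _rng(config, "accessibility")
    chrom_lengths = {rec.id: len(rec.sequence) for rec in genome}
    motif_by_id = {m.motif_id: m for m in motifs}
    tf_genes = set(assignment.tf_gene_of_cluster.values())
    jun_like = assignment.tf_gene_of_cluster.get(0)

    # --- summits -----------------------------------------------------------
    summit_rows = []  # (chrom, pos, p, gene_id, forced_da)
    for g in genes:
        tss = g.tss
        upstream = -1 if g.interval.strand == "+" else +1
        if g.gene_id == jun_like:
            offsets = [(400 * upstream, True), (3600, True), (-3600, True)]
        else:
            prox = int(rng.integers(300, 701)) * upstream
            offsets = [(prox, False)]
            # distal summits start beyond the 2 kb gene body so their 500 bp
            # peaklets never overlap exons by more than 50 bp
            for _ in range(int(rng.integers(1, 4))):
                off = int(rng.integers(2400, 4001)) * (1 if rng.random() < 0.5 else -1)
                offsets.append((off, False))
        for off, forced in offsets:
            pos = tss + off
            if not 250 <= pos < chrom_lengths[g.interval.chrom] - 250:
                continue
            log10p = rng.uniform(-30.0, -15.0)
            summit_rows.append((g.interval.chrom, pos, 10.0 ** log10p, g.gene_id, forced))
    # sub-threshold decoy summits, dropped by the p < 1e-10 retention rule
    n_decoys = max(1, len(summit_rows) // 20)
    chrom_names = list(chrom_lengths)
    for _ in range(n_decoys):
        chrom = chrom_names[int(rng.integers(0, len(chrom_names)))]
        pos = int(rng.integers(250, chrom_lengths[chrom] - 250))
        summit_rows.append((chrom, pos, 10.0 ** rng.uniform(-9.9, -5.0), None, False))

    summits = pd.DataFrame(
        summit_rows, columns=["chrom", "pos", "p_value", "gene_id", "forced_da"]
    )
    peaklets = build_peaklets(
        list(zip(summits["chrom"], summits["pos"], summits["p_value"])),
        chrom_lengths,
    )
    # map each retained peaklet back to its source gene for truth bookkeeping
    retained = summits[summits["p_value"] < 1e-10].sort_values(["chrom", "pos"])
    retained = retained.reset_index(drop=True)
    assert len(retained) == len(peaklets)
    pid_gene = dict(zip((p.peaklet_id for p in peaklets), retained["gene_id"]))
    pid_forced = dict(zip((p.peaklet_id for p in peaklets), retained["forced_da"]))

    # --- differential accessibility ---------------------------------------
    truth = GroundTruth()
    da_direction = {}  # peaklet_id -> (direction, dpi)
    forced_ids = [pid for pid, f in pid_forced.items() if f]
    for pid in forced_ids:
        da_direction[pid] = ("open", 2)
    eligible = [
        p.peaklet_id
        for p in peaklets
        if p.peaklet_id not in da_direction and pid_gene[p.peaklet_id] not in tf_genes
    ]
    n_da = int(round(config.frac_da_peaklets * len(peaklets)))
    n_da = min(max(n_da - len(forced_ids), 0), len(eligible))
    chosen = rng.choice(eligible, size=n_da, replace=False) if n_da else []
    for i, pid in enumerate(chosen):
        da_direction[pid] = ("open", 2) if i % 2 == 0 else ("closed", 12)
    truth.da_peaklets = [
        (pid, d, t) for pid, (d, t) in sorted(da_direction.items())
    ]

    # --- counts ------------------------------------------------------------
    samples = make_sample_table(config)
    n_s = len(samples)
    mu = np.full((len(peaklets), n_s), config.accessibility_mean)
    tp = np.asarray(samples.timepoints_dpi)
    for pi, p in enumerate(peaklets):
        hit = da_direction.get(p.peaklet_id)
        if hit is None:
            continue
        direction, dpi = hit
        factor = 2.0 ** config.de_log2fc
        mu[pi, tp == dpi] *= factor if direction == "open" else 1.0 / factor
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    counts_df = pd.DataFrame(
        counts,
        index=[p.peaklet_id for p in peaklets],
        columns=list(samples.sample_ids),
    )

    # --- motif planting ----------------------------------------------------
    seqs = {rec.id: bytearray(rec.sequence, "ascii") for rec in genome}
    planted = []
    planted_spans: dict[str, list] = {}  # chrom -> (start, end, motif_id, strand)
    for p in peaklets:
        gid = pid_gene[p.peaklet_id]
        if gid is None:
            continue
        c = assignment.cluster_of_gene.get(gid)
        if c is None:
            continue
        if rng.random() >= config.motif_plant_rate:
            continue
        motif = motif_by_id[assignment.motif_of_cluster[c]]
        site = motif.consensus
        if motif.length > p.interval.width:
            raise ValueError("planted motif longer than peaklet")
        spans = planted_spans.setdefault(p.interval.chrom, [])
        # overlapping peaklets of the same gene may already contain the site
        reused = next(
            (
                s
                for s in spans
                if s[2] == motif.motif_id
                and s[0] >= p.interval.start
                and s[1] <= p.interval.end
            ),
            None,
        )
        if reused is not None:
            planted.append(
                (p.peaklet_id, motif.motif_id, reused[0] - p.interval.start, reused[3])
            )
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        inserted = site if strand == "+" else _revcomp(site)
        for _attempt in range(20):
            offset = int(rng.integers(0, p.interval.width - motif.length + 1))
            start = p.interval.start + offset
            end = start + motif.length
            if any(s[0] < end and s[1] > start for s in spans):
                continue  # would overwrite an earlier planted site
            seqs[p.interval.chrom][start:end] = inserted.encode()
            spans.append((start, end, motif.motif_id, strand))
            planted.append((p.peaklet_id, motif.motif_id, offset, strand))
            break
    truth.planted_hits = planted

    planted_by_gene = {}
    for pid, mid, _off, _s in planted:
        planted_by_gene.setdefault(pid_gene[pid], set()).add(mid)
    edges = []
    for c, tf_gid in assignment.tf_gene_of_cluster.items():
        mid = assignment.motif_of_cluster[c]
        for gid, cl in assignment.cluster_of_gene.items():
            if cl == c and mid in planted_by_gene.get(gid, ()):
                edges.append((tf_gid, gid))
    truth.true_edges = sorted(edges)

    genome_out = [SequenceRecord(rec.id, seqs[rec.id].decode()) for rec in genome]

    # --- read intervals ----------------------------------------------------
    reads_by_sample = {}
    if emit_reads:
        half = config.read_length // 2
        for si, sid in enumerate(samples.sample_ids):
            chroms_out, starts_out = [], []
            for pi, p in enumerate(peaklets):
                n_reads = int(counts[pi, si])
                if n_reads == 0:
                    continue
                jitter = rng.integers(-150, 151, size=n_reads)
                center = (p.interval.start + p.interval.end) // 2
                starts_out.append(center - half + jitter)
                chroms_out.extend([p.interval.chrom] * n_reads)
            starts = (
                np.concatenate(starts_out) if starts_out else np.empty(0, dtype=int)
            )
            reads_by_sample[sid] = pd.DataFrame(
                {
                    "chrom": chroms_out,
                    "start": starts,
                    "end": starts + config.read_length,
                }
            )
    return summits, peaklets, counts_df, reads_by_sample, genome_out, truth


def simulate_peaklet_counts(
    n_peaklets: int,
    n_da: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    da_dpi: int = 2,
    direction: str = "open",
):
    """Focused count-matrix simulation for differential-accessibility checks.

    The first ``n_da`` peaklets change at ``da_dpi`` (open: x 2**de_log2fc;
    closed: the inverse); the rest are stable.
    """
    samples = make_sample_table(config)
    tp = np.asarray(samples.timepoints_dpi)
    mu = np.full((n_peaklets, len(samples)), config.accessibility_mean)
    factor = 2.0 ** config.de_log2fc
    if direction == "closed":
        factor = 1.0 / factor
    mu[:n_da, tp == da_dpi] *= factor
    counts = _nb_draw(rng, mu, config.nb_dispersion)
    ids = [f"pk{i:05d}" for i in range(n_peaklets)]
    return pd.DataFrame(counts, index=ids, columns=list(samples.sample_ids)), samples


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGTN", "TGCAN"))[::-1]


# ---------------------------------------------------------------------------
# Bundles + truth manifest


def simulate_all(config: SimulationConfig, outdir=None, emit_reads: bool = True):
    """Run every generator stage consistently; optionally write all files.

    Returns a dict with keys: genome, genes, motifs, assignment, counts,
    effective_lengths, samples, summits, peaklets, accessibility_counts,
    reads_by_sample, truth, tf_catalog.
    """
    genome, genes = simulate_genome_and_annotation(config)
    motifs = simulate_motif_library(config)
    assignment = assign_clusters(genes, config)
    counts, eff_len, samples, truth_expr = simulate_expression(genes, config, assignment)
    summits, peaklets, acc_counts, reads, genome_out, truth_acc = simulate_accessibility(
        genome, genes, motifs, assignment, config, emit_reads=emit_reads
    )
    truth = GroundTruth(
        cluster_of_gene=truth_expr.cluster_of_gene,
        tf_gene_of_cluster=truth_expr.tf_gene_of_cluster,
        motif_of_cluster=truth_expr.motif_of_cluster,
        da_peaklets=truth_acc.da_peaklets,
        planted_hits=truth_acc.planted_hits,
        true_edges=truth_acc.true_edges,
    )
    tf_catalog = _tf_catalog(assignment, motifs, genes, config)
    bundle = {
        "genome": genome_out,
        "genes": genes,
        "motifs": motifs,
        "assignment": assignment,
        "counts": counts,
        "effective_lengths": eff_len,
        "samples": samples,
        "summits": summits,
        "peaklets": peaklets,
        "accessibility_counts": acc_counts,
        "reads_by_sample": reads,
        "truth": truth,
        "tf_catalog": tf_catalog,
    }
    if outdir is not None:
        _write_bundle(bundle, Path(outdir))
    return bundle


def _tf_catalog(assignment, motifs, genes, config):
    """TF catalog table: the per-cluster regulators plus motif-less decoys."""
    motif_tf = {m.motif_id: m.tf_name for m in motifs}
    rows = []
    for c in sorted(assignment.tf_gene_of_cluster):
        mid = assignment.motif_of_cluster[c]
        rows.append(
            {
                "gene_id": assignment.tf_gene_of_cluster[c],
                "family": f"family{c % 4}",
                "motif_id": mid,
                "tf_name": motif_tf[mid],
            }
        )
    # a couple of catalog entries without motifs, drawn from null genes
    null_ids = sorted(
        gid for gid, cl in assignment.cluster_of_gene.items() if cl is None
    )
    for gid in null_ids[:2]:
        rows.append({"gene_id": gid, "family": "familyX", "motif_id": "", "tf_name": ""})
    return pd.DataFrame(rows)


def _write_bundle(bundle, outdir: Path):
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(bundle["genome"], outdir / "genome.fa")
    write_gff_genes(bundle["genes"], outdir / "genes.gff3")
    write_jaspar(bundle["motifs"], outdir / "motifs.jaspar")
    bundle["counts"].rename_axis("transcript_id").to_csv(
        outdir / "counts.tsv", sep="\t"
    )
    bundle["effective_lengths"].rename_axis("transcript_id").to_frame().to_csv(
        outdir / "effective_lengths.tsv", sep="\t"
    )
    st = bundle["samples"]
    pd.DataFrame(
        {
            "sample_id": st.sample_ids,
            "timepoint_dpi": st.timepoints_dpi,
            "replicate": st.replicates,
        }
    ).to_csv(outdir / "samples.tsv", sep="\t", index=False)
    bundle["summits"][["chrom", "pos", "p_value"]].to_csv(
        outdir / "summits.tsv", sep="\t", index=False
    )
    reads_dir = outdir / "reads"
    reads_dir.mkdir(exist_ok=True)
    for sid, df in bundle["reads_by_sample"].items():
        bed = df.copy()
        bed["name"] = "read"
        bed["score"] = 0
        bed["strand"] = "+"
        bed.to_csv(reads_dir / f"{sid}.bed", sep="\t", index=False, header=False)
    bundle["tf_catalog"].to_csv(outdir / "tf_catalog.tsv", sep="\t", index=False)
    write_truth(bundle["truth"], outdir / "truth.json")


def write_truth(truth: GroundTruth, path) -> None:
    payload = {
        "cluster_of_gene": truth.cluster_of_gene,
        "tf_gene_of_cluster": {str(k): v for k, v in truth.tf_gene_of_cluster.items()},
        "motif_of_cluster": {str(k): v for k, v in truth.motif_of_cluster.items()},
        "da_peaklets": [list(x) for x in truth.da_peaklets],
        "planted_hits": [list(x) for x in truth.planted_hits],
        "true_edges": [list(x) for x in truth.true_edges],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)


def read_truth(path) -> GroundTruth:
    with open(path) as fh:
        payload = json.load(fh)
    return GroundTruth(
        cluster_of_gene=payload["cluster_of_gene"],
        tf_gene_of_cluster={int(k): v for k, v in payload["tf_gene_of_cluster"].items()},
        motif_of_cluster={int(k): v for k, v in payload["motif_of_cluster"].items()},
        da_peaklets=[tuple(x) for x in payload["da_peaklets"]],
        planted_hits=[tuple(x) for x in payload["planted_hits"]],
        true_edges=[tuple(x) for x in payload["true_edges"]],
    )
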