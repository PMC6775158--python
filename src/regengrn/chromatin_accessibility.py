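"""Accessible-chromatin peaklets: construction, counting, testing, annotation.

A "peaklet" is a fixed 500 bp window centered on a retained peak summit
(summit p-value < 1e-10), the unit of accessible chromatin throughout the
pipeline. Accessibility is quantified by counting overlapping reads per
sample and tested for differential accessibility against 0 dpi with the
same NB machinery as the expression analysis. Peaklets are annotated
relative to gene models: proximal (center within 1 kb of a TSS), distal
(1 kb to 100 kb), or unassigned; peaklets overlapping an exon by more than
50 bp are excluded from the proximal/distal assignment but still receive a
genic class (5'UTR > exon > intron > intergenic by precedence).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

from .expression_temporal import DifferentialExpressionResult, nb_differential
from .io_formats import GeneModel, GenomicInterval, SampleTable

__all__ = [
    "PeakSummit",
    "Peaklet",
    "build_peaklets",
    "count_overlaps",
    "differential_accessibility",
    "DifferentialAccessibilityResult",
    "annotate_peaklets",
    "genomic_distribution",
]

DEFAULT_WIDTH = 500
DEFAULT_P_CUT = 1e-10
PROXIMAL_BP = 1000
DISTAL_BP = 100_000
EXON_OVERLAP_BP = 50


@dataclass(frozen=True)
class PeakSummit:
    chrom: str
    pos: int
    p_value: float

    def __post_init__(self):
        if not 0 < self.p_value <= 1:
            raise ValueError(f"summit p-value {self.p_value} outside (0, 1]")
        if self.pos < 0:
            raise ValueError("summit position must be nonnegative")


@dataclass(frozen=True)
class Peaklet:
    peaklet_id: str
    interval: GenomicInterval
    summit: PeakSummit

    @property
    def clipped(self) -> bool:
        return self.interval.width != DEFAULT_WIDTH


def build_peaklets(
    summits,
    chrom_lengths: dict,
    width: int = DEFAULT_WIDTH,
    p_cut: float = DEFAULT_P_CUT,
) -> list:
    """Fixed-width windows around retained summits.

    Summits with p-value >= ``p_cut`` are dropped; each retained summit at
    position ``s`` yields ``[s - width/2, s + width/2)`` clipped to the
    chromosome. Overlapping peaklets are kept as distinct entries; ids are
    assigned in (chrom, pos) sort order.
    """
    if width % 2 != 0:
        raise ValueError("peaklet width must be even")
    half = width // 2
    parsed = []
    for s in summits:
        if isinstance(s, PeakSummit):
            parsed.append(s)
        else:
            chrom, pos, p = s
            parsed.append(PeakSummit(str(chrom), int(pos), float(p)))
    retained = [s for s in parsed if s.p_value < p_cut]
    for s in retained:
        if s.chrom not in chrom_lengths:
            raise ValueError(f"summit on unknown chromosome {s.chrom!r}")
        if s.pos >= chrom_lengths[s.chrom]:
            raise ValueError(f"summit {s.chrom}:{s.pos} beyond chromosome end")
    retained.sort(key=lambda s: (s.chrom, s.pos))
    peaklets = []
    for i, s in enumerate(retained):
        start = max(0, s.pos - half)
        end = min(chrom_lengths[s.chrom], s.pos + half)
        peaklets.append(
            Peaklet(f"peaklet_{i:05d}", GenomicInterval(s.chrom, start, end), s)
        )
    return peaklets


def count_overlaps(reads_by_sample: dict, peaklets, samples: SampleTable | None = None):
    """Count reads overlapping each peaklet by >= 1 bp, per sample.

    ``reads_by_sample`` maps sample id to a DataFrame with columns
    chrom/start/end (0-based half-open). A read overlapping two peaklets
    counts in both. Returns a peaklet x sample count DataFrame.
    """
    pids = [p.peaklet_id for p in peaklets]
    out = pd.DataFrame(0, index=pids, columns=list(reads_by_sample), dtype=int)
    by_chrom: dict[str, list] = {}
    for p in peaklets:
        by_chrom.setdefault(p.interval.chrom, []).append(p)
    for sid, reads in reads_by_sample.items():
        if not isinstance(reads, pd.DataFrame):
            reads = pd.DataFrame(
                [(iv.chrom, iv.start, iv.end) for iv in reads],
                columns=["chrom", "start", "end"],
            )
        for chrom, grp in reads.groupby("chrom", sort=False):
            plist = by_chrom.get(chrom)
            if not plist:
                continue
            starts = np.sort(grp["start"].to_numpy())
            ends = np.sort(grp["end"].to_numpy())
            p_start = np.array([p.interval.start for p in plist])
            p_end = np.array([p.interval.end for p in plist])
            # reads with start < peaklet_end minus reads ending at/before start
            n = np.searchsorted(starts, p_end, side="left") - np.searchsorted(
                ends, p_start, side="right"
            )
            out.loc[[p.peaklet_id for p in plist], sid] = n
    return out


@dataclass
class DifferentialAccessibilityResult:
    """NB test results per peaklet with open/closed direction calls."""

    de: DifferentialExpressionResult
    fdr: float
    calls: pd.DataFrame  # columns: peaklet_id, timepoint, direction, log2fc, q

    @property
    def table(self) -> pd.DataFrame:
        return self.de.table

    @property
    def differential_ids(self) -> list:
        return sorted(self.calls["peaklet_id"].unique())


def differential_accessibility(
    counts: pd.DataFrame, samples: SampleTable, fdr: float = 0.05
) -> DifferentialAccessibilityResult:
    """Per-contrast NB Wald tests; a peaklet is differentially accessible if
    any contrast is significant at the given FDR. Direction is the sign of
    the log2 fold-change at that contrast (open > 0, closed < 0)."""
    de = nb_differential(counts, samples)
    rows = []
    for t in de.contrasts:
        q = de.table[f"wald_q_{t}"]
        lfc = de.table[f"log2fc_{t}"]
        sig = de.table.index[(q < fdr).fillna(False)]
        for pid in sig:
            rows.append(
                {
                    "peaklet_id": pid,
                    "timepoint": t,
                    "direction": "open" if lfc.loc[pid] > 0 else "closed",
                    "log2fc": lfc.loc[pid],
                    "q": q.loc[pid],
                }
            )
    calls = pd.DataFrame(rows, columns=["peaklet_id", "timepoint", "direction", "log2fc", "q"])
    return DifferentialAccessibilityResult(de=de, fdr=fdr, calls=calls)


# ---------------------------------------------------------------------------
# Annotation


def _tree(intervals) -> dict:
    trees: dict[str, IntervalTree] = {}
    for iv, payload in intervals:
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, payload)
    return trees


def annotate_peaklets(
    peaklets,
    genes,
    proximal_bp: int = PROXIMAL_BP,
    distal_bp: int = DISTAL_BP,
    exon_overlap_bp: int = EXON_OVERLAP_BP,
) -> pd.DataFrame:
    """Classify peaklets relative to gene models.

    Distance is |peaklet center - TSS|, minimized over genes (ties broken
    by lexicographic gene id). Location class: proximal (<= proximal_bp),
    distal (in (proximal_bp, distal_bp)), else unassigned. Peaklets whose
    maximum overlap with any single exon exceeds ``exon_overlap_bp`` are
    excluded from the proximal/distal assignment (location unassigned,
    reason 'exonic'). Genic class by precedence 5'UTR > exon > intron >
    intergenic on any 1 bp overlap.
    """
    genes = sorted(genes, key=lambda g: g.gene_id)
    tss_by_chrom: dict[str, tuple] = {}
    for g in genes:
        tss_by_chrom.setdefault(g.interval.chrom, ([], []))
        tss_by_chrom[g.interval.chrom][0].append(g.tss)
        tss_by_chrom[g.interval.chrom][1].append(g.gene_id)
    exon_trees = _tree((ex, g.gene_id) for g in genes for ex in g.exons)
    utr_trees = _tree((u, g.gene_id) for g in genes for u in g.utr5)
    gene_trees = _tree((g.interval, g.gene_id) for g in genes)

    rows = []
    for p in peaklets:
        iv = p.interval
        center = iv.center
        chrom = iv.chrom
        # nearest TSS
        if chrom in tss_by_chrom:
            tss_arr = np.asarray(tss_by_chrom[chrom][0])
            d = np.abs(tss_arr - center)
            j = int(d.argmin())  # first occurrence = smallest gene_id (sorted)
            nearest, dist = tss_by_chrom[chrom][1][j], int(d[j])
        else:
            nearest, dist = None, None
        # exon overlap
        max_exon_ov = 0
        exonic_hit = False
        for hit in exon_trees.get(chrom, IntervalTree()).overlap(iv.start, iv.end):
            exonic_hit = True
            ov = min(iv.end, hit.end) - max(iv.start, hit.begin)
            max_exon_ov = max(max_exon_ov, ov)
        utr_hit = bool(utr_trees.get(chrom, IntervalTree()).overlap(iv.start, iv.end))
        genic_hit = bool(gene_trees.get(chrom, IntervalTree()).overlap(iv.start, iv.end))
        if utr_hit:
            genic_class = "5'UTR"
        elif exonic_hit:
            genic_class = "exon"
        elif genic_hit:
            genic_class = "intron"
        else:
            genic_class = "intergenic"
        if max_exon_ov > exon_overlap_bp:
            location, reason = "unassigned", "exonic"
        elif dist is None:
            location, reason = "unassigned", "no_gene_on_chrom"
        elif dist <= proximal_bp:
            location, reason = "proximal", ""
        elif dist < distal_bp:
            location, reason = "distal", ""
        else:
            location, reason = "unassigned", "beyond_distal_window"
        rows.append(
            {
                "peaklet_id": p.peaklet_id,
                "location_class": location,
                "genic_class": genic_class,
                "nearest_gene": nearest,
                "tss_distance": dist,
                "unassigned_reason": reason,
            }
        )
    return pd.DataFrame(rows).set_index("peaklet_id")


def genomic_distribution(annotations: pd.DataFrame) -> pd.DataFrame:
    """Fractions of peaklets per genic class and per location class."""
    if len(annotations) == 0:
        raise ValueError("no annotations provided")
    rows = []
    for axis in ("genic_class", "location_class"):
        frac = annotations[axis].value_counts(normalize=True)
        for cls, f in frac.items():
            rows.append({"axis": axis, "class": cls, "fraction": float(f)})
    return pd.DataFrame(rows)
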