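"""Readers/writers for the standard formats the pipeline touches.

Coordinate convention: every interval in this package is 0-based,
half-open ``[start, end)``. BED is native; GFF3 (1-based, closed) is
converted on read and is the only 1-based entry point. The TSS of a
'-'-strand gene is ``end - 1`` in half-open coordinates (the biological
5' end).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

__all__ = [
    "FormatError",
    "GenomicInterval",
    "SequenceRecord",
    "GeneModel",
    "MotifMatrix",
    "SampleTable",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "read_gff_genes",
    "write_gff_genes",
    "read_jaspar",
    "write_jaspar",
    "write_table",
]

_VALID_BASES = set("ACGTN")
BASES = ("A", "C", "G", "T")


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not self.chrom:
            raise ValueError("chrom must be nonempty")
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def center(self) -> int:
        return (self.start + self.end) // 2

    def overlap_bp(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))


@dataclass(frozen=True)
class SequenceRecord:
    id: str
    sequence: str

    def __post_init__(self):
        if len(self.sequence) < 1:
            raise ValueError(f"empty sequence for record {self.id!r}")
        bad = set(self.sequence) - _VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r} contains characters outside ACGTN: {sorted(bad)}"
            )


@dataclass(frozen=True)
class GeneModel:
    """Gene with strand-resolved TSS, exons and 5'UTR intervals."""

    gene_id: str
    transcript_ids: tuple
    interval: GenomicInterval
    exons: tuple = ()
    utr5: tuple = ()

    def __post_init__(self):
        for ex in self.exons:
            if ex.start < self.interval.start or ex.end > self.interval.end:
                raise ValueError(f"exon {ex} outside gene {self.gene_id}")

    @property
    def tss(self) -> int:
        """5' end of the gene: start on '+', end-1 on '-'."""
        if self.interval.strand == "-":
            return self.interval.end - 1
        return self.interval.start


@dataclass(frozen=True)
class MotifMatrix:
    """Position frequency matrix: 4 x L base counts, rows A,C,G,T."""

    motif_id: str
    tf_name: str
    counts: np.ndarray

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x L matrix")
        if counts.shape[1] < 4:
            raise ValueError("motif length must be >= 4")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if np.any(counts.sum(axis=0) <= 0):
            raise ValueError("every column must have positive total count")

    @property
    def length(self) -> int:
        return self.counts.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in np.argmax(self.counts, axis=0))


@dataclass(frozen=True)
class SampleTable:
    """Design table mapping samples to (days-post-injury, replicate)."""

    sample_ids: tuple
    timepoints_dpi: tuple
    replicates: tuple

    VALID_TIMEPOINTS = (0, 2, 4, 7, 12)

    def __post_init__(self):
        if not (len(self.sample_ids) == len(self.timepoints_dpi) == len(self.replicates)):
            raise ValueError("sample table columns must have equal length")
        for t in self.timepoints_dpi:
            if t not in self.VALID_TIMEPOINTS:
                raise ValueError(f"timepoint {t} not in {self.VALID_TIMEPOINTS}")
        pairs = list(zip(self.timepoints_dpi, self.replicates))
        if len(set(pairs)) != len(pairs):
            raise ValueError("(timepoint, replicate) pairs must be unique")

    def __len__(self):
        return len(self.sample_ids)

    @property
    def timepoint_levels(self) -> tuple:
        return tuple(sorted(set(self.timepoints_dpi)))

    def sample_indices(self, timepoint: int) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.timepoints_dpi) == timepoint)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> list:
    """Read a FASTA file into uppercased :class:`SequenceRecord` objects."""
    records = []
    with open(path) as fh:
        first = fh.read(1)
        if first == "":
            raise FormatError(f"{path}: empty FASTA file")
        if first != ">":
            raise FormatError(f"{path}: FASTA must start with '>'")
        fh.seek(0)
        for rec in SeqIO.parse(fh, "fasta"):
            if not rec.id:
                raise FormatError(f"{path}: record with empty header")
            records.append(SequenceRecord(rec.id, str(rec.seq).upper()))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path, width: int = 80) -> None:
    bio = [
        _BioSeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(bio)


# ---------------------------------------------------------------------------
# BED


def read_bed(path):
    """Read BED3/BED6 into intervals plus optional (name, score) columns.

    Returns a list of ``(GenomicInterval, name, score)`` tuples; name is
    ``None`` and score ``0.0`` when the columns are absent.
    """
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            if start >= end:
                raise FormatError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 else None
            try:
                score = float(fields[4]) if len(fields) > 4 and fields[4] != "." else 0.0
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            out.append((GenomicInterval(chrom, start, end, strand), name, score))
    return out


# ---------------------------------------------------------------------------
# GFF3 gene models

_GFF_ATTR = re.compile(r"([^=;]+)=([^;]*)")


def _gff_attrs(s: str) -> dict:
    return {k.strip(): v for k, v in _GFF_ATTR.findall(s)}


def read_gff_genes(path) -> list:
    """Read gene/mRNA/exon/five_prime_UTR features from GFF3 into GeneModels.

    GFF 1-based closed coordinates are converted to 0-based half-open.
    Raises :class:`FormatError` on orphan ``Parent`` references.
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    pending: list[tuple] = []  # (kind, parent_mrna, interval, lineno)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GFF columns")
            chrom, _src, ftype, start1, end1, _score, strand, _frame, attrs = fields
            try:
                start, end = int(start1) - 1, int(end1)
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-integer coordinates") from exc
            a = _gff_attrs(attrs)
            if ftype == "gene":
                gid = a.get("ID")
                if gid is None:
                    raise FormatError(f"{path}:{lineno}: gene without ID")
                genes[gid] = {
                    "interval": GenomicInterval(chrom, start, end, strand),
                    "transcripts": [],
                    "exons": [],
                    "utr5": [],
                }
            elif ftype == "mRNA":
                tid, parent = a.get("ID"), a.get("Parent")
                if tid is None or parent is None:
                    raise FormatError(f"{path}:{lineno}: mRNA needs ID and Parent")
                if parent not in genes:
                    raise FormatError(
                        f"{path}:{lineno}: mRNA Parent {parent!r} not a known gene"
                    )
                mrna_parent[tid] = parent
                genes[parent]["transcripts"].append(tid)
            elif ftype in ("exon", "five_prime_UTR"):
                parent = a.get("Parent")
                if parent is None:
                    raise FormatError(f"{path}:{lineno}: {ftype} without Parent")
                pending.append(
                    (ftype, parent, GenomicInterval(chrom, start, end, strand), lineno)
                )
    for ftype, parent, iv, lineno in pending:
        if parent not in mrna_parent:
            raise FormatError(
                f"{path}:{lineno}: {ftype} Parent {parent!r} not a known mRNA"
            )
        rec = genes[mrna_parent[parent]]
        rec["exons" if ftype == "exon" else "utr5"].append(iv)
    out = []
    for gid in sorted(genes):
        rec = genes[gid]
        out.append(
            GeneModel(
                gene_id=gid,
                transcript_ids=tuple(rec["transcripts"]),
                interval=rec["interval"],
                exons=tuple(sorted(rec["exons"], key=lambda iv: iv.start)),
                utr5=tuple(sorted(rec["utr5"], key=lambda iv: iv.start)),
            )
        )
    return out


def write_gff_genes(genes: Sequence[GeneModel], path) -> None:
    """Write GeneModels as GFF3 (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            iv = g.interval
            fh.write(
                f"{iv.chrom}\tregengrn\tgene\t{iv.start + 1}\t{iv.end}\t.\t"
                f"{iv.strand}\t.\tID={g.gene_id}\n"
            )
            for tid in g.transcript_ids:
                fh.write(
                    f"{iv.chrom}\tregengrn\tmRNA\t{iv.start + 1}\t{iv.end}\t.\t"
                    f"{iv.strand}\t.\tID={tid};Parent={g.gene_id}\n"
                )
                for ex in g.exons:
                    fh.write(
                        f"{iv.chrom}\tregengrn\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                        f"{iv.strand}\t.\tParent={tid}\n"
                    )
                for u in g.utr5:
                    fh.write(
                        f"{iv.chrom}\tregengrn\tfive_prime_UTR\t{u.start + 1}\t"
                        f"{u.end}\t.\t{iv.strand}\t.\tParent={tid}\n"
                    )


# ---------------------------------------------------------------------------
# JASPAR PFM text

_JASPAR_ROW = re.compile(r"^\s*([ACGT])\s*\[?\s*([0-9.\s]*?)\s*\]?\s*$")


def read_jaspar(path) -> list:
    """Parse JASPAR-style PFM text (">ID NAME" + 4 bracketed count rows)."""
    motifs = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    i = 0
    while i < len(lines):
        header = lines[i]
        if not header.startswith(">"):
            raise FormatError(f"{path}: expected '>' header, got {header!r}")
        parts = header[1:].split(None, 1)
        if not parts:
            raise FormatError(f"{path}: empty motif header")
        motif_id = parts[0]
        tf_name = parts[1].strip() if len(parts) > 1 else motif_id
        rows: dict[str, list] = {}
        i += 1
        while i < len(lines) and not lines[i].startswith(">"):
            m = _JASPAR_ROW.match(lines[i])
            if not m:
                raise FormatError(f"{path}: malformed count row {lines[i]!r}")
            base, nums = m.group(1), m.group(2).split()
            rows[base] = [float(x) for x in nums]
            i += 1
        if set(rows) != set(BASES):
            raise FormatError(
                f"{path}: motif {motif_id} missing rows for {sorted(set(BASES) - set(rows))}"
            )
        lengths = {len(v) for v in rows.values()}
        if len(lengths) != 1:
            raise FormatError(f"{path}: motif {motif_id} has rows of unequal length")
        counts = np.array([rows[b] for b in BASES])
        motifs.append(MotifMatrix(motif_id, tf_name, counts))
    if not motifs:
        raise FormatError(f"{path}: no motifs found")
    return motifs


def write_jaspar(motifs: Iterable[MotifMatrix], path) -> None:
    with open(path, "w") as fh:
        for m in motifs:
            fh.write(f">{m.motif_id} {m.tf_name}\n")
            for bi, base in enumerate(BASES):
                row = " ".join(f"{v:g}" for v in m.counts[bi])
                fh.write(f"{base} [ {row} ]\n")


# ---------------------------------------------------------------------------
# Tables


def write_table(rows, path, format: str = "TSV", columns: Sequence[str] | None = None):
    """Write rows (list of dicts or a DataFrame) as TSV (header) or BED (no header)."""
    import pandas as pd

    fmt = format.upper()
    if fmt not in ("TSV", "BED"):
        raise ValueError(f"unknown table format {format!r}")
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows), columns=columns)
    if columns is not None:
        df = df.reindex(columns=list(columns))
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, header=(fmt == "TSV"))
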