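"""PWM motif scanning, enrichment testing and co-occurrence networks.

Position frequency matrices are converted to log2-odds position weight
matrices against a background nucleotide distribution, and sequences are
scanned on both strands; a window is a hit when its score reaches a fixed
fraction (default 0.8) of the motif's maximum achievable score. Per-peaklet
presence is binarized (>= 1 hit) for Fisher-exact enrichment of a
foreground peaklet set against a background, and for pairwise motif
co-occurrence (shared peaklets, Jaccard fraction).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression_temporal import bh_adjust
from .io_formats import BASES, MotifMatrix, SequenceRecord

__all__ = [
    "PositionWeightMatrix",
    "MotifHit",
    "HitMatrix",
    "pfm_to_pwm",
    "scan_sequence",
    "build_hit_matrix",
    "motif_enrichment",
    "cooccurrence_network",
    "estimate_background",
]

DEFAULT_THRESHOLD_FRACTION = 0.8
_COMP = np.array([3, 2, 1, 0])  # A<->T, C<->G in A,C,G,T index space
_BASE_INDEX = np.full(128, 4, dtype=np.int8)
for _i, _b in enumerate("ACGT"):
    _BASE_INDEX[ord(_b)] = _i


@dataclass(frozen=True)
class PositionWeightMatrix:
    """Log2-odds motif model with its scanning threshold."""

    motif_id: str
    tf_name: str
    log_odds: np.ndarray  # 4 x L, rows A,C,G,T, bits
    background: np.ndarray
    pseudocount: float
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION

    @property
    def length(self) -> int:
        return self.log_odds.shape[1]

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    @property
    def threshold(self) -> float:
        return self.threshold_fraction * self.max_score

    def reverse_complement(self) -> "PositionWeightMatrix":
        return PositionWeightMatrix(
            motif_id=self.motif_id,
            tf_name=self.tf_name,
            log_odds=self.log_odds[_COMP][:, ::-1].copy(),
            background=self.background,
            pseudocount=self.pseudocount,
            threshold_fraction=self.threshold_fraction,
        )


@dataclass(frozen=True)
class MotifHit:
    peaklet_id: str
    motif_id: str
    offset: int  # forward-strand coordinate of the window start
    strand: str
    score: float


@dataclass
class HitMatrix:
    """Boolean peaklet x motif presence matrix plus the underlying hits."""

    matrix: pd.DataFrame
    hits: list

    def presence(self, motif_id: str) -> pd.Series:
        return self.matrix[motif_id]


def estimate_background(sequences) -> np.ndarray:
    """Base frequencies over a sequence collection (N ignored), A,C,G,T order."""
    counts = np.zeros(5)
    for seq in sequences:
        s = seq.sequence if isinstance(seq, SequenceRecord) else seq
        idx = _BASE_INDEX[np.frombuffer(s.encode(), dtype=np.uint8)]
        counts += np.bincount(idx, minlength=5)
    acgt = counts[:4]
    if acgt.sum() == 0:
        raise ValueError("no ACGT bases in background sequences")
    return acgt / acgt.sum()


def pfm_to_pwm(
    pfm: MotifMatrix,
    background=None,
    pseudocount: float = 1.0,
    threshold_fraction: float = DEFAULT_THRESHOLD_FRACTION,
) -> PositionWeightMatrix:
    """Log2-odds PWM: pseudocounts are distributed by background frequency.

    ``log_odds[b,j] = log2(((counts[b,j] + pc*bg[b]) / (colsum_j + pc)) / bg[b])``
    """
    bg = np.full(4, 0.25) if background is None else np.asarray(background, float)
    if bg.shape != (4,) or np.any(bg <= 0) or abs(bg.sum() - 1) > 1e-9:
        raise ValueError("background must be 4 positive probabilities summing to 1")
    counts = pfm.counts
    colsum = counts.sum(axis=0)
    if np.any(colsum <= 0):
        raise ValueError("zero-sum PFM column")
    if pseudocount <= 0 and np.any(counts == 0):
        raise ValueError("pseudocount must be positive when the PFM has zero counts")
    prob = (counts + pseudocount * bg[:, None]) / (colsum + pseudocount)
    log_odds = np.log2(prob / bg[:, None])
    return PositionWeightMatrix(
        motif_id=pfm.motif_id,
        tf_name=pfm.tf_name,
        log_odds=log_odds,
        background=bg,
        pseudocount=pseudocount,
        threshold_fraction=threshold_fraction,
    )


def _window_scores(idx: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    """Scores of every window; windows containing N score -inf."""
    L = log_odds.shape[1]
    n_win = len(idx) - L + 1
    if n_win <= 0:
        return np.empty(0)
    ext = np.vstack([log_odds, np.full(L, -np.inf)])  # 5th row: N
    scores = np.zeros(n_win)
    for j in range(L):
        scores += ext[idx[j : j + n_win], j]
    return scores


def scan_sequence(
    pwm: PositionWeightMatrix, seq: str, threshold_fraction: float | None = None,
    seq_id: str = "",
) -> list:
    """Both-strand scan; hits are windows scoring >= fraction * max score.

    Offsets are reported on the forward coordinate system (window start),
    for both strands. A sequence shorter than the motif yields no hits.
    """
    frac = pwm.threshold_fraction if threshold_fraction is None else threshold_fraction
    thr = frac * pwm.max_score
    seq = seq.upper()
    if set(seq) - set("ACGTN"):
        raise ValueError("sequence contains characters outside ACGTN")
    idx = _BASE_INDEX[np.frombuffer(seq.encode(), dtype=np.uint8)]
    hits = []
    for strand, lo in (("+", pwm.log_odds), ("-", pwm.reverse_complement().log_odds)):
        scores = _window_scores(idx, lo)
        for off in np.flatnonzero(scores >= thr):
            hits.append(
                MotifHit(seq_id, pwm.motif_id, int(off), strand, float(scores[off]))
            )
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def build_hit_matrix(
    peaklets,
    genome,
    pwms,
    threshold_fraction: float | None = None,
) -> HitMatrix:
    """Scan every peaklet sequence with every PWM; binarize to presence."""
    seqs = {
        rec.id: rec.sequence for rec in genome
    } if not isinstance(genome, dict) else genome
    pids = [p.peaklet_id for p in peaklets]
    matrix = pd.DataFrame(
        False, index=pids, columns=[pwm.motif_id for pwm in pwms], dtype=bool
    )
    all_hits = []
    for p in peaklets:
        iv = p.interval
        if iv.chrom not in seqs or iv.end > len(seqs[iv.chrom]):
            raise ValueError(f"peaklet {p.peaklet_id} outside genome")
        subseq = seqs[iv.chrom][iv.start : iv.end]
        for pwm in pwms:
            hits = scan_sequence(
                pwm, subseq, threshold_fraction=threshold_fraction, seq_id=p.peaklet_id
            )
            if hits:
                matrix.loc[p.peaklet_id, pwm.motif_id] = True
                all_hits.extend(hits)
    return HitMatrix(matrix=matrix, hits=all_hits)


def motif_enrichment(
    foreground_ids,
    background_ids,
    hit_matrix: HitMatrix | pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher exact enrichment of each motif in the foreground.

    When the background is a superset of the foreground it is treated as
    the sampling universe (hypergeometric upper tail); a disjoint
    background forms the second column of the 2x2 table directly. BH
    adjusts across motifs; ``enriched`` means q < alpha.
    """
    M = hit_matrix.matrix if isinstance(hit_matrix, HitMatrix) else hit_matrix
    fore = list(dict.fromkeys(foreground_ids))
    back = list(dict.fromkeys(background_ids))
    if not fore:
        raise ValueError("empty foreground")
    missing = (set(fore) | set(back)) - set(M.index)
    if missing:
        raise ValueError(f"ids not in hit matrix: {sorted(missing)[:3]} ...")
    fore_set = set(fore)
    superset = fore_set <= set(back)
    Mf = M.loc[fore]
    Mb = M.loc[back]
    rows = []
    for motif in M.columns:
        k, n = int(Mf[motif].sum()), len(fore)
        K, N = int(Mb[motif].sum()), len(back)
        if superset:
            table = [[k, n - k], [K - k, (N - n) - (K - k)]]
        else:
            table = [[k, n - k], [K, N - K]]
        odds, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "motif_id": motif,
                "foreground_hits": k,
                "foreground_size": n,
                "background_hits": K,
                "background_size": N,
                "odds_ratio": odds,
                "p": p,
            }
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["enriched"] = out["q"] < alpha
    return out


def cooccurrence_network(
    hit_matrix: HitMatrix | pd.DataFrame,
    enriched_motifs=None,
    peaklet_subset=None,
    denominator: str = "union",
) -> pd.DataFrame:
    """Pairwise motif co-occurrence over a peaklet set.

    ``shared_peaklets`` counts peaklets hit by both motifs;
    ``shared_fraction`` divides by the union (Jaccard, default) or by the
    smaller of the two motif peaklet sets. Pairs sharing no peaklet are
    omitted.
    """
    M = hit_matrix.matrix if isinstance(hit_matrix, HitMatrix) else hit_matrix
    if peaklet_subset is not None:
        M = M.loc[list(peaklet_subset)]
    if enriched_motifs is not None:
        M = M[list(enriched_motifs)]
    if denominator not in ("union", "min"):
        raise ValueError("denominator must be 'union' or 'min'")
    B = M.to_numpy(dtype=int)
    inter = B.T @ B
    sizes = B.sum(axis=0)
    motifs = list(M.columns)
    rows = []
    for i in range(len(motifs)):
        for j in range(i + 1, len(motifs)):
            shared = int(inter[i, j])
            if shared == 0:
                continue
            if denominator == "union":
                denom = int(sizes[i] + sizes[j] - shared)
            else:
                denom = int(min(sizes[i], sizes[j]))
            rows.append(
                {
                    "motif_a": motifs[i],
                    "motif_b": motifs[j],
                    "shared_peaklets": shared,
                    "shared_fraction": shared / denom if denom else 0.0,
                }
            )
    return pd.DataFrame(
        rows, columns=["motif_a", "motif_b", "shared_peaklets", "shared_fraction"]
    )
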