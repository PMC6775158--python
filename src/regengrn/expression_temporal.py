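"""Temporal differential expression and clustering.

Counts are normalized to transcripts-per-million (TPM), tested for
differential expression against the uninjured 0 dpi baseline with a
negative-binomial (NB) model (per-timepoint means, per-feature
method-of-moments dispersion; Wald tests per contrast and a likelihood
ratio test across the time factor), corrected by Benjamini-Hochberg, and
the standardized log2(TPM+1) profiles of the retained transcripts are
clustered with K-means (Lloyd's algorithm with random restarts).

The NB Wald/LRT here is a deliberately plain stand-in for bootstrap-based
transcript-level inference: downstream stages only consume per-contrast
fold-changes and FDR-adjusted p-values.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import cdist
from statsmodels.stats.multitest import multipletests

from .io_formats import SampleTable

__all__ = [
    "compute_tpm",
    "log_zscore",
    "ZscoreMatrix",
    "nb_differential",
    "DifferentialExpressionResult",
    "bh_adjust",
    "kmeans_temporal",
    "TemporalClustering",
]

LOW_COUNT_TOTAL = 10  # features below this total are not tested


def compute_tpm(counts: pd.DataFrame, effective_lengths: pd.Series) -> pd.DataFrame:
    """Transcripts per million: length-normalized rates scaled to 1e6 per sample."""
    lengths = effective_lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValueError(f"missing effective length for {missing} ...")
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    rate = counts.div(lengths, axis=0)
    denom = rate.sum(axis=0)
    if (denom == 0).any():
        bad = denom.index[denom == 0].tolist()
        raise ValueError(f"all-zero counts in sample(s) {bad}")
    return rate.div(denom, axis=1) * 1e6


@dataclass
class ZscoreMatrix:
    """Row-standardized log2(TPM + pseudocount) profiles.

    ``z`` holds the retained rows (sample SD > 0); ``flagged_constant``
    lists rows excluded from clustering because their profile is flat.
    """

    z: pd.DataFrame
    flagged_constant: list
    pseudocount: float = 1.0
    log_base: int = 2


def log_zscore(
    tpm: pd.DataFrame, transcripts=None, pseudocount: float = 1.0
) -> ZscoreMatrix:
    """Standardize log2(TPM+1) per transcript across all samples.

    Uses the sample (n-1) standard deviation. Rows with zero variance are
    flagged and excluded rather than divided by zero.
    """
    sub = tpm if transcripts is None else tpm.loc[list(transcripts)]
    logged = np.log2(sub + pseudocount)
    mu = logged.mean(axis=1)
    sd = logged.std(axis=1, ddof=1)
    constant = sd <= 0
    z = logged.loc[~constant].sub(mu[~constant], axis=0).div(sd[~constant], axis=0)
    return ZscoreMatrix(
        z=z, flagged_constant=list(sub.index[constant]), pseudocount=pseudocount
    )


# ---------------------------------------------------------------------------
# Differential testing


@dataclass
class DifferentialExpressionResult:
    """Per-feature Wald contrasts vs 0 dpi plus a time-factor LRT.

    ``table`` is indexed by feature id with columns ``log2fc_<t>``,
    ``wald_p_<t>``, ``wald_q_<t>`` for each post-injury timepoint, plus
    ``lrt_p``/``lrt_q`` and ``tested`` (low-count features are excluded
    from testing and carry NaN statistics).
    """

    table: pd.DataFrame
    contrasts: tuple
    baseline: int = 0

    def significant(self, fdr: float = 0.05, test: str = "lrt") -> pd.Index:
        if test == "lrt":
            mask = self.table["lrt_q"] < fdr
        else:
            qcols = [f"wald_q_{t}" for t in self.contrasts]
            mask = (self.table[qcols] < fdr).any(axis=1)
        return self.table.index[mask.fillna(False)]


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, capped at 1)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(np.isnan(p)) or np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def nb_differential(
    counts: pd.DataFrame,
    samples: SampleTable,
    contrasts=None,
    baseline: int = 0,
    min_total: int = LOW_COUNT_TOTAL,
) -> DifferentialExpressionResult:
    """NB differential test of each post-injury timepoint against baseline.

    Model: one NB mean per timepoint (log link, so the group MLE is the
    group mean) and a per-feature dispersion obtained by shrinking the
    pooled method-of-moments estimate toward a common dispersion fitted by
    Cox-Reid-adjusted profile likelihood across all features (prior weight
    ``prior_df``), floored at 1e-8. The moment estimator alone is too
    noisy at 2-3 replicates per group and makes the tests anticonservative.
    Wald z-scores use the delta-method variance of the log fold-change; the
    LRT compares the per-timepoint model with a single-mean null against
    chi2(T-1).
    """
    tps = samples.timepoint_levels
    if baseline not in tps:
        raise ValueError(f"baseline timepoint {baseline} absent from design")
    if contrasts is None:
        contrasts = tuple(t for t in tps if t != baseline)
    group_idx = {t: samples.sample_indices(t) for t in tps}
    for t, idx in group_idx.items():
        if len(idx) < 2:
            raise ValueError(f"timepoint {t} has fewer than 2 replicates")

    X = counts.to_numpy(dtype=float)
    total = X.sum(axis=1)
    tested = total >= min_total
    Xt = X[tested]
    n_feat = Xt.shape[0]
    T = len(tps)

    m = np.empty((n_feat, T))
    v = np.empty((n_feat, T))
    n_per = np.empty(T)
    for j, t in enumerate(tps):
        block = Xt[:, group_idx[t]]
        m[:, j] = block.mean(axis=1)
        v[:, j] = block.var(axis=1, ddof=1)
        n_per[j] = block.shape[1]

    group_of_sample = np.empty(X.shape[1], dtype=int)
    for j, t in enumerate(tps):
        group_of_sample[group_idx[t]] = j

    # pooled method-of-moments dispersion: Var = mu + alpha mu^2 per group
    w = n_per - 1.0
    num = ((v - m) * w).sum(axis=1)
    den = (np.square(m) * w).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        alpha_mom = np.where(den > 0, num / den, 0.0)
    alpha_mom = np.maximum(alpha_mom, 1e-8)
    # empirical-Bayes style shrinkage toward the CR-adjusted common fit
    resid_df = float(X.shape[1] - T)
    prior_df = 40.0
    if n_feat > 0 and resid_df > 0:
        alpha_common = _cr_common_dispersion(Xt, m, n_per, group_of_sample)
        alpha = (resid_df * alpha_mom + prior_df * alpha_common) / (
            resid_df + prior_df
        )
    else:
        alpha = alpha_mom
    alpha = np.maximum(alpha, 1e-8)
    r = 1.0 / alpha

    # log-likelihoods under the per-timepoint and the single-mean model
    mu_full = np.maximum(m[:, group_of_sample], 1e-8)
    mu_null = np.maximum(Xt.mean(axis=1), 1e-8)[:, None]
    ll_full = _nb_loglik(Xt, mu_full, r[:, None]).sum(axis=1)
    ll_null = _nb_loglik(Xt, mu_null, r[:, None]).sum(axis=1)
    lrt = np.clip(2.0 * (ll_full - ll_null), 0.0, None)
    lrt_p = stats.chi2.sf(lrt, df=T - 1)

    cols: dict[str, np.ndarray] = {}
    j0 = tps.index(baseline)
    m0 = m[:, j0]
    for t in contrasts:
        jt = tps.index(t)
        mt = m[:, jt]
        lfc = np.log2((mt + 0.5) / (m0 + 0.5))
        var_ln = (1.0 / (mt + 0.5) + alpha) / n_per[jt] + (
            1.0 / (m0 + 0.5) + alpha
        ) / n_per[j0]
        z = np.log((mt + 0.5) / (m0 + 0.5)) / np.sqrt(var_ln)
        p = 2.0 * stats.norm.sf(np.abs(z))
        cols[f"log2fc_{t}"] = lfc
        cols[f"wald_p_{t}"] = p
        cols[f"wald_q_{t}"] = bh_adjust(p)
    cols["lrt_p"] = lrt_p
    cols["lrt_q"] = bh_adjust(lrt_p)

    table = pd.DataFrame(index=counts.index, columns=list(cols), dtype=float)
    table.loc[counts.index[tested], list(cols)] = np.column_stack(list(cols.values()))
    table["tested"] = tested
    return DifferentialExpressionResult(table=table, contrasts=tuple(contrasts), baseline=baseline)


def _nb_loglik(x, mu, r):
    p = r / (r + mu)
    return stats.nbinom.logpmf(x, r, p)


def _cr_common_dispersion(X, m, n_per, group_of_sample) -> float:
    """Common NB dispersion by Cox-Reid-adjusted profile likelihood.

    The adjustment subtracts half the log determinant of the information
    of the mean parameters (for a one-way layout, ``prod_t n_t w_t`` with
    working weights ``w_t = mu_t / (1 + alpha mu_t)``), removing most of
    the bias from plugging in the fitted group means.
    """
    from scipy import optimize

    mu_full = np.maximum(m[:, group_of_sample], 1e-8)
    m_safe = np.maximum(m, 1e-8)

    def neg_apl(log_alpha):
        a = np.exp(log_alpha)
        r = 1.0 / a
        ll = _nb_loglik(X, mu_full, r).sum()
        wgt = m_safe / (1.0 + a * m_safe)
        cr = 0.5 * np.log(n_per[None, :] * wgt).sum()
        return -(ll - cr)

    res = optimize.minimize_scalar(
        neg_apl, bounds=(np.log(1e-6), np.log(10.0)), method="bounded"
    )
    return float(np.exp(res.x))


# ---------------------------------------------------------------------------
# K-means


@dataclass
class TemporalClustering:
    K: int
    assignment: pd.Series  # feature id -> cluster label (0-based)
    centroids: np.ndarray  # K x samples
    seed: int
    n_restarts: int
    within_ss: float

    def members(self, k: int) -> pd.Index:
        return self.assignment.index[self.assignment == k]


def kmeans_temporal(
    z, K: int = 7, seed: int = 0, n_restarts: int = 10, max_iter: int = 300
) -> TemporalClustering:
    """Lloyd K-means on standardized temporal profiles.

    Each restart initializes centroids from K distinct rows; iterations run
    until the assignment is stable (or ``max_iter``); empty clusters are
    repaired by reseeding with the point farthest from its centroid; the
    restart with the lowest within-cluster sum of squares wins.
    Deterministic given ``seed``.
    """
    if isinstance(z, ZscoreMatrix):
        z = z.z
    X = z.to_numpy(dtype=float) if isinstance(z, pd.DataFrame) else np.asarray(z, float)
    index = z.index if isinstance(z, pd.DataFrame) else pd.RangeIndex(len(X))
    n = X.shape[0]
    if K < 2:
        raise ValueError("K must be >= 2")
    if K > n:
        raise ValueError(f"K={K} exceeds number of rows ({n})")

    rng = np.random.default_rng(seed)
    best_assign, best_cent, best_wss = None, None, np.inf
    for _ in range(n_restarts):
        cent = X[rng.choice(n, size=K, replace=False)].copy()
        assign = np.full(n, -1)
        prev_wss = np.inf
        for _it in range(max_iter):
            d2 = cdist(X, cent, "sqeuclidean")
            new_assign = d2.argmin(axis=1)
            point_d2 = d2[np.arange(n), new_assign]
            for k in range(K):
                if not np.any(new_assign == k):
                    far = int(point_d2.argmax())
                    cent[k] = X[far]
                    new_assign[far] = k
                    point_d2[far] = 0.0
            wss = float(point_d2.sum())
            assert wss <= prev_wss + 1e-8, "within-SS increased during Lloyd iteration"
            prev_wss = wss
            if np.array_equal(new_assign, assign):
                break
            assign = new_assign
            for k in range(K):
                cent[k] = X[assign == k].mean(axis=0)
        d2 = cdist(X, cent, "sqeuclidean")
        wss = float(d2[np.arange(n), assign].sum())
        if wss < best_wss:
            best_assign, best_cent, best_wss = assign.copy(), cent.copy(), wss
    return TemporalClustering(
        K=K,
        assignment=pd.Series(best_assign, index=index, name="cluster"),
        centroids=best_cent,
        seed=seed,
        n_restarts=n_restarts,
        within_ss=best_wss,
    )
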