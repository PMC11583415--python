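"""Co-essentiality mapping from gene-effect matrices.

The fitness profile of a query gene across cell lines is correlated
(Pearson) against every other screened gene on the complete-case line set,
the coefficients are ranked, and significance is calibrated against an
empirical permutation null built by correlating the query profile against
randomly resampled gene-effect vectors.  Genes are called co-essential
when their permutation-adjusted p-value is below alpha AND their
coefficient exceeds the knee ("inflection point") of the positive segment
of the ranked-coefficient curve; anti-essential symmetrically on the
negative segment.

The knee of a ranked segment is located kneedle-style: the index
maximising the perpendicular distance between the (rank, r) curve and the
chord joining the segment's endpoints, ties broken toward the smallest
rank.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class InflectionThresholds:
    """Knee thresholds of the ranked correlation curve.

    ``r_pos``/``r_neg`` are the coefficients at the positive/negative knee;
    ``idx_pos``/``idx_neg`` the 1-based ranks (over the full descending
    ranking) where they sit.  A side without >= 3 values is undefined
    (NaN threshold, index 0).
    """

    r_pos: float
    r_neg: float
    idx_pos: int
    idx_neg: int

    @property
    def pos_defined(self) -> bool:
        return np.isfinite(self.r_pos)

    @property
    def neg_defined(self) -> bool:
        return np.isfinite(self.r_neg)


def _complete_case_pearson(X: np.ndarray, q: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Column-wise Pearson r of q against each column of X, dropping rows
    where either value is missing.  Returns (r, n_used); r is NaN where a
    column has < 2 usable rows or zero variance."""
    valid = ~np.isnan(X) & ~np.isnan(q)[:, None]
    n = valid.sum(axis=0).astype(float)
    Xv = np.where(valid, X, 0.0)
    Qv = np.where(valid, q[:, None], 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        sx = Xv.sum(axis=0)
        sq = Qv.sum(axis=0)
        sxx = (Xv * Xv).sum(axis=0)
        sqq = (Qv * Qv).sum(axis=0)
        sxq = (Xv * Qv).sum(axis=0)
        cov = sxq - sx * sq / n
        varx = sxx - sx * sx / n
        varq = sqq - sq * sq / n
        denom = np.sqrt(varx * varq)
        r = np.where(denom > 0, cov / denom, np.nan)
    r = np.clip(r, -1.0, 1.0)
    return r, n.astype(int)


def correlate_all(gene_effect: pd.DataFrame, query: str, min_lines: int = 3) -> pd.DataFrame:
    """Pearson-correlate the query gene's fitness profile against all genes.

    ``gene_effect`` is lines x genes with NaN for missing scores.  For each
    target gene, lines missing either the query or the target score are
    dropped (complete-case); genes left with fewer than ``min_lines``
    usable lines, or with zero variance on them, are omitted with a logged
    diagnostic.  Rows are ranked by descending r (rank 1 = strongest
    positive).
    """
    if query not in gene_effect.columns:
        raise KeyError(f"query gene {query!r} not in matrix")
    q = gene_effect[query].to_numpy(dtype=float)
    if (~np.isnan(q)).sum() < min_lines:
        raise ValueError(f"query {query!r} has fewer than {min_lines} non-missing lines")
    X = gene_effect.to_numpy(dtype=float)
    r, n_used = _complete_case_pearson(X, q)
    out = pd.DataFrame({"gene": gene_effect.columns, "r": r, "n_used": n_used})
    bad = out["r"].isna() | (out["n_used"] < min_lines)
    if bad.any():
        logger.info(
            "dropping %d genes with <%d complete cases or zero variance",
            int(bad.sum()),
            min_lines,
        )
    out = out.loc[~bad].sort_values("r", ascending=False, kind="mergesort")
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def permutation_adjust_correlations(
    gene_effect: pd.DataFrame,
    query: str,
    observed: pd.DataFrame,
    n_perm: int = 100_000,
    seed: int = 0,
    chunk: int = 20_000,
) -> pd.DataFrame:
    """Attach pooled-null permutation p-values to a correlation table.

    The null is built by drawing ``n_perm`` gene-effect vectors (random
    gene column, values permuted across lines) and correlating each with
    the query profile; one shared two-sided null serves all genes:
    ``p_perm = (1 + #{|r_null| >= |r_obs|}) / (1 + n_perm)``.  The add-one
    form keeps p in [1/(n_perm+1), 1].  Deterministic given ``seed``.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if n_perm < 20 / 0.05:
        warnings.warn("n_perm very small for alpha = 0.05 resolution")
    rng = np.random.default_rng(seed)
    q = gene_effect[query].to_numpy(dtype=float)
    X = gene_effect.to_numpy(dtype=float)
    L, G = X.shape
    null_abs = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        cols = rng.integers(0, G, size=m)
        block = X[:, cols]
        # independent row permutation per column = resampled score vectors
        order = np.argsort(rng.random((L, m)), axis=0)
        block = np.take_along_axis(block, order, axis=0)
        r, _ = _complete_case_pearson(block, q)
        r = np.nan_to_num(r, nan=0.0)
        null_abs[done : done + m] = np.abs(r)
        done += m
    null_sorted = np.sort(null_abs)
    r_obs = observed["r"].to_numpy(dtype=float)
    # count of null |r| >= |r_obs|
    exceed = n_perm - np.searchsorted(null_sorted, np.abs(r_obs), side="left")
    out = observed.copy()
    out["p_perm"] = (1.0 + exceed) / (1.0 + n_perm)
    return out


def _knee_index(y: np.ndarray) -> int:
    """0-based index of the point with maximal perpendicular distance from
    the chord joining the first and last points of the (index, y) curve.
    Ties (including a perfectly linear segment) resolve to the first index.
    """
    m = len(y)
    x = np.arange(m, dtype=float)
    dx, dy = x[-1] - x[0], y[-1] - y[0]
    norm = np.hypot(dx, dy)
    if norm == 0:
        return 0
    dist = np.abs(dx * (y - y[0]) - dy * (x - x[0])) / norm
    return int(np.argmax(dist))


def find_inflection(ranked_r) -> InflectionThresholds:
    """Locate the knees of the positive and negative segments of a ranked
    (descending) correlation-coefficient curve.

    Each segment needs at least 3 values; an undefined side is flagged with
    a NaN threshold and a warning.  Returned indices are 1-based ranks over
    the full descending list.
    """
    r = np.asarray(list(ranked_r), dtype=float)
    if np.any(np.diff(r) > 1e-12):
        raise ValueError("ranked_r must be sorted in descending order")
    pos = r[r > 0]
    neg = r[r < 0]
    n_pos, n_neg = len(pos), len(neg)

    if n_pos >= 3:
        i = _knee_index(pos)
        idx_pos, r_pos = i + 1, float(pos[i])
    else:
        warnings.warn("fewer than 3 positive coefficients; positive knee undefined")
        idx_pos, r_pos = 0, float("nan")

    if n_neg >= 3:
        # mirror: scan the negative tail from least to most negative
        i = _knee_index(neg)
        idx_neg = len(r) - n_neg + i + 1
        r_neg = float(neg[i])
    else:
        warnings.warn("fewer than 3 negative coefficients; negative knee undefined")
        idx_neg, r_neg = 0, float("nan")

    return InflectionThresholds(r_pos=r_pos, r_neg=r_neg, idx_pos=idx_pos, idx_neg=idx_neg)


def call_essentiality_network(
    rows: pd.DataFrame,
    thresholds: InflectionThresholds,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Fill the co-/anti-essential call column.

    coessential iff p_perm < alpha and r strictly above the positive knee;
    antiessential iff p_perm < alpha and r strictly below the negative
    knee; otherwise none.  An undefined knee empties that call class with a
    warning.
    """
    if "p_perm" not in rows.columns:
        raise ValueError("rows must carry p_perm (run permutation_adjust_correlations)")
    out = rows.copy()
    call = np.full(len(out), "none", dtype=object)
    sig = out["p_perm"].to_numpy() < alpha
    r = out["r"].to_numpy(dtype=float)
    if thresholds.pos_defined:
        call[sig & (r > thresholds.r_pos)] = "coessential"
    else:
        warnings.warn("positive knee undefined; no coessential calls")
    if thresholds.neg_defined:
        call[sig & (r < thresholds.r_neg)] = "antiessential"
    else:
        warnings.warn("negative knee undefined; no antiessential calls")
    out["call"] = call
    return out


def map_essentiality_network(
    gene_effect: pd.DataFrame,
    query: str,
    n_perm: int = 100_000,
    seed: int = 0,
    alpha: float = 0.05,
    include_self: bool = False,
) -> tuple[pd.DataFrame, InflectionThresholds]:
    """End-to-end essentiality map: correlate, permutation-adjust, locate
    knees, call the network.  The query's self-correlation row is dropped
    by default before thresholding."""
    rows = correlate_all(gene_effect, query)
    if not include_self:
        rows = rows.loc[rows["gene"] != query].reset_index(drop=True)
        rows["rank"] = np.arange(1, len(rows) + 1)
    rows = permutation_adjust_correlations(gene_effect, query, rows, n_perm=n_perm, seed=seed)
    thresholds = find_inflection(rows["r"])
    return call_essentiality_network(rows, thresholds, alpha=alpha), thresholds


def network_to_table(rows: pd.DataFrame, thresholds: InflectionThresholds) -> pd.DataFrame:
    """Render the network in the published column dialect."""
    return pd.DataFrame(
        {
            "GeneName": rows["gene"],
            "Estimate": rows["r"],
            "Perm.adj.p.value": rows["p_perm"],
            "Rank": rows["rank"],
            "Candidate_inflection": rows["call"],
        }
    )
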