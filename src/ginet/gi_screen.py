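"""Differential-lethality genetic-interaction screening.

For each screened gene, knockout lethality probabilities are compared
between the query-gene LOF cell-line group and the wild-type control group
with a two-sided Mann-Whitney U test.  Raw p-values are adjusted against a
pooled permutation null built by shuffling the group labels ``n_perm``
times; by default the per-shuffle null statistic is the minimum p across
all screened genes (Westfall-Young single-step min-p), so the adjusted p —
the add-one fraction of null statistics at or below the observed p —
corrects for the multiplicity of the genome-wide screen.  Candidates are
summarised by an interaction score combining significance and effect size,

    score = -log10(adj p) * log2(median LOF lethality / median WT lethality),

positive for synthetic-lethal (SL) candidates (knockout more lethal in LOF
lines) and negative for alleviating (AL) ones.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
import pandas as pd
from scipy import stats

from ginet.genotyping import assign_genotype_groups, screen_groups

logger = logging.getLogger(__name__)


def rank_sum_test(values_lof, values_wt) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test of two lethality samples.

    Exact enumeration when both groups have <= 8 values and no ties;
    tie-corrected normal approximation (with continuity correction)
    otherwise.  Returns (U of the first sample, p).  Two identical
    constant samples give p = 1 by exchangeability.
    """
    x = np.asarray(list(values_lof), dtype=float)
    y = np.asarray(list(values_wt), dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return float(len(x) * len(y) / 2.0), 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(min(res.pvalue, 1.0))


def _rank_sigma(X: np.ndarray, n1: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-column mid-ranks and tie-corrected Mann-Whitney normal SD for a
    split into groups of n1 and L-n1 rows."""
    L, G = X.shape
    n2 = L - n1
    ranks = stats.rankdata(X, axis=0)
    tie_term = np.zeros(G)
    Xs = np.sort(X, axis=0)
    has_ties = (np.diff(Xs, axis=0) == 0).any(axis=0)
    for j in np.flatnonzero(has_ties):
        _, counts = np.unique(X[:, j], return_counts=True)
        tie_term[j] = np.sum(counts**3 - counts)
    sigma = np.sqrt(n1 * n2 / 12.0 * ((L + 1) - tie_term / (L * (L - 1))))
    return ranks, sigma


def _null_p_block(
    ranks: np.ndarray, sigma: np.ndarray, n1: int, m: int, rng: np.random.Generator
) -> np.ndarray:
    """(m x G) matrix of null Mann-Whitney p-values from m random label
    shuffles shared across genes (tie-corrected normal approximation with
    continuity correction)."""
    L, G = ranks.shape
    n2 = L - n1
    sel = np.argsort(rng.random((m, L)), axis=1)[:, :n1]
    indicator = np.zeros((m, L))
    np.put_along_axis(indicator, sel, 1.0, axis=1)
    R1 = indicator @ ranks
    U1 = R1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (np.abs(U1 - mu) - 0.5) / sigma[None, :]
    p = 2.0 * stats.norm.sf(z)
    p = np.where(sigma[None, :] > 0, p, 1.0)
    return np.minimum(p, 1.0)


def permutation_adjust_screen(
    leth_matrix: pd.DataFrame,
    lof_lines,
    wt_lines,
    observed_pvals: pd.Series,
    n_perm: int = 10_000,
    seed: int = 0,
    strategy: str = "pooled_minp",
    chunk: int = 1_000,
) -> pd.Series:
    """Permutation-adjust observed screen p-values by label shuffling.

    Each permutation shuffles the LOF/WT labels over the pooled lines and
    recomputes the per-gene Mann-Whitney p-values.  Strategies differ in
    the null statistic pooled over genes:

    * ``'pooled_minp'`` (default) — the per-shuffle null statistic is the
      minimum p across all genes (Westfall-Young single-step min-p), so
      ``adj_p(g) = (1 + #{min-p_null <= p_obs(g)}) / (1 + n_perm)``
      controls the family-wise error over the screened genome;
    * ``'pooled_marginal'`` — one random gene's shuffled p per draw; the
      shared null calibrates but does not correct for multiplicity;
    * ``'per_gene'`` — each gene compared against its own shuffled null.

    All strategies are deterministic given ``seed`` and return adjusted p
    in [1/(n_perm+1), 1], monotone in the observed p.
    """
    lof_lines, wt_lines = list(lof_lines), list(wt_lines)
    if len(lof_lines) < 2 or len(wt_lines) < 2:
        raise ValueError("both groups need >= 2 members")
    if n_perm < 20:
        warnings.warn("n_perm too small for useful alpha resolution")
    if strategy not in ("pooled_minp", "pooled_marginal", "per_gene"):
        raise ValueError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)
    sub = leth_matrix.loc[lof_lines + wt_lines, observed_pvals.index]
    X = sub.to_numpy(dtype=float)
    n1 = len(lof_lines)
    G = X.shape[1]
    ranks, sigma = _rank_sigma(X, n1)

    obs = observed_pvals.to_numpy(dtype=float)
    if strategy == "per_gene":
        count = np.zeros(G)
    else:
        null_stat = np.empty(n_perm)
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        block = _null_p_block(ranks, sigma, n1, m, rng)
        if strategy == "pooled_minp":
            null_stat[done : done + m] = block.min(axis=1)
        elif strategy == "pooled_marginal":
            cols = rng.integers(0, G, size=m)
            null_stat[done : done + m] = block[np.arange(m), cols]
        else:
            count += (block <= obs[None, :]).sum(axis=0)
        done += m

    if strategy == "per_gene":
        adj = (1.0 + count) / (1.0 + n_perm)
    else:
        null_sorted = np.sort(null_stat)
        count = np.searchsorted(null_sorted, obs, side="right")
        adj = (1.0 + count) / (1.0 + n_perm)
    return pd.Series(adj, index=observed_pvals.index, name="adj_pval")


def interaction_score(
    adj_pval: float,
    mutant_median: float,
    control_median: float,
    median_floor: float = 1e-4,
) -> float:
    """Genetic-interaction score: -log10(adj p) x log2(mutant/control
    median lethality).  Medians below ``median_floor`` are raised to it so
    the ratio stays finite; equal medians give exactly 0."""
    if not 0 < adj_pval <= 1:
        raise ValueError("adj_pval must be in (0, 1]")
    for m in (mutant_median, control_median):
        if not 0 <= m <= 1:
            raise ValueError("medians must be in [0, 1]")
    if mutant_median == control_median:
        return 0.0
    num = max(mutant_median, median_floor)
    den = max(control_median, median_floor)
    return float(-np.log10(adj_pval) * np.log2(num / den))


def run_gi_screen(
    panel,
    query: str,
    mode: str = "trans_het_only",
    alpha: float = 0.05,
    n_perm: int = 10_000,
    seed: int = 0,
    context: str | None = None,
    strategy: str = "pooled_minp",
    median_floor: float = 1e-4,
) -> pd.DataFrame:
    """Run the differential-lethality screen for ``query`` on a panel.

    Cell lines are genotyped from the panel's mutation and copy-number
    tables (``mode`` as in :func:`ginet.genotyping.assign_genotype_groups`);
    optionally restricted to one cancer ``context`` (annotation
    ``disease``).  Per screened gene: group medians/SDs on the
    complete-case line sets, Mann-Whitney p, pooled permutation adjustment,
    log2 fold change of medians, interaction score, and an SL/AL direction
    call for genes with adj p < alpha.  Rows are ordered by descending
    interaction score.
    """
    ann = panel.annotations
    samples = list(panel.lethality.index)
    if context is not None:
        keep = set(ann.loc[ann["disease"] == context, "DepMap_ID"])
        samples = [s for s in samples if s in keep]
        if not samples:
            raise ValueError(f"context {context!r} matches no cell lines")
    sample_set = set(samples)
    assignments = assign_genotype_groups(
        [m for m in panel.mutations if m.sample_id in sample_set],
        [c for c in panel.copy_number if c.sample_id in sample_set],
        samples,
        query,
        mode=mode,
    )
    mutant, control = screen_groups(assignments)
    if len(mutant) < 2 or len(control) < 2:
        raise ValueError(
            f"screen needs >= 2 lines per group; context={context!r} gives "
            f"{len(mutant)} mutant and {len(control)} control lines"
        )
    logger.info(
        "screening %s: %d mutant vs %d control lines", query, len(mutant), len(control)
    )

    leth = panel.lethality
    genes = [g for g in leth.columns if g != query]
    Xm = leth.loc[mutant, genes].to_numpy(dtype=float)
    Xc = leth.loc[control, genes].to_numpy(dtype=float)

    mut_median = np.nanmedian(Xm, axis=0)
    ctl_median = np.nanmedian(Xc, axis=0)
    mut_sd = np.nanstd(Xm, axis=0, ddof=1)
    ctl_sd = np.nanstd(Xc, axis=0, ddof=1)

    if np.isnan(Xm).any() or np.isnan(Xc).any():
        pvals = np.array(
            [
                rank_sum_test(Xm[:, j][~np.isnan(Xm[:, j])], Xc[:, j][~np.isnan(Xc[:, j])])[1]
                for j in range(len(genes))
            ]
        )
    else:
        res = stats.mannwhitneyu(Xm, Xc, alternative="two-sided", axis=0)
        pvals = np.minimum(np.asarray(res.pvalue, dtype=float), 1.0)
    observed = pd.Series(pvals, index=genes, name="pval")

    adj = permutation_adjust_screen(
        leth.loc[mutant + control, genes],
        mutant,
        control,
        observed,
        n_perm=n_perm,
        seed=seed,
        strategy=strategy,
    )

    num = np.maximum(mut_median, median_floor)
    den = np.maximum(ctl_median, median_floor)
    log2fc = np.where(mut_median == ctl_median, 0.0, np.log2(num / den))
    score = -np.log10(adj.to_numpy()) * log2fc
    direction = np.full(len(genes), "none", dtype=object)
    sig = adj.to_numpy() < alpha
    direction[sig & (mut_median > ctl_median)] = "SL"
    direction[sig & (mut_median < ctl_median)] = "AL"

    out = pd.DataFrame(
        {
            "gene": genes,
            "control_median": ctl_median,
            "mutant_median": mut_median,
            "control_sd": ctl_sd,
            "mutant_sd": mut_sd,
            "pval": observed.to_numpy(),
            "adj_pval": adj.to_numpy(),
            "log2fc_by_median": log2fc,
            "interaction_score": score,
            "direction": direction,
        }
    )
    return out.sort_values(
        "interaction_score", ascending=False, kind="mergesort"
    ).reset_index(drop=True)


def screen_to_table(rows: pd.DataFrame) -> pd.DataFrame:
    """Render a screen result in the published column dialect."""
    return pd.DataFrame(
        {
            "GeneNames": rows["gene"],
            "Control_median": rows["control_median"],
            "Mutant_median": rows["mutant_median"],
            "Control_sd": rows["control_sd"],
            "Mutant_sd": rows["mutant_sd"],
            "Pval": rows["pval"],
            "log2FC_by_median": rows["log2fc_by_median"],
            "Interaction_score": rows["interaction_score"],
            "Adj_pval": rows["adj_pval"],
            "GI_direction": rows["direction"],
        }
    )
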