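"""Cohort-level marker scores and group-comparison statistics.

Formula-defined markers used across tumour cohorts:

* TMB — somatic mutation count divided by the effective genome footprint
  in megabases (whole-genome default 2934.876451 Mb; panel studies pass
  their own exonic coverage);
* MSI status — MSIsensor >= 10 and MANTIS >= 0.4 (conjunctive when both
  scores are present; single-score fallback is flagged), or inferred on
  gene panels from LOF alterations in mismatch-repair genes;
* immune expression signatures — cytolytic activity (geometric mean of
  GZMA and PRF1 FPKM), M1/M2 macrophage polarisation and IFN-gamma
  signalling scores (fixed 10-gene arithmetic means).

Group comparisons follow the cohort conventions: Welch's t with BH
correction across a marker family (groups under 3 samples reported
not-analysed), one-way ANOVA with Tukey HSD beyond two groups, Fisher's
exact test for 2x2 co-occurrence, chi-square equality of proportions, and
the log-rank test for survival (groups under 10 cases not analysed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests
from lifelines.statistics import multivariate_logrank_test

from ginet.genotyping import MutationRecord, classify_variant

EFFECTIVE_GENOME_MB = 2934.876451

M1M2_GENES = (
    "CXCL11", "IDO1", "CCL19", "CXCL9", "PLA1A",
    "LAMP3", "CCR7", "APOL6", "CXCL10", "TNIP3",
)
IFNG_GENES = (
    "CCR5", "CXCL10", "CXCL11", "CXCL9", "GZMA",
    "HLA-DRA", "IDO1", "IFNG", "PRF1", "STAT1",
)
MMR_GENES = frozenset({"MLH1", "MLH3", "PMS2", "MSH2", "MSH3", "MSH6"})


@dataclass(frozen=True)
class MarkerConfig:
    genome_size_mb: float = EFFECTIVE_GENOME_MB
    msisensor_min: float = 10.0
    mantis_min: float = 0.4
    panel_mmr_genes: frozenset = MMR_GENES
    cytolytic_genes: tuple[str, str] = ("GZMA", "PRF1")
    m1m2_genes: tuple[str, ...] = M1M2_GENES
    ifng_genes: tuple[str, ...] = IFNG_GENES
    cytolytic_pseudocount: float = 0.0


DEFAULT_MARKER_CONFIG = MarkerConfig()


@dataclass(frozen=True)
class TwoByTwo:
    """Counts of a 2x2 contingency table [[a, b], [c, d]]."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("counts must be non-negative integers")

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=int)


def compute_tmb(n_mutations: int, genome_size_mb: float = EFFECTIVE_GENOME_MB) -> float:
    """Tumour mutation burden: mutations per megabase of footprint."""
    if n_mutations < 0:
        raise ValueError("mutation count must be non-negative")
    if genome_size_mb <= 0:
        raise ValueError("genome size must be positive")
    return n_mutations / genome_size_mb


def call_msi_scores(
    msisensor: float | None,
    mantis: float | None,
    config: MarkerConfig = DEFAULT_MARKER_CONFIG,
) -> str:
    """Call MSI/MSS from MSIsensor and MANTIS scores (inclusive thresholds).

    MSI when every present score meets its threshold; MSS otherwise;
    'unknown' when both are absent (single-score calls are a fallback the
    caller may want to flag).
    """
    present = []
    if msisensor is not None and not (isinstance(msisensor, float) and np.isnan(msisensor)):
        if msisensor < 0:
            raise ValueError("MSIsensor score must be non-negative")
        present.append(msisensor >= config.msisensor_min)
    if mantis is not None and not (isinstance(mantis, float) and np.isnan(mantis)):
        if mantis < 0:
            raise ValueError("MANTIS score must be non-negative")
        present.append(mantis >= config.mantis_min)
    if not present:
        return "unknown"
    return "MSI" if all(present) else "MSS"


def infer_msi_from_panel(
    mutations: list[MutationRecord],
    config: MarkerConfig = DEFAULT_MARKER_CONFIG,
) -> str:
    """Infer MSI on a gene panel: any LOF alteration in an MMR gene."""
    for rec in mutations:
        if rec.gene in config.panel_mmr_genes and classify_variant(rec.variant_class) == "lof":
            return "MSI"
    return "MSS"


def cytolytic_score(
    gzma_fpkm: float,
    prf1_fpkm: float,
    pseudocount: float = 0.0,
) -> float:
    """Cytolytic activity: geometric mean of GZMA and PRF1 FPKM.

    No pseudocount by default (either gene at zero gives zero)."""
    if gzma_fpkm < 0 or prf1_fpkm < 0:
        raise ValueError("FPKM values must be non-negative")
    return float(np.sqrt((gzma_fpkm + pseudocount) * (prf1_fpkm + pseudocount)))


def signature_mean_score(fpkm: dict[str, float] | pd.Series, gene_list) -> float:
    """Arithmetic mean FPKM over a fixed gene list; missing genes error."""
    gene_list = list(gene_list)
    if not gene_list:
        raise ValueError("gene list must be non-empty")
    missing = [g for g in gene_list if g not in fpkm]
    if missing:
        raise KeyError(f"genes missing from expression table: {missing}")
    return float(np.mean([fpkm[g] for g in gene_list]))


def score_samples(
    fpkm: pd.DataFrame,
    clinical: pd.DataFrame | None = None,
    config: MarkerConfig = DEFAULT_MARKER_CONFIG,
) -> pd.DataFrame:
    """Per-sample marker scores from a samples x genes FPKM matrix.

    Adds MSI calls when a clinical table with MSIsensor/MANTIS columns is
    given (joined on sample_id).
    """
    g1, g2 = config.cytolytic_genes
    rows = []
    for sample, expr in fpkm.iterrows():
        rows.append(
            {
                "sample_id": sample,
                "cytolytic": cytolytic_score(expr[g1], expr[g2], config.cytolytic_pseudocount),
                "m1m2": signature_mean_score(expr, config.m1m2_genes),
                "ifng": signature_mean_score(expr, config.ifng_genes),
            }
        )
    out = pd.DataFrame(rows)
    if clinical is not None:
        cols = clinical.set_index("sample_id")
        out["msi"] = [
            call_msi_scores(
                cols["MSIsensor"].get(s), cols["MANTIS"].get(s), config
            )
            for s in out["sample_id"]
        ]
    return out


def fisher_exact_2x2(
    table: TwoByTwo,
    sided: str = "two_sided",
    conditional_or: bool = False,
) -> tuple[float, float]:
    """Fisher's exact test on a 2x2 table.

    Two-sided p sums the probabilities of all fixed-margin tables no more
    likely than the observed one (probability-mass rule).  The odds ratio
    is the sample (a d)/(b c), infinite when bc = 0 with ad > 0; with
    ``conditional_or`` the conditional MLE is returned instead.
    """
    arr = table.as_array()
    if arr.sum() == 0:
        raise ValueError("all-zero table")
    alternative = {"two_sided": "two-sided", "less": "less", "greater": "greater"}[sided]
    res = stats.fisher_exact(arr, alternative=alternative)
    if conditional_or:
        odds = float(stats.contingency.odds_ratio(arr, kind="conditional").statistic)
    else:
        ad, bc = table.a * table.d, table.b * table.c
        odds = float("nan") if ad == 0 and bc == 0 else (float("inf") if bc == 0 else ad / bc)
    return float(res.pvalue), odds


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, correction: bool = True
) -> float:
    """Two-sided chi-square test of equal proportions k1/n1 vs k2/n2,
    with Yates continuity correction by default."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("denominators must be positive")
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("counts must satisfy 0 <= k <= n")
    table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
    if table[:, 0].sum() == 0 or table[:, 1].sum() == 0:
        return 1.0
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.pvalue)


def compare_groups(
    values: pd.DataFrame,
    labels: pd.Series,
    family: list[str] | None = None,
    min_group: int = 3,
) -> dict:
    """Marker-family group comparison with small-group masking.

    ``values`` is samples x markers, ``labels`` maps the same samples to
    group names.  Groups with fewer than ``min_group`` samples are reported
    under ``not_analysed`` and excluded from testing.  With two eligible
    groups each marker gets a Welch t p-value, BH-corrected across the
    ``family`` (default: all marker columns); with more, a one-way ANOVA p
    and Tukey HSD pairwise table are added.
    """
    family = list(family) if family is not None else list(values.columns)
    labels = labels.loc[values.index]
    sizes = labels.value_counts()
    eligible = sorted(sizes[sizes >= min_group].index)
    not_analysed = sorted(sizes[sizes < min_group].index)
    if len(sizes) < 2:
        raise ValueError("need at least 2 groups")
    result: dict = {"not_analysed": not_analysed, "groups": eligible}
    if len(eligible) < 2:
        result["tests"] = None
        return result

    rows = []
    for marker in family:
        samples = [values.loc[labels == g, marker].dropna() for g in eligible]
        if len(eligible) == 2:
            t, p = stats.ttest_ind(samples[0], samples[1], equal_var=False)
            rows.append({"marker": marker, "welch_p": float(p)})
        else:
            _, anova_p = stats.f_oneway(*samples)
            t, p = stats.ttest_ind(samples[0], samples[1], equal_var=False)
            rows.append({"marker": marker, "welch_p": float(p), "anova_p": float(anova_p)})
    tests = pd.DataFrame(rows).set_index("marker")
    tests["bh_q"] = multipletests(tests["welch_p"], method="fdr_bh")[1]
    result["tests"] = tests

    if len(eligible) > 2:
        tukey = {}
        mask = labels.isin(eligible)
        for marker in family:
            res = pairwise_tukeyhsd(
                values.loc[mask, marker].to_numpy(), labels[mask].to_numpy()
            )
            tukey[marker] = pd.DataFrame(
                res.summary().data[1:], columns=res.summary().data[0]
            )
        result["tukey"] = tukey
    return result


def logrank_test(times, events, groups, min_group: int = 10) -> dict:
    """Log-rank test across survival groups.

    Groups with fewer than ``min_group`` cases are dropped and listed under
    ``not_analysed``; if fewer than two groups remain the result carries
    ``analysed=False`` and no p-value.
    """
    df = pd.DataFrame({"time": times, "event": events, "group": groups})
    if (df["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    sizes = df["group"].value_counts()
    keep = sizes[sizes >= min_group].index
    dropped = sorted(sizes[sizes < min_group].index)
    sub = df[df["group"].isin(keep)]
    if len(keep) < 2:
        return {"analysed": False, "not_analysed": dropped, "chi_sq": None, "pval": None}
    res = multivariate_logrank_test(sub["time"], sub["group"], sub["event"])
    return {
        "analysed": True,
        "not_analysed": dropped,
        "chi_sq": float(res.test_statistic),
        "pval": float(res.p_value),
    }
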