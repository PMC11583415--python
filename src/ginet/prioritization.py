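"""Tiering, drug tractability and priority classes for GI candidates.

Candidates from a differential-lethality screen are stratified three ways:

* GI prediction tier (I/II/III) from screen statistics — tier I needs
  adjusted p < 0.01, |log2 fold change of group medians| > 2 and a median
  lethality above 0.5 in at least one group; tier II relaxes p to < 0.05;
  tier III drops the median condition (all comparisons strict);
* drug tractability group (I/II/III) from the minimal Open-Targets-style
  tractability bucket: buckets 1-3 are clinically precedented targets,
  4-6 have high-quality structure/ligand evidence, 7-9 weaker evidence;
* priority class A-D crossing the two: A = (tier I, group I),
  B = (tier I, group II), C = (tier I, group III or untracked),
  D = any tier II/III candidate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

TIERS = ("I", "II", "III", "none")
DRUG_GROUPS = ("I", "II", "III", "none")
PRIORITY_CLASSES = ("A", "B", "C", "D", "none")


@dataclass(frozen=True)
class TierThresholds:
    """Screen-statistic cutoffs per tier; tier I implies II implies III."""

    tier1_p_max: float = 0.01
    tier2_p_max: float = 0.05
    tier3_p_max: float = 0.05
    log2fc_min: float = 2.0
    median_min: float = 0.5
    # 'median': max of the two group medians must exceed median_min
    median_rule: str = "median"


DEFAULT_THRESHOLDS = TierThresholds()


def assign_gi_tier(
    adj_pval: float,
    log2fc_by_median: float,
    control_median: float,
    mutant_median: float,
    thresholds: TierThresholds = DEFAULT_THRESHOLDS,
) -> str:
    """Assign the strictest satisfied GI prediction tier.

    Tier I: adj p < 0.01, |log2fc| > 2 and max(group medians) > 0.5;
    tier II relaxes p to < 0.05; tier III additionally drops the median
    condition.  All comparisons strict.  Returns 'none' if no tier holds.
    """
    for val, name in ((adj_pval, "adj_pval"), (log2fc_by_median, "log2fc_by_median")):
        if val is None or not np.isfinite(val):
            raise ValueError(f"missing or non-finite {name}")
    fc_ok = abs(log2fc_by_median) > thresholds.log2fc_min
    median_ok = max(control_median, mutant_median) > thresholds.median_min
    if adj_pval < thresholds.tier1_p_max and fc_ok and median_ok:
        return "I"
    if adj_pval < thresholds.tier2_p_max and fc_ok and median_ok:
        return "II"
    if adj_pval < thresholds.tier3_p_max and fc_ok:
        return "III"
    return "none"


def assign_drug_group(bucket: int | None, override_group: str | None = None) -> str:
    """Map a minimal tractability bucket (1-9 or None) to drug group.

    Buckets 1-3 -> I (clinical precedence), 4-6 -> II, 7-9 -> III,
    no bucket -> 'none'.  An explicit ``override_group`` wins and is
    logged (manual re-classification support).
    """
    if override_group is not None:
        if override_group not in DRUG_GROUPS:
            raise ValueError(f"invalid override group {override_group!r}")
        logger.info("drug group override applied: %s", override_group)
        return override_group
    if bucket is None or (isinstance(bucket, float) and np.isnan(bucket)):
        return "none"
    bucket = int(bucket)
    if not 1 <= bucket <= 9:
        raise ValueError(f"tractability bucket {bucket} outside 1..9")
    if bucket <= 3:
        return "I"
    if bucket <= 6:
        return "II"
    return "III"


def assign_priority_class(gi_tier: str, drug_group: str) -> str:
    """Combine GI tier and drug group into priority class A-D.

    A = (I, I); B = (I, II); C = (I, III or none); D = any tier II/III;
    'none' when the candidate has no tier.  Total over the 4 x 4 enum
    product.
    """
    if gi_tier not in TIERS:
        raise ValueError(f"invalid GI tier {gi_tier!r}")
    if drug_group not in DRUG_GROUPS:
        raise ValueError(f"invalid drug group {drug_group!r}")
    if gi_tier == "none":
        return "none"
    if gi_tier == "I":
        return {"I": "A", "II": "B", "III": "C", "none": "C"}[drug_group]
    return "D"


def read_tractability(path) -> pd.DataFrame:
    """Read a tractability TSV (columns: gene, bucket[, modality]) into a
    per-gene minimal-bucket table."""
    df = pd.read_csv(path, sep="\t")
    if "gene" not in df.columns or "bucket" not in df.columns:
        raise ValueError("tractability table needs 'gene' and 'bucket' columns")
    return df.groupby("gene", as_index=False)["bucket"].min()


def prioritize_screen(
    screen: pd.DataFrame,
    tractability: pd.DataFrame | None = None,
    overrides: dict[str, str] | None = None,
    thresholds: TierThresholds = DEFAULT_THRESHOLDS,
) -> pd.DataFrame:
    """Annotate a GI screen table with tier, drug group and priority class.

    ``screen`` is the output of :func:`ginet.gi_screen.run_gi_screen`;
    ``tractability`` a per-gene minimal-bucket table; ``overrides`` maps
    gene -> drug group for manual re-classifications.
    """
    overrides = overrides or {}
    buckets: dict[str, int] = {}
    if tractability is not None:
        buckets = dict(zip(tractability["gene"], tractability["bucket"]))
    out = screen.copy()
    tiers, groups, classes = [], [], []
    for row in out.itertuples(index=False):
        tier = assign_gi_tier(
            row.adj_pval,
            row.log2fc_by_median,
            row.control_median,
            row.mutant_median,
            thresholds,
        )
        group = assign_drug_group(buckets.get(row.gene), overrides.get(row.gene))
        tiers.append(tier)
        groups.append(group)
        classes.append(assign_priority_class(tier, group))
    out["gi_tier"] = tiers
    out["drug_group"] = groups
    out["priority_class"] = classes
    return out
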