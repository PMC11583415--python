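"""Variant classification and cell-line genotype group assignment.

A screen compares knockout lethality between cell lines carrying
loss-of-function (LOF) alterations of a query gene and wild-type control
lines.  LOF variant classes are nonsense mutations, frameshift insertions
and deletions, and nonstop mutations; missense and silent variants do not
count, and lines carrying only such variants are excluded from both groups
rather than treated as controls.

Zygosity is approximated from alteration counts: a single LOF mutation on
neutral copy number is heterozygous; more than one LOF mutation, or an LOF
mutation combined with copy-number loss, is trans-heterozygous (two hits,
likely protein-deficient).  True homozygosity is never inferred — it is
accepted only through an explicit ``homozygous_samples`` input.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

LOF_CLASSES = frozenset(
    {"Nonsense_Mutation", "Frame_Shift_Ins", "Frame_Shift_Del", "Nonstop_Mutation"}
)
NON_LOF_CLASSES = frozenset({"Missense_Mutation", "Silent", "Other"})
VARIANT_CLASSES = LOF_CLASSES | NON_LOF_CLASSES

CN_STATES = ("deep_loss", "shallow_loss", "neutral", "gain")

GROUPS = (
    "control_wt",
    "heterozygous_lof",
    "trans_heterozygous_lof",
    "homozygous_lof",
    "excluded",
)


@dataclass(frozen=True)
class MutationRecord:
    """One somatic small variant in MAF-like terms."""

    sample_id: str
    gene: str
    variant_class: str
    protein_change: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be non-empty")
        if self.variant_class not in VARIANT_CLASSES:
            raise ValueError(
                f"unknown variant class {self.variant_class!r}; "
                f"expected one of {sorted(VARIANT_CLASSES)}"
            )


@dataclass(frozen=True)
class CopyNumberRecord:
    """Discretised copy-number state for one (sample, gene)."""

    sample_id: str
    gene: str
    cn_state: str

    def __post_init__(self) -> None:
        if self.cn_state not in CN_STATES:
            raise ValueError(
                f"unknown CN state {self.cn_state!r}; expected one of {CN_STATES}"
            )


def classify_variant(variant_class: str) -> str:
    """Classify a MAF variant class as ``'lof'`` or ``'non_lof'``.

    Nonsense mutations, frameshift insertions/deletions and nonstop
    mutations are loss-of-function; missense, silent and anything else are
    not.  Unknown class strings raise a ``ValueError`` naming the value.
    """
    if variant_class in LOF_CLASSES:
        return "lof"
    if variant_class in NON_LOF_CLASSES:
        return "non_lof"
    raise ValueError(
        f"unknown variant class {variant_class!r}; "
        f"expected one of {sorted(VARIANT_CLASSES)}"
    )


def assign_genotype_groups(
    mutations: Iterable[MutationRecord],
    cn: Iterable[CopyNumberRecord],
    samples: Sequence[str],
    gene: str,
    mode: str = "all_lof",
    homozygous_samples: Iterable[str] = (),
    deep_loss_alone_is_lof: bool = False,
) -> pd.DataFrame:
    """Partition ``samples`` into genotype groups for ``gene``.

    Rules, applied per sample:

    * ``homozygous_lof`` — only via the explicit ``homozygous_samples``
      input (zygosity is never inferred from counts);
    * ``trans_heterozygous_lof`` — at least two LOF mutations, or at least
      one LOF mutation combined with copy-number loss (deep or shallow);
    * ``heterozygous_lof`` — exactly one LOF mutation on neutral copy
      number;
    * ``control_wt`` — no mutation of any class and neutral copy number;
    * ``excluded`` — everything else, notably samples whose only mutations
      are missense/silent and samples with CN change but no LOF mutation.

    ``mode='trans_het_only'`` additionally excludes heterozygous lines from
    the mutant group, for screens restricted to two-hit lines.  With
    ``deep_loss_alone_is_lof`` (patient-cohort convention) a deep
    copy-number loss without any SNV counts as a homozygous LOF alteration.

    Returns a DataFrame with columns ``sample_id``, ``gene``, ``group``;
    every sample receives exactly one group.
    """
    if not len(samples):
        raise ValueError("samples must be non-empty")
    if mode not in ("all_lof", "trans_het_only"):
        raise ValueError(f"unknown mode {mode!r}")
    sample_set = set(samples)
    homozygous = set(homozygous_samples)

    n_lof: dict[str, int] = {s: 0 for s in samples}
    n_any: dict[str, int] = {s: 0 for s in samples}
    for rec in mutations:
        if rec.gene != gene:
            continue
        if rec.sample_id not in sample_set:
            raise ValueError(
                f"mutation sample {rec.sample_id!r} absent from samples list"
            )
        n_any[rec.sample_id] += 1
        if classify_variant(rec.variant_class) == "lof":
            n_lof[rec.sample_id] += 1

    cn_state: dict[str, str] = {s: "neutral" for s in samples}
    for rec in cn:
        if rec.gene != gene:
            continue
        if rec.sample_id not in sample_set:
            raise ValueError(f"CN sample {rec.sample_id!r} absent from samples list")
        cn_state[rec.sample_id] = rec.cn_state

    rows = []
    for s in samples:
        lof, any_mut, state = n_lof[s], n_any[s], cn_state[s]
        loss = state in ("deep_loss", "shallow_loss")
        if s in homozygous:
            group = "homozygous_lof"
        elif lof >= 2 or (lof >= 1 and loss):
            group = "trans_heterozygous_lof"
        elif lof == 1 and state == "neutral":
            group = "heterozygous_lof"
        elif lof == 0 and any_mut == 0 and state == "deep_loss" and deep_loss_alone_is_lof:
            group = "homozygous_lof"
        elif any_mut == 0 and state == "neutral":
            group = "control_wt"
        else:
            group = "excluded"
        if mode == "trans_het_only" and group == "heterozygous_lof":
            group = "excluded"
        rows.append((s, gene, group))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "group"])


def screen_groups(assignments: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Split a genotype assignment table into (mutant, control) sample lists."""
    mutant_labels = {"heterozygous_lof", "trans_heterozygous_lof", "homozygous_lof"}
    mutant = assignments.loc[
        assignments["group"].isin(mutant_labels), "sample_id"
    ].tolist()
    control = assignments.loc[
        assignments["group"] == "control_wt", "sample_id"
    ].tolist()
    return mutant, control


def select_screening_contexts(
    per_context_mutations: Mapping[str, Mapping[str, int]],
    line_counts: Mapping[str, int],
    min_pct_mutated: float = 10.0,
    min_pct_lof: float = 25.0,
    min_lines: int = 10,
) -> pd.DataFrame:
    """Select cancer contexts eligible for a context-specific screen.

    ``per_context_mutations`` maps each context to a summary with keys
    ``n_samples`` (cohort size), ``n_mutated_samples`` (samples with any
    mutation of the query gene), ``n_mutations`` and ``n_lof_mutations``.
    A context is selected when at least ``min_pct_mutated`` percent of
    samples are mutated, at least ``min_pct_lof`` percent of those
    mutations are LOF, and at least ``min_lines`` dependency-screened cell
    lines exist (all thresholds inclusive).

    Contexts with zero samples are reported unselected with a logged
    warning rather than raising on division.
    """
    rows = []
    for context, summary in per_context_mutations.items():
        n_samples = int(summary["n_samples"])
        n_mutated = int(summary["n_mutated_samples"])
        n_mut = int(summary["n_mutations"])
        n_lof = int(summary["n_lof_mutations"])
        if min(n_samples, n_mutated, n_mut, n_lof) < 0:
            raise ValueError(f"negative counts for context {context!r}")
        n_lines = int(line_counts.get(context, 0))
        if n_samples == 0:
            logger.warning("context %s has zero samples; not selected", context)
            rows.append((context, 0.0, 0.0, n_lines, False))
            continue
        pct_mutated = 100.0 * n_mutated / n_samples
        pct_lof = 100.0 * n_lof / n_mut if n_mut else 0.0
        selected = (
            pct_mutated >= min_pct_mutated
            and pct_lof >= min_pct_lof
            and n_lines >= min_lines
        )
        rows.append((context, pct_mutated, pct_lof, n_lines, selected))
    return pd.DataFrame(
        rows,
        columns=[
            "context",
            "pct_samples_mutated",
            "pct_mutations_lof",
            "n_cell_lines",
            "selected",
        ],
    )
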