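#!/usr/bin/env python
"""Genotype the panel for the query gene and select screening contexts.

Assigns every cell line to an LOF / control group for G0001 and applies
the context-eligibility thresholds (>= 10% of samples mutated, >= 25% of
mutations LOF, >= 10 cell lines).  Writes results/genotypes.csv and
results/contexts.csv.
"""

from pathlib import Path

from ginet.genotyping import assign_genotype_groups, select_screening_contexts, screen_groups
from ginet.io import load_bundle_dir
from ginet.pipeline import summarize_context_mutations

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    panel = load_bundle_dir(SCRATCH / "panel")
    samples = list(panel.lethality.index)
    table = assign_genotype_groups(panel.mutations, panel.copy_number, samples, "G0001")
    mutant, control = screen_groups(table)
    print(f"G0001 groups: {len(mutant)} mutant vs {len(control)} control lines")
    print(table["group"].value_counts().to_string())
    table.to_csv(RESULTS / "genotypes.csv", index=False)

    summaries, line_counts = summarize_context_mutations(panel, "G0001")
    contexts = select_screening_contexts(summaries, line_counts)
    contexts.to_csv(RESULTS / "contexts.csv", index=False)
    selected = contexts.loc[contexts["selected"], "context"].tolist()
    print(f"eligible contexts: {selected or 'none beyond pan-cancer'}")


if __name__ == "__main__":
    main()
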