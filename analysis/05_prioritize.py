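#!/usr/bin/env python
"""Prioritise GI candidates against drug tractability.

Crosses the screen's GI tiers with a synthetic tractability-bucket table
(labelled synthetic: buckets assigned deterministically for the demo, not
real Open Targets data) into priority classes A-D.  Writes
results/priority.csv.
"""

from pathlib import Path

import pandas as pd

from ginet.prioritization import prioritize_screen

RESULTS = Path(__file__).resolve().parents[1] / "results"


def synthetic_tractability(genes) -> pd.DataFrame:
    """Synthetic stand-in bucket table: gene index modulo 9, plus a
    guaranteed bucket-1 entry for the planted partner G0010."""
    buckets = [(g, (i % 9) + 1) for i, g in enumerate(sorted(genes))]
    df = pd.DataFrame(buckets, columns=["gene", "bucket"])
    df.loc[df["gene"] == "G0010", "bucket"] = 1
    return df


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    screen = pd.read_csv(RESULTS / "gi_screen.csv").rename(
        columns={
            "GeneNames": "gene", "Adj_pval": "adj_pval",
            "log2FC_by_median": "log2fc_by_median",
            "Control_median": "control_median", "Mutant_median": "mutant_median",
            "GI_direction": "direction",
        }
    )
    tract = synthetic_tractability(screen["gene"])
    out = prioritize_screen(screen, tract)
    out.to_csv(RESULTS / "priority.csv", index=False)
    called = out[out["priority_class"] != "none"]
    print(f"{len(called)} prioritised candidates")
    cols = ["gene", "adj_pval", "log2fc_by_median", "gi_tier", "drug_group", "priority_class"]
    print(called[cols].to_string(index=False))


if __name__ == "__main__":
    main()
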