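#!/usr/bin/env python
"""Generate the study-condition synthetic dependency panel.

200 cell lines x 2,000 genes with a planted co-essential pair
(G0002 ~ G0003, rho = 0.9) and a planted synthetic-lethal interaction
(G0001 -> G0010, lethality mean 0.8 in the 40 LOF lines vs 0.2 in the
160 WT lines).  Writes the DepMap-dialect bundle under scratch/panel/.
"""

from pathlib import Path

from ginet.simulate import default_screen_config, simulate_dependency_panel, write_depmap_bundle

SEED = 1
OUT = Path(__file__).resolve().parents[1] / "scratch" / "panel"


def main() -> None:
    cfg = default_screen_config(seed=SEED)
    panel = simulate_dependency_panel(cfg)
    paths = write_depmap_bundle(panel, OUT)
    missing = panel.gene_effect.isna().to_numpy().mean()
    print(f"panel: {cfg.n_lines} lines x {cfg.n_genes} genes, "
          f"{cfg.n_lof_lines} LOF lines, {missing:.1%} missing gene effects")
    print(f"planted truth: {panel.truth.coessential_pairs} {panel.truth.gi_pairs}")
    for name, path in paths.items():
        print(f"  wrote {name}: {path}")


if __name__ == "__main__":
    main()
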