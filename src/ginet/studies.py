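"""Planted-truth recovery studies over the synthetic panels.

Each study runs the relevant pipeline stage across many seeded synthetic
datasets at the study conditions (200 cell lines x 2,000 genes, 40 LOF vs
160 WT lines, planted synthetic-lethal lethality means 0.8 vs 0.2, planted
co-essential pairs at rho 0.9) and reports operating characteristics:
sensitivity and empirical false-discovery rate for the GI screen,
co-essential call recovery, and gap-statistic cluster-number recovery.

These functions are the substance behind the acceptance checks and the
analysis drivers; everything is deterministic given the master seed.
"""

from __future__ import annotations

import numpy as np

from ginet.coessentiality import map_essentiality_network
from ginet.gi_screen import run_gi_screen
from ginet.pipeline import stage_seed
from ginet.simulate import SimulationConfig, default_screen_config, simulate_dependency_panel
from ginet.term_clustering import GeneSetCollection, cluster_terms


def sl_recovery_study(
    master_seed: int,
    n_seeds: int = 100,
    n_perm: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Planted-SL recovery across seeded panels at the study conditions.

    Per seed one panel is simulated and screened; a discovery is any gene
    with an SL/AL direction call.  Returns pooled sensitivity (planted
    partner recovered with direction SL), empirical FDR over all
    discoveries, and counts.
    """
    base = stage_seed(master_seed, "sl-recovery")
    tp = fp = fn = 0
    for i in range(n_seeds):
        cfg = default_screen_config(seed=(base + i) % 2**31)
        panel = simulate_dependency_panel(cfg)
        truth = {p["partner_gene"] for p in panel.truth.gi_pairs}
        res = run_gi_screen(
            panel, "G0001", alpha=alpha, n_perm=n_perm, seed=(base + 31 * i) % 2**31
        )
        hits = res.loc[res["direction"] != "none"]
        sl_hits = set(hits.loc[hits["direction"] == "SL", "gene"])
        tp += len(truth & sl_hits)
        fn += len(truth - sl_hits)
        fp += len(set(hits["gene"]) - truth)
    n_disc = tp + fp
    return {
        "n_seeds": n_seeds,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "fdr": fp / n_disc if n_disc else 0.0,
        "true_positives": tp,
        "false_positives": fp,
    }


def null_screen_study(
    master_seed: int,
    n_seeds: int = 10,
    n_perm: int = 1000,
    alpha: float = 0.05,
) -> dict:
    """Fraction of genes reaching adj p < alpha on panels with no planted
    effect (the query gene is mutated but interacts with nothing)."""
    base = stage_seed(master_seed, "null-screen")
    fractions = []
    for i in range(n_seeds):
        cfg = default_screen_config(
            seed=(base + i) % 2**31, planted_gi=(), query_genes=("G0001",)
        )
        panel = simulate_dependency_panel(cfg)
        res = run_gi_screen(
            panel, "G0001", alpha=alpha, n_perm=n_perm, seed=(base + 7 * i) % 2**31
        )
        fractions.append(float((res["adj_pval"] < alpha).mean()))
    return {
        "n_seeds": n_seeds,
        "n_genes": cfg.n_genes - 1,
        "mean_fraction_significant": float(np.mean(fractions)),
        "max_fraction_significant": float(np.max(fractions)),
    }


def coessentiality_recovery_study(
    master_seed: int,
    n_seeds: int = 100,
    n_perm: int = 2000,
    rho: float = 0.9,
    alpha: float = 0.05,
) -> dict:
    """Planted co-essential pair recovery and unplanted call rate.

    Per seed: one study-condition panel, essentiality map of the planted
    pair's first gene, success when the partner is called co-essential.
    The false-call rate counts unplanted genes receiving any call.
    """
    base = stage_seed(master_seed, "coessentiality-recovery")
    recovered = 0
    false_rates = []
    for i in range(n_seeds):
        cfg = default_screen_config(
            seed=(base + i) % 2**31,
            planted_coessential=(("G0002", "G0003", rho),),
        )
        panel = simulate_dependency_panel(cfg)
        rows, _ = map_essentiality_network(
            panel.gene_effect, "G0002",
            n_perm=n_perm, seed=(base + 13 * i) % 2**31, alpha=alpha,
        )
        calls = rows.set_index("gene")["call"]
        if calls.get("G0003") == "coessential":
            recovered += 1
        unplanted = calls.drop(index=["G0003"], errors="ignore")
        false_rates.append(float((unplanted != "none").mean()))
    return {
        "n_seeds": n_seeds,
        "recovery_rate": recovered / n_seeds,
        "mean_unplanted_call_rate": float(np.mean(false_rates)),
    }


def planted_term_collection(
    k: int,
    rng: np.random.Generator,
    terms_per: int = 8,
    core: int = 18,
    size: int = 20,
    pool_extra: int = 12,
) -> GeneSetCollection:
    """k term families on disjoint gene pools (between-family Jaccard 0);
    terms within a family share an ``core``-gene core out of ``size``."""
    terms = {}
    for c in range(k):
        pool = [f"C{c}_g{i}" for i in range(core + pool_extra)]
        for t in range(terms_per):
            extra = list(rng.choice(pool[core:], size=size - core, replace=False))
            terms[f"T{c}_{t}"] = set(pool[:core]) | set(extra)
    return GeneSetCollection.from_dict(terms)


def gap_recovery_study(
    master_seed: int,
    n_seeds: int = 100,
    n_boot: int = 200,
    k_range: tuple[int, ...] = (2, 3, 4, 5),
    k_max: int = 6,
) -> dict:
    """Gap-statistic recovery of planted term-cluster counts."""
    base = stage_seed(master_seed, "gap-recovery")
    correct = 0
    for i in range(n_seeds):
        rng = np.random.default_rng((base + i) % 2**31)
        k_true = k_range[i % len(k_range)]
        coll = planted_term_collection(k_true, rng)
        k_opt, _, _ = cluster_terms(
            coll, k_max=k_max, n_boot=n_boot, seed=(base + 17 * i) % 2**31
        )
        correct += k_opt == k_true
    return {"n_seeds": n_seeds, "recovery_rate": correct / n_seeds}
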