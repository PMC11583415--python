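"""Configuration-driven end-to-end runs.

A pipeline run genotypes the panel for the query gene, maps the
essentiality network, screens each eligible context for genetic
interactions, prioritises candidates against drug tractability, and
writes every table plus a manifest (inputs, per-stage seeds, output
checksums) sufficient to re-run bit-identically.

Per-stage seeds are derived by hashing (master seed, stage name) so adding
a stage never perturbs the randomness of earlier ones.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from ginet import coessentiality, gi_screen, prioritization
from ginet.genotyping import assign_genotype_groups, classify_variant
from ginet.io import load_bundle_dir
from ginet.simulate import DependencyPanel

logger = logging.getLogger(__name__)


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """Inputs and knobs of an end-to-end run.

    ``panel_dir`` points at a DepMap-dialect bundle directory; contexts
    are annotation ``disease`` values ('pan-cancer' screens all lines).
    """

    panel_dir: str
    query_gene: str
    output_dir: str
    seed: int
    contexts: list[str] = field(default_factory=lambda: ["pan-cancer"])
    mode: str = "trans_het_only"
    alpha: float = 0.05
    n_perm_correlation: int = 100_000
    n_perm_screen: int = 10_000
    tractability_path: str | None = None
    run_coessentiality: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not Path(self.panel_dir).is_dir():
            raise ValueError(f"panel directory not found: {self.panel_dir}")
        if self.tractability_path is not None and not Path(self.tractability_path).exists():
            raise ValueError(f"tractability file not found: {self.tractability_path}")


@dataclass
class ReportBundle:
    """Outputs of a pipeline run plus the reproducibility manifest."""

    essentiality: pd.DataFrame | None
    screens: dict[str, pd.DataFrame]
    priorities: dict[str, pd.DataFrame]
    manifest: dict


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, panel: DependencyPanel | None = None) -> ReportBundle:
    """Execute genotype -> essentiality map -> screens -> prioritisation.

    ``panel`` may be passed directly (e.g. a fresh simulation); otherwise
    it is loaded from ``config.panel_dir``.  Contexts whose screen
    preconditions fail (too few mutant or control lines) are skipped with
    a logged reason rather than aborting the run.
    """
    config.validate()
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    if panel is None:
        panel = load_bundle_dir(config.panel_dir)

    import ginet

    manifest: dict = {
        "version": ginet.__version__,
        "schema": 1,
        "master_seed": config.seed,
        "query_gene": config.query_gene,
        "stage_seeds": {},
        "outputs": {},
        "skipped_contexts": {},
    }
    written: list[Path] = []

    def _emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        written.append(path)

    essentiality = None
    if config.run_coessentiality:
        seed = stage_seed(config.seed, "coessentiality")
        manifest["stage_seeds"]["coessentiality"] = seed
        rows, thresholds = coessentiality.map_essentiality_network(
            panel.gene_effect,
            config.query_gene,
            n_perm=config.n_perm_correlation,
            seed=seed,
            alpha=config.alpha,
        )
        essentiality = rows
        manifest["inflection"] = {
            "r_pos": thresholds.r_pos,
            "r_neg": thresholds.r_neg,
            "idx_pos": thresholds.idx_pos,
            "idx_neg": thresholds.idx_neg,
        }
        _emit("essentiality_network.csv", coessentiality.network_to_table(rows, thresholds))

    tractability = None
    if config.tractability_path is not None:
        tractability = prioritization.read_tractability(config.tractability_path)

    screens: dict[str, pd.DataFrame] = {}
    priorities: dict[str, pd.DataFrame] = {}
    for context in config.contexts:
        ctx_arg = None if context == "pan-cancer" else context
        seed = stage_seed(config.seed, f"screen:{context}")
        manifest["stage_seeds"][f"screen:{context}"] = seed
        try:
            screen = gi_screen.run_gi_screen(
                panel,
                config.query_gene,
                mode=config.mode,
                alpha=config.alpha,
                n_perm=config.n_perm_screen,
                seed=seed,
                context=ctx_arg,
            )
        except ValueError as exc:
            logger.warning("skipping context %s: %s", context, exc)
            manifest["skipped_contexts"][context] = str(exc)
            continue
        screens[context] = screen
        prioritised = prioritization.prioritize_screen(screen, tractability)
        priorities[context] = prioritised
        safe = context.replace("/", "-").replace(" ", "_")
        _emit(f"gi_screen_{safe}.csv", gi_screen.screen_to_table(screen))
        _emit(f"priority_{safe}.csv", prioritised)

    for path in written:
        manifest["outputs"][path.name] = _checksum(path)
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))

    return ReportBundle(
        essentiality=essentiality,
        screens=screens,
        priorities=priorities,
        manifest=manifest,
    )


def summarize_context_mutations(
    panel: DependencyPanel, query: str
) -> tuple[dict[str, dict[str, int]], dict[str, int]]:
    """Per-context mutation summary and line counts for context selection,
    computed from the panel's own annotation and mutation tables."""
    ann = panel.annotations
    by_line = {}
    for rec in panel.mutations:
        if rec.gene == query:
            by_line.setdefault(rec.sample_id, []).append(rec.variant_class)
    summaries: dict[str, dict[str, int]] = {}
    line_counts: dict[str, int] = {}
    for context, sub in ann.groupby("disease"):
        ids = list(sub["DepMap_ID"])
        classes = [c for s in ids for c in by_line.get(s, [])]
        summaries[context] = {
            "n_samples": len(ids),
            "n_mutated_samples": sum(1 for s in ids if s in by_line),
            "n_mutations": len(classes),
            "n_lof_mutations": sum(1 for c in classes if classify_variant(c) == "lof"),
        }
        line_counts[context] = len(ids)
    return summaries, line_counts
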