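"""Seeded DepMap-like synthetic data with planted ground truth.

The generator emulates the input tables a dependency-screen analysis
consumes — a lines x genes gene-effect matrix (CERES-like, roughly centred,
with missing entries), a lines x genes knockout lethality-probability
matrix in [0, 1], MAF-like mutation records, copy-number states and
cell-line annotations — while planting known structure:

* co-essential gene pairs with a target Pearson correlation, built from a
  shared latent factor so the population correlation equals ``rho``;
* genetic interactions: partner-gene lethality drawn with mean
  ``lof_mean`` in the lines labelled LOF for the query gene and ``wt_mean``
  elsewhere (``lof_mean > wt_mean`` plants a synthetic-lethal effect,
  the reverse an alleviating one);
* expression cohorts with planted per-group fold changes on marker genes.

Everything is driven by one integer seed; identical configs give
element-wise identical outputs.

Distributional choices (gene effects standard normal per gene with small
line offsets; lethality from Beta distributions parameterised by mean and
concentration; missingness completely at random) are stand-ins chosen for
plausibility, not claims about DepMap — see docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from ginet.genotyping import MutationRecord, CopyNumberRecord

_MAX_SEED = 2**31 - 1


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a synthetic dependency panel.

    ``planted_coessential`` holds (gene_a, gene_b, rho) triples;
    ``planted_gi`` holds (query_gene, partner_gene, lof_mean, wt_mean)
    with means in (0, 1).  The first ``n_lof_lines`` lines carry
    trans-heterozygous LOF mutations of each planted query gene.
    """

    n_lines: int = 200
    n_genes: int = 2000
    seed: int = 0
    missing_rate: float = 0.02
    planted_coessential: tuple[tuple[str, str, float], ...] = ()
    planted_gi: tuple[tuple[str, str, float, float], ...] = ()
    n_lof_lines: int = 40
    # genes that get LOF mutations in the LOF lines even without a planted
    # effect (null screens); planted_gi query genes are always included
    query_genes: tuple[str, ...] = ()
    cancer_types: tuple[str, ...] = ("COAD/READ", "LUSC", "STAD", "UCEC", "BLCA")
    line_offset_sd: float = 0.1
    beta_concentration: float = 10.0
    missense_noise_rate: float = 0.0
    msi_fraction: float = 0.2

    def gene_names(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"G{i:0{width}d}" for i in range(1, self.n_genes + 1)]

    def line_names(self) -> list[str]:
        return [f"ACH-{i:06d}" for i in range(1, self.n_lines + 1)]

    def validate(self) -> None:
        if self.n_lines < 2 or self.n_genes < 2:
            raise ValueError("need at least 2 lines and 2 genes")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.n_lof_lines < self.n_lines:
            raise ValueError("n_lof_lines must be < n_lines")
        universe = set(self.gene_names())
        seen: set[str] = set()
        for a, b, rho in self.planted_coessential:
            if not -1 < rho < 1:
                raise ValueError(f"rho {rho} outside (-1, 1) for pair ({a}, {b})")
            for g in (a, b):
                if g not in universe:
                    raise ValueError(f"planted gene {g!r} outside gene universe")
                if g in seen:
                    raise ValueError(f"planted gene {g!r} used more than once")
                seen.add(g)
        for g in self.query_genes:
            if g not in universe:
                raise ValueError(f"query gene {g!r} outside gene universe")
        for q, p, lof_mean, wt_mean in self.planted_gi:
            for g in (q, p):
                if g not in universe:
                    raise ValueError(f"planted gene {g!r} outside gene universe")
            if p in seen:
                raise ValueError(f"planted partner {p!r} used more than once")
            seen.add(p)
            for m in (lof_mean, wt_mean):
                if not 0 < m < 1:
                    raise ValueError(f"planted mean {m} outside (0, 1)")
            if lof_mean == wt_mean:
                raise ValueError(f"lof_mean equals wt_mean for partner {p!r}")


@dataclass
class GroundTruth:
    """Planted structure recorded alongside a simulated panel or cohort."""

    coessential_pairs: list[dict] = field(default_factory=list)
    gi_pairs: list[dict] = field(default_factory=list)
    marker_effects: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


@dataclass
class DependencyPanel:
    """Paired gene-effect / lethality matrices with genomic side tables.

    Both matrices are lines x genes DataFrames indexed by cell-line ID with
    identical index/columns; ``gene_effect`` may contain NaN, ``lethality``
    is complete and bounded in [0, 1].
    """

    gene_effect: pd.DataFrame
    lethality: pd.DataFrame
    mutations: list[MutationRecord]
    copy_number: list[CopyNumberRecord]
    annotations: pd.DataFrame
    truth: GroundTruth

    def validate(self) -> None:
        if not self.gene_effect.index.equals(self.lethality.index):
            raise ValueError("gene_effect and lethality line sets differ")
        if not self.gene_effect.columns.equals(self.lethality.columns):
            raise ValueError("gene_effect and lethality gene sets differ")
        vals = self.lethality.to_numpy()
        if np.isnan(vals).any() or (vals < 0).any() or (vals > 1).any():
            raise ValueError("lethality values must lie in [0, 1]")
        known = set(self.annotations["DepMap_ID"])
        for rec in self.mutations:
            if rec.sample_id not in known:
                raise ValueError(f"mutation sample {rec.sample_id!r} not annotated")
        for rec in self.copy_number:
            if rec.sample_id not in known:
                raise ValueError(f"CN sample {rec.sample_id!r} not annotated")


def _planted_pair(rng: np.random.Generator, n: int, rho: float) -> tuple[np.ndarray, np.ndarray]:
    # shared latent factor: corr(a, b) = rho exactly in population
    f = rng.standard_normal(n)
    s = abs(rho)
    a = np.sqrt(s) * f + np.sqrt(1 - s) * rng.standard_normal(n)
    b = np.sign(rho) * np.sqrt(s) * f + np.sqrt(1 - s) * rng.standard_normal(n)
    return a, b


def _beta_from_mean(rng: np.random.Generator, mean, concentration: float, size) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    return rng.beta(mean * concentration, (1.0 - mean) * concentration, size=size)


def simulate_dependency_panel(config: SimulationConfig) -> DependencyPanel:
    """Generate a dependency panel with the planted structure recorded.

    Deterministic given ``config.seed``.  Planted co-essential pairs are
    excluded from line offsets so their correlation is calibrated exactly;
    planted GI partners get Beta-distributed lethality with mean
    ``lof_mean`` in LOF lines and ``wt_mean`` in the rest; LOF lines carry
    two LOF mutation records for the query gene (trans-heterozygous by the
    genotyping rules) and every (line, query-gene) pair gets a neutral
    copy-number record unless noise says otherwise.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = config.gene_names()
    lines = config.line_names()
    L, G = config.n_lines, config.n_genes
    gene_idx = {g: i for i, g in enumerate(genes)}

    # --- gene effects ---------------------------------------------------
    effects = rng.standard_normal((L, G))
    offsets = rng.normal(0.0, config.line_offset_sd, size=L)
    effects += offsets[:, None]
    truth = GroundTruth()
    for a, b, rho in config.planted_coessential:
        xa, xb = _planted_pair(rng, L, rho)
        effects[:, gene_idx[a]] = xa
        effects[:, gene_idx[b]] = xb
        truth.coessential_pairs.append({"gene_a": a, "gene_b": b, "rho": rho})
    if config.missing_rate > 0:
        mask = rng.random((L, G)) < config.missing_rate
        effects[mask] = np.nan
    gene_effect = pd.DataFrame(effects, index=lines, columns=genes)

    # --- lethality probabilities ----------------------------------------
    base_means = rng.uniform(0.05, 0.5, size=G)
    leth = _beta_from_mean(rng, base_means[None, :], config.beta_concentration, (L, G))
    lof_lines = lines[: config.n_lof_lines]
    is_lof = np.zeros(L, dtype=bool)
    is_lof[: config.n_lof_lines] = True
    for q, p, lof_mean, wt_mean in config.planted_gi:
        j = gene_idx[p]
        col = np.where(
            is_lof,
            _beta_from_mean(rng, lof_mean, config.beta_concentration, L),
            _beta_from_mean(rng, wt_mean, config.beta_concentration, L),
        )
        leth[:, j] = col
        truth.gi_pairs.append(
            {
                "query_gene": q,
                "partner_gene": p,
                "lof_mean": lof_mean,
                "wt_mean": wt_mean,
                "direction": "SL" if lof_mean > wt_mean else "AL",
                "effect_size": abs(lof_mean - wt_mean),
            }
        )
    lethality = pd.DataFrame(leth, index=lines, columns=genes)

    # --- mutations, copy number, annotations ----------------------------
    mutations: list[MutationRecord] = []
    copy_number: list[CopyNumberRecord] = []
    query_genes = sorted({q for q, *_ in config.planted_gi} | set(config.query_genes))
    for q in query_genes:
        for s in lof_lines:
            mutations.append(MutationRecord(s, q, "Nonsense_Mutation", "p.Q100*"))
            mutations.append(MutationRecord(s, q, "Frame_Shift_Del", "p.L200fs"))
        if config.missense_noise_rate > 0:
            noisy = rng.random(L - config.n_lof_lines) < config.missense_noise_rate
            for s, hit in zip(lines[config.n_lof_lines :], noisy):
                if hit:
                    mutations.append(MutationRecord(s, q, "Missense_Mutation", "p.A1T"))
        for s in lines:
            copy_number.append(CopyNumberRecord(s, q, "neutral"))

    types = rng.choice(config.cancer_types, size=L)
    msi = np.where(rng.random(L) < config.msi_fraction, "MSI", "MSS")
    annotations = pd.DataFrame(
        {
            "DepMap_ID": lines,
            "stripped_cell_line_name": [f"LINE{i:04d}" for i in range(1, L + 1)],
            "disease": types,
            "disease_subtype": [f"{t} subtype" for t in types],
            "MSI_status": msi,
        }
    )

    panel = DependencyPanel(gene_effect, lethality, mutations, copy_number, annotations, truth)
    panel.validate()
    return panel


def default_screen_config(seed: int, **overrides) -> SimulationConfig:
    """The study-condition panel: 200 x 2000, one planted co-essential pair
    (rho 0.9) and one planted SL (lethality mean 0.8 in 40 LOF lines vs 0.2
    in 160 WT lines)."""
    cfg = dict(
        n_lines=200,
        n_genes=2000,
        seed=seed,
        missing_rate=0.02,
        planted_coessential=(("G0002", "G0003", 0.9),),
        planted_gi=(("G0001", "G0010", 0.8, 0.2),),
        n_lof_lines=40,
    )
    cfg.update(overrides)
    return SimulationConfig(**cfg)


# ---------------------------------------------------------------------------
# Expression cohorts
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of a synthetic expression/clinical cohort.

    ``group_sizes`` maps group label -> n samples (each >= 3);
    ``planted_log2fc`` maps group -> {gene: log2 fold change relative to
    the baseline mean}; ``msi_groups`` lists groups whose samples receive
    MSI-range MSIsensor/MANTIS scores; ``hazards`` maps group ->
    exponential event hazard (per month).
    """

    group_sizes: tuple[tuple[str, int], ...] = (("WT", 50), ("LOF", 50))
    genes: tuple[str, ...] = ()
    seed: int = 0
    planted_log2fc: tuple[tuple[str, tuple[tuple[str, float], ...]], ...] = ()
    msi_groups: tuple[str, ...] = ()
    hazards: tuple[tuple[str, float], ...] = ()
    base_mean_log_sd: float = 1.0
    noise_log2_sd: float = 0.5
    censor_months: float = 60.0

    def validate(self) -> None:
        if len(self.group_sizes) < 2:
            raise ValueError("need at least 2 groups")
        for g, n in self.group_sizes:
            if n < 3:
                raise ValueError(f"group {g!r} has {n} samples; need >= 3")
        if not self.genes:
            raise ValueError("gene list must be non-empty")
        groups = {g for g, _ in self.group_sizes}
        for g, effects in self.planted_log2fc:
            if g not in groups:
                raise ValueError(f"planted group {g!r} not in group_sizes")
            for gene, _ in effects:
                if gene not in self.genes:
                    raise ValueError(f"planted gene {gene!r} not in gene list")


@dataclass
class ExpressionCohort:
    """FPKM matrix (samples x genes) plus clinical table and ground truth."""

    fpkm: pd.DataFrame
    clinical: pd.DataFrame
    truth: GroundTruth


def simulate_expression_cohort(config: CohortConfig) -> ExpressionCohort:
    """Generate an FPKM matrix, clinical table and survival columns.

    Baseline per-gene means are log-normal; planted group effects multiply
    the mean by ``2**log2fc``; multiplicative log-normal noise on top keeps
    FPKM non-negative.  Survival times are exponential per group with
    uniform censoring at ``censor_months``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    genes = list(config.genes)
    groups = [g for g, n in config.group_sizes for _ in range(n)]
    n = len(groups)
    samples = [f"S{i:04d}" for i in range(1, n + 1)]
    planted = {g: dict(effects) for g, effects in config.planted_log2fc}

    base = np.exp(rng.normal(np.log(10.0), config.base_mean_log_sd, size=len(genes)))
    log2fc = np.zeros((n, len(genes)))
    for i, grp in enumerate(groups):
        for j, gene in enumerate(genes):
            log2fc[i, j] = planted.get(grp, {}).get(gene, 0.0)
    noise = rng.normal(0.0, config.noise_log2_sd, size=(n, len(genes)))
    fpkm = base[None, :] * np.exp2(log2fc + noise)
    fpkm_df = pd.DataFrame(fpkm, index=samples, columns=genes)

    hazards = dict(config.hazards)
    msi_groups = set(config.msi_groups)
    rows = []
    for s, grp in zip(samples, groups):
        lam = hazards.get(grp, 0.02)
        t_event = rng.exponential(1.0 / lam)
        t_cens = rng.uniform(0.0, config.censor_months)
        time = min(t_event, t_cens)
        event = int(t_event <= t_cens)
        if grp in msi_groups:
            msisensor = rng.uniform(10.0, 40.0)
            mantis = rng.uniform(0.4, 1.0)
        else:
            msisensor = rng.uniform(0.0, 10.0)
            mantis = rng.uniform(0.0, 0.4)
        rows.append((s, grp, time, event, msisensor, mantis))
    clinical = pd.DataFrame(
        rows,
        columns=["sample_id", "group", "time", "event", "MSIsensor", "MANTIS"],
    )
    truth = GroundTruth(
        marker_effects={g: dict(effects) for g, effects in config.planted_log2fc}
    )
    return ExpressionCohort(fpkm_df, clinical, truth)


# ---------------------------------------------------------------------------
# DepMap-dialect writers
# ---------------------------------------------------------------------------


def _depmap_header(genes, gene_idx) -> list[str]:
    return [f"{g} ({gene_idx[g]})" for g in genes]


def write_depmap_bundle(panel: DependencyPanel, outdir: str | Path) -> dict[str, Path]:
    """Write a panel as DepMap-dialect text files.

    Matrix CSVs carry header cells ``"SYMBOL (ENTREZID)"`` (Entrez stands in
    as the 1-based gene index); mutations go to a MAF-like TSV, copy number
    and annotations to TSV/CSV.  Ground truth is serialised to JSON.
    Returns the written paths keyed by table name.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    genes = list(panel.gene_effect.columns)
    gene_idx = {g: i for i, g in enumerate(genes, start=1)}
    header = _depmap_header(genes, gene_idx)

    paths: dict[str, Path] = {}

    def _write_matrix(df: pd.DataFrame, name: str) -> None:
        out = df.copy()
        out.columns = header
        out.index.name = "DepMap_ID"
        path = outdir / f"{name}.csv"
        out.to_csv(path)
        paths[name] = path

    _write_matrix(panel.gene_effect, "gene_effect")
    _write_matrix(panel.lethality, "lethality")

    maf = pd.DataFrame(
        [
            (m.gene, m.variant_class, m.sample_id, m.protein_change or "")
            for m in panel.mutations
        ],
        columns=["Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode", "Protein_Change"],
    )
    paths["mutations"] = outdir / "mutations.tsv"
    maf.to_csv(paths["mutations"], sep="\t", index=False)

    cn = pd.DataFrame(
        [(c.sample_id, c.gene, c.cn_state) for c in panel.copy_number],
        columns=["sample_id", "gene", "cn_state"],
    )
    paths["copy_number"] = outdir / "copy_number.tsv"
    cn.to_csv(paths["copy_number"], sep="\t", index=False)

    paths["annotations"] = outdir / "sample_info.csv"
    panel.annotations.to_csv(paths["annotations"], index=False)

    paths["truth"] = outdir / "truth.json"
    paths["truth"].write_text(panel.truth.to_json())
    return paths
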