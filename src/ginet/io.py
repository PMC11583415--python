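"""DepMap-dialect readers.

Matrix CSVs carry one cell line per row (index column ``DepMap_ID``) and
header cells of the form ``"SYMBOL (ENTREZID)"``, which are normalised to
the bare symbol; the symbol -> Entrez mapping is preserved on request.
Mutations arrive as MAF-like TSV, copy number and annotations as
TSV/CSV.
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import pandas as pd

from ginet.genotyping import MutationRecord, CopyNumberRecord
from ginet.simulate import DependencyPanel, GroundTruth

_HEADER_RE = re.compile(r"^\s*(?P<symbol>\S+)\s*\((?P<entrez>[^)]*)\)\s*$")

MAF_REQUIRED = ("Hugo_Symbol", "Variant_Classification", "Tumor_Sample_Barcode")


def parse_gene_header(cell: str) -> tuple[str, str | None]:
    """Split a ``"SYMBOL (ENTREZID)"`` header cell; plain symbols pass through."""
    m = _HEADER_RE.match(cell)
    if m:
        return m.group("symbol"), m.group("entrez") or None
    return cell.strip(), None


def read_depmap_matrix(path) -> pd.DataFrame:
    """Read a DepMap-style matrix CSV (lines x genes, symbol headers)."""
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split(",")
    symbols = [parse_gene_header(c)[0] for c in header[1:]]
    dupes = sorted({s for s in symbols if symbols.count(s) > 1})
    if dupes:
        raise ValueError(f"duplicate gene columns in {path}: {dupes}")
    df = pd.read_csv(path, index_col=0)
    df.columns = symbols
    return df


def read_maf(path) -> list[MutationRecord]:
    """Read a MAF-like TSV into mutation records; validates the header."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MAF_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"MAF {path} missing required column(s): {missing}")
    records = []
    for row in df.itertuples(index=False):
        protein = getattr(row, "Protein_Change", None)
        records.append(
            MutationRecord(
                sample_id=row.Tumor_Sample_Barcode,
                gene=row.Hugo_Symbol,
                variant_class=row.Variant_Classification,
                protein_change=protein if isinstance(protein, str) and protein else None,
            )
        )
    return records


def read_copy_number(path) -> list[CopyNumberRecord]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ("sample_id", "gene", "cn_state") if c not in df.columns]
    if missing:
        raise ValueError(f"copy-number table {path} missing column(s): {missing}")
    return [
        CopyNumberRecord(row.sample_id, row.gene, row.cn_state)
        for row in df.itertuples(index=False)
    ]


def load_depmap_bundle(
    effects_path,
    lethality_path,
    maf_path,
    cn_path,
    annotations_path,
    truth_path=None,
) -> DependencyPanel:
    """Assemble a dependency panel from DepMap-dialect files.

    The two matrices must agree on their cell-line and gene sets; a
    mismatch is an error rather than a silent intersection.
    """
    gene_effect = read_depmap_matrix(effects_path)
    lethality = read_depmap_matrix(lethality_path)
    if set(gene_effect.index) != set(lethality.index):
        raise ValueError("gene-effect and lethality matrices disagree on cell lines")
    if list(gene_effect.columns) != list(lethality.columns):
        raise ValueError("gene-effect and lethality matrices disagree on genes")
    lethality = lethality.loc[gene_effect.index]

    annotations = pd.read_csv(annotations_path)
    if "DepMap_ID" not in annotations.columns:
        raise ValueError("annotation CSV missing DepMap_ID column")

    truth = GroundTruth()
    if truth_path is not None and Path(truth_path).exists():
        data = json.loads(Path(truth_path).read_text())
        truth = GroundTruth(**data)

    panel = DependencyPanel(
        gene_effect=gene_effect,
        lethality=lethality,
        mutations=read_maf(maf_path),
        copy_number=read_copy_number(cn_path),
        annotations=annotations,
        truth=truth,
    )
    panel.validate()
    return panel


def load_bundle_dir(directory) -> DependencyPanel:
    """Load a bundle written by :func:`ginet.simulate.write_depmap_bundle`."""
    d = Path(directory)
    return load_depmap_bundle(
        d / "gene_effect.csv",
        d / "lethality.csv",
        d / "mutations.tsv",
        d / "copy_number.tsv",
        d / "sample_info.csv",
        d / "truth.json",
    )
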