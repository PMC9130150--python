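"""Readers and writers for the pipeline's tabular interchange formats.

Everything is plain delimited text: gene x sample expression TSV with a
one-line header, a gene-annotation TSV (gene_id, gc, length_bp), a clinical
TSV, GMT gene-set collections, and YAML/JSON panel configs.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .containers import (
    LOG2_NORMALIZED,
    RAW_COUNTS,
    ClinicalTable,
    ExpressionMatrix,
    GenePanel,
    ScoreTable,
)


def read_expression(
    path: str | Path,
    value_scale: str = RAW_COUNTS,
    annotation_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a gene x sample TSV (first column = gene id, header = samples)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    values = pd.read_csv(path, sep="\t", index_col=0)
    values.index = values.index.astype(str)
    values.index.name = None
    gc = length = None
    if annotation_path is not None:
        ann = read_gene_annotation(annotation_path)
        gc, length = ann["gc"], ann["length_bp"]
    return ExpressionMatrix(values, value_scale=value_scale, gene_gc=gc, gene_length=length)


def write_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    frame = expr.values.copy()
    frame.index.name = "gene_id"
    frame.to_csv(path, sep="\t")


def read_gene_annotation(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene annotation file not found: {path}")
    ann = pd.read_csv(path, sep="\t", index_col="gene_id")
    for col in ("gc", "length_bp"):
        if col not in ann.columns:
            raise ValueError(f"annotation file lacks column {col!r}")
    return ann


def write_gene_annotation(expr: ExpressionMatrix, path: str | Path) -> None:
    if expr.gene_gc is None or expr.gene_length is None:
        raise ValueError("expression matrix carries no GC/length annotation")
    ann = pd.DataFrame({"gc": expr.gene_gc, "length_bp": expr.gene_length.astype(int)})
    ann.index.name = "gene_id"
    ann.to_csv(path, sep="\t")


#: default mapping from on-disk column names to canonical clinical fields
CLINICAL_COLUMNS = {
    "sample_id": "sample_id",
    "arm": "arm",
    "time": "time",
    "event": "event",
    "pcr": "pcr",
    "age": "age",
    "tumor_size": "tumor_size",
    "nodal_status": "nodal_status",
    "grade": "grade",
    "er_pr": "er_pr",
}


def read_clinical(path: str | Path, column_map: dict[str, str] | None = None) -> ClinicalTable:
    """Read a clinical TSV; ``column_map`` renames file columns to canonical ones."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"clinical file not found: {path}")
    data = pd.read_csv(path, sep="\t")
    if column_map:
        data = data.rename(columns={v: k for k, v in column_map.items()})
    if "sample_id" not in data.columns:
        raise ValueError("clinical table requires a 'sample_id' column")
    data["sample_id"] = data["sample_id"].astype(str)
    return ClinicalTable(data.set_index("sample_id"))


def write_clinical(clinical: ClinicalTable, path: str | Path) -> None:
    out = clinical.data.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_panels(path: str | Path) -> list[GenePanel]:
    """Read panels from YAML/JSON: ``{name: {method: ..., genes: [...]}}``."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"panel config not found: {path}")
    text = path.read_text()
    spec = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(spec, dict) or not spec:
        raise ValueError(f"panel config {path} must map panel name -> definition")
    panels = []
    for name, body in spec.items():
        if not isinstance(body, dict) or "genes" not in body:
            raise ValueError(f"panel {name!r} must define a 'genes' list")
        panels.append(
            GenePanel(
                name=str(name),
                genes=[str(g) for g in body["genes"]],
                method=body.get("method", "log_geometric_mean"),
            )
        )
    return panels


def write_panels(panels: list[GenePanel], path: str | Path) -> None:
    spec = {p.name: {"method": p.method, "genes": list(p.genes)} for p in panels}
    Path(path).write_text(yaml.safe_dump(spec, sort_keys=False))


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read a GMT gene-set file: name <tab> description <tab> genes..."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"gene-set file not found: {path}")
    sets: dict[str, list[str]] = {}
    for line in path.read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:60]!r}")
        name, _desc, *genes = fields
        genes = [g for g in genes if g]
        if name in sets:
            raise ValueError(f"duplicate gene set {name!r}")
        sets[name] = genes
    if not sets:
        raise ValueError(f"no gene sets found in {path}")
    return sets


def write_gmt(gene_sets: dict[str, list[str]], path: str | Path, description: str = "na") -> None:
    lines = [
        "\t".join([name, description, *genes]) for name, genes in gene_sets.items()
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def write_scores(tables: list[ScoreTable], path: str | Path) -> None:
    """Write score tables in long format (sample_id, panel, score, group, cutoff)."""
    frames = [t.to_frame().reset_index() for t in tables]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_scores(path: str | Path) -> list[ScoreTable]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"score file not found: {path}")
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    tables = []
    for panel, sub in frame.groupby("panel", sort=False):
        sub = sub.set_index("sample_id")
        group = sub["group"] if "group" in sub.columns else None
        cutoff = float(sub["cutoff"].iloc[0]) if "cutoff" in sub.columns else None
        tables.append(ScoreTable(str(panel), sub["score"], group=group, cutoff=cutoff))
    return tables
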