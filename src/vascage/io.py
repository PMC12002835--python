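"""Readers and writers for the package's file formats.

TSV is the canonical interchange format. Expression matrices are also
accepted as GCT 1.2 (read-only). Protein matrices follow the wide
DIA-NN-style layout: first column protein/gene symbol, one column per
sample, empty cell or literal ``NaN`` meaning missing. The missing-value
sentinel on write is the empty string, which round-trips with the reader.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ParseError, ValidationError
from .proteomics import ProteomicsMatrix
from .regulon import GenePanel

logger = logging.getLogger(__name__)


def _check_rect(path: Path, sep: str = "\t") -> None:
    widths = set()
    with open(path) as fh:
        for i, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            widths.add(line.rstrip("\n").count(sep))
            if len(widths) > 1:
                raise ParseError(f"{path}: ragged row", line=i)


def read_expression(path, format: str = "auto") -> pd.DataFrame:
    """Read a gene x sample TPM matrix from TSV or GCT 1.2.

    Duplicate gene ids and negative values are rejected with the gene
    named. ``format='auto'`` sniffs the ``#1.2`` GCT magic.
    """
    path = Path(path)
    if format == "auto":
        with open(path) as fh:
            format = "gct" if fh.readline().strip() == "#1.2" else "tsv"
    if format == "gct":
        with open(path) as fh:
            magic = fh.readline().strip()
            if magic != "#1.2":
                raise ParseError(f"{path}: not a GCT 1.2 file (header {magic!r})",
                                 line=1)
            dims = fh.readline().split()
            if len(dims) < 2:
                raise ParseError(f"{path}: malformed GCT dimension line", line=2)
            df = pd.read_csv(fh, sep="\t", index_col=0)
        df = df.drop(columns=[c for c in ("Description",) if c in df.columns])
        if df.shape != (int(dims[0]), int(dims[1])):
            raise ParseError(
                f"{path}: GCT dimensions {dims[:2]} disagree with data {df.shape}")
    elif format == "tsv":
        _check_rect(path)
        df = pd.read_csv(path, sep="\t", index_col=0)
    else:
        raise ValidationError(f"unknown expression format {format!r}")
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise ParseError(f"{path}: duplicate gene ids {dup[:5]}")
    vals = df.to_numpy(dtype=float)
    if np.isnan(vals).any() or (vals < 0).any():
        bad = df.index[np.argwhere(np.isnan(vals) | (vals < 0))[0][0]]
        raise ParseError(f"{path}: negative or missing TPM for gene {bad!r}")
    df.index = df.index.astype(str)
    df.index.name = "gene_id"
    return df


def write_expression(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="gene_id")


def read_metadata(path) -> pd.DataFrame:
    """Read cohort metadata (sample_id, age, sex, tissue) from TSV."""
    df = pd.read_csv(path, sep="\t")
    need = {"sample_id", "age", "sex"}
    if not need.issubset(df.columns):
        raise ParseError(f"{path}: metadata needs columns {sorted(need)}")
    if df["sample_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate sample ids")
    ages = df["age"].to_numpy(dtype=float)
    if (ages < 15).any() or (ages > 100).any():
        raise ParseError(f"{path}: ages must lie in [15, 100]")
    if not set(df["sex"].unique()) <= {1, 2}:
        raise ParseError(f"{path}: sex must be coded 1 (male) / 2 (female)")
    return df


def write_metadata(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_proteome(path, scale: str, groups_path=None) -> ProteomicsMatrix:
    """Read a wide DIA-NN-style protein matrix plus a sample->group TSV.

    ``scale`` must be declared explicitly ('raw' or 'log2'); there is no
    auto-detection. Empty cells and literal NaN both parse as missing.
    """
    if scale not in ("raw", "log2"):
        raise ValidationError("scale must be declared: 'raw' or 'log2'")
    path = Path(path)
    _check_rect(path)
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["", "NaN", "nan"])
    df.index = df.index.astype(str)
    if groups_path is not None:
        g = pd.read_csv(groups_path, sep="\t")
        if not {"sample_id", "group"}.issubset(g.columns):
            raise ParseError(f"{groups_path}: needs columns sample_id, group")
        groups = g.set_index("sample_id")["group"]
    else:
        groups = pd.Series("all", index=df.columns, name="group")
    return ProteomicsMatrix(values=df.astype(float), groups=groups, scale=scale)


def write_proteome(m: ProteomicsMatrix, path) -> None:
    m.values.to_csv(path, sep="\t", index_label="protein_id", na_rep="")


def write_groups(m: ProteomicsMatrix, path) -> None:
    pd.DataFrame({"sample_id": m.groups.index, "group": m.groups.to_numpy()}
                 ).to_csv(path, sep="\t", index=False)


def write_corr_table(table: pd.DataFrame, path) -> None:
    from .age_screen import CORR_COLUMNS

    table[CORR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_corr_table(path, tissue: str | None = None) -> pd.DataFrame:
    from .age_screen import CORR_COLUMNS

    df = pd.read_csv(path, sep="\t")
    missing = set(CORR_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: correlation table lacks {sorted(missing)}")
    df["gene_id"] = df["gene_id"].astype(str)
    df.attrs["tissue"] = tissue or ""
    return df


def write_gene_set(genes, path, thresholds: dict | None = None) -> None:
    """One symbol per line with a header comment recording thresholds."""
    with open(path, "w") as fh:
        if thresholds:
            params = " ".join(f"{k}={v}" for k, v in sorted(thresholds.items()))
            fh.write(f"# {params}\n")
        for g in genes:
            fh.write(f"{g}\n")


def read_gene_set(path) -> list:
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                out.append(line)
    return out


def read_panels(path) -> list[GenePanel]:
    """Read gene panels from two-column TSV or one-per-line text.

    TSV: columns ``panel_name`` and ``gene_symbol``. Plain text: a
    ``# panel: NAME`` header line followed by one symbol per line.
    """
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# panel:"):
        panels, name, symbols = [], None, []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line.startswith("# panel:"):
                    if name is not None:
                        panels.append(GenePanel(name, tuple(symbols)))
                    name, symbols = line.split(":", 1)[1].strip(), []
                elif line and not line.startswith("#"):
                    symbols.append(line)
        if name is not None:
            panels.append(GenePanel(name, tuple(symbols)))
        return panels
    df = pd.read_csv(path, sep="\t")
    if not {"panel_name", "gene_symbol"}.issubset(df.columns):
        raise ParseError(f"{path}: need columns panel_name, gene_symbol or a "
                         "'# panel:' header")
    return [GenePanel(name, tuple(sub["gene_symbol"]))
            for name, sub in df.groupby("panel_name", sort=True)]


def write_de_result(de, path) -> None:
    from .proteomics import DE_COLUMNS

    de.table[DE_COLUMNS].to_csv(path, sep="\t", index=False)


def read_de_result(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    df["protein_id"] = df["protein_id"].astype(str)
    return df


def read_annotations(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"protein_id", "role"}.issubset(df.columns):
        raise ParseError(f"{path}: need columns protein_id, role")
    return df


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
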