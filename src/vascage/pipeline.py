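"""Configuration, run manifests, and the two orchestrated workflows.

``aging-screen``: per-tissue correlation tables -> pan-arterial and
extended concordance sets -> panel deviation tests.

``proteome-de``: log2 transform (if raw) -> valid-value filter ->
permutation-FDR t test -> downshift imputation -> PCA -> z-score ->
hierarchical clustering.

Every run writes a JSON manifest recording the tool version, a hash of
the effective configuration, per-stage seeds and parameters, and SHA-256
digests of all input files, so identical config + inputs reproduce
identical artifacts.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, io
from .age_screen import correlate_age, extended_set, pan_arterial_set
from .errors import ValidationError
from .proteomics import (filter_valid, hcluster, impute_downshift,
                         log2_transform, pca_scores, ttest_permutation_fdr,
                         zscore_rows)
from .regulon import panel_deviation_test

logger = logging.getLogger(__name__)


@dataclass
class Config:
    """All stage parameters, defaulting to the published workflow values."""

    workflow: str = ""  # "aging-screen" | "proteome-de"
    out_dir: str = "vascage_out"
    seed: int = 0
    # aging screen
    alpha: float = 0.05
    sum_r_cut: float = 0.5
    sec_r_cut: float = 0.1
    age_bins: tuple = ((20, 39), (40, 59), (60, 79))
    expression: dict = field(default_factory=dict)  # tissue -> path
    metadata: str = ""
    primary_tissues: tuple = ()
    secondary_tissue: str = ""
    panels: str = ""  # optional panel file
    # proteomics
    matrix: str = ""
    groups: str = ""
    scale: str = "raw"
    min_valid: int = 3
    n_perm: int = 250
    fdr: float = 0.05
    s0: float = 0.0
    impute_width: float = 0.4
    impute_downshift: float = 1.8
    kmeans_pre: int = 0  # 0 = off
    n_components: int = 2

    @classmethod
    def from_yaml(cls, path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        for key in ("age_bins", "primary_tissues"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(tuple(x) if isinstance(x, list) else x
                                 for x in raw[key])
        return cls(**raw)

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _file_digest(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def build_manifest(config: Config, inputs: list, stages: dict) -> dict:
    return {
        "tool": "vascage",
        "version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
        "config_hash": config.digest(),
        "config": dataclasses.asdict(config),
        "inputs": {str(p): _file_digest(p) for p in inputs},
        "stages": stages,
    }


def _fail_stage(out_dir: Path, stage: str, err: Exception):
    failed = out_dir / "failed"
    failed.mkdir(exist_ok=True)
    for f in sorted(out_dir.iterdir()):
        if f.is_file():
            f.rename(failed / f.name)
    raise RuntimeError(f"stage {stage!r} failed: {err}") from err


def run_pipeline(config: Config) -> dict:
    """Execute the configured workflow; returns the manifest (also written).

    On a stage error, artifacts produced so far are preserved under a
    ``failed/`` prefix inside the output directory and the error is
    re-raised naming the stage.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if config.workflow == "aging-screen":
        manifest = _run_aging_screen(config, out_dir)
    elif config.workflow == "proteome-de":
        manifest = _run_proteome_de(config, out_dir)
    else:
        raise ValidationError(
            f"workflow must be 'aging-screen' or 'proteome-de', "
            f"got {config.workflow!r}")
    io.write_json(manifest, out_dir / "manifest.json")
    return manifest


def _run_aging_screen(config: Config, out_dir: Path) -> dict:
    if len(config.expression) != 3:
        raise ValidationError("aging-screen needs exactly 3 tissue matrices")
    inputs = list(config.expression.values()) + [config.metadata]
    stages: dict = {}
    meta = io.read_metadata(config.metadata)

    tables = {}
    stage = "correlate_age"
    try:
        for tissue, path in config.expression.items():
            expr = io.read_expression(path)
            sub = meta.loc[meta["tissue"] == tissue] if "tissue" in meta else meta
            table = correlate_age(expr, sub, tissue=tissue)
            tables[tissue] = table
            io.write_corr_table(table, out_dir / f"corr_{tissue}.tsv")
        stages[stage] = {"tissues": list(tables), "alpha": config.alpha}
    except Exception as err:  # noqa: BLE001 - stage boundary
        _fail_stage(out_dir, stage, err)

    stage = "concordance"
    try:
        pan = pan_arterial_set(tables, alpha=config.alpha)
        io.write_gene_set(pan["gene_id"], out_dir / "pan_arterial_set.txt",
                          {"alpha": config.alpha})
        primary = config.primary_tissues or tuple(list(tables)[:2])
        secondary = config.secondary_tissue or list(tables)[2]
        ext = extended_set(tables, primary, secondary, alpha=config.alpha,
                           sum_r_cut=config.sum_r_cut, sec_r_cut=config.sec_r_cut)
        io.write_gene_set(ext["gene_id"], out_dir / "extended_set.txt",
                          {"alpha": config.alpha, "sum_r_cut": config.sum_r_cut,
                           "sec_r_cut": config.sec_r_cut})
        stages[stage] = {"n_pan": len(pan), "n_extended": len(ext),
                         "primary": list(primary), "secondary": secondary}
    except Exception as err:  # noqa: BLE001
        _fail_stage(out_dir, stage, err)

    if config.panels:
        stage = "panel_deviation"
        try:
            inputs.append(config.panels)
            rows = []
            for panel in io.read_panels(config.panels):
                for tissue, table in tables.items():
                    res = panel_deviation_test(panel, table)
                    rows.append({"tissue": tissue, "panel": res.panel,
                                 "n_mapped": res.n_mapped,
                                 "panel_median_r": res.panel_median_r,
                                 "genome_median_r": res.genome_median_r,
                                 "direction": res.direction, "p": res.p_value})
            import pandas as pd

            pd.DataFrame(rows).to_csv(out_dir / "panel_deviation.tsv",
                                      sep="\t", index=False)
            stages[stage] = {"n_tests": len(rows)}
        except Exception as err:  # noqa: BLE001
            _fail_stage(out_dir, stage, err)

    return build_manifest(config, inputs, stages)


def _run_proteome_de(config: Config, out_dir: Path) -> dict:
    inputs = [config.matrix] + ([config.groups] if config.groups else [])
    stages: dict = {}
    m = io.read_proteome(config.matrix, scale=config.scale,
                         groups_path=config.groups or None)

    stage = "preprocess"
    try:
        if m.scale == "raw":
            m = log2_transform(m)
        m = filter_valid(m, min_valid=config.min_valid)
        stages[stage] = {"min_valid": config.min_valid,
                         "n_proteins": int(m.values.shape[0])}
    except Exception as err:  # noqa: BLE001
        _fail_stage(out_dir, stage, err)

    stage = "permutation_fdr"
    try:
        de = ttest_permutation_fdr(m, n_perm=config.n_perm, fdr=config.fdr,
                                   s0=config.s0, seed=config.seed)
        io.write_de_result(de, out_dir / "de_result.tsv")
        stages[stage] = {"n_perm": de.n_perm_used, "fdr": config.fdr,
                         "s0": config.s0, "seed": config.seed,
                         "n_significant": int(de.table["significant"].sum()),
                         "d_threshold": de.d_threshold}
    except Exception as err:  # noqa: BLE001
        _fail_stage(out_dir, stage, err)

    stage = "impute_pca_cluster"
    try:
        imputed = impute_downshift(m, width=config.impute_width,
                                   downshift=config.impute_downshift,
                                   seed=config.seed)
        pca = pca_scores(imputed, n_components=config.n_components)
        pca.scores.to_csv(out_dir / "pca_scores.tsv", sep="\t",
                          index_label="sample_id")
        z = zscore_rows(imputed)
        clust = hcluster(z, kmeans_pre=config.kmeans_pre or None,
                         seed=config.seed)
        (out_dir / "row_dendrogram.nwk").write_text(clust.row_newick + "\n")
        (out_dir / "col_dendrogram.nwk").write_text(clust.col_newick + "\n")
        stages[stage] = {
            "width": config.impute_width, "downshift": config.impute_downshift,
            "seed": config.seed,
            "explained_variance": [float(v)
                                   for v in pca.explained_variance_ratio],
            "col_order": [str(c) for c in clust.col_order]}
    except Exception as err:  # noqa: BLE001
        _fail_stage(out_dir, stage, err)

    return build_manifest(config, inputs, stages)
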