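"""Regulon-attrition statistics, confounder-adjusted regression, and qPCR
fold-change calculation.

A *regulon* is a panel of genes under a common transcriptional regulator
(e.g. the smooth-muscle genes controlled by SRF/myocardin). Coordinated
age-related decline of a regulon shows up as a negative deviation of the
panel's age-correlation R-values from the genome-wide median R, tested
with a one-sample Wilcoxon signed-rank test per tissue.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import PanelMappingError, ValidationError
from .stats_core import TestResult, ols_fit, wilcoxon_one_sample

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GenePanel:
    """A named, non-empty panel of unique gene symbols."""

    name: str
    symbols: tuple

    def __post_init__(self):
        if not self.symbols:
            raise ValidationError(f"panel {self.name!r} is empty")
        upper = [s.upper() for s in self.symbols]
        if len(set(upper)) != len(upper):
            raise ValidationError(f"panel {self.name!r} has duplicate symbols")

    def map_to(self, universe) -> tuple[list, list]:
        """Split symbols into (mapped, unmapped) against ``universe``.

        Matching is exact but case-insensitive. Raises
        :class:`PanelMappingError` when fewer than half the symbols map.
        """
        lookup = {str(u).upper(): u for u in universe}
        mapped, unmapped = [], []
        for s in self.symbols:
            key = str(s).upper()
            (mapped if key in lookup else unmapped).append(
                lookup.get(key, s))
        if len(mapped) < 0.5 * len(self.symbols):
            raise PanelMappingError(self.name, unmapped)
        return mapped, unmapped


@dataclass(frozen=True)
class PanelDeviationResult:
    tissue: str
    panel: str
    n_mapped: int
    panel_median_r: float
    genome_median_r: float
    direction: int  # sign of (panel median - genome median)
    p_value: float
    test: TestResult


def panel_deviation_test(panel: GenePanel, table: pd.DataFrame,
                         min_mapped: int = 5,
                         mode: str = "auto") -> PanelDeviationResult:
    """Test whether a panel's R-values deviate from the genome median R.

    ``table`` is a correlation table (one tissue). The null location mu0
    is the median R over all non-degenerate genes in that tissue (in a
    null screen this is close to 0); the panel's R-values are compared to
    it with a two-sided one-sample Wilcoxon signed-rank test. Panel genes
    absent from the table, or degenerate there, are excluded and logged.
    """
    sub = table.loc[~table["degenerate"]]
    genome_median = float(np.median(sub["R"].to_numpy()))
    mapped, unmapped = panel.map_to(sub["gene_id"])
    if unmapped:
        logger.info("panel %r: %d symbols not in the non-degenerate universe: %s",
                    panel.name, len(unmapped), unmapped[:5])
    if len(mapped) < min_mapped:
        raise ValidationError(
            f"panel {panel.name!r}: only {len(mapped)} genes map "
            f"(need >= {min_mapped}); unmapped: {unmapped[:10]}")
    r = sub.set_index("gene_id").loc[mapped, "R"].to_numpy(dtype=float)
    test = wilcoxon_one_sample(r, mu0=genome_median, mode=mode)
    panel_median = float(np.median(r))
    return PanelDeviationResult(
        tissue=str(table.attrs.get("tissue", "")),
        panel=panel.name,
        n_mapped=len(mapped),
        panel_median_r=panel_median,
        genome_median_r=genome_median,
        direction=int(np.sign(panel_median - genome_median)),
        p_value=test.p_value,
        test=test,
    )


def covariate_model(target: str, covariate_genes, expr: pd.DataFrame,
                    meta: pd.DataFrame):
    """OLS of a target gene's TPM on age, sex, and covariate gene TPMs.

    Models how much of the target's variance is explained by age together
    with potential confounders (sex, plus marker genes such as a
    macrophage marker or an upstream regulator). Sex stays coded 1/2 for
    coefficient comparability. Returns :class:`vascage.stats_core.OLSResult`.
    """
    for g in [target, *covariate_genes]:
        if g not in expr.index:
            raise ValidationError(f"gene {g!r} not in the expression matrix")
    m = meta.set_index("sample_id").loc[list(expr.columns)]
    y = expr.loc[target].to_numpy(dtype=float)
    cols = [m["age"].to_numpy(dtype=float), m["sex"].to_numpy(dtype=float)]
    names = ["age", "sex"]
    for g in covariate_genes:
        cols.append(expr.loc[g].to_numpy(dtype=float))
        names.append(str(g))
    X = np.column_stack(cols)
    return ols_fit(y, X, names=names)


def delta_delta_ct(ct: pd.DataFrame, reference: str,
                   control_samples) -> pd.DataFrame:
    """Relative qPCR quantification by the 2^-ddCt method.

    ``ct`` is a sample x gene table of Ct cycle values including the
    ``reference`` gene column; ``control_samples`` names the rows of the
    control group. Per sample, dCt = Ct_gene - Ct_reference; ddCt
    subtracts the control-group mean dCt; fold = 2^-ddCt, so the control
    group has geometric-mean fold 1 by construction. Samples missing the
    reference Ct are excluded with a logged flag.

    Returns a long DataFrame (sample, gene, dct, ddct, fold, log2_fold);
    downstream statistics should use ``log2_fold``.
    """
    if reference not in ct.columns:
        raise ValidationError(f"reference gene {reference!r} not in Ct table")
    vals = ct.to_numpy(dtype=float)
    if np.nanmin(vals) <= 0 or np.nanmax(vals) >= 45:
        raise ValidationError("Ct values must lie in the open interval (0, 45)")
    control_samples = list(control_samples)
    missing_ctrl = set(control_samples) - set(ct.index)
    if missing_ctrl or not control_samples:
        raise ValidationError(f"control samples not in table: {sorted(missing_ctrl)}")

    ref_ct = ct[reference]
    usable = ref_ct.notna()
    dropped = ct.index[~usable].tolist()
    if dropped:
        logger.warning("delta_delta_ct: samples missing reference Ct excluded: %s",
                       dropped)
    ct = ct.loc[usable]
    genes = [g for g in ct.columns if g != reference]
    dct = ct[genes].sub(ct[reference], axis=0)
    ctrl_idx = [s for s in control_samples if s in ct.index]
    if not ctrl_idx:
        raise ValidationError("every control sample lacks a reference Ct")
    ddct = dct.sub(dct.loc[ctrl_idx].mean(axis=0), axis=1)
    fold = np.power(2.0, -ddct)
    out = (ddct.stack().rename("ddct").reset_index())
    out.columns = ["sample", "gene", "ddct"]
    out["dct"] = dct.stack().to_numpy()
    out["fold"] = fold.stack().to_numpy()
    out["log2_fold"] = -out["ddct"]
    out["is_control"] = out["sample"].isin(ctrl_idx)
    return out[["sample", "gene", "dct", "ddct", "fold", "log2_fold", "is_control"]]
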