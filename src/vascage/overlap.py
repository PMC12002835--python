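"""Set- and panel-level comparisons across differential-expression results.

Covers four recurring questions about a pair (or one) of DE contrasts:
which proteins move significantly *and in the same direction* in two
contrasts; whether a regulon panel's fold-changes are shifted as a group;
how many annotated pathway regulators change in the direction expected to
activate the pathway; and which reduced proteins intersect an
independently induced transcript set, net of known targets.

"Significant" always means the permutation-FDR flag carried by the
DEResult table — never a raw p-value cutoff — so every overlap inherits
the FDR semantics of the upstream test. Symbol matching is exact but
case-insensitive; supplying harmonized symbols is the caller's job.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .regulon import GenePanel
from .stats_core import TestResult, wilcoxon_one_sample

logger = logging.getLogger(__name__)


def _norm(ids) -> pd.Index:
    return pd.Index([str(i).upper() for i in ids])


def _de_frame(de) -> pd.DataFrame:
    table = de.table if hasattr(de, "table") else de
    need = {"protein_id", "log2fc", "significant"}
    if not need.issubset(table.columns):
        raise ValidationError(f"DE table lacks columns {sorted(need - set(table.columns))}")
    out = table.copy()
    out["_key"] = _norm(out["protein_id"])
    return out.set_index("_key")


@dataclass
class OverlapReport:
    n_universe: int
    n_sig_a: int
    n_sig_b: int
    concordant: pd.DataFrame  # protein_id, log2fc_a, log2fc_b, direction
    discordant: pd.DataFrame

    @property
    def n_concordant(self) -> int:
        return len(self.concordant)

    @property
    def n_discordant(self) -> int:
        return len(self.discordant)


def directional_overlap(a, b) -> OverlapReport:
    """Proteins significant in both contrasts, split by sign agreement.

    Operates on the intersection of the two protein universes (size
    logged). Symmetric in its arguments up to column naming.
    """
    ta, tb = _de_frame(a), _de_frame(b)
    shared = ta.index.intersection(tb.index)
    if shared.empty:
        raise ValidationError("the two DE results share no proteins")
    if len(shared) < max(len(ta), len(tb)):
        logger.info("directional_overlap: universes differ; using %d shared "
                    "proteins", len(shared))
    ta, tb = ta.loc[shared], tb.loc[shared]
    both = ta["significant"].to_numpy() & tb["significant"].to_numpy()
    fa = ta["log2fc"].to_numpy(dtype=float)
    fb = tb["log2fc"].to_numpy(dtype=float)
    same = np.sign(fa) == np.sign(fb)

    def build(mask):
        df = pd.DataFrame({
            "protein_id": ta.loc[mask, "protein_id"].to_numpy(),
            "log2fc_a": fa[mask],
            "log2fc_b": fb[mask],
        })
        df["direction"] = np.where(df["log2fc_a"] > 0, "up", "down")
        return df.sort_values("protein_id", ignore_index=True)

    return OverlapReport(
        n_universe=len(shared),
        n_sig_a=int(ta["significant"].sum()),
        n_sig_b=int(tb["significant"].sum()),
        concordant=build(both & same),
        discordant=build(both & ~same),
    )


def panel_fc_test(panel: GenePanel, de, min_mapped: int = 5):
    """One-sample Wilcoxon of a panel's log2 fold-changes against zero.

    Returns ``(TestResult, summary DataFrame)``; the summary lists each
    mapped member with its log2FC and significance flag, and the result's
    ``extra['median_log2fc']`` holds the panel median.
    """
    t = _de_frame(de)
    t = t.loc[t["tested"]] if "tested" in t.columns else t
    mapped, unmapped = panel.map_to(t["protein_id"])
    keys = _norm(mapped)
    if len(keys) < min_mapped:
        raise ValidationError(
            f"panel {panel.name!r}: only {len(keys)} proteins have a "
            f"fold-change (need >= {min_mapped}); unmapped: {unmapped[:10]}")
    sub = t.loc[keys]
    fc = sub["log2fc"].to_numpy(dtype=float)
    test = wilcoxon_one_sample(fc, mu0=0.0)
    test = TestResult(test.statistic, test.p_value, test.method, test.df_or_n,
                      test.degenerate, test.p_floored,
                      {**test.extra, "median_log2fc": float(np.median(fc)),
                       "panel": panel.name, "n_mapped": len(keys)})
    summary = pd.DataFrame({
        "protein_id": sub["protein_id"].to_numpy(),
        "log2fc": fc,
        "significant": sub["significant"].to_numpy(),
    }).sort_values("protein_id", ignore_index=True)
    return test, summary


def regulator_consistency(de, annotations: pd.DataFrame):
    """Count DE pathway regulators changing in the activation-consistent way.

    ``annotations`` has columns ``protein_id`` and ``role`` in
    {'activator', 'inhibitor'}. A change is activation-consistent when an
    activator goes up or an inhibitor goes down. Returns
    ``(n_regulators_de, n_activation_consistent, member table)``.
    """
    if annotations.empty:
        raise ValidationError("annotations are empty")
    ann = annotations.copy()
    ann["_key"] = _norm(ann["protein_id"])
    bad_roles = set(ann["role"]) - {"activator", "inhibitor"}
    if bad_roles:
        raise ValidationError(f"unknown roles: {sorted(bad_roles)}")
    conflicts = (ann.groupby("_key")["role"].nunique() > 1)
    if conflicts.any():
        raise ValidationError(
            f"conflicting roles for: {sorted(conflicts.index[conflicts])}")
    ann = ann.drop_duplicates("_key").set_index("_key")

    t = _de_frame(de)
    hit = t.index.intersection(ann.index)
    sig = t.loc[hit].loc[t.loc[hit, "significant"]]
    roles = ann.loc[sig.index, "role"]
    fc = sig["log2fc"].to_numpy(dtype=float)
    consistent = ((roles == "activator").to_numpy() & (fc > 0)) | \
                 ((roles == "inhibitor").to_numpy() & (fc < 0))
    members = pd.DataFrame({
        "protein_id": sig["protein_id"].to_numpy(),
        "role": roles.to_numpy(),
        "log2fc": fc,
        "activation_consistent": consistent,
    }).sort_values("protein_id", ignore_index=True)
    return len(members), int(consistent.sum()), members


def intersect_novel_targets(reduced_proteins, induced_transcripts,
                            known_targets) -> list:
    """(reduced ∩ induced) minus known targets, sorted, case-insensitive.

    The canonical use: proteins that fall on regulator knockout,
    intersected with transcripts induced by the regulator in an
    independent overexpression experiment, minus targets already on the
    curated panel — candidate novel direct targets.
    """
    norm = lambda ids: {str(i).upper(): str(i) for i in ids}
    reduced, induced, known = norm(reduced_proteins), norm(induced_transcripts), \
        set(norm(known_targets))
    hits = (set(reduced) & set(induced)) - known
    return sorted(reduced[h] for h in hits)
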