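"""Transcriptome-wide aging screen across arterial tissues.

The screen correlates each gene's TPM against donor age (Pearson), adjusts
p-values per tissue with Benjamini-Hochberg, and derives two concordance
gene sets across three tissues:

* the *pan-arterial* set — significant (q < alpha) with a consistent sign
  of R in all three tissues;
* the *extended* set — significant in the two well-powered tissues, with a
  large and sign-consistent sum of R across all three, and a directionally
  consistent R above a floor in the third (under-powered) tissue.

Genes are ranked by an effect-size proxy, mean TPM x OLS slope, which
favours abundantly expressed genes with large absolute change per year.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .stats_core import TestResult, bh_adjust, kruskal_wallis, _floor_p

logger = logging.getLogger(__name__)

CORR_COLUMNS = ["gene_id", "n", "R", "p", "q", "slope", "mean_tpm",
                "effect_proxy", "degenerate"]

#: Closed age-bin intervals, inclusive on both ends after flooring ages.
DEFAULT_AGE_BINS = ((20, 39), (40, 59), (60, 79))


def _align_meta(expr: pd.DataFrame, meta: pd.DataFrame) -> pd.DataFrame:
    missing = set(expr.columns) - set(meta["sample_id"])
    if missing:
        raise ValidationError(
            f"{len(missing)} expression samples absent from metadata, "
            f"e.g. {sorted(missing)[:5]}")
    m = meta.set_index("sample_id").loc[list(expr.columns)]
    return m


def correlate_age(expr: pd.DataFrame, meta: pd.DataFrame,
                  tissue: str | None = None) -> pd.DataFrame:
    """Per-gene Pearson correlation of TPM against donor age.

    ``expr`` is a gene x sample TPM DataFrame; ``meta`` must carry
    ``sample_id`` and ``age`` columns covering every expression sample.
    Returns a correlation table with columns ``CORR_COLUMNS`` and
    ``.attrs['tissue']`` set. Genes with zero variance (including
    all-silent genes) are flagged degenerate and excluded from the BH
    denominator; their q is NaN.

    The per-gene computation is vectorised but agrees exactly with
    :func:`vascage.stats_core.pearson_age_corr` applied row by row.
    """
    if expr.shape[1] < 3:
        raise ValidationError("need at least 3 samples")
    if expr.index.duplicated().any():
        dups = expr.index[expr.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate gene ids: {dups[:5]}")
    m = _align_meta(expr, meta)
    x = m["age"].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValidationError("age is constant across samples")

    Y = expr.to_numpy(dtype=float)
    n = x.size
    xc = x - x.mean()
    ssx = float(xc @ xc)
    mean_y = Y.mean(axis=1)
    Yc = Y - mean_y[:, None]
    ssy = (Yc * Yc).sum(axis=1)
    sxy = Yc @ xc
    degenerate = ssy == 0.0

    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.clip(sxy / np.sqrt(ssx * ssy), -1.0, 1.0)
        slope = sxy / ssx
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r * r, 0.0))
    p = 2.0 * sps.t.sf(np.abs(t), n - 2)
    p[np.abs(r) == 1.0] = 0.0
    p = np.array([_floor_p(v)[0] for v in p])
    r[degenerate] = np.nan
    p[degenerate] = np.nan
    slope[degenerate] = 0.0

    q = np.full(len(expr), np.nan)
    ok = ~degenerate
    if ok.any():
        q[ok] = bh_adjust(p[ok])
    n_deg = int(degenerate.sum())
    if n_deg:
        logger.info("correlate_age: %d degenerate (constant) genes excluded "
                    "from BH adjustment", n_deg)

    table = pd.DataFrame({
        "gene_id": expr.index.to_numpy(),
        "n": n,
        "R": r,
        "p": p,
        "q": q,
        "slope": slope,
        "mean_tpm": mean_y,
        "effect_proxy": mean_y * slope,
        "degenerate": degenerate,
    })
    table.attrs["tissue"] = tissue if tissue is not None else ""
    return table


def _check_universes(tables: dict[str, pd.DataFrame]) -> list[str]:
    its = iter(tables.items())
    first_name, first = next(its)
    universe = list(first["gene_id"])
    ref = set(universe)
    for name, t in its:
        other = set(t["gene_id"])
        if other != ref:
            diff = sorted(ref.symmetric_difference(other))
            raise ValidationError(
                f"gene universes differ between {first_name!r} and {name!r}; "
                f"difference: {diff[:10]} ({len(diff)} genes)")
    return universe


def pan_arterial_set(tables: dict[str, pd.DataFrame],
                     alpha: float = 0.05) -> pd.DataFrame:
    """Genes with q < alpha and a consistent sign of R in all three tissues.

    Returns a DataFrame with ``gene_id`` and ``mean_R`` (mean of R across
    tissues), sorted by gene_id.
    """
    if len(tables) != 3:
        raise ValidationError("expected exactly 3 correlation tables")
    genes = _check_universes(tables)
    R = np.column_stack([t.set_index("gene_id").loc[genes, "R"].to_numpy()
                         for t in tables.values()])
    Q = np.column_stack([t.set_index("gene_id").loc[genes, "q"].to_numpy()
                         for t in tables.values()])
    with np.errstate(invalid="ignore"):
        sig = np.all(Q < alpha, axis=1)
        consistent = (np.all(R > 0, axis=1) | np.all(R < 0, axis=1))
    keep = sig & consistent & ~np.isnan(R).any(axis=1)
    out = pd.DataFrame({"gene_id": np.asarray(genes)[keep],
                        "mean_R": R[keep].mean(axis=1)})
    return out.sort_values("gene_id", ignore_index=True)


def extended_set(tables: dict[str, pd.DataFrame], primary: tuple[str, str],
                 secondary: str, alpha: float = 0.05, sum_r_cut: float = 0.5,
                 sec_r_cut: float = 0.1) -> pd.DataFrame:
    """Concordant genes rescued from an under-powered third tissue.

    Criteria: q < alpha in both ``primary`` tissues with agreeing R signs;
    |sum of R across all three tissues| > ``sum_r_cut`` with the sum's sign
    matching the primary signs; and R in ``secondary`` directionally
    consistent with |R| > ``sec_r_cut``. The absolute-value form of the
    sum cutoff covers decreasing and increasing genes symmetrically.
    """
    for t in (*primary, secondary):
        if t not in tables:
            raise ValidationError(f"tissue {t!r} not among tables {list(tables)}")
    genes = _check_universes(tables)
    get = lambda t, col: tables[t].set_index("gene_id").loc[genes, col].to_numpy()
    r1, r2, r3 = get(primary[0], "R"), get(primary[1], "R"), get(secondary, "R")
    q1, q2 = get(primary[0], "q"), get(primary[1], "q")
    s = r1 + r2 + r3
    with np.errstate(invalid="ignore"):
        sign_ok = np.sign(r1) == np.sign(r2)
        keep = ((q1 < alpha) & (q2 < alpha) & sign_ok
                & (np.abs(s) > sum_r_cut) & (np.sign(s) == np.sign(r1))
                & (np.sign(r3) == np.sign(r1)) & (np.abs(r3) > sec_r_cut))
    keep &= ~(np.isnan(r1) | np.isnan(r2) | np.isnan(r3))
    out = pd.DataFrame({"gene_id": np.asarray(genes)[keep], "sum_R": s[keep]})
    return out.sort_values("gene_id", ignore_index=True)


def effect_proxy_rank(table: pd.DataFrame, k: int,
                      direction: str = "negative") -> pd.DataFrame:
    """Top-``k`` genes by the effect proxy (mean TPM x slope).

    ``direction='negative'`` sorts ascending (most negative proxies first),
    ``'positive'`` descending. Ties break lexicographically on gene_id.
    """
    if direction not in ("negative", "positive"):
        raise ValidationError("direction must be 'negative' or 'positive'")
    sub = table.loc[~table["degenerate"]].copy()
    if sub.empty:
        raise ValidationError("no non-degenerate genes to rank")
    if k > len(sub):
        logger.warning("effect_proxy_rank: k=%d > %d available genes; "
                       "returning all", k, len(sub))
        k = len(sub)
    asc = direction == "negative"
    sub = sub.sort_values(["effect_proxy", "gene_id"],
                          ascending=[asc, True], kind="mergesort")
    return sub.head(k).reset_index(drop=True)


def age_bin_summary(values, meta: pd.DataFrame,
                    bins=DEFAULT_AGE_BINS) -> dict:
    """Per-age-bin medians of one gene's TPM plus a Kruskal-Wallis test.

    Ages are floored to integers before assignment to the closed bins
    (public cohort ages are integer years or decade brackets); samples
    outside every bin are dropped with a logged count. An empty bin yields
    a degenerate result without a test.
    """
    v = np.asarray(values, dtype=float)
    ages = np.floor(meta["age"].to_numpy(dtype=float)).astype(int)
    if v.size != ages.size:
        raise ValidationError("values and metadata lengths differ")
    groups, rows = [], []
    n_dropped = v.size
    for lo, hi in bins:
        mask = (ages >= lo) & (ages <= hi)
        g = v[mask]
        n_dropped -= g.size
        groups.append(g)
        rows.append({"bin": f"{lo}-{hi}", "n": int(g.size),
                     "median": float(np.median(g)) if g.size else np.nan})
    if n_dropped:
        logger.info("age_bin_summary: %d samples outside all bins dropped",
                    n_dropped)
    summary = pd.DataFrame(rows)
    if any(g.size == 0 for g in groups):
        test = TestResult(np.nan, np.nan, "kruskal-wallis", len(bins) - 1,
                          degenerate=True)
    else:
        test = kruskal_wallis(groups)
    return {"summary": summary, "test": test, "n_dropped": n_dropped}
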