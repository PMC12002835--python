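"""Label-free proteomics post-processing.

Mirrors the standard Perseus-style workflow on a wide protein-quantity
matrix: log2 transform, valid-value filtering, a two-sample Student t test
with a permutation-based FDR over balanced group-label reassignments,
downshifted-Gaussian imputation (for PCA only), row z-scoring, and
average-linkage hierarchical clustering.

The permutation FDR works on the symmetric statistic threshold |d| >= c,
where d = (mean1 - mean2) / (pooled SE + s0). For each candidate c the
estimated FDR is the mean over permutations of the number of permuted
|d*| >= c, divided by the observed count at the same threshold. The
significant set is the largest threshold set whose estimated FDR stays at
or below the target. With s0 = 0 the statistic is the plain Student t.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy

from .errors import ValidationError

logger = logging.getLogger(__name__)

DE_COLUMNS = ["protein_id", "log2fc", "t", "p", "significant",
              "n_valid_g1", "n_valid_g2", "tested"]


@dataclass
class ProteomicsMatrix:
    """Protein x sample quantities with explicit missingness.

    ``values``: DataFrame (proteins x samples) with NaN for missing cells.
    ``groups``: Series mapping sample id to group label.
    ``scale``: 'raw' (all present values > 0) or 'log2'.
    """

    values: pd.DataFrame
    groups: pd.Series
    scale: str

    def __post_init__(self):
        if self.scale not in ("raw", "log2"):
            raise ValidationError(f"scale must be 'raw' or 'log2', got {self.scale!r}")
        if self.values.index.duplicated().any():
            raise ValidationError("duplicate protein ids")
        missing = set(self.values.columns) - set(self.groups.index)
        if missing:
            raise ValidationError(f"samples without group assignment: {sorted(missing)}")
        self.groups = self.groups.loc[list(self.values.columns)]
        if self.scale == "raw":
            present = self.values.to_numpy()
            if np.nanmin(present) <= 0:
                raise ValidationError("raw-scale matrix contains non-positive values")

    @property
    def group_labels(self) -> list:
        seen = []
        for g in self.groups:
            if g not in seen:
                seen.append(g)
        return seen

    def copy_with(self, values: pd.DataFrame, scale: str | None = None
                  ) -> "ProteomicsMatrix":
        return ProteomicsMatrix(values=values, groups=self.groups.copy(),
                                scale=scale or self.scale)


@dataclass
class DEResult:
    """Differential-expression outcome of the permutation-FDR t test."""

    table: pd.DataFrame  # columns DE_COLUMNS
    d_threshold: float  # |d| cutoff defining the significant set (inf if none)
    fdr_target: float
    n_perm_used: int
    s0: float
    group1: str
    group2: str
    fdr_curve: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def significant(self) -> pd.DataFrame:
        return self.table.loc[self.table["significant"]]


def log2_transform(m: ProteomicsMatrix) -> ProteomicsMatrix:
    """log2 of every present value; missing cells stay missing."""
    if m.scale != "raw":
        raise ValidationError("matrix is already on log2 scale")
    vals = m.values.to_numpy(dtype=float)
    bad = np.argwhere(~np.isnan(vals) & (vals <= 0))
    if bad.size:
        i, j = bad[0]
        raise ValidationError(
            f"non-positive value at protein {m.values.index[i]!r}, "
            f"sample {m.values.columns[j]!r}")
    return m.copy_with(pd.DataFrame(np.log2(vals), index=m.values.index,
                                    columns=m.values.columns), scale="log2")


def filter_valid(m: ProteomicsMatrix, min_valid: int = 3) -> ProteomicsMatrix:
    """Keep proteins with >= ``min_valid`` present values in every group."""
    valid = m.values.notna()
    keep = pd.Series(True, index=m.values.index)
    for g in m.group_labels:
        cols = m.groups.index[m.groups == g]
        keep &= valid[cols].sum(axis=1) >= min_valid
    n_removed = int((~keep).sum())
    if n_removed:
        logger.info("filter_valid: removed %d of %d proteins (min %d valid "
                    "per group)", n_removed, len(keep), min_valid)
    return m.copy_with(m.values.loc[keep])


def _group_stats(X: np.ndarray, mask: np.ndarray):
    """Per-row mean/var/count over columns selected by boolean ``mask``.

    NaN-aware without materialising masked copies; ``mask`` may be a
    (n_assignments x n_samples) stack, giving stacked outputs.
    """
    V = ~np.isnan(X)
    Xz = np.where(V, X, 0.0)
    cnt = V.astype(float) @ mask.T  # proteins x assignments
    s1 = Xz @ mask.T
    s2 = (Xz * Xz) @ mask.T
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = (s2 - cnt * mean * mean) / (cnt - 1.0)
    return mean, var, cnt


def _perm_assignments(n_total: int, n1: int, n_perm: int, seed: int,
                      identity: tuple) -> list[tuple]:
    """Balanced label reassignments, identity excluded, w/o replacement."""
    total = math.comb(n_total, n1)
    if total - 1 <= n_perm or total <= 200_000:
        pool = [c for c in itertools.combinations(range(n_total), n1)
                if c != identity]
        if len(pool) <= n_perm:
            logger.info("ttest_permutation_fdr: only %d distinct non-identity "
                        "assignments exist; using all", len(pool))
            return pool
        rng = np.random.default_rng(seed)
        pick = rng.choice(len(pool), size=n_perm, replace=False)
        return [pool[i] for i in sorted(pick)]
    rng = np.random.default_rng(seed)
    seen = {identity}
    out = []
    while len(out) < n_perm:
        c = tuple(sorted(rng.choice(n_total, size=n1, replace=False)))
        if c not in seen:
            seen.add(c)
            out.append(c)
    return out


def _d_stat(mean1, mean2, var1, var2, n1, n2, s0):
    with np.errstate(invalid="ignore", divide="ignore"):
        df = n1 + n2 - 2.0
        sp2 = ((n1 - 1.0) * var1 + (n2 - 1.0) * var2) / df
        se = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
        d = (mean1 - mean2) / (se + s0)
    return d, se, df


def ttest_permutation_fdr(m: ProteomicsMatrix, n_perm: int = 250,
                          fdr: float = 0.05, s0: float = 0.0,
                          seed: int = 0) -> DEResult:
    """Two-sided Student t test with a permutation-estimated FDR.

    Group labels are reassigned ``n_perm`` times, sampled uniformly
    without replacement from the distinct balanced assignments (identity
    excluded). A protein is tested when both observed groups have >= 2
    valid values. The reported p comes from the Student t reference with
    the per-protein degrees of freedom; significance, however, is defined
    by the permutation FDR on |d| (d includes ``s0``), never by a raw-p
    cutoff.
    """
    labels = m.group_labels
    if len(labels) != 2:
        raise ValidationError(f"need exactly 2 groups, got {labels}")
    if m.scale != "log2":
        raise ValidationError("run log2_transform first (matrix must be log2 scale)")
    g1, g2 = labels
    X = m.values.to_numpy(dtype=float)
    is_g1 = (m.groups == g1).to_numpy()
    n_total = X.shape[1]
    n1 = int(is_g1.sum())
    identity = tuple(np.flatnonzero(is_g1))

    def stats_for(assignments: np.ndarray):
        mask1 = np.zeros((len(assignments), n_total))
        for i, idx in enumerate(assignments):
            mask1[i, list(idx)] = 1.0
        mask2 = 1.0 - mask1
        mean1, var1, c1 = _group_stats(X, mask1)
        mean2, var2, c2 = _group_stats(X, mask2)
        d, se, df = _d_stat(mean1, mean2, var1, var2, c1, c2, s0)
        ok = (c1 >= 2) & (c2 >= 2)
        return d, se, df, ok, mean1, mean2, c1, c2

    d_all, _, df_all, tested, mean1, mean2, c1, c2 = stats_for([identity])
    d_obs, df_obs, tested = d_all[:, 0], df_all[:, 0], tested[:, 0]
    mean1, mean2, c1, c2 = mean1[:, 0], mean2[:, 0], c1[:, 0], c2[:, 0]

    perms = _perm_assignments(n_total, n1, n_perm, seed, identity)
    d_perm = stats_for(perms)[0]
    n_perm_used = len(perms)

    abs_obs = np.abs(d_obs[tested])
    flat_perm = np.abs(d_perm[tested].ravel())
    flat_perm = np.sort(flat_perm[np.isfinite(flat_perm)])

    # FDR(c) at candidate thresholds c = each observed |d| (ascending);
    # ties counted exactly via searchsorted.
    cand = np.sort(abs_obs)
    n_tested = cand.size
    obs_count = n_tested - np.searchsorted(cand, cand, side="left")
    perm_ge = flat_perm.size - np.searchsorted(flat_perm, cand, side="left")
    perm_mean = perm_ge / max(n_perm_used, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        fdr_hat = np.minimum(1.0, perm_mean / obs_count)
    # q(v) = min over thresholds c <= v of FDR(c); non-increasing in v, so the
    # significant set {q <= fdr} is the largest threshold set meeting the target.
    q_asc = np.minimum.accumulate(fdr_hat)
    sig_sorted = q_asc <= fdr
    if sig_sorted.any():
        d_threshold = float(cand[np.flatnonzero(sig_sorted)[0]])
        sig_tested = abs_obs >= d_threshold
    else:
        d_threshold = float("inf")
        sig_tested = np.zeros(n_tested, dtype=bool)

    # per-protein two-sided p from the Student t reference (plain t, s0 = 0)
    if s0 == 0.0:
        t_stat = d_obs
    else:
        id_mask = np.zeros((1, n_total))
        id_mask[0, list(identity)] = 1.0
        _, var1o, _ = _group_stats(X, id_mask)
        _, var2o, _ = _group_stats(X, 1.0 - id_mask)
        t_stat, _, _ = _d_stat(mean1, mean2, var1o[:, 0], var2o[:, 0],
                               c1, c2, 0.0)
    with np.errstate(invalid="ignore"):
        p = 2.0 * sps.t.sf(np.abs(t_stat), np.maximum(df_obs, 1.0))
    p = np.where(tested, np.maximum(p, np.finfo(float).tiny), np.nan)

    significant = np.zeros(len(X), dtype=bool)
    significant[np.flatnonzero(tested)] = sig_tested
    n_untested = int((~tested).sum())
    if n_untested:
        logger.info("ttest_permutation_fdr: %d proteins untested (<2 valid "
                    "values in a group)", n_untested)

    table = pd.DataFrame({
        "protein_id": m.values.index.to_numpy(),
        "log2fc": mean1 - mean2,
        "t": np.where(tested, t_stat, np.nan),
        "p": p,
        "significant": significant,
        "n_valid_g1": c1.astype(int),
        "n_valid_g2": c2.astype(int),
        "tested": tested,
    })
    curve = pd.DataFrame({"threshold": cand, "obs_count": obs_count,
                          "perm_mean_count": perm_mean, "fdr_hat": fdr_hat,
                          "fdr_monotone": q_asc})
    return DEResult(table=table, d_threshold=d_threshold, fdr_target=fdr,
                    n_perm_used=n_perm_used, s0=s0, group1=g1, group2=g2,
                    fdr_curve=curve)


def impute_downshift(m: ProteomicsMatrix, width: float = 0.4,
                     downshift: float = 1.8, seed: int = 0) -> ProteomicsMatrix:
    """Downshifted-Gaussian imputation of missing cells, per sample column.

    For a column with observed mean mu and sample SD sigma, each missing
    cell is drawn from Normal(mu - downshift*sigma, (width*sigma)^2),
    modelling values missing because the protein sits below the detection
    range. Observed cells are never altered. Intended for PCA input only;
    the DE test runs on observed values.
    """
    if m.scale != "log2":
        raise ValidationError("impute on log2 scale")
    vals = m.values.to_numpy(dtype=float).copy()
    rng = np.random.default_rng(seed)
    for j, col in enumerate(m.values.columns):
        obs = vals[:, j][~np.isnan(vals[:, j])]
        n_miss = int(np.isnan(vals[:, j]).sum())
        if obs.size < 2 and n_miss > 0:
            raise ValidationError(
                f"column {col!r} has fewer than 2 observed values")
        if n_miss == 0:
            continue
        mu, sigma = obs.mean(), obs.std(ddof=1)
        draws = rng.normal(mu - downshift * sigma, width * sigma, n_miss)
        vals[np.isnan(vals[:, j]), j] = draws
    return m.copy_with(pd.DataFrame(vals, index=m.values.index,
                                    columns=m.values.columns))


def zscore_rows(m: ProteomicsMatrix) -> ProteomicsMatrix:
    """Centre and scale each protein row to mean 0, sample SD 1."""
    vals = m.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("matrix has missing values; impute first")
    sd = vals.std(axis=1, ddof=1)
    const = sd == 0
    if const.any():
        raise ValidationError(
            f"constant rows cannot be z-scored: "
            f"{list(m.values.index[const][:10])}")
    z = (vals - vals.mean(axis=1, keepdims=True)) / sd[:, None]
    return m.copy_with(pd.DataFrame(z, index=m.values.index,
                                    columns=m.values.columns))


@dataclass
class ClusterResult:
    row_linkage: np.ndarray
    col_linkage: np.ndarray
    row_order: list
    col_order: list
    row_newick: str
    col_newick: str
    row_cluster_of: pd.Series | None = None  # set when k-means preprocessing on


def _linkage_newick(Z: np.ndarray, labels: list) -> str:
    tree = hierarchy.to_tree(Z)

    def walk(node):
        if node.is_leaf():
            return str(labels[node.id]).replace(" ", "_")
        left, right = walk(node.get_left()), walk(node.get_right())
        dl = max(node.dist - node.get_left().dist, 0.0)
        dr = max(node.dist - node.get_right().dist, 0.0)
        return f"({left}:{dl:.6g},{right}:{dr:.6g})"

    return walk(tree) + ";"


def hcluster(m: ProteomicsMatrix, kmeans_pre: int | None = None,
             seed: int = 0) -> ClusterResult:
    """Average-linkage hierarchical clustering, Euclidean distance.

    Rows (proteins) and columns (samples) are clustered separately. With
    ``kmeans_pre=k``, rows are first reduced to k seeded k-means centroids
    and the row dendrogram is built on centroids, with member rows
    attached in centroid order — the standard shortcut for very tall
    matrices. Requires a complete (imputed or fully observed) matrix.
    """
    vals = m.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("matrix has missing values; impute first")
    if vals.shape[0] < 2:
        raise ValidationError("need at least 2 rows to cluster")

    col_Z = hierarchy.average(_condensed(vals.T))
    col_order = list(np.asarray(m.values.columns)[hierarchy.leaves_list(col_Z)])

    row_cluster_of = None
    if kmeans_pre:
        from sklearn.cluster import KMeans

        k = min(kmeans_pre, vals.shape[0])
        km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(vals)
        row_Z = hierarchy.average(_condensed(km.cluster_centers_))
        centroid_order = hierarchy.leaves_list(row_Z)
        row_order = []
        for c in centroid_order:
            members = np.flatnonzero(km.labels_ == c)
            row_order.extend(m.values.index[members])
        row_labels = [f"cluster_{c}" for c in range(k)]
        row_newick = _linkage_newick(row_Z, row_labels)
        row_cluster_of = pd.Series(km.labels_, index=m.values.index,
                                   name="kmeans_cluster")
    else:
        row_Z = hierarchy.average(_condensed(vals))
        row_order = list(np.asarray(m.values.index)[hierarchy.leaves_list(row_Z)])
        row_newick = _linkage_newick(row_Z, list(m.values.index))

    return ClusterResult(
        row_linkage=row_Z, col_linkage=col_Z,
        row_order=row_order, col_order=col_order,
        row_newick=row_newick,
        col_newick=_linkage_newick(col_Z, list(m.values.columns)),
        row_cluster_of=row_cluster_of,
    )


def _condensed(X: np.ndarray) -> np.ndarray:
    from scipy.spatial.distance import pdist

    return pdist(X, metric="euclidean")


@dataclass
class PCAResult:
    scores: pd.DataFrame  # samples x components
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame  # proteins x components


def pca_scores(m: ProteomicsMatrix, n_components: int = 2) -> PCAResult:
    """Sample scores from an SVD of the protein-centred matrix.

    Samples are the observations, proteins the features (each centred).
    Sign convention: per component, the loading of largest magnitude is
    made positive, so output is deterministic.
    """
    vals = m.values.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise ValidationError("matrix has missing values; impute first")
    n_samples = vals.shape[1]
    if n_components > min(vals.shape):
        raise ValidationError(
            f"n_components={n_components} exceeds min(matrix dims)={min(vals.shape)}")
    D = vals.T - vals.mean(axis=1)  # samples x proteins, protein-centred
    U, S, Vt = np.linalg.svd(D, full_matrices=False)
    for c in range(n_components):
        j = int(np.argmax(np.abs(Vt[c])))
        if Vt[c, j] < 0:
            Vt[c] *= -1.0
            U[:, c] *= -1.0
    scores = U[:, :n_components] * S[:n_components]
    evr = (S**2) / (S**2).sum()
    comp_names = [f"PC{i + 1}" for i in range(n_components)]
    return PCAResult(
        scores=pd.DataFrame(scores, index=m.values.columns, columns=comp_names),
        explained_variance_ratio=evr[:n_components],
        loadings=pd.DataFrame(Vt[:n_components].T, index=m.values.index,
                              columns=comp_names),
    )
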