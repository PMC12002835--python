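"""Seeded generators for ground-truth-labelled synthetic inputs.

Two generators cover the two analysis arms:

* :func:`gen_expression_cohort` emulates multi-artery bulk RNA-seq cohorts
  (gene x donor TPM matrices with donor age and sex) in which a configurable
  fraction of genes carries a linear age trend on the TPM scale, and
  designated "regulon" panels carry coordinated trends.
* :func:`gen_proteome` emulates a two-group label-free proteomics experiment
  (log-normal protein intensities, fixed log2 fold-changes on a subset, and
  intensity-dependent missing-not-at-random dropout).

Every generator takes an explicit seed; one global seed is expanded into
independent per-stream child seeds so adding a stream never perturbs the
others. Identical spec + seed gives identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ValidationError
from .proteomics import ProteomicsMatrix
from .regulon import GenePanel

#: Cohort sizes mirroring the three arterial tissues at reduced scale.
DEFAULT_TISSUE_SIZES = {"tibial_artery": 300, "aorta": 200, "coronary_artery": 120}


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a simulated multi-tissue expression cohort.

    ``slope_scale`` bounds the signed *relative* slope s of age-dependent
    genes: expected TPM = baseline * (1 + s*(age - mid)/halfspan), so
    s = 0.5 means a 50% change between the age midpoint and either end of
    the range. Magnitudes are drawn uniformly from [0.1, slope_scale].
    ``noise_cv`` is the coefficient of variation of the multiplicative
    log-normal noise. ``panel_spec`` lists (name, size, direction) for
    panels of coordinated-trend genes, direction in {-1, +1}.
    """

    seed: int
    n_genes: int = 2000
    n_samples_per_tissue: dict = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_SIZES))
    age_range: tuple[float, float] = (20.0, 79.0)
    frac_age_dependent: float = 0.1
    slope_scale: float = 0.5
    noise_cv: float = 0.5
    panel_spec: tuple = (("regulon_down", 20, -1),)
    baseline_log_mean: float = math.log(20.0)
    baseline_log_sd: float = 1.5
    age_style: str = "continuous"  # or "decade" (bracket midpoints)

    def __post_init__(self):
        if not (0.0 <= self.frac_age_dependent <= 1.0):
            raise ValidationError("frac_age_dependent must be in [0, 1]")
        if self.n_genes < 1 or any(n < 1 for n in self.n_samples_per_tissue.values()):
            raise ValidationError("counts must be >= 1")
        if self.age_range[0] >= self.age_range[1]:
            raise ValidationError("age_range min must be < max")
        if self.noise_cv < 0:
            raise ValidationError("noise_cv must be >= 0")
        if self.age_style not in ("continuous", "decade"):
            raise ValidationError("age_style must be 'continuous' or 'decade'")
        if self.seed is None:
            raise ValidationError("seed is required; there is no implicit randomness")


@dataclass(frozen=True)
class ProteomeSpec:
    """Parameters of a simulated two-group label-free proteome.

    Log2 intensities are Normal(baseline + group effect, ``base_sd``);
    per-protein baselines are Normal(``base_mean``, ``base_spread``) so the
    intensity-dependent dropout has a range to act on. A fraction
    ``frac_de`` of proteins receives a log2 fold-change of +/-``lfc_scale``
    in the second group. Each cell goes missing independently with
    probability sigmoid((dropout_midpoint - intensity) * dropout_steepness).
    """

    seed: int
    n_proteins: int = 2000
    groups: tuple = (("Ctrl", 6), ("KO", 6))
    frac_de: float = 0.1
    lfc_scale: float = 2.0
    base_mean: float = 25.0
    base_sd: float = 0.3
    base_spread: float = 2.0
    dropout_midpoint: float = 20.0
    dropout_steepness: float = 1.0
    scale: str = "log2"  # or "raw" to emit 2**intensity

    def __post_init__(self):
        if any(n < 2 for _, n in self.groups):
            raise ValidationError("every group needs at least 2 samples")
        if not (0.0 <= self.frac_de <= 1.0):
            raise ValidationError("frac_de must be in [0, 1]")
        if self.dropout_steepness < 0:
            raise ValidationError("dropout_steepness must be >= 0")
        if self.scale not in ("log2", "raw"):
            raise ValidationError("scale must be 'log2' or 'raw'")
        if self.seed is None:
            raise ValidationError("seed is required")


def _child_rngs(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(n)]


def gen_expression_cohort(spec: CohortSpec):
    """Simulate per-tissue TPM matrices with known age trends.

    Returns ``(matrices, metadata, truth)`` where ``matrices`` maps tissue
    label to a gene x sample DataFrame of TPM, ``metadata`` is a DataFrame
    with sample_id / age / sex / tissue, and ``truth`` records the injected
    relative slope and panel membership per gene.
    """
    rng_structure, rng_baseline, rng_slopes, rng_cohort = _child_rngs(spec.seed, 4)

    n_genes = spec.n_genes
    gene_ids = np.array([f"G{i:05d}" for i in range(n_genes)])
    baseline = np.exp(
        rng_baseline.normal(spec.baseline_log_mean, spec.baseline_log_sd, n_genes))

    # Panel genes first (coordinated trends), then free age-dependent genes.
    rel_slope = np.zeros(n_genes)
    panel_of = np.array([""] * n_genes, dtype=object)
    n_panel_total = sum(size for _, size, _ in spec.panel_spec)
    if n_panel_total > n_genes:
        raise ValidationError("panel genes exceed n_genes")
    perm = rng_structure.permutation(n_genes)
    cursor = 0
    for name, size, direction in spec.panel_spec:
        if direction not in (-1, 1):
            raise ValidationError(f"panel direction must be -1 or +1, got {direction}")
        idx = perm[cursor:cursor + size]
        cursor += size
        rel_slope[idx] = direction * rng_slopes.uniform(0.1, spec.slope_scale, size)
        panel_of[idx] = name
    n_trend = round(spec.frac_age_dependent * n_genes)
    n_free = max(0, n_trend - n_panel_total)
    idx_free = perm[cursor:cursor + n_free]
    signs = rng_slopes.choice([-1.0, 1.0], n_free)
    rel_slope[idx_free] = signs * rng_slopes.uniform(0.1, spec.slope_scale, n_free)

    age_lo, age_hi = spec.age_range
    age_mid = 0.5 * (age_lo + age_hi)
    halfspan = 0.5 * (age_hi - age_lo)

    # log-normal noise with unit mean and CV = noise_cv
    sigma = math.sqrt(math.log(1.0 + spec.noise_cv**2)) if spec.noise_cv > 0 else 0.0

    matrices = {}
    meta_rows = []
    tissue_rngs = rng_cohort.spawn(len(spec.n_samples_per_tissue))
    for (tissue, n_samples), tissue_ss in zip(
            spec.n_samples_per_tissue.items(), tissue_rngs):
        rng_age, rng_sex, rng_noise = [np.random.default_rng(s)
                                       for s in tissue_ss.spawn(3)]
        ages = rng_age.uniform(age_lo, age_hi, n_samples)
        if spec.age_style == "decade":
            ages = (np.floor(ages / 10.0) * 10.0) + 5.0
        sex = rng_sex.choice([1, 2], n_samples)
        sample_ids = [f"{tissue}_S{j:04d}" for j in range(n_samples)]

        trend = 1.0 + np.outer(rel_slope, (ages - age_mid) / halfspan)
        expected = baseline[:, None] * trend
        n_negative = int((expected < 0).sum())
        if n_negative > 0.01 * expected.size:
            raise ValidationError(
                f"{n_negative} of {expected.size} expected TPM cells are negative; "
                "reduce slope_scale")
        expected = np.clip(expected, 0.0, None)
        if sigma > 0:
            noise = rng_noise.lognormal(-0.5 * sigma**2, sigma, expected.shape)
        else:
            noise = 1.0
        values = expected * noise
        matrices[tissue] = pd.DataFrame(values, index=gene_ids, columns=sample_ids)
        meta_rows.append(pd.DataFrame({
            "sample_id": sample_ids, "age": ages, "sex": sex, "tissue": tissue}))

    metadata = pd.concat(meta_rows, ignore_index=True)
    tpm_slope = baseline * rel_slope / halfspan  # TPM per year, same in all tissues
    truth = pd.DataFrame({
        "gene_id": gene_ids,
        "rel_slope": rel_slope,
        "tpm_slope_per_year": tpm_slope,
        "is_age_dependent": rel_slope != 0.0,
        "panel": panel_of,
        "baseline_tpm": baseline,
    })
    return matrices, metadata, truth


def gen_gene_panels(truth: pd.DataFrame, n_null_panels: int, panel_size: int,
                    seed: int) -> list[GenePanel]:
    """Injected trend panels plus ``n_null_panels`` uniform random panels."""
    if panel_size > len(truth):
        raise ValidationError("panel_size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    panels = []
    for name in sorted(set(truth.loc[truth["panel"] != "", "panel"])):
        symbols = tuple(truth.loc[truth["panel"] == name, "gene_id"])
        panels.append(GenePanel(name=name, symbols=symbols))
    genes = truth["gene_id"].to_numpy()
    for i in range(n_null_panels):
        pick = rng.choice(len(genes), size=panel_size, replace=False)
        panels.append(GenePanel(name=f"null_{i:04d}", symbols=tuple(genes[pick])))
    return panels


def gen_proteome(spec: ProteomeSpec):
    """Simulate a two-group protein quantity matrix with MNAR dropout.

    Returns ``(matrix, truth)``; ``truth`` records the injected log2
    fold-change and DE flag per protein. The number of flagged proteins is
    exactly ``round(frac_de * n_proteins)``.
    """
    rng_base, rng_fc, rng_noise, rng_drop = _child_rngs(spec.seed, 4)

    n = spec.n_proteins
    protein_ids = np.array([f"P{i:05d}" for i in range(n)])
    baselines = rng_base.normal(spec.base_mean, spec.base_spread, n)

    n_de = round(spec.frac_de * n)
    de_idx = rng_fc.choice(n, size=n_de, replace=False)
    log2fc = np.zeros(n)
    log2fc[de_idx] = rng_fc.choice([-1.0, 1.0], n_de) * spec.lfc_scale

    sample_ids, group_labels = [], []
    for label, size in spec.groups:
        for j in range(size):
            sample_ids.append(f"{label}_{j + 1}")
            group_labels.append(label)
    n_samples = len(sample_ids)
    # group effect applied to all non-reference groups (two-group design)
    ref = spec.groups[0][0]
    effect = np.array([0.0 if g == ref else 1.0 for g in group_labels])

    mean = baselines[:, None] + np.outer(log2fc, effect)
    intensity = mean + rng_noise.normal(0.0, spec.base_sd, (n, n_samples))

    p_miss = expit((spec.dropout_midpoint - intensity) * spec.dropout_steepness)
    missing = rng_drop.random((n, n_samples)) < p_miss
    overall = missing.mean()
    if overall > 0.9:
        raise ValidationError(
            f"dropout parameters give {overall:.0%} missingness; relax them")
    values = intensity.copy()
    if spec.scale == "raw":
        values = np.power(2.0, values)
    values[missing] = np.nan

    matrix = ProteomicsMatrix(
        values=pd.DataFrame(values, index=protein_ids, columns=sample_ids),
        groups=pd.Series(group_labels, index=sample_ids, name="group"),
        scale=spec.scale,
    )
    truth = pd.DataFrame({
        "protein_id": protein_ids,
        "log2fc": log2fc,
        "is_de": log2fc != 0.0,
        "baseline_log2": baselines,
    })
    return matrix, truth
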