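"""Recovery and calibration experiments on synthetic cohorts.

These routines run the full analysis stages on simulated data with known
ground truth and measure how well the truth is recovered: sensitivity of
the concordance gene sets for strong injected trends, false-positive
behaviour under the null, calibration of the panel deviation test, and
realized FDR / sensitivity of the permutation-FDR proteomics test. They
back both the test suite and the reproduction script.

Seeds: each experiment takes a base seed and derives independent
per-replicate seeds from it, all below 2^31.
"""

from __future__ import annotations

import numpy as np

from .age_screen import correlate_age, extended_set, pan_arterial_set
from .proteomics import filter_valid, ttest_permutation_fdr
from .regulon import panel_deviation_test
from .stats_core import Contingency2x2, chi_square_2x2
from .synthetic import CohortSpec, ProteomeSpec, gen_expression_cohort, \
    gen_gene_panels, gen_proteome

#: |relative slope| at or above which an injected trend counts as "strong".
STRONG_SLOPE = 0.3


def _seeds(base_seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(base_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def aortopathy_chi2():
    """Chi-squared test of the 4-of-7 vs 0-of-7 aortopathy incidence table."""
    return chi_square_2x2(Contingency2x2(4, 3, 0, 7), correction="none")


def _screen_tables(seed: int, frac_age_dependent: float = 0.1):
    spec = CohortSpec(seed=seed, frac_age_dependent=frac_age_dependent)
    matrices, meta, truth = gen_expression_cohort(spec)
    tables = {
        t: correlate_age(mat, meta.loc[meta["tissue"] == t], tissue=t)
        for t, mat in matrices.items()
    }
    return tables, truth


def screen_recovery(n_seeds: int = 20, base_seed: int = 0) -> dict:
    """Sensitivity of the concordance sets for strong trends, plus FPs.

    Per seed: simulate the default 3-tissue cohort (2,000 genes, 10%
    age-dependent), run the screen, and measure the fraction of strong
    trend genes (|relative slope| >= STRONG_SLOPE) recovered in the
    pan-arterial and extended sets, and the number of null genes wrongly
    included in each set.
    """
    pan_sens, ext_sens, pan_fp, ext_fp = [], [], [], []
    for seed in _seeds(base_seed, n_seeds):
        tables, truth = _screen_tables(seed)
        tissues = list(tables)
        pan = set(pan_arterial_set(tables)["gene_id"])
        ext = set(extended_set(tables, (tissues[0], tissues[1]), tissues[2])
                  ["gene_id"])
        strong = set(truth.loc[truth["rel_slope"].abs() >= STRONG_SLOPE,
                               "gene_id"])
        null = set(truth.loc[~truth["is_age_dependent"], "gene_id"])
        pan_sens.append(len(pan & strong) / len(strong))
        ext_sens.append(len(ext & strong) / len(strong))
        pan_fp.append(len(pan & null))
        ext_fp.append(len(ext & null))
    return {
        "pan_sensitivity_mean": float(np.mean(pan_sens)),
        "extended_sensitivity_mean": float(np.mean(ext_sens)),
        "pan_false_positives_median": float(np.median(pan_fp)),
        "extended_false_positives_median": float(np.median(ext_fp)),
        "n_seeds": n_seeds,
    }


def screen_null(n_seeds: int = 20, base_seed: int = 1) -> dict:
    """Size of the pan-arterial set on fully null cohorts (no trends)."""
    sizes = []
    for seed in _seeds(base_seed, n_seeds):
        spec = CohortSpec(seed=seed, frac_age_dependent=0.0, panel_spec=())
        matrices, meta, _ = gen_expression_cohort(spec)
        tables = {t: correlate_age(mat, meta.loc[meta["tissue"] == t], tissue=t)
                  for t, mat in matrices.items()}
        sizes.append(len(pan_arterial_set(tables)))
    sizes = np.array(sizes)
    return {"pan_sizes": sizes.tolist(),
            "n_empty": int((sizes == 0).sum()),
            "n_seeds": n_seeds}


def panel_null_calibration(n_panels: int = 1000, panel_size: int = 20,
                           alpha: float = 0.05, seed: int = 2) -> dict:
    """Rejection rate of the panel deviation test over random null panels.

    One fully null cohort is simulated; ``n_panels`` panels are sampled
    uniformly from its gene universe and each is tested against the
    genome median R at level ``alpha``. The signed-rank test's
    discreteness makes the rate conservative (<= alpha up to Monte Carlo
    error).
    """
    spec = CohortSpec(seed=seed, frac_age_dependent=0.0, panel_spec=())
    matrices, meta, truth = gen_expression_cohort(spec)
    tissue = next(iter(matrices))
    table = correlate_age(matrices[tissue],
                          meta.loc[meta["tissue"] == tissue], tissue=tissue)
    panels = gen_gene_panels(truth, n_null_panels=n_panels,
                             panel_size=panel_size, seed=seed + 1)
    rejections = sum(
        panel_deviation_test(p, table).p_value < alpha for p in panels)
    mc_error = float(np.sqrt(alpha * (1 - alpha) / n_panels))
    return {"rejection_rate": rejections / n_panels, "alpha": alpha,
            "mc_error": mc_error, "n_panels": n_panels}


def panel_detection(n_seeds: int = 20, base_seed: int = 3,
                    alpha: float = 0.05) -> dict:
    """Detection rate for the injected negative-trend panel across seeds."""
    detected = 0
    for seed in _seeds(base_seed, n_seeds):
        tables, truth = _screen_tables(seed)
        table = next(iter(tables.values()))
        panels = gen_gene_panels(truth, n_null_panels=0, panel_size=20,
                                 seed=seed)
        res = panel_deviation_test(panels[0], table)
        if res.p_value < alpha and res.direction < 0:
            detected += 1
    return {"detection_rate": detected / n_seeds, "n_seeds": n_seeds}


def proteome_null(n_seeds: int = 20, base_seed: int = 4) -> dict:
    """Significant-set sizes of the permutation-FDR test on null proteomes."""
    sizes = []
    for seed in _seeds(base_seed, n_seeds):
        matrix, _ = gen_proteome(ProteomeSpec(seed=seed, frac_de=0.0))
        m = filter_valid(matrix)
        de = ttest_permutation_fdr(m, seed=seed)
        sizes.append(int(de.table["significant"].sum()))
    return {"sizes": sizes, "median_size": float(np.median(sizes)),
            "n_seeds": n_seeds}


def proteome_recovery(n_seeds: int = 20, base_seed: int = 5) -> dict:
    """Realized FDR and sensitivity of the permutation-FDR test.

    Mixed simulations at the default study scale: 2,000 proteins, 6 vs 6
    samples, 10% true differences of |log2FC| = 2 against within-group SD
    0.3, intensity-dependent dropout. Averages over seeds.
    """
    fdrs, sens = [], []
    for seed in _seeds(base_seed, n_seeds):
        matrix, truth = gen_proteome(ProteomeSpec(seed=seed))
        m = filter_valid(matrix)
        de = ttest_permutation_fdr(m, seed=seed)
        flagged = set(de.table.loc[de.table["significant"], "protein_id"])
        true_de = set(truth.loc[truth["is_de"], "protein_id"])
        # restrict truth to proteins that survived the valid-value filter
        tested_universe = set(m.values.index)
        true_de_tested = true_de & tested_universe
        if flagged:
            fdrs.append(len(flagged - true_de) / len(flagged))
        else:
            fdrs.append(0.0)
        sens.append(len(flagged & true_de_tested) / len(true_de_tested)
                    if true_de_tested else float("nan"))
    return {"realized_fdr_mean": float(np.mean(fdrs)),
            "sensitivity_mean": float(np.nanmean(sens)),
            "n_seeds": n_seeds}


def imputation_moments(n_cells: int = 10000, mu: float = 20.0,
                       sigma: float = 1.0, width: float = 0.4,
                       downshift: float = 1.8, seed: int = 6) -> dict:
    """Empirical mean/SD of downshift-imputed cells in a controlled column.

    Builds one sample column whose observed values have exactly mean
    ``mu`` and sample SD ``sigma``, plus ``n_cells`` missing cells, and
    imputes. The draws should have mean mu - downshift*sigma and SD
    width*sigma.
    """
    import pandas as pd

    from .proteomics import ProteomicsMatrix, impute_downshift

    rng = np.random.default_rng(seed)
    obs = rng.normal(mu, sigma, 1000)
    obs = (obs - obs.mean()) / obs.std(ddof=1) * sigma + mu  # exact moments
    col = np.concatenate([obs, np.full(n_cells, np.nan)])
    m = ProteomicsMatrix(
        values=pd.DataFrame({"S1": col},
                            index=[f"P{i}" for i in range(col.size)]),
        groups=pd.Series({"S1": "g"}),
        scale="log2",
    )
    out = impute_downshift(m, width=width, downshift=downshift, seed=seed + 1)
    imputed = out.values.to_numpy()[len(obs):, 0]
    return {"mean": float(imputed.mean()),
            "sd": float(imputed.std(ddof=1)),
            "expected_mean": mu - downshift * sigma,
            "expected_sd": width * sigma,
            "n_cells": n_cells}
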