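import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from vascage.synthetic import CohortSpec, ProteomeSpec, gen_expression_cohort, \
    gen_proteome

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """A small 3-tissue cohort with injected trends, shared across tests."""
    spec = CohortSpec(
        seed=11,
        n_genes=400,
        n_samples_per_tissue={"tibial_artery": 150, "aorta": 100,
                              "coronary_artery": 80},
        frac_age_dependent=0.15,
        panel_spec=(("regulon_down", 15, -1),),
    )
    matrices, meta, truth = gen_expression_cohort(spec)
    return spec, matrices, meta, truth


@pytest.fixture(scope="session")
def small_proteome():
    spec = ProteomeSpec(seed=21, n_proteins=400)
    matrix, truth = gen_proteome(spec)
    return spec, matrix, truth


@pytest.fixture()
def tiny_expr():
    """Tiny deterministic expression matrix + metadata for exact checks."""
    rng = np.random.default_rng(7)
    ages = np.array([25.0, 32.0, 41.0, 50.0, 58.0, 66.0, 74.0, 78.0])
    samples = [f"S{i}" for i in range(len(ages))]
    expr = pd.DataFrame(rng.uniform(1, 100, (4, len(ages))),
                        index=["LINEAR", "NOISY1", "NOISY2", "FLAT"],
                        columns=samples)
    expr.loc["LINEAR"] = 10.0 + 0.5 * ages
    expr.loc["FLAT"] = 5.0
    meta = pd.DataFrame({"sample_id": samples, "age": ages,
                         "sex": [1, 2] * 4, "tissue": "aorta"})
    return expr, meta
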