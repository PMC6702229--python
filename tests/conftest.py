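import warnings

import numpy as np
import pandas as pd
import pytest

from neomix.cohort import SimConfig, generate_cohort
from neomix.factors import fit_joint_factors, standardize_block
from neomix.preprocess import (
    beta_to_m,
    drop_sex_chromosome_features,
    filter_low_expression,
    normalize_expression,
    select_variable_features,
)

warnings.filterwarnings("ignore", message=".*did not converge.*")


def preprocess_blocks(cohort):
    """Standard preprocessing path: sex-feature removal, normalisation,
    variable-feature selection (50% expression / 5% methylation), block
    standardisation."""
    expr = filter_low_expression(drop_sex_chromosome_features(cohort.expression, cohort.annotation))
    expr_norm = normalize_expression(expr)
    mvals = beta_to_m(drop_sex_chromosome_features(cohort.methylation, cohort.annotation))
    be, _ = standardize_block(expr_norm.loc[select_variable_features(expr_norm, 0.5)])
    bm, _ = standardize_block(mvals.loc[select_variable_features(mvals, 0.05)])
    return {"expression": be, "methylation": bm}


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(SimConfig(seed=0))


@pytest.fixture(scope="session")
def default_blocks(default_cohort):
    return preprocess_blocks(default_cohort)


@pytest.fixture(scope="session")
def default_model(default_blocks):
    return fit_joint_factors(default_blocks, 5, tol=1e-6)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny fast cohort for structural tests."""
    cfg = SimConfig(
        n_samples=48, n_genes=400, n_cpgs=400,
        cluster_sizes=(20, 16, 10, 2, 0), seed=11,
    )
    return generate_cohort(cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def planted_factor_model(n_per_cluster=(20, 20, 20), seed=0, n_noise_factors=3,
                         noise_scale=0.05, separation=6.0):
    """Construct a FactorModel directly from planted well-separated scores.

    Two signal factors separate three clusters; trailing factors are pure
    noise with tiny variance-explained weight.
    """
    from neomix.factors import FactorModel

    r = np.random.default_rng(seed)
    centres = np.array([[0, 0], [separation, 0], [separation / 2, separation]])
    rows, labels = [], []
    for ci, m in enumerate(n_per_cluster):
        rows.append(centres[ci] + r.normal(0, 0.5, size=(m, 2)))
        labels += [ci] * m
    z_signal = np.vstack(rows)
    z_noise = r.normal(0, 0.5, size=(len(labels), n_noise_factors))
    z = np.hstack([z_signal, z_noise])
    names = [f"LF{i + 1}" for i in range(z.shape[1])]
    samples = [f"S{i:03d}" for i in range(len(labels))]
    varexp = np.array([[0.5, 0.3] + [noise_scale / n_noise_factors] * n_noise_factors])
    model = FactorModel(
        Z=pd.DataFrame(z, index=samples, columns=names),
        W={"block": pd.DataFrame(np.zeros((2, z.shape[1])), columns=names)},
        varexp=pd.DataFrame(varexp, index=["block"], columns=names),
    )
    return model, np.array(labels)
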