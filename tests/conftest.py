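"""Shared fixtures: the synthetic benchmark pipeline computed once per session."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

import scired as sr

FIXTURE_SEED = 11
PIPELINE_K = 10


@pytest.fixture(scope="session")
def fixture_data():
    cfg = sr.FixtureConfig(seed=FIXTURE_SEED)
    return sr.make_fixture_dataset(cfg)


@pytest.fixture(scope="session")
def design(fixture_data):
    _, cov = fixture_data
    return sr.build_design_matrix(cov, ["protocol", "library_size"])


@pytest.fixture(scope="session")
def pearson_residuals_matrix(fixture_data, design):
    cm, _ = fixture_data
    return sr.compute_residual_matrix(cm, design, "pearson")


@pytest.fixture(scope="session")
def factor_model(pearson_residuals_matrix):
    est = sr.RotatedFactorizer(n_factors=PIPELINE_K, rotation="varimax")
    return est.fit(pearson_residuals_matrix).model_


@pytest.fixture(scope="session")
def fca_table(factor_model, fixture_data):
    _, cov = fixture_data
    return sr.ensemble_fca(factor_model, cov, ["line"], seed=0)


@pytest.fixture(scope="session")
def models_by_residual_type(fixture_data, design):
    """Rotated factor models for all three residual flavors."""
    cm, _ = fixture_data
    out = {}
    for rtype in ("pearson", "response", "deviance"):
        rm = sr.compute_residual_matrix(cm, design, rtype)
        out[rtype] = sr.RotatedFactorizer(n_factors=PIPELINE_K).fit(rm).model_
    return out


@pytest.fixture(scope="session")
def permutation_result(factor_model, fixture_data):
    """Full 200-shuffle permutation benchmark on the line covariate."""
    _, cov = fixture_data
    return sr.run_permutation_benchmark(
        factor_model, cov, ["line"], n_perm=200, alpha=0.05, seed=0
    )


@pytest.fixture(scope="session")
def overlap_report():
    """Metric-overlap correlations at reduced simulation scale."""
    params = sr.MixtureParams(n_cells=1000, n_factors=10, n_rounds=20, seed=1)
    return sr.metric_overlap_correlation(
        params,
        metrics=(
            "silhouette",
            "bimodality_index",
            "asv_arithmetic",
            "asv_geometric",
        ),
    )


def align_factors(reference: sr.FactorModel, other: sr.FactorModel) -> dict:
    """Map other's factor names onto reference's by absolute score correlation."""
    k = reference.n_factors
    C = np.abs(np.corrcoef(reference.scores.T, other.scores.T)[:k, k:])
    ri, ci = linear_sum_assignment(-C)
    return {
        other.factor_names[c]: reference.factor_names[r] for r, c in zip(ri, ci)
    }
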