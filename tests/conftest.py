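"""Shared fixtures: tiny deterministic datasets and cached scenario runs."""

from __future__ import annotations

import warnings

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from xferdrp.containers import (DrugScreenDataset, ExpressionMatrix,
                                ResponseTable)
from xferdrp.preprocess import minmax_scale_response

settings.register_profile(
    "ci", derandomize=True, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_dataset(n_genes: int, n_samples: int, seed: int = 0,
                 signal: float = 1.0, noise: float = 0.5,
                 cohort_id: str = "toy") -> DrugScreenDataset:
    """Small linear-signal dataset with normalized AUC, for functional tests."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_genes, n_samples))
    beta = rng.standard_normal(n_genes) * signal / np.sqrt(n_genes)
    auc = beta @ X + rng.normal(0, noise, n_samples)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    samples = [f"S{i:04d}" for i in range(n_samples)]
    expr = ExpressionMatrix(genes, samples, X)
    resp = minmax_scale_response(ResponseTable(samples, auc, drug="TOY"))
    return DrugScreenDataset(expr, resp, cohort_id)


@pytest.fixture
def toy_dataset() -> DrugScreenDataset:
    return make_dataset(20, 12, seed=3)


@pytest.fixture
def suppress_user_warnings():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield
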