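"""Comparison methods run under the identical frozen CV plan.

Two classical baselines: an elastic net on the top-k features by univariate
regression F statistic (selection refit on every training fold — never on
held-out samples), and a single-gene polynomial regression (the clinical
biomarker baseline: degree-2 fit on one gene's expression).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.feature_selection import f_regression
from sklearn.linear_model import ElasticNetCV

from .containers import DataError, DrugScreenDataset, ExpressionMatrix
from .evaluation import CVPlan, ExperimentResult, run_cv
from .preprocess import PreprocessConfig


@dataclass(frozen=True)
class BenchmarkConfig:
    """Elastic-net and polynomial baseline settings.

    ``en_k_grid`` — feature-count grid for F-statistic selection.
    ``en_mixing`` — L1/L2 mixing (0.5 by default); the penalty strength is
    chosen per training fold by an internal 3-fold CV over a log grid.
    """

    en_k_grid: tuple[int, ...] = (5, 10, 15, 20, 50, 100)
    en_mixing: float = 0.5
    en_alphas: tuple[float, ...] = tuple(np.logspace(-3, 1, 9))
    en_inner_folds: int = 3
    poly_gene: str = "MGMT"
    poly_degree: int = 2

    def __post_init__(self) -> None:
        if any(k < 1 for k in self.en_k_grid):
            raise ValueError("feature counts must be >= 1")
        if not 0.0 <= self.en_mixing <= 1.0:
            raise ValueError("en_mixing must lie in [0, 1]")
        if self.poly_degree < 1:
            raise ValueError("poly_degree must be >= 1")


def f_statistic_select(expr: ExpressionMatrix, auc: np.ndarray, k: int) -> list[str]:
    """Top-k genes by univariate linear-regression F statistic vs AUC.

    Sorted by F descending, ties broken by gene id ascending. Callers must
    pass training-partition data only.
    """
    if k > expr.n_genes:
        raise ValueError(f"k={k} exceeds {expr.n_genes} genes")
    auc = np.asarray(auc, dtype=np.float64)
    if auc.size != expr.n_samples:
        raise DataError("auc length does not match sample count")
    with np.errstate(divide="ignore", invalid="ignore"):
        f_stats, _ = f_regression(expr.values.T, auc)
    f_stats = np.nan_to_num(f_stats, nan=0.0, posinf=np.finfo(float).max)
    order = sorted(range(expr.n_genes),
                   key=lambda i: (-f_stats[i], expr.gene_ids[i]))
    return [expr.gene_ids[i] for i in order[:k]]


class _ElasticNetPredictor:
    def __init__(self, genes: list[str], model):
        self.genes = genes
        self.model = model

    def predict(self, expr: ExpressionMatrix) -> np.ndarray:
        X = expr.subset_genes(self.genes).values.T
        return self.model.predict(X)


def elastic_net_factory(k: int, cfg: BenchmarkConfig):
    """run_cv factory: F-statistic selection + ElasticNet, both on the fold."""

    def factory(train_ds: DrugScreenDataset, seed: int) -> _ElasticNetPredictor:
        genes = f_statistic_select(train_ds.expression, train_ds.response.auc, k)
        X = train_ds.expression.subset_genes(genes).values.T
        inner = min(cfg.en_inner_folds, train_ds.n_samples)
        model = ElasticNetCV(l1_ratio=cfg.en_mixing, alphas=list(cfg.en_alphas),
                             cv=inner, max_iter=5000, random_state=seed)
        model.fit(X, train_ds.response.auc)
        return _ElasticNetPredictor(genes, model)

    return factory


def elastic_net_benchmark(ds: DrugScreenDataset, plan: CVPlan,
                          cfg: BenchmarkConfig | None = None,
                          preprocess: PreprocessConfig | None = None) -> dict[int, ExperimentResult]:
    """One ExperimentResult per feature count k, under the frozen plan."""
    cfg = cfg or BenchmarkConfig()
    out = {}
    for k in cfg.en_k_grid:
        if k > ds.expression.n_genes:
            raise ValueError(f"k={k} exceeds {ds.expression.n_genes} genes")
        out[k] = run_cv(ds, elastic_net_factory(k, cfg), plan, preprocess,
                        label=f"elastic_net_k{k}")
    return out


class _PolyPredictor:
    def __init__(self, gene: str, coeffs: np.ndarray):
        self.gene = gene
        self.coeffs = coeffs

    def predict(self, expr: ExpressionMatrix) -> np.ndarray:
        x = expr.subset_genes([self.gene]).values[0]
        return np.polyval(self.coeffs, x)


def polynomial_factory(gene: str, degree: int):
    """run_cv factory: least-squares polynomial on one gene's expression."""

    def factory(train_ds: DrugScreenDataset, seed: int) -> _PolyPredictor:
        x = train_ds.expression.subset_genes([gene]).values[0]
        coeffs = np.polyfit(x, train_ds.response.auc, degree)
        return _PolyPredictor(gene, coeffs)

    return factory


def single_gene_polynomial(ds: DrugScreenDataset, gene: str, degree: int,
                           plan: CVPlan,
                           preprocess: PreprocessConfig | None = None) -> ExperimentResult:
    """Degree-``degree`` single-gene regression under the frozen plan."""
    if gene not in ds.gene_ids:
        raise DataError(f"gene '{gene}' not present in dataset")
    return run_cv(ds, polynomial_factory(gene, degree), plan, preprocess,
                  label=f"poly_{gene}_deg{degree}")
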