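"""Core domain containers: expression matrices, response tables, screen datasets.

Expression values are always stored genes x samples on a log scale (or are
log2-transformed by :mod:`xferdrp.preprocess` before modelling). Alignment and
gene-intersection operations never alter numeric values — they only select and
reorder rows/columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np


class DataError(ValueError):
    """Malformed or inconsistent input data."""


class AlignmentError(DataError):
    """Samples or genes cannot be aligned between containers."""


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        seen: set[str] = set()
        dups = [i for i in ids if i in seen or seen.add(i)]  # type: ignore[func-returns-value]
        raise DataError(f"duplicate {what}: {sorted(set(dups))}")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with stable string identifiers.

    Attributes
    ----------
    gene_ids : list of str
        Unique row identifiers (gene symbols or other stable ids).
    sample_ids : list of str
        Unique column identifiers.
    values : ndarray, shape (n_genes, n_samples)
        Finite, float64, log-scale expression.
    meta : dict
        Free-form annotations (cohort name, platform, ``log_transformed`` flag).
    """

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=np.float64)
        _check_unique(self.gene_ids, "gene ids")
        _check_unique(self.sample_ids, "sample ids")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise DataError(
                f"values shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if not np.all(np.isfinite(self.values)):
            raise DataError("expression values contain non-finite entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``genes`` in the given order (all must be present)."""
        index = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in index]
        if missing:
            raise AlignmentError(f"genes absent from matrix: {missing[:10]}")
        rows = [index[g] for g in genes]
        return ExpressionMatrix(list(genes), list(self.sample_ids),
                                self.values[rows, :], dict(self.meta))

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        """Restrict to ``samples`` in the given order (all must be present)."""
        index = {s: i for i, s in enumerate(self.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise AlignmentError(f"samples absent from matrix: {missing[:10]}")
        cols = [index[s] for s in samples]
        return ExpressionMatrix(list(self.gene_ids), list(samples),
                                self.values[:, cols], dict(self.meta))


@dataclass
class ResponseTable:
    """Per-sample dose-response AUC for one drug.

    ``auc`` is the area under the cell-viability-vs-dose curve (lower = more
    sensitive). ``normalized`` records whether min-max scaling to
    ``norm_bounds`` has been applied.
    """

    sample_ids: list[str]
    auc: np.ndarray
    drug: str = "unknown"
    normalized: bool = False
    norm_bounds: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.auc = np.asarray(self.auc, dtype=np.float64)
        _check_unique(self.sample_ids, "sample ids")
        if self.auc.shape != (len(self.sample_ids),):
            raise DataError("auc length does not match sample_ids")
        if not np.all(np.isfinite(self.auc)):
            raise DataError("auc contains non-finite values")
        if self.normalized:
            if self.norm_bounds is None:
                raise DataError("normalized response requires norm_bounds")
            lo, hi = self.norm_bounds
            if self.auc.size and (self.auc.min() < lo - 1e-9 or self.auc.max() > hi + 1e-9):
                raise DataError(f"normalized auc outside bounds {self.norm_bounds}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)


@dataclass
class DrugScreenDataset:
    """An expression matrix column-aligned with an AUC response for one drug."""

    expression: ExpressionMatrix
    response: ResponseTable
    cohort_id: str

    def __post_init__(self) -> None:
        if self.expression.sample_ids != self.response.sample_ids:
            raise AlignmentError(
                "expression and response sample ids differ (order matters); "
                "use align_dataset()"
            )
        if self.response.n_samples < 2:
            raise DataError("a drug screen dataset needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return self.response.n_samples

    @property
    def gene_ids(self) -> list[str]:
        return self.expression.gene_ids

    @property
    def drug(self) -> str:
        return self.response.drug

    def subset_samples(self, samples: Sequence[str]) -> "DrugScreenDataset":
        index = {s: i for i, s in enumerate(self.response.sample_ids)}
        missing = [s for s in samples if s not in index]
        if missing:
            raise AlignmentError(f"samples absent from dataset: {missing[:10]}")
        rows = [index[s] for s in samples]
        resp = ResponseTable(list(samples), self.response.auc[rows],
                             self.response.drug, self.response.normalized,
                             self.response.norm_bounds)
        return DrugScreenDataset(self.expression.subset_samples(samples), resp,
                                 self.cohort_id)

    def subset_genes(self, genes: Sequence[str]) -> "DrugScreenDataset":
        return DrugScreenDataset(self.expression.subset_genes(genes),
                                 self.response, self.cohort_id)


@dataclass
class InputLayerWeights:
    """Gene-indexed first-dense-layer weights — the unit of transfer.

    ``W`` has one row per gene (genes x H1) and ``b`` one entry per first
    hidden unit. Rows are addressed by gene id, never by position, so the
    same archive can initialize models built on a different gene ordering
    or a gene subset.
    """

    gene_ids: list[str]
    W: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.W = np.asarray(self.W, dtype=np.float64)
        self.b = np.asarray(self.b, dtype=np.float64)
        _check_unique(self.gene_ids, "gene ids")
        if self.W.ndim != 2 or self.W.shape[0] != len(self.gene_ids):
            raise DataError(
                f"W shape {self.W.shape} does not match {len(self.gene_ids)} genes")
        if self.b.shape != (self.W.shape[1],):
            raise DataError("b length does not match hidden width of W")
        if not (np.all(np.isfinite(self.W)) and np.all(np.isfinite(self.b))):
            raise DataError("weights contain non-finite values")

    @property
    def hidden_size(self) -> int:
        return self.W.shape[1]


def align_dataset(expr: ExpressionMatrix, resp: ResponseTable,
                  cohort_id: str) -> DrugScreenDataset:
    """Restrict and reorder expression columns to the response sample order.

    Every response sample must be present in the expression matrix; numeric
    values are never altered, only selected and reordered.
    """
    missing = sorted(set(resp.sample_ids) - set(expr.sample_ids))
    if missing:
        raise AlignmentError(
            f"response samples absent from expression matrix: {missing}")
    return DrugScreenDataset(expr.subset_samples(resp.sample_ids), resp, cohort_id)


def intersect_genes(matrices: Sequence[ExpressionMatrix]) -> list[ExpressionMatrix]:
    """Restrict every matrix to the common gene set, rows sorted ascending.

    Mirrors the cross-platform gene-space intersection needed before weights
    can be transferred between cohorts profiled on different platforms. The
    ascending sort makes the resulting row order deterministic regardless of
    input ordering.
    """
    if len(matrices) < 2:
        raise ValueError("intersect_genes needs at least 2 matrices")
    common = set(matrices[0].gene_ids)
    for m in matrices[1:]:
        common &= set(m.gene_ids)
    if not common:
        raise DataError("gene intersection across matrices is empty")
    genes = sorted(common)
    return [m.subset_genes(genes) for m in matrices]


def intersect_datasets(datasets: Sequence[DrugScreenDataset]) -> list[DrugScreenDataset]:
    """``intersect_genes`` lifted to aligned screen datasets."""
    exprs = intersect_genes([d.expression for d in datasets])
    return [DrugScreenDataset(e, d.response, d.cohort_id)
            for e, d in zip(exprs, datasets)]


def collapse_duplicate_genes(gene_ids: Sequence[str],
                             values: np.ndarray) -> tuple[list[str], np.ndarray]:
    """Keep the first row per duplicated gene id, warning about the rest."""
    seen: dict[str, int] = {}
    keep: list[int] = []
    dropped: list[str] = []
    for i, g in enumerate(gene_ids):
        if g in seen:
            dropped.append(g)
        else:
            seen[g] = i
            keep.append(i)
    if dropped:
        warnings.warn(
            f"dropped {len(dropped)} duplicate gene row(s), keeping first "
            f"occurrence: {sorted(set(dropped))[:10]}", UserWarning)
    return [gene_ids[i] for i in keep], values[keep, :]
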