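"""Dataset- and partition-level preprocessing.

The modelling pipeline applies, in order: log2 transform (if the platform did
not already deliver log-scale values), a low-variance gene filter (genes whose
variance falls strictly below a quantile of all gene variances are dropped),
min-max scaling of the per-drug AUC to [0, 10], and per-partition feature
standardization. AUC scaling is fit once per (cohort, drug) on all samples
before cross-validation — this mirrors the per-dataset normalization the
modelled screening cohorts receive; the train/test leakage this implies for
absolute values is documented (ranks, and hence Spearman scores, are
unaffected because min-max scaling is strictly monotone).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .containers import DataError, ExpressionMatrix, ResponseTable

logger = logging.getLogger(__name__)

STANDARDIZE_MODES = ("per_partition_independent", "fit_on_train")


@dataclass
class PreprocessConfig:
    """Thresholds and modes for the preprocessing steps.

    ``standardize_mode='per_partition_independent'`` scales train and test
    partitions separately (the default behaviour of the modelled pipeline);
    ``'fit_on_train'`` applies train-fold statistics to the test fold and is
    the leakage-free alternative.
    """

    log2_pseudocount: float = 0.0
    variance_quantile: float = 0.25
    auc_lo: float = 0.0
    auc_hi: float = 10.0
    standardize_mode: str = "per_partition_independent"

    def __post_init__(self) -> None:
        if not 0.0 <= self.variance_quantile < 1.0:
            raise ValueError("variance_quantile must lie in [0, 1)")
        if not self.auc_lo < self.auc_hi:
            raise ValueError("auc_lo must be < auc_hi")
        if self.log2_pseudocount < 0:
            raise ValueError("log2_pseudocount must be non-negative")
        if self.standardize_mode not in STANDARDIZE_MODES:
            raise ValueError(f"standardize_mode must be one of {STANDARDIZE_MODES}")


def log2_transform(expr: ExpressionMatrix, pseudocount: float = 0.0) -> ExpressionMatrix:
    """Return a copy with values replaced by ``log2(value + pseudocount)``."""
    shifted = expr.values + pseudocount
    if np.any(shifted <= 0):
        g, s = np.argwhere(shifted <= 0)[0]
        raise DataError(
            f"log2 transform of non-positive value at gene "
            f"'{expr.gene_ids[g]}', sample '{expr.sample_ids[s]}' "
            f"(value + pseudocount = {shifted[g, s]})")
    meta = dict(expr.meta)
    meta["log_transformed"] = True
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids),
                            np.log2(shifted), meta)


def variance_filter(expr: ExpressionMatrix, q: float = 0.25) -> ExpressionMatrix:
    """Drop genes whose variance is strictly below the ``q``-quantile.

    The threshold is the linear-interpolation quantile of the per-gene
    variance vector (population variance, across samples). Genes exactly at
    the threshold are kept ("lower than" is strict). Counts and the threshold
    are logged so a run is auditable.
    """
    if not 0.0 <= q < 1.0:
        raise ValueError("quantile must lie in [0, 1)")
    if expr.n_samples < 2:
        raise DataError("variance filter needs at least 2 samples")
    variances = expr.values.var(axis=1)
    threshold = float(np.quantile(variances, q))  # linear interpolation
    keep = variances >= threshold
    out = ExpressionMatrix([g for g, k in zip(expr.gene_ids, keep) if k],
                           list(expr.sample_ids), expr.values[keep, :],
                           dict(expr.meta))
    logger.info("variance_filter: q=%.3f threshold=%.6g n_before=%d n_after=%d",
                q, threshold, expr.n_genes, out.n_genes)
    return out


def minmax_scale_response(resp: ResponseTable, lo: float = 0.0,
                          hi: float = 10.0) -> ResponseTable:
    """Min-max scale the AUC vector to [lo, hi] (strictly monotone).

    Rank order is preserved exactly, so Spearman correlations computed against
    raw or scaled AUC are identical.
    """
    if lo >= hi:
        raise ValueError("lo must be < hi")
    amin, amax = float(resp.auc.min()), float(resp.auc.max())
    if amax <= amin:
        raise DataError(
            f"cannot min-max scale a constant AUC vector (all = {amin})")
    scaled = lo + (resp.auc - amin) / (amax - amin) * (hi - lo)
    return ResponseTable(list(resp.sample_ids), scaled, resp.drug,
                         normalized=True, norm_bounds=(lo, hi))


def standardize_features(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Center and scale each gene row to mean 0, population sd 1.

    Zero-variance rows (including any row of a single-sample matrix) map to
    all-zeros with a warning rather than NaN, so downstream models see finite
    inputs.
    """
    if expr.n_samples < 1:
        raise DataError("cannot standardize an empty matrix")
    mean = expr.values.mean(axis=1, keepdims=True)
    sd = expr.values.std(axis=1, keepdims=True)  # population sd (divisor n)
    constant = (sd[:, 0] == 0)
    if constant.any():
        warnings.warn(
            f"standardize_features: {int(constant.sum())} constant gene "
            f"row(s) mapped to zeros", UserWarning)
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (expr.values - mean) / safe_sd
    z[constant, :] = 0.0
    meta = dict(expr.meta)
    meta["standardized"] = True
    return ExpressionMatrix(list(expr.gene_ids), list(expr.sample_ids), z, meta)
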