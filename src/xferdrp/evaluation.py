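"""Frozen repeated stratified CV, Spearman scoring, and nonparametric tests.

Model quality is scored exclusively by the Spearman correlation coefficient
(SCC) between predicted and observed AUC — the response is treated as a
relative ranking, never an absolute value. Each dataset gets one frozen
:class:`CVPlan` (repeated stratified k-fold assignments, a pure function of
the response vector and a seed); every method compared on that dataset
consumes the identical plan, which is what licenses the paired signed-rank
test over per-repetition SCCs.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb, erf, sqrt
from typing import Callable, Protocol, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import DataError, DrugScreenDataset, ExpressionMatrix
from .preprocess import PreprocessConfig, standardize_features
from ._seeds import derive_seed


def spearman(pred: Sequence[float], obs: Sequence[float]) -> float:
    """Spearman correlation: Pearson correlation of average ranks.

    Ties receive average ranks. If either vector is constant the correlation
    is undefined; 0 is returned with a degeneracy warning so repetition
    vectors stay complete for paired tests.
    """
    pred = np.asarray(pred, dtype=np.float64)
    obs = np.asarray(obs, dtype=np.float64)
    if pred.shape != obs.shape:
        raise ValueError(f"length mismatch: {pred.shape} vs {obs.shape}")
    if pred.ndim != 1 or pred.size < 3:
        raise ValueError("spearman needs 1-d vectors of length >= 3")
    rp, ro = rankdata(pred), rankdata(obs)
    if np.ptp(rp) == 0 or np.ptp(ro) == 0:
        warnings.warn("spearman: constant vector, correlation undefined; "
                      "returning 0", UserWarning)
        return 0.0
    rp = rp - rp.mean()
    ro = ro - ro.mean()
    return float(np.dot(rp, ro) / np.sqrt(np.dot(rp, rp) * np.dot(ro, ro)))


@dataclass
class CVPlan:
    """Frozen repeated stratified k-fold assignments.

    ``assignments[r, i]`` is the fold index of sample ``i`` in repetition
    ``r``. Stratification bins samples by AUC quantile groups; within each
    bin the samples are shuffled (repetition-specific RNG) and dealt to folds
    by one continuous round-robin, so overall fold sizes differ by at most 1
    and per-bin fold counts differ by at most 1.
    """

    n_samples: int
    k: int
    repetitions: int
    seed: int
    strat_bins: int
    assignments: np.ndarray

    @property
    def plan_hash(self) -> str:
        h = hashlib.sha256()
        h.update(f"{self.n_samples}:{self.k}:{self.repetitions}:"
                 f"{self.seed}:{self.strat_bins}:".encode())
        h.update(np.ascontiguousarray(self.assignments, dtype=np.int64).tobytes())
        return h.hexdigest()

    def folds(self, repetition: int):
        """Yield (train_idx, test_idx) pairs for one repetition."""
        a = self.assignments[repetition]
        for fold in range(self.k):
            test = np.flatnonzero(a == fold)
            train = np.flatnonzero(a != fold)
            yield train, test


def make_cv_plan(auc: Sequence[float], k: int, repetitions: int, seed: int,
                 strat_bins: int) -> CVPlan:
    """Build a frozen stratified plan from the response vector alone."""
    auc = np.asarray(auc, dtype=np.float64)
    n = auc.size
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    if k < 2 or repetitions < 1 or strat_bins < 1:
        raise ValueError("need k >= 2, repetitions >= 1, strat_bins >= 1")
    # quantile-group stratification: sort by AUC (ties by index, stable) and
    # cut into strat_bins contiguous groups of near-equal size
    order = np.argsort(auc, kind="stable")
    bins: list[np.ndarray] = [
        order[(n * b) // strat_bins:(n * (b + 1)) // strat_bins]
        for b in range(strat_bins)]
    assignments = np.empty((repetitions, n), dtype=np.int64)
    for rep in range(repetitions):
        rng = np.random.default_rng([seed, rep])
        pointer = 0
        for members in bins:
            shuffled = rng.permutation(members)
            for s in shuffled:
                assignments[rep, s] = pointer % k
                pointer += 1
    return CVPlan(n, k, repetitions, seed, strat_bins, assignments)


class Predictor(Protocol):
    def predict(self, expr: ExpressionMatrix) -> np.ndarray: ...


# A model factory builds and fits a fresh predictor on a training dataset.
ModelFactory = Callable[[DrugScreenDataset, int], Predictor]


@dataclass
class ExperimentResult:
    """Per-repetition SCCs of one method on one dataset under one CVPlan."""

    label: str
    per_rep_scc: np.ndarray
    plan_hash: str
    predictions: np.ndarray | None = None  # repetitions x n pooled OOF preds
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.per_rep_scc = np.asarray(self.per_rep_scc, dtype=np.float64)

    @property
    def mean_scc(self) -> float:
        return float(self.per_rep_scc.mean())

    @property
    def sd_scc(self) -> float:
        return float(self.per_rep_scc.std(ddof=1)) if self.per_rep_scc.size > 1 else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"label": self.label,
                             "repetition": np.arange(self.per_rep_scc.size),
                             "scc": self.per_rep_scc})


def run_cv(ds: DrugScreenDataset, model_factory: ModelFactory, plan: CVPlan,
           preprocess: PreprocessConfig | None = None,
           label: str = "experiment",
           scc_mode: str = "pooled") -> ExperimentResult:
    """Repeated k-fold evaluation of a model factory under a frozen plan.

    Per repetition, each fold trains a fresh predictor on the training
    partition (features standardized per ``preprocess.standardize_mode``) and
    predicts the held-out partition. With ``scc_mode='pooled'`` (default) the
    out-of-fold predictions are pooled into one vector and scored once per
    repetition; ``'fold_mean'`` averages per-fold SCCs instead.
    """
    if plan.n_samples != ds.n_samples:
        raise DataError(f"plan covers {plan.n_samples} samples, dataset has "
                        f"{ds.n_samples}")
    if scc_mode not in ("pooled", "fold_mean"):
        raise ValueError("scc_mode must be 'pooled' or 'fold_mean'")
    preprocess = preprocess or PreprocessConfig()
    samples = ds.response.sample_ids
    obs = ds.response.auc
    per_rep = np.empty(plan.repetitions)
    pooled_all = np.empty((plan.repetitions, ds.n_samples))
    for rep in range(plan.repetitions):
        pooled = np.empty(ds.n_samples)
        fold_sccs = []
        for fold_no, (train_idx, test_idx) in enumerate(plan.folds(rep)):
            train_ds = ds.subset_samples([samples[i] for i in train_idx])
            test_expr = ds.expression.subset_samples(
                [samples[i] for i in test_idx])
            if preprocess.standardize_mode == "per_partition_independent":
                train_expr = standardize_features(train_ds.expression)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", UserWarning)
                    test_expr = standardize_features(test_expr)
            else:  # fit_on_train
                mean = train_ds.expression.values.mean(axis=1, keepdims=True)
                sd = train_ds.expression.values.std(axis=1, keepdims=True)
                sd = np.where(sd == 0, 1.0, sd)
                train_expr = ExpressionMatrix(
                    train_ds.gene_ids, train_ds.response.sample_ids,
                    (train_ds.expression.values - mean) / sd)
                test_expr = ExpressionMatrix(
                    test_expr.gene_ids, test_expr.sample_ids,
                    (test_expr.values - mean) / sd)
            train_std = DrugScreenDataset(train_expr, train_ds.response,
                                          ds.cohort_id)
            fold_seed = derive_seed(plan.seed, "fold", rep, fold_no)
            predictor = model_factory(train_std, fold_seed)
            preds = np.asarray(predictor.predict(test_expr), dtype=np.float64)
            pooled[test_idx] = preds
            if scc_mode == "fold_mean" and len(test_idx) >= 3:
                fold_sccs.append(spearman(preds, obs[test_idx]))
        pooled_all[rep] = pooled
        if scc_mode == "pooled":
            per_rep[rep] = spearman(pooled, obs)
        else:
            per_rep[rep] = float(np.mean(fold_sccs))
    return ExperimentResult(label, per_rep, plan.plan_hash, pooled_all)


def _signed_rank_exact_p(w_obs: float, ranks: np.ndarray) -> float:
    """Exact two-sided p for the signed-rank statistic by subset-sum counting.

    Equivalent to enumerating all 2^n sign patterns: W+ is the sum of a
    uniformly random subset of the ranks. Average ranks can be half-integers,
    so sums are tracked on a doubled integer grid.
    """
    doubled = np.rint(2 * ranks).astype(np.int64)
    total = int(doubled.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in doubled:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:total + 1 - r]
        counts = counts + shifted
    n_patterns = 2.0 ** len(ranks)
    w2 = int(np.rint(2 * w_obs))
    p_le = counts[:w2 + 1].sum() / n_patterns
    p_ge = counts[w2:].sum() / n_patterns
    return min(1.0, 2.0 * min(p_le, p_ge))


def paired_wilcoxon(a: Sequence[float], b: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired vectors.

    Zero differences are dropped; ties in |d| get average ranks. The null
    distribution is exact (full sign enumeration) for n <= 12 non-zero
    differences and a continuity-corrected normal approximation above. If
    every difference is zero, returns 1 with a warning.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired vectors must be 1-d and equal length")
    if a.size < 5:
        raise ValueError("paired_wilcoxon needs n >= 5 pairs")
    d = a - b
    d = d[d != 0]
    if d.size == 0:
        warnings.warn("paired_wilcoxon: all differences zero; p = 1",
                      UserWarning)
        return 1.0
    ranks = rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    n = d.size
    if n <= 12:
        return _signed_rank_exact_p(w_plus, ranks)
    mean = n * (n + 1) / 4.0
    # tie correction on the variance
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - \
        float(np.sum(tie_counts ** 3 - tie_counts)) / 48.0
    z = (w_plus - mean - 0.5 * np.sign(w_plus - mean)) / sqrt(var)
    p = 2.0 * (1.0 - 0.5 * (1.0 + erf(abs(z) / sqrt(2.0))))
    return min(1.0, max(p, np.nextafter(0, 1)))


def rank_sum_test(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum p-value (two independent groups).

    Exact by enumeration of all rank splits for m + n <= 12; tie-corrected
    normal approximation above.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    m, n = a.size, b.size
    w_obs = float(ranks[:m].sum())
    if m + n <= 12:
        sums = [sum(c) for c in combinations(ranks, m)]
        sums = np.asarray(sums)
        total = comb(m + n, m)
        p_le = float(np.sum(sums <= w_obs + 1e-9)) / total
        p_ge = float(np.sum(sums >= w_obs - 1e-9)) / total
        return min(1.0, 2.0 * min(p_le, p_ge))
    mean = m * (m + n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    N = m + n
    tie_term = float(np.sum(tie_counts ** 3 - tie_counts)) / (N * (N - 1))
    var = m * n / 12.0 * (N + 1 - tie_term)
    if var == 0:
        return 1.0
    z = (w_obs - mean - 0.5 * np.sign(w_obs - mean)) / sqrt(var)
    p = 2.0 * (1.0 - 0.5 * (1.0 + erf(abs(z) / sqrt(2.0))))
    return min(1.0, max(p, np.nextafter(0, 1)))


def subsample_sweep(target: DrugScreenDataset, sizes: Sequence[int],
                    n_samplings: int,
                    experiment: Callable[[DrugScreenDataset, int], ExperimentResult],
                    seed: int) -> pd.DataFrame:
    """Re-run an experiment on random subsets of the target of given sizes.

    For each (size, sampling) cell a subset is drawn without replacement and
    ``experiment(subset, cell_seed)`` is evaluated under the standard CV
    protocol; the tidy result table has one row per cell with the mean and SD
    of the per-repetition SCCs.
    """
    n = target.n_samples
    for size in sizes:
        if size >= n:
            raise ValueError(f"subsample size {size} must be < n={n}")
        if size < 3:
            raise ValueError("subsample size must be >= 3")
    rows = []
    for size in sizes:
        for sampling in range(n_samplings):
            cell_seed = derive_seed(seed, "sweep", size, sampling)
            rng = np.random.default_rng(cell_seed)
            chosen = sorted(rng.choice(n, size=size, replace=False))
            subset = target.subset_samples(
                [target.response.sample_ids[i] for i in chosen])
            result = experiment(subset, cell_seed)
            rows.append({"size": size, "sampling": sampling,
                         "mean_scc": result.mean_scc, "sd_scc": result.sd_scc})
    return pd.DataFrame(rows)
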