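"""Orchestration of the transfer-learning experiments.

The study design this package implements compares, on one small target
cohort under identical frozen CV partitions:

* ``no_tl`` — a regressor trained from scratch on the target training folds;
* ``one_step`` — the first dense layer initialized from a model pretrained on
  one source-drug cohort, then fine-tuned on the target training folds;
* ``two_step`` — the pretrained first layer is first refined by training on
  the full domain cohort, and the refined first layer then initializes the
  target model.

Between stages only the gene-indexed first dense layer travels; upper layers
are freshly initialized at every stage. Stage-level seeds derive from
``hash(global_seed, stage, drug)`` so adding a source drug never perturbs the
draws of other stages.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .containers import (DrugScreenDataset, InputLayerWeights,
                         intersect_datasets)
from .evaluation import (CVPlan, ExperimentResult, make_cv_plan, run_cv,
                         subsample_sweep)
from .nn import (ModelState, NetworkConfig, build_model, extract_input_layer,
                 inject_input_layer, predict, train)
from .preprocess import PreprocessConfig, standardize_features
from ._seeds import derive_seed

logger = logging.getLogger(__name__)

MODES = ("no_tl", "one_step", "two_step")


@dataclass(frozen=True)
class CVParams:
    """Parameters from which a frozen CVPlan is derived for one dataset."""

    k: int = 3
    repetitions: int = 10
    strat_bins: int = 3
    seed: int = 0


@dataclass
class TransferPlan:
    """Everything one experiment needs: cohorts, network, CV design, seeds.

    All datasets must already be dataset-level preprocessed (log-scale
    expression, AUC min-max scaled to [0, 10]); call :func:`intersect_plan`
    to reduce every cohort to the common gene intersection before running.
    ``pretrain_epochs``/``refine_epochs`` override ``network.epochs`` for the
    source and domain training stages (larger cohorts usually need fewer
    passes than tiny target folds).
    """

    source: dict[str, DrugScreenDataset]
    target: DrugScreenDataset
    domain: DrugScreenDataset | None = None
    network: NetworkConfig = field(
        default_factory=lambda: NetworkConfig(n_genes=1))
    target_cv: CVParams = field(default_factory=CVParams)
    domain_cv: CVParams = field(default_factory=lambda: CVParams(k=5, strat_bins=5))
    mode: str = "two_step"
    pretrain_epochs: int | None = None
    refine_epochs: int | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")
        if self.mode == "two_step" and self.domain is None:
            raise ValueError("two_step mode requires a domain dataset")


def intersect_plan(plan: TransferPlan) -> TransferPlan:
    """Reduce every cohort in the plan to the common gene intersection."""
    names = list(plan.source)
    datasets = [plan.source[d] for d in names] + [plan.target]
    if plan.domain is not None:
        datasets.append(plan.domain)
    reduced = intersect_datasets(datasets)
    source = dict(zip(names, reduced[:len(names)]))
    target = reduced[len(names)]
    domain = reduced[len(names) + 1] if plan.domain is not None else None
    return replace(plan, source=source, target=target, domain=domain)


class _DNNPredictor:
    """Adapter giving a trained ModelState the run_cv predictor interface."""

    def __init__(self, model: ModelState):
        self.model = model

    def predict(self, expr) -> np.ndarray:
        return predict(self.model, expr)


def dnn_factory(network: NetworkConfig,
                source_weights: InputLayerWeights | None = None):
    """Model factory for run_cv: fresh seeded model per fold, optional
    first-layer initialization from source weights, then fine-tuning."""

    def factory(train_ds: DrugScreenDataset, seed: int) -> _DNNPredictor:
        cfg = replace(network, n_genes=train_ds.expression.n_genes, seed=seed)
        model = build_model(cfg, list(train_ds.gene_ids))
        if source_weights is not None:
            model = inject_input_layer(model, source_weights)
        return _DNNPredictor(train(model, train_ds))

    return factory


def _fit_full(ds: DrugScreenDataset, network: NetworkConfig, seed: int,
              epochs: int | None,
              source_weights: InputLayerWeights | None = None) -> ModelState:
    """Train one model on a whole (standardized) dataset — no CV."""
    cfg = replace(network, n_genes=ds.expression.n_genes, seed=seed,
                  epochs=network.epochs if epochs is None else epochs)
    expr = standardize_features(ds.expression)
    std = DrugScreenDataset(expr, ds.response, ds.cohort_id)
    model = build_model(cfg, list(ds.gene_ids))
    if source_weights is not None:
        model = inject_input_layer(model, source_weights)
    return train(model, std)


def pretrain_source(plan: TransferPlan, drugs: list[str] | None = None
                    ) -> dict[str, tuple[ModelState, InputLayerWeights]]:
    """Experiment-1 stage: one model per source drug on the full source cohort.

    ``drugs`` restricts pretraining to a subset; seeds derive per drug, so a
    restricted run reproduces the corresponding models of a full run exactly.
    """
    if not plan.source:
        raise ValueError("transfer plan has no source datasets")
    if drugs is not None:
        unknown = set(drugs) - set(plan.source)
        if unknown:
            raise ValueError(f"unknown source drug(s): {sorted(unknown)}")
    out = {}
    for drug, ds in plan.source.items():
        if drugs is not None and drug not in drugs:
            continue
        seed = derive_seed(plan.seed, "pretrain", drug)
        model = _fit_full(ds, plan.network, seed, plan.pretrain_epochs)
        out[drug] = (model, extract_input_layer(model))
        logger.info("pretrained source model for %s (n=%d, final MSE %.4f)",
                    drug, ds.n_samples, model.training_log[-1]
                    if model.training_log else float("nan"))
    return out


def _cv_plan_for(ds: DrugScreenDataset, cv: CVParams) -> CVPlan:
    return make_cv_plan(ds.response.auc, cv.k, cv.repetitions, cv.seed,
                        cv.strat_bins)


def no_tl_experiment(target: DrugScreenDataset, network: NetworkConfig,
                     cv: CVParams, preprocess: PreprocessConfig | None = None,
                     label: str = "no_tl") -> ExperimentResult:
    """Train-from-scratch baseline under the frozen target CV plan."""
    plan = _cv_plan_for(target, cv)
    return run_cv(target, dnn_factory(network), plan, preprocess, label)


def one_step_transfer(source_w: InputLayerWeights, target: DrugScreenDataset,
                      network: NetworkConfig, cv: CVParams,
                      preprocess: PreprocessConfig | None = None,
                      label: str = "one_step") -> ExperimentResult:
    """Source-to-target transfer evaluated by the frozen target CV plan."""
    missing = set(target.gene_ids) - set(source_w.gene_ids)
    if missing:
        raise ValueError(
            f"{len(missing)} target gene(s) not covered by source weights")
    plan = _cv_plan_for(target, cv)
    return run_cv(target, dnn_factory(network, source_w), plan, preprocess,
                  label)


def select_best_source(results: dict[str, ExperimentResult]) -> str:
    """Pick the source drug with maximal mean SCC (ties: lexicographic)."""
    if not results:
        raise ValueError("no source results to select from")
    ranked = sorted(results.items(), key=lambda kv: (-kv[1].mean_scc, kv[0]))
    best = ranked[0][0]
    margins = {d: round(r.mean_scc, 4) for d, r in results.items()}
    logger.info("selected source drug %s; mean SCCs %s", best, margins)
    return best


@dataclass
class TwoStepResult:
    """Outcome of a full two-step run: stage weights and the target score."""

    result: ExperimentResult
    selected_drug: str
    source_weights: InputLayerWeights
    refined_weights: InputLayerWeights
    domain_results: dict[str, ExperimentResult] = field(default_factory=dict)
    refined_model: ModelState | None = None


def two_step_transfer(plan: TransferPlan, source_drug: str | None = None,
                      refine: bool = True,
                      label: str = "two_step") -> TwoStepResult:
    """Pretrain -> (select) -> refine on domain -> fine-tune/evaluate on target.

    If ``source_drug`` is None and several sources exist, the drug whose
    one-step transfer scores best on the domain cohort (its own frozen CV
    plan) is selected. The refinement stage trains on the *full* domain
    cohort initialized with the selected source's first layer; its first
    layer then initializes the target models. With ``refine=False`` the
    refinement stage is skipped and the run reproduces one-step transfer
    exactly (identical seeds, identical partitions).
    """
    pretrained = pretrain_source(
        plan, drugs=None if source_drug is None else [source_drug])
    domain_results: dict[str, ExperimentResult] = {}
    if source_drug is None:
        if len(pretrained) == 1:
            source_drug = next(iter(pretrained))
        else:
            if plan.domain is None:
                raise ValueError("source selection requires a domain dataset")
            for drug, (_, w) in pretrained.items():
                domain_results[drug] = one_step_transfer(
                    w, plan.domain, plan.network, plan.domain_cv,
                    plan.preprocess, label=f"one_step_domain_{drug}")
            source_drug = select_best_source(domain_results)
    if source_drug not in pretrained:
        raise ValueError(f"unknown source drug '{source_drug}'")
    source_w = pretrained[source_drug][1]

    refined_model = None
    if refine:
        if plan.domain is None:
            raise ValueError("refinement requires a domain dataset")
        refine_seed = derive_seed(plan.seed, "refine", source_drug)
        refined_model = _fit_full(plan.domain, plan.network, refine_seed,
                                  plan.refine_epochs, source_weights=source_w)
        refined_w = extract_input_layer(refined_model)
    else:
        refined_w = source_w

    result = one_step_transfer(refined_w, plan.target, plan.network,
                               plan.target_cv, plan.preprocess, label=label)
    return TwoStepResult(result, source_drug, source_w, refined_w,
                         domain_results, refined_model)


def run_mode(plan: TransferPlan, mode: str | None = None) -> ExperimentResult:
    """Run one comparison arm (no_tl / one_step / two_step) on the target."""
    mode = mode or plan.mode
    if mode == "no_tl":
        return no_tl_experiment(plan.target, plan.network, plan.target_cv,
                                plan.preprocess)
    if mode == "one_step":
        pretrained = pretrain_source(plan)
        if len(pretrained) > 1 and plan.domain is not None:
            two = two_step_transfer(plan, refine=False, label="one_step")
            return two.result
        drug = next(iter(pretrained))
        return one_step_transfer(pretrained[drug][1], plan.target,
                                 plan.network, plan.target_cv, plan.preprocess,
                                 label="one_step")
    if mode == "two_step":
        return two_step_transfer(plan).result
    raise ValueError(f"unknown mode '{mode}'")


def sweep_two_step(plan: TransferPlan, sizes, n_samplings: int,
                   refined_w: InputLayerWeights | None = None) -> pd.DataFrame:
    """Target-size sensitivity sweep.

    The transferred first layer is computed once from the full pipeline and
    held fixed across all subset sizes; each (size, sampling) cell re-runs
    the standard repeated CV on a random target subset.
    """
    if refined_w is None:
        refined_w = two_step_transfer(plan).refined_weights

    def experiment(subset: DrugScreenDataset, cell_seed: int) -> ExperimentResult:
        cv = replace(plan.target_cv, seed=cell_seed)
        return one_step_transfer(refined_w, subset, plan.network, cv,
                                 plan.preprocess, label="sweep")

    return subsample_sweep(plan.target, sizes, n_samplings, experiment,
                           plan.seed)


def grid_search(ds: DrugScreenDataset, network: NetworkConfig, cv: CVParams,
                learning_rates=(1e-4, 1e-3), epoch_grid=(50, 100),
                preprocess: PreprocessConfig | None = None) -> tuple[NetworkConfig, pd.DataFrame]:
    """Small CV grid over optimizer settings on one (source) cohort.

    Returns the best configuration by mean SCC and the full tidy grid table.
    """
    rows = []
    best_cfg, best_scc = None, -np.inf
    for lr, ep in itertools.product(learning_rates, epoch_grid):
        cfg = replace(network, learning_rate=lr, epochs=ep)
        res = run_cv(ds, dnn_factory(cfg), _cv_plan_for(ds, cv), preprocess,
                     label=f"grid_lr{lr}_ep{ep}")
        rows.append({"learning_rate": lr, "epochs": ep,
                     "mean_scc": res.mean_scc, "sd_scc": res.sd_scc})
        if res.mean_scc > best_scc:
            best_cfg, best_scc = cfg, res.mean_scc
    return best_cfg, pd.DataFrame(rows)
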