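"""Canonical study conditions for the synthetic transfer experiments.

This module pins, in one place, the default synthetic scenario and the
scaled-down network used throughout the test suite, the CLI examples and the
reproduction script: a mechanism-matched source drug (s = 0.9, n = 700), a
mechanism-unrelated source drug (s = 0, n = 700), a domain cohort of 80 and a
target cohort of 22 samples over 500 genes, evaluated by 3-fold CV with 10
repetitions on the target. The network keeps the reference architecture's
shape (two hidden layers, sigmoid/softplus/softplus, dropout 0.3/0.1, L2
1e-4) at reduced width and epoch count so a full comparison runs in minutes
on one CPU; docs/methods.md discusses the choice.
"""

from __future__ import annotations

from dataclasses import replace

from .nn import NetworkConfig
from .pipeline import CVParams, TransferPlan, intersect_plan
from .preprocess import PreprocessConfig, minmax_scale_response
from .simulate import SyntheticConfig, SyntheticTriplet, simulate_triplet
from .containers import DrugScreenDataset
from ._seeds import derive_seed

#: scaled-down regressor used by the default synthetic scenario
SCENARIO_NETWORK = NetworkConfig(
    n_genes=1,  # overridden per stage
    hidden_sizes=(100, 20),
    activations=("sigmoid", "softplus", "softplus"),
    dropout=(0.3, 0.1),
    reg_strength=1e-4,
    learning_rate=1e-3,
    epochs=80,
    batch_size=32,
)

SCENARIO_PRETRAIN_EPOCHS = 30
SCENARIO_REFINE_EPOCHS = 60


def default_scenario_config(seed: int = 0) -> SyntheticConfig:
    """The default synthetic triplet (see module docstring) at a given seed."""
    return SyntheticConfig(seed=seed)


def scale_dataset(ds: DrugScreenDataset, lo: float = 0.0,
                  hi: float = 10.0) -> DrugScreenDataset:
    """Min-max scale a dataset's AUC in place of the raw table."""
    return DrugScreenDataset(ds.expression,
                             minmax_scale_response(ds.response, lo, hi),
                             ds.cohort_id)


def scenario_plan(seed: int = 0,
                  cfg: SyntheticConfig | None = None,
                  triplet: SyntheticTriplet | None = None) -> TransferPlan:
    """Simulate (or take) a triplet and assemble the ready-to-run plan.

    Responses are min-max scaled to [0, 10] per cohort, gene spaces reduced
    to the common intersection, and the CV seeds derived from ``seed`` so the
    partitions are frozen across every mode compared at that seed.
    """
    if triplet is None:
        triplet = simulate_triplet(cfg or default_scenario_config(seed))
    source = {d: scale_dataset(ds) for d, ds in triplet.source.items()}
    domain = scale_dataset(triplet.domain)
    target = scale_dataset(triplet.target)
    plan = TransferPlan(
        source=source, target=target, domain=domain,
        network=SCENARIO_NETWORK,
        target_cv=CVParams(k=3, repetitions=10, strat_bins=3,
                           seed=derive_seed(seed, "cv", "target")),
        domain_cv=CVParams(k=5, repetitions=5, strat_bins=5,
                           seed=derive_seed(seed, "cv", "domain")),
        pretrain_epochs=SCENARIO_PRETRAIN_EPOCHS,
        refine_epochs=SCENARIO_REFINE_EPOCHS,
        preprocess=PreprocessConfig(),
        seed=seed,
    )
    return intersect_plan(plan)


def small_scenario_plan(seed: int = 0) -> TransferPlan:
    """A miniature triplet for fast functional tests (not the study scale)."""
    cfg = SyntheticConfig(
        n_genes=60, latent_dim=4,
        drugs=(replace(SyntheticConfig().drugs[0], n_samples=60),
               replace(SyntheticConfig().drugs[1], n_samples=60)),
        domain_n=30, target_n=16, seed=seed)
    plan = scenario_plan(seed, cfg=cfg)
    return replace(
        plan,
        network=replace(SCENARIO_NETWORK, hidden_sizes=(20, 8), epochs=20),
        target_cv=replace(plan.target_cv, repetitions=3),
        domain_cv=replace(plan.domain_cv, k=3, repetitions=2, strat_bins=3),
        pretrain_epochs=10, refine_epochs=10)
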