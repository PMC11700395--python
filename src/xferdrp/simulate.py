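"""Linked synthetic source/domain/target cohorts for transfer experiments.

The generator emulates the structure of a multi-cohort drug screen: one large
heterogeneous source cohort screened with several drugs, one medium
domain-specific cohort and one small target cohort, with partially shared
response mechanisms between drugs and partially overlapping gene spaces.

Generative model
----------------
Each sample carries a latent state ``z ~ N(0, I_latent)``. Expression is
``x = B z + cohort_shift + eps_expr`` with a fixed seeded loading matrix
``B`` over a global gene universe; each gene loads on a single latent factor
with an N(0, 1) coefficient, so under the default expression noise (sd 3)
individual genes are only weakly informative and reliable latent recovery
needs many genes and many samples — which is what makes the small-cohort
task hard and pretraining on the large source cohort valuable.
Each cohort observes a random subset of the universe (a shared core of
``gene_overlap * n_genes`` genes plus a cohort-specific remainder) in its own
random gene order, which exercises gene-addressed weight transfer exactly as
mismatched platforms do.

The target drug acts through a unit mechanism vector ``w*``. A source drug
with mechanism similarity ``s`` acts through ``w_d = s w* + sqrt(1-s^2)
w_perp``, so ``s = 1`` shares the response mechanism fully and ``s = 0`` not
at all. Raw response is ``r = logistic(z . w_d + eps_auc)`` in (0, 1);
``skew`` applies ``r' = r^(1/(1+skew))``, pushing mass toward the resistant
bound (high viability AUC) the way a screen of a broadly ineffective drug
looks. AUC tables are returned raw; callers apply min-max scaling to [0, 10].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit
from scipy.stats import skew as _skewness

from .containers import DrugScreenDataset, ExpressionMatrix, ResponseTable
from ._seeds import derive_seed


@dataclass(frozen=True)
class DrugSpec:
    """One source drug: id, mechanism similarity to the target drug in [0,1],
    resistance skew >= 0, and cohort size."""

    drug_id: str
    mechanism_similarity: float = 1.0
    skew: float = 0.0
    n_samples: int = 700

    def __post_init__(self) -> None:
        if not 0.0 <= self.mechanism_similarity <= 1.0:
            raise ValueError("mechanism_similarity must lie in [0, 1]")
        if self.skew < 0:
            raise ValueError("skew must be >= 0")
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic triplet.

    Defaults mirror the modelled cohort structure: two source drugs of 700
    samples each (one mechanism-matched at s = 0.9, one unrelated at s = 0),
    a domain cohort of 80 and a target cohort of 22 samples, 500 genes with a
    90% shared core, and moderate noise on both expression and response.
    """

    n_genes: int = 500
    latent_dim: int = 8
    drugs: tuple[DrugSpec, ...] = (
        DrugSpec("DRUG_A", mechanism_similarity=0.9, skew=0.0, n_samples=700),
        DrugSpec("DRUG_B", mechanism_similarity=0.0, skew=0.0, n_samples=700),
    )
    domain_n: int = 80
    target_n: int = 22
    noise_sd_expr: float = 3.0
    noise_sd_auc: float = 0.5
    cohort_shift_sd: float = 0.3
    gene_overlap: float = 0.9
    target_drug: str = "TARGET_DRUG"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.latent_dim < 1:
            raise ValueError("n_genes and latent_dim must be positive")
        if self.domain_n < 2 or self.target_n < 2:
            raise ValueError("cohort sizes must be >= 2")
        if not 0.0 < self.gene_overlap <= 1.0:
            raise ValueError("gene_overlap must lie in (0, 1]")
        if min(self.noise_sd_expr, self.noise_sd_auc, self.cohort_shift_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")
        if not self.drugs:
            raise ValueError("at least one source drug is required")
        ids = [d.drug_id for d in self.drugs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate source drug ids")


@dataclass
class SyntheticTriplet:
    source: dict[str, DrugScreenDataset]
    domain: DrugScreenDataset
    target: DrugScreenDataset

    def all_datasets(self) -> list[DrugScreenDataset]:
        return [*self.source.values(), self.domain, self.target]


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _mechanism_vectors(cfg: SyntheticConfig) -> dict[str, np.ndarray]:
    """Target mechanism w* plus one vector per source drug at its similarity."""
    rng = np.random.default_rng(derive_seed(cfg.seed, "mechanism"))
    w_star = _unit(rng.standard_normal(cfg.latent_dim))
    vectors = {cfg.target_drug: w_star}
    for spec in cfg.drugs:
        drng = np.random.default_rng(
            derive_seed(cfg.seed, "mechanism", spec.drug_id))
        raw = drng.standard_normal(cfg.latent_dim)
        perp = raw - (raw @ w_star) * w_star
        perp = _unit(perp)
        s = spec.mechanism_similarity
        vectors[spec.drug_id] = s * w_star + np.sqrt(max(0.0, 1 - s * s)) * perp
    return vectors


def _gene_universe(cfg: SyntheticConfig) -> tuple[list[str], np.ndarray]:
    """Gene ids and the fixed loading matrix B (universe x latent).

    Loadings are sparse: each gene belongs to one latent factor with an
    N(0, 1) coefficient, mimicking expression programs in which a gene tracks
    one dominant biological axis. Combined with the default expression noise
    each gene is only weakly informative on its own, so reliable latent
    recovery needs many genes and many samples.
    """
    width = max(4, len(str(cfg.n_genes)))
    genes = [f"G{i:0{width}d}" for i in range(cfg.n_genes)]
    rng = np.random.default_rng(derive_seed(cfg.seed, "loadings"))
    B = np.zeros((cfg.n_genes, cfg.latent_dim))
    factor = rng.integers(0, cfg.latent_dim, size=cfg.n_genes)
    B[np.arange(cfg.n_genes), factor] = rng.standard_normal(cfg.n_genes)
    return genes, B


def _cohort_genes(cfg: SyntheticConfig, genes: list[str],
                  cohort_key: str) -> list[str]:
    """Shared core + cohort-specific subset of the remainder, shuffled order."""
    rng = np.random.default_rng(derive_seed(cfg.seed, "genes", cohort_key))
    n_core = int(round(cfg.gene_overlap * cfg.n_genes))
    core = genes[:n_core]
    extras = [g for g in genes[n_core:] if rng.random() < 0.5]
    chosen = core + extras
    order = rng.permutation(len(chosen))
    return [chosen[i] for i in order]


def _simulate_cohort(cfg: SyntheticConfig, B: np.ndarray, genes: list[str],
                     cohort_key: str, cohort_id: str, drug_id: str,
                     w: np.ndarray, n: int, skew_param: float) -> DrugScreenDataset:
    gene_index = {g: i for i, g in enumerate(genes)}
    cohort_genes = _cohort_genes(cfg, genes, cohort_key)
    rows = [gene_index[g] for g in cohort_genes]
    rng = np.random.default_rng(derive_seed(cfg.seed, "samples", cohort_key))
    z = rng.standard_normal((n, cfg.latent_dim))
    shift = rng.normal(0.0, cfg.cohort_shift_sd, size=len(rows))
    eps = rng.normal(0.0, cfg.noise_sd_expr, size=(len(rows), n))
    values = B[rows, :] @ z.T + shift[:, None] + eps
    lin = z @ w + rng.normal(0.0, cfg.noise_sd_auc, size=n)
    r = expit(lin) ** (1.0 / (1.0 + skew_param))
    sample_ids = [f"{cohort_key}_{i:04d}" for i in range(n)]
    expr = ExpressionMatrix(cohort_genes, sample_ids, values,
                            meta={"cohort": cohort_id, "log_transformed": True,
                                  "synthetic": True})
    resp = ResponseTable(sample_ids, r, drug=drug_id)
    return DrugScreenDataset(expr, resp, cohort_id)


def simulate_triplet(cfg: SyntheticConfig) -> SyntheticTriplet:
    """Generate the linked source/domain/target cohorts.

    Deterministic under ``cfg.seed``; every cohort and drug block draws from
    its own derived seed, so adding a source drug never perturbs the draws of
    the others or of the domain/target cohorts.
    """
    genes, B = _gene_universe(cfg)
    mechanisms = _mechanism_vectors(cfg)
    source = {}
    for spec in cfg.drugs:
        source[spec.drug_id] = _simulate_cohort(
            cfg, B, genes, f"source_{spec.drug_id}", "source", spec.drug_id,
            mechanisms[spec.drug_id], spec.n_samples, spec.skew)
    domain = _simulate_cohort(cfg, B, genes, "domain", "domain",
                              cfg.target_drug, mechanisms[cfg.target_drug],
                              cfg.domain_n, 0.0)
    target = _simulate_cohort(cfg, B, genes, "target", "target",
                              cfg.target_drug, mechanisms[cfg.target_drug],
                              cfg.target_n, 0.0)
    return SyntheticTriplet(source, domain, target)


def cohort_summary(ds: DrugScreenDataset, resistance_cutoff: float = 0.95) -> dict:
    """Distribution diagnostics of a cohort's response.

    Reports sample and gene counts, AUC quantiles, the moment skewness
    coefficient and the fraction of samples above a resistance cutoff (on the
    same scale as the stored AUC).
    """
    auc = ds.response.auc
    qs = np.quantile(auc, [0.0, 0.25, 0.5, 0.75, 1.0])
    return {
        "cohort_id": ds.cohort_id,
        "drug": ds.drug,
        "n_samples": ds.n_samples,
        "n_genes": ds.expression.n_genes,
        "auc_min": float(qs[0]), "auc_q25": float(qs[1]),
        "auc_median": float(qs[2]), "auc_q75": float(qs[3]),
        "auc_max": float(qs[4]),
        "skewness": float(_skewness(auc)),
        "fraction_resistant": float(np.mean(auc > resistance_cutoff)),
        "resistance_cutoff": resistance_cutoff,
    }


def write_triplet(triplet: SyntheticTriplet, out_dir) -> dict[str, dict[str, str]]:
    """Write each cohort as expression TSV + response CSV; returns the paths."""
    from pathlib import Path
    from .io import write_expression, write_response

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, dict[str, str]] = {}
    named = {f"source_{d}": ds for d, ds in triplet.source.items()}
    named["domain"] = triplet.domain
    named["target"] = triplet.target
    for name, ds in named.items():
        e = out / f"{name}_expression.tsv"
        r = out / f"{name}_response.csv"
        write_expression(ds.expression, e)
        write_response(ds.response, r)
        paths[name] = {"expression": str(e), "response": str(r)}
    return paths
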