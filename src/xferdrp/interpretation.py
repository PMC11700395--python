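"""Per-gene importance from first-layer weights; preranked-list export.

A trained model's first dense layer assigns each gene H1 outgoing weights.
Collapsing them to one scalar per gene gives a ranking of gene influence on
the predicted response; the signed sum (default) preserves direction, so an
external preranked enrichment tool can distinguish pathways loaded in the
sensitive vs the resistant direction. The enrichment statistic itself is out
of scope — only the standard two-column ``.rnk`` input is produced.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import InputLayerWeights

AGGREGATIONS = ("sum", "mean", "l2")


@dataclass
class GeneScoreTable:
    """Signed (or unsigned, for l2) per-gene scores, exported sorted."""

    gene_ids: list[str]
    score: np.ndarray
    aggregation: str

    def __post_init__(self) -> None:
        self.score = np.asarray(self.score, dtype=np.float64)
        if self.score.shape != (len(self.gene_ids),):
            raise ValueError("score length does not match gene_ids")

    def sorted(self) -> "GeneScoreTable":
        """Descending by score; ties broken by gene id ascending."""
        order = sorted(range(len(self.gene_ids)),
                       key=lambda i: (-self.score[i], self.gene_ids[i]))
        return GeneScoreTable([self.gene_ids[i] for i in order],
                              self.score[order], self.aggregation)

    def to_frame(self) -> pd.DataFrame:
        t = self.sorted()
        return pd.DataFrame({"gene_id": t.gene_ids, "score": t.score})

    def top(self, n: int) -> pd.DataFrame:
        return self.to_frame().head(n)


def gene_weight_scores(w: InputLayerWeights,
                       aggregation: str = "sum") -> GeneScoreTable:
    """Collapse the genes x H1 first-layer weight matrix to one score per gene.

    ``sum`` (default) and ``mean`` are signed and rank identically for a fixed
    H1; ``l2`` is unsigned (row norm).
    """
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}")
    if aggregation == "sum":
        score = w.W.sum(axis=1)
    elif aggregation == "mean":
        score = w.W.mean(axis=1)
    else:
        score = np.sqrt((w.W ** 2).sum(axis=1))
    return GeneScoreTable(list(w.gene_ids), score, aggregation)


def write_rnk(table: GeneScoreTable, path: str | Path) -> None:
    """Write the standard two-column tab-delimited preranked file.

    Rows sorted by score descending (ties by gene id), no header — the format
    preranked enrichment tools consume.
    """
    t = table.sorted()
    with open(path, "w") as fh:
        for g, s in zip(t.gene_ids, t.score):
            fh.write(f"{g}\t{float(s)!r}\n")


def read_rnk(path: str | Path) -> GeneScoreTable:
    """Read a two-column preranked file back (aggregation unknown)."""
    genes, scores = [], []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            g, s = line.rstrip("\n").split("\t")
            genes.append(g)
            scores.append(float(s))
    return GeneScoreTable(genes, np.asarray(scores), "unknown")
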