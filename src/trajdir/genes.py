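"""Gene-level interpretation of a directionality center.

A trajectory's direction is a unit vector in the analysis space.  When the
analysis ran on principal components, the PCA loading matrix maps that
vector back to gene space: each gene's score is the inner product of its
loading row with the center, i.e. the rate at which the gene changes per
unit of travel along the trajectory's direction.  Positive scores are
genes up-regulated along the trajectory, negative scores down-regulated.
When the analysis ran directly in gene space the identity loading matrix
reproduces the center itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LoadingMatrix",
    "GeneScoreTable",
    "direction_gene_scores",
    "top_k",
]


@dataclass
class LoadingMatrix:
    """Genes x components loading matrix with identifiers."""

    loadings: np.ndarray
    gene_ids: Sequence[str]
    component_ids: Optional[Sequence[str]] = None

    def __post_init__(self) -> None:
        self.loadings = np.asarray(self.loadings, dtype=float)
        if self.loadings.ndim != 2:
            raise ValueError("loadings must be 2-D (genes, components)")
        g, n = self.loadings.shape
        if len(self.gene_ids) != g:
            raise ValueError("gene_ids length mismatch")
        if len(set(self.gene_ids)) != g:
            raise ValueError("duplicate gene_ids")
        if self.component_ids is not None and len(self.component_ids) != n:
            raise ValueError("component_ids length mismatch")

    @classmethod
    def identity(cls, gene_ids: Sequence[str]) -> "LoadingMatrix":
        """Identity loadings for analyses run directly in gene space."""
        return cls(np.eye(len(gene_ids)), list(gene_ids))

    def truncated(self, first_k: int) -> "LoadingMatrix":
        cids = (None if self.component_ids is None
                else list(self.component_ids)[:first_k])
        return LoadingMatrix(self.loadings[:, :first_k],
                             self.gene_ids, cids)


@dataclass
class GeneScoreTable:
    """Per-gene scores, sorted descending (ties broken by gene id)."""

    table: pd.DataFrame  # columns: gene_id, score

    @property
    def gene_ids(self) -> list[str]:
        return self.table["gene_id"].tolist()

    @property
    def scores(self) -> np.ndarray:
        return self.table["score"].to_numpy()

    def score_of(self, gene_id: str) -> float:
        row = self.table.loc[self.table["gene_id"] == gene_id, "score"]
        if row.empty:
            raise KeyError(gene_id)
        return float(row.iloc[0])


def direction_gene_scores(center: np.ndarray, loadings: LoadingMatrix,
                          component_weights: Optional[np.ndarray] = None,
                          ) -> GeneScoreTable:
    """Score each gene by the projection of the direction onto its axis.

    ``component_weights`` (e.g. per-component variances) optionally rescale
    the center before projection; by default scores are plain inner
    products, consistent with unit-norm directions against unit-norm
    loadings.
    """
    center = np.asarray(center, dtype=float)
    if center.shape != (loadings.loadings.shape[1],):
        raise ValueError(
            f"center has {center.shape[0]} components but loadings have "
            f"{loadings.loadings.shape[1]}")
    if component_weights is not None:
        component_weights = np.asarray(component_weights, dtype=float)
        if component_weights.shape != center.shape:
            raise ValueError("component_weights length mismatch")
        center = center * component_weights
    scores = loadings.loadings @ center
    df = pd.DataFrame({"gene_id": list(loadings.gene_ids), "score": scores})
    df = df.sort_values(["score", "gene_id"],
                        ascending=[False, True],
                        kind="mergesort").reset_index(drop=True)
    return GeneScoreTable(table=df)


def top_k(table: GeneScoreTable, k: int) -> tuple[list[str], list[str]]:
    """Top k up-regulated (descending) and down-regulated (ascending) genes.

    Ties are broken by the lexicographically smaller gene id, so the output
    is deterministic.
    """
    g = len(table.table)
    if not 1 <= k <= g:
        raise ValueError(f"k = {k} outside [1, {g}]")
    up = table.table["gene_id"].head(k).tolist()
    down_df = table.table.sort_values(
        ["score", "gene_id"], ascending=[True, True], kind="mergesort")
    down = down_df["gene_id"].head(k).tolist()
    return up, down
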