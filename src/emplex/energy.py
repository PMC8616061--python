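"""Transcriptional diversity and correlation-network single-cell energy.

Three per-cell quantities proxy developmental potential and EMT
plasticity:

* **transcriptional diversity** — the number of genes with at least one
  count; independent of any normalization;
* **single-cell energy** — an entropy-like score over a gene-gene
  network built by thresholding pairwise expression correlations at
  ``|r| >= tau`` (default 0.4). Expression is rescaled per gene to
  ``z in [0, 1]`` by dividing by the gene's maximum, and each networked,
  expressed gene contributes ``-z * ln(z / sum of neighbor z)``; the
  energy is maximized when many connected genes are broadly
  co-expressed;
* **EMT circuit energy** — the same energy computed after restricting
  the matrix to the union of the epithelial and mesenchymal signature
  genes, so it is maximal in hybrid states co-expressing both programs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from emplex.errors import ValidationError
from emplex.io import CountMatrix, ExpressionMatrix
from emplex.scoring import GeneSignature

__all__ = [
    "GeneNetwork",
    "transcriptional_diversity",
    "build_gene_network",
    "single_cell_energy",
    "emt_circuit_energy",
]


@dataclass
class GeneNetwork:
    """Correlation-thresholded gene-gene network."""

    nodes: list[str]
    edges: list[tuple[str, str, float]]  # (gene_i, gene_j, correlation)
    tau: float

    def __post_init__(self) -> None:
        for a, b, w in self.edges:
            if a == b:
                raise ValidationError("self-edges are not allowed")
            if abs(w) < self.tau - 1e-12:
                raise ValidationError(
                    f"edge ({a}, {b}) weight {w} below threshold {self.tau}"
                )

    def neighbors(self) -> dict[str, list[str]]:
        adj: dict[str, list[str]] = {g: [] for g in self.nodes}
        for a, b, _ in self.edges:
            adj[a].append(b)
            adj[b].append(a)
        return adj

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def transcriptional_diversity(raw: CountMatrix) -> np.ndarray:
    """Number of expressed genes (count >= 1) per cell, on raw counts."""
    return (raw.values > 0).sum(axis=0)


def build_gene_network(
    expr: ExpressionMatrix, tau: float = 0.4, method: str = "pearson"
) -> GeneNetwork:
    """Connect gene pairs whose expression correlation across all cells
    satisfies ``|r| >= tau``; zero-variance genes get no edges."""
    if not (0.0 < tau <= 1.0):
        raise ValidationError("tau must lie in (0, 1]")
    if expr.n_cells < 3:
        raise ValidationError("need >= 3 cells to estimate correlations")
    if method not in {"pearson", "spearman"}:
        raise ValidationError("method must be 'pearson' or 'spearman'")

    X = expr.values.astype(float)
    if method == "spearman":
        X = rankdata(X, axis=1)
    sd = X.std(axis=1)
    variable = sd > 0
    corr = np.zeros((expr.n_genes, expr.n_genes))
    if variable.sum() >= 2:
        sub = np.corrcoef(X[variable])
        corr[np.ix_(variable, variable)] = sub
    edges = []
    idx_i, idx_j = np.triu_indices(expr.n_genes, k=1)
    strong = np.abs(corr[idx_i, idx_j]) >= tau
    for i, j in zip(idx_i[strong], idx_j[strong]):
        edges.append((expr.gene_names[i], expr.gene_names[j], float(corr[i, j])))
    return GeneNetwork(nodes=list(expr.gene_names), edges=edges, tau=tau)


def single_cell_energy(
    expr: ExpressionMatrix, net: GeneNetwork
) -> np.ndarray:
    """Entropy-like per-cell energy over the gene network.

    Expression is rescaled per gene by its maximum over cells
    (``z in [0, 1]``; 0 if the max is 0); the cell's energy sums
    ``-z_i * ln(z_i / sum_{j in N(i)} z_j)`` over genes that are both
    expressed (``z_i > 0``) and networked, with a term set to 0 when the
    neighbor sum vanishes. Isolated genes never contribute.
    """
    gene_index = {g: i for i, g in enumerate(expr.gene_names)}
    missing = [g for g in net.nodes if g not in gene_index]
    if missing:
        raise ValidationError(f"network genes absent from matrix: {missing[:5]}")

    X = expr.values.astype(float)
    gmax = X.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        Z = np.where(gmax[:, None] > 0, X / np.maximum(gmax[:, None], 1e-300), 0.0)

    A = np.zeros((expr.n_genes, expr.n_genes))
    for a, b, _ in net.edges:
        i, j = gene_index[a], gene_index[b]
        A[i, j] = A[j, i] = 1.0
    degree = A.sum(axis=1)
    NS = A @ Z  # neighbor z-sum, gene x cell
    active = (Z > 0) & (NS > 0) & (degree[:, None] > 0)
    terms = np.zeros_like(Z)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(active, Z / np.maximum(NS, 1e-300), 1.0)
    terms[active] = -Z[active] * np.log(ratio[active])
    return terms.sum(axis=0)


def emt_circuit_energy(
    expr: ExpressionMatrix,
    sig_e: GeneSignature,
    sig_m: GeneSignature,
    tau: float = 0.4,
    method: str = "pearson",
) -> np.ndarray:
    """Single-cell energy on the matrix restricted to the union of the
    epithelial and mesenchymal signature genes (the EMT circuit)."""
    wanted = list(dict.fromkeys(list(sig_e.genes) + list(sig_m.genes)))
    present = [g for g in wanted if g in set(expr.gene_names)]
    if len(present) < 2:
        raise ValidationError(
            "need >= 2 signature genes present to build the EMT circuit"
        )
    gene_index = {g: i for i, g in enumerate(expr.gene_names)}
    rows = [gene_index[g] for g in present]
    sub = ExpressionMatrix(
        values=expr.values[rows, :],
        gene_names=present,
        cell_names=list(expr.cell_names),
        provenance=expr.provenance,
    )
    net = build_gene_network(sub, tau=tau, method=method)
    return single_cell_energy(sub, net)
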