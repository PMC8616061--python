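"""Consensus clustering, model selection and EMT trajectory inference.

The stage mirrors quantitative transition-cell trajectory analysis:

1. a consensus cell-cell similarity matrix is built from an ensemble of
   k-means runs over PCA embeddings (sweeping component count and k);
2. the number of clusters is chosen by the largest gap between
   consecutive eigenvalues of the similarity matrix, constrained to a
   minimum of three so at least one intermediate state can appear;
3. soft memberships come from a symmetric nonnegative matrix
   factorization ``S ~ H H^T``; cells without a dominant membership are
   flagged as transition cells;
4. the trajectory starts at the cluster with the highest epithelial and
   lowest mesenchymal score and follows transition-cell-weighted edges;
   pseudotime interpolates between consecutive clusters using the two
   largest memberships.

Base k-means runs use a deterministic farthest-point initialization so
the whole stage is equivariant under permutations of the cells.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA

from emplex.errors import ValidationError
from emplex.io import ExpressionMatrix

__all__ = [
    "ConsensusResult",
    "SoftMembership",
    "Trajectory",
    "build_consensus",
    "select_k",
    "soft_cluster",
    "infer_trajectory",
]


@dataclass
class ConsensusResult:
    """Consensus co-clustering similarity and its spectrum."""

    similarity: np.ndarray  # cell x cell, entries in [0, 1], diagonal 1
    eigenvalues: np.ndarray  # descending
    runs: int
    cell_names: list[str] | None = None

    def __post_init__(self) -> None:
        S = np.asarray(self.similarity, dtype=float)
        if not np.allclose(S, S.T, atol=1e-12):
            raise ValidationError("similarity must be symmetric")
        if ((S < -1e-12) | (S > 1 + 1e-12)).any():
            raise ValidationError("similarity entries must lie in [0, 1]")
        if not np.allclose(np.diag(S), 1.0):
            raise ValidationError("similarity diagonal must be 1")
        self.similarity = S


@dataclass
class SoftMembership:
    """Row-stochastic cell x cluster memberships with transition flags."""

    H: np.ndarray
    hard_label: np.ndarray
    transition_flag: np.ndarray
    delta: float
    cell_names: list[str] | None = None

    def __post_init__(self) -> None:
        H = np.asarray(self.H, dtype=float)
        if (H < 0).any():
            raise ValidationError("memberships must be nonnegative")
        if not np.allclose(H.sum(axis=1), 1.0, atol=1e-9):
            raise ValidationError("membership rows must sum to 1")
        if not np.array_equal(self.hard_label, H.argmax(axis=1)):
            raise ValidationError("hard_label inconsistent with H")
        self.H = H

    @property
    def k(self) -> int:
        return self.H.shape[1]


@dataclass
class Trajectory:
    """An ordered path through the clusters with per-cell pseudotime."""

    start_cluster: int
    cluster_order: list[int]
    edge_weights: dict[tuple[int, int], int]
    pseudotime: np.ndarray
    alt_paths: list[tuple[list[int], int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.cluster_order[0] != self.start_cluster:
            raise ValidationError("cluster_order must begin at start_cluster")


def _farthest_point_centers(X: np.ndarray, k: int) -> np.ndarray:
    """Deterministic, order-independent k-means init: start from the
    point of largest norm, then repeatedly add the point farthest from
    the chosen centers."""
    norms = (X**2).sum(axis=1)
    centers = [int(np.argmax(norms))]
    d2 = ((X - X[centers[0]]) ** 2).sum(axis=1)
    for _ in range(1, k):
        nxt = int(np.argmax(d2))
        centers.append(nxt)
        d2 = np.minimum(d2, ((X - X[nxt]) ** 2).sum(axis=1))
    return X[centers]


def build_consensus(
    expr: ExpressionMatrix,
    n_runs: int = 100,
    k_range: tuple[int, ...] = (3, 4, 5, 6, 7, 8),
    seed: int = 0,
    pca_components: tuple[int, ...] = (5, 10, 15),
) -> ConsensusResult:
    """Build the consensus similarity from a k-means ensemble.

    Each base run clusters the cells with k-means on the first ``d``
    principal components, for (d, k) combinations cycled through in a
    seeded order; ``similarity[i, j]`` is the fraction of runs in which
    cells i and j land in the same cluster. Eigenvalues of the
    similarity matrix are returned in descending order.
    """
    if n_runs < 1:
        raise ValidationError("n_runs must be >= 1")
    n_cells = expr.n_cells
    if n_cells < 2:
        raise ValidationError("need at least 2 cells")

    X = expr.values.T  # cells x genes
    max_d = min(max(pca_components), n_cells - 1, expr.n_genes)
    dims = sorted({min(d, max_d) for d in pca_components})
    ks = sorted({k for k in k_range if k < n_cells})
    if not ks:
        raise ValidationError("k_range has no value below the cell count")

    combos = list(itertools.product(dims, ks))
    rng = np.random.default_rng(seed)
    order = [combos[i] for i in rng.permutation(len(combos))]
    schedule = [order[i % len(order)] for i in range(n_runs)]

    co = np.zeros((n_cells, n_cells))
    for d, k in schedule:
        # each run sees a random 60% gene subspace: diversifies the
        # ensemble without breaking cell-permutation equivariance
        genes = rng.choice(
            expr.n_genes, size=max(2, int(0.6 * expr.n_genes)), replace=False
        )
        d_eff = min(d, len(genes), n_cells - 1)
        emb = PCA(n_components=d_eff, svd_solver="full").fit_transform(
            X[:, genes]
        )
        km = KMeans(
            n_clusters=k,
            init=_farthest_point_centers(emb, k),
            n_init=1,
            max_iter=300,
        )
        labels = km.fit_predict(emb)
        co += labels[:, None] == labels[None, :]
    S = co / n_runs
    np.fill_diagonal(S, 1.0)
    eig = np.sort(np.linalg.eigvalsh(S))[::-1]
    return ConsensusResult(
        similarity=S, eigenvalues=eig, runs=n_runs,
        cell_names=list(expr.cell_names),
    )


def select_k(cons: ConsensusResult, k_min: int = 3, k_max: int = 8) -> int:
    """Choose the cluster number by the largest eigengap.

    Returns the k in ``[k_min, k_max]`` maximizing ``lambda_k -
    lambda_{k+1}`` of the descending similarity spectrum (ties go to the
    smallest k). The floor of three clusters guarantees room for at
    least one intermediate state.
    """
    if k_min < 2:
        raise ValidationError("k_min must be >= 2")
    n = len(cons.eigenvalues)
    if k_max >= n:
        raise ValidationError("k_max must be below the cell count")
    lam = cons.eigenvalues
    gaps = {k: lam[k - 1] - lam[k] for k in range(k_min, k_max + 1)}
    # near-equal gaps count as ties (smallest k wins); the tolerance
    # absorbs floating-point noise in degenerate spectra
    tol = 1e-9 * max(1.0, abs(lam[0]))
    max_gap = max(gaps.values())
    return min(k for k, g in gaps.items() if g >= max_gap - tol)


def soft_cluster(
    cons: ConsensusResult,
    k: int,
    seed: int = 0,
    delta: float = 0.2,
    max_iter: int = 500,
    tol: float = 1e-6,
) -> SoftMembership:
    """Soft memberships by symmetric NMF of the similarity matrix.

    ``H >= 0`` minimizing ``||S - H H^T||_F`` via multiplicative updates
    from a seeded nonnegative initialization; rows are then normalized
    to sum 1. A cell is a transition cell when the gap between its two
    largest memberships is below ``delta``.
    """
    S = cons.similarity
    n = S.shape[0]
    if not (2 <= k < n):
        raise ValidationError("need 2 <= k < number of cells")
    rng = np.random.default_rng(seed)
    # seeded nonnegative init: hard k-means partition of the spectral
    # embedding of S, softened with uniform noise, scaled to match S
    lam, vec = np.linalg.eigh(S)
    emb = vec[:, ::-1][:, :k] * np.sqrt(np.maximum(lam[::-1][:k], 0.0))
    km = KMeans(
        n_clusters=k, init=_farthest_point_centers(emb, k), n_init=1
    ).fit(emb)
    indicator = np.eye(k)[km.labels_]
    scale = np.sqrt(S.mean())
    H = scale * (
        0.8 * indicator + 0.2 * rng.uniform(0.0, 1.0, size=(n, k))
    ) + 1e-6

    eps = 1e-12
    prev_obj = np.inf
    converged = False
    for _ in range(max_iter):
        SH = S @ H
        HHtH = H @ (H.T @ H)
        H = H * (0.5 + 0.5 * SH / (HHtH + eps))
        obj = np.linalg.norm(S - H @ H.T, "fro") ** 2
        if prev_obj < np.inf and abs(prev_obj - obj) <= tol * max(prev_obj, eps):
            converged = True
            break
        prev_obj = obj
    if not converged:
        warnings.warn(
            "symmetric NMF did not converge; returning best iterate"
        )

    row_sum = H.sum(axis=1, keepdims=True)
    H = np.where(row_sum > 0, H / np.maximum(row_sum, eps), 1.0 / k)
    hard = H.argmax(axis=1)
    part = np.partition(H, -2, axis=1)
    gap = part[:, -1] - part[:, -2]
    return SoftMembership(
        H=H,
        hard_label=hard,
        transition_flag=gap < delta,
        delta=delta,
        cell_names=cons.cell_names,
    )


def _transition_edges(memb: SoftMembership) -> dict[tuple[int, int], int]:
    """Count transition cells per unordered cluster pair, keyed by the
    cell's two largest memberships."""
    weights: dict[tuple[int, int], int] = {}
    top2 = np.argsort(-memb.H, axis=1)[:, :2]
    for c in np.flatnonzero(memb.transition_flag):
        a, b = sorted(top2[c].tolist())
        weights[(a, b)] = weights.get((a, b), 0) + 1
    return weights


def _path_weight(path: list[int], w: dict[tuple[int, int], int]) -> int:
    return sum(
        w.get(tuple(sorted((path[i], path[i + 1]))), 0)
        for i in range(len(path) - 1)
    )


def infer_trajectory(
    memb: SoftMembership,
    cluster_scores: pd.DataFrame,
    method: str = "auto",
) -> Trajectory:
    """Order the clusters along the EMT axis and assign pseudotime.

    Parameters
    ----------
    memb
        Soft memberships with transition flags.
    cluster_scores
        One row per cluster id with columns ``epithelial`` and
        ``mesenchymal`` (mean signature scores).
    method
        ``"greedy"``: from the start cluster repeatedly move to the
        unvisited cluster with the heaviest transition-cell edge;
        ``"exhaustive"``: enumerate all orders (k <= 8);
        ``"auto"``: exhaustive for k <= 6, greedy otherwise.

    The start cluster maximizes the epithelial score and minimizes the
    mesenchymal score, formalized as the minimal sum of (rank of E
    descending + rank of M ascending); an unresolved tie raises an
    error listing the tied clusters, in which case candidate starting
    points should be tried explicitly.
    """
    k = memb.k
    if k < 2:
        raise ValidationError("need at least 2 clusters")
    missing = [c for c in range(k) if c not in cluster_scores.index]
    if missing:
        raise ValidationError(f"cluster_scores missing clusters {missing}")

    e = cluster_scores.loc[list(range(k)), "epithelial"].to_numpy(float)
    m = cluster_scores.loc[list(range(k)), "mesenchymal"].to_numpy(float)
    e_rank = (-e).argsort().argsort()  # 0 = highest epithelial
    m_rank = m.argsort().argsort()  # 0 = lowest mesenchymal
    rank_sum = e_rank + m_rank
    best = rank_sum.min()
    tied = np.flatnonzero(rank_sum == best)
    if len(tied) > 1:
        raise ValidationError(
            f"no unique start cluster: clusters {tied.tolist()} tie on the "
            "epithelial/mesenchymal rank sum; test candidates explicitly"
        )
    start = int(tied[0])

    weights = _transition_edges(memb)
    if method == "auto":
        method = "exhaustive" if k <= 6 else "greedy"

    alt_paths: list[tuple[list[int], int]] = []
    if method == "exhaustive":
        if k > 8:
            raise ValidationError("exhaustive enumeration limited to k <= 8")
        others = [c for c in range(k) if c != start]
        scored = sorted(
            (
                ([start] + list(p), _path_weight([start] + list(p), weights))
                for p in itertools.permutations(others)
            ),
            key=lambda t: (-t[1], t[0]),
        )
        order = scored[0][0]
        alt_paths = [(p, w) for p, w in scored[1:11]]
    elif method == "greedy":
        order = [start]
        while len(order) < k:
            cur = order[-1]
            remaining = [c for c in range(k) if c not in order]
            nxt = min(
                remaining,
                key=lambda c: (-weights.get(tuple(sorted((cur, c))), 0), c),
            )
            order.append(nxt)
    else:
        raise ValidationError(f"unknown method {method!r}")

    pos = {c: i for i, c in enumerate(order)}
    pseudotime = np.zeros(memb.H.shape[0])
    for c in range(memb.H.shape[0]):
        a = int(memb.hard_label[c])
        i = pos[a]
        neighbors = []
        if i > 0:
            neighbors.append(order[i - 1])
        if i < k - 1:
            neighbors.append(order[i + 1])
        b = max(neighbors, key=lambda q: memb.H[c, q])
        h_a, h_b = memb.H[c, a], memb.H[c, b]
        frac = h_b / (h_a + h_b) if (h_a + h_b) > 0 else 0.0
        pseudotime[c] = i + frac if pos[b] > i else i - frac
    return Trajectory(
        start_cluster=start,
        cluster_order=order,
        edge_weights=weights,
        pseudotime=pseudotime,
        alt_paths=alt_paths,
    )
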