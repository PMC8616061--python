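"""Cluster-level ligand-receptor signaling analysis.

Quantifies how strongly each cell cluster signals to each other cluster
through a database of ligand-receptor pairs, in the style of mass-action
communication inference: cluster-average ligand and receptor expression
(geometric mean over subunits, so a missing subunit nullifies a complex)
are combined through a Hill function into a communication probability,
significance is assessed by a cluster-label permutation null, and the
significant probabilities are aggregated into outgoing/incoming strengths,
per-pathway signaling roles (sender, receiver, mediator, influencer) and
per-pathway information flow, with a comparison layer for multi-condition
experiments.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from emplex.errors import ValidationError
from emplex.io import CountMatrix

__all__ = [
    "LRDatabase",
    "CommunicationTensor",
    "SignalingRoles",
    "communication_probability",
    "permutation_significance",
    "interaction_strengths",
    "information_flow",
    "compare_conditions",
]


@dataclass(frozen=True)
class LRPair:
    """One ligand-receptor interaction: subunit gene lists per side."""

    pathway: str
    ligand_subunits: tuple[str, ...]
    receptor_subunits: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.ligand_subunits or not self.receptor_subunits:
            raise ValidationError("ligand and receptor subunit lists must be nonempty")


@dataclass
class LRDatabase:
    """A collection of ligand-receptor pairs grouped into pathways."""

    entries: list[LRPair]

    def __post_init__(self) -> None:
        keys = [
            (e.pathway, e.ligand_subunits, e.receptor_subunits)
            for e in self.entries
        ]
        if len(set(keys)) != len(keys):
            raise ValidationError("duplicate (pathway, ligand, receptor) entry")

    @property
    def pathways(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.entries:
            seen.setdefault(e.pathway, None)
        return list(seen)

    @property
    def genes(self) -> list[str]:
        out: dict[str, None] = {}
        for e in self.entries:
            for g in e.ligand_subunits + e.receptor_subunits:
                out.setdefault(g, None)
        return list(out)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pathway": [e.pathway for e in self.entries],
                "ligand": [",".join(e.ligand_subunits) for e in self.entries],
                "receptor": [",".join(e.receptor_subunits) for e in self.entries],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LRDatabase":
        entries = [
            LRPair(
                str(row["pathway"]),
                tuple(str(row["ligand"]).split(",")),
                tuple(str(row["receptor"]).split(",")),
            )
            for _, row in df.iterrows()
        ]
        return cls(entries)

    @classmethod
    def read_tsv(cls, path) -> "LRDatabase":
        return cls.from_frame(pd.read_csv(path, sep="\t"))

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


@dataclass
class CommunicationTensor:
    """Sender x receiver x pair communication probabilities.

    ``prob[a, b, p]`` is the Hill-transformed product of cluster ``a``'s
    ligand expression and cluster ``b``'s receptor expression for pair
    ``p``; ``pvals`` (same shape) holds permutation p-values once
    :func:`permutation_significance` has run.
    """

    prob: np.ndarray
    clusters: list
    pairs: list[LRPair]
    Kh: float
    pvals: np.ndarray | None = None
    nperm: int = 0

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, dtype=float)
        if ((self.prob < 0) | (self.prob > 1)).any():
            raise ValidationError("communication probabilities must lie in [0, 1]")

    @property
    def pathway_of_pair(self) -> list[str]:
        return [p.pathway for p in self.pairs]


@dataclass
class SignalingRoles:
    """Per-cluster, per-pathway sender/receiver/mediator/influencer scores."""

    table: pd.DataFrame  # index (pathway, cluster); columns: the four roles


def _normalized_log(raw: CountMatrix) -> np.ndarray:
    """Library-size normalize each cell to the median depth, then log1p."""
    totals = raw.values.sum(axis=0).astype(float)
    scale = np.median(totals[totals > 0]) if (totals > 0).any() else 1.0
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = np.where(totals > 0, raw.values * (scale / np.maximum(totals, 1)), 0.0)
    return np.log1p(norm)


def _cluster_means(
    expr: np.ndarray, labels: np.ndarray, clusters: list
) -> np.ndarray:
    """Gene x cluster arithmetic mean of ``expr`` within each cluster."""
    out = np.zeros((expr.shape[0], len(clusters)))
    for j, c in enumerate(clusters):
        mask = labels == c
        if mask.any():
            out[:, j] = expr[:, mask].mean(axis=1)
    return out


def _pair_probabilities(
    means: np.ndarray,
    gene_index: dict[str, int],
    pairs: list[LRPair],
    Kh: float,
) -> np.ndarray:
    """(clusters x clusters x pairs) Hill probabilities from cluster means."""
    n_c = means.shape[1]
    prob = np.zeros((n_c, n_c, len(pairs)))
    for p, pair in enumerate(pairs):
        lig_rows = [gene_index[g] for g in pair.ligand_subunits]
        rec_rows = [gene_index[g] for g in pair.receptor_subunits]
        # geometric mean over subunits: a silent subunit kills the complex
        L = np.exp(np.log(np.maximum(means[lig_rows, :], 0.0) + 1e-300).mean(axis=0))
        R = np.exp(np.log(np.maximum(means[rec_rows, :], 0.0) + 1e-300).mean(axis=0))
        L[means[lig_rows, :].min(axis=0) <= 0] = 0.0
        R[means[rec_rows, :].min(axis=0) <= 0] = 0.0
        LR = np.outer(L, R)
        prob[:, :, p] = LR / (Kh + LR)
    return prob


def _prepare(
    raw: CountMatrix, labels, db: LRDatabase
) -> tuple[np.ndarray, np.ndarray, list, list[LRPair], dict[str, int]]:
    labels = np.asarray(labels)
    if labels.shape[0] != raw.n_cells:
        raise ValidationError("labels must align with cells")
    clusters = sorted(set(labels.tolist()))
    if len(clusters) < 2:
        raise ValidationError("communication analysis needs >= 2 clusters")
    gene_index = {g: i for i, g in enumerate(raw.gene_names)}
    pairs: list[LRPair] = []
    dropped = []
    for pair in db.entries:
        if all(g in gene_index for g in pair.ligand_subunits + pair.receptor_subunits):
            pairs.append(pair)
        else:
            dropped.append(pair.pathway)
    if dropped:
        warnings.warn(
            f"dropping {len(dropped)} ligand-receptor pair(s) with missing "
            f"subunit genes: {sorted(set(dropped))}"
        )
    if not pairs:
        raise ValidationError("no ligand-receptor pair has all subunits in the matrix")
    expr = _normalized_log(raw)
    return expr, labels, clusters, pairs, gene_index


def communication_probability(
    raw: CountMatrix,
    labels,
    db: LRDatabase,
    Kh: float = 0.5,
) -> CommunicationTensor:
    """Compute sender x receiver x pair communication probabilities.

    Counts are library-size normalized per cell and ``log1p``-transformed;
    ligand (resp. receptor) expression of a cluster is the geometric mean
    over subunits of the cluster-average expression; the probability is
    the Hill transform ``L*R / (Kh + L*R)``.
    """
    if Kh <= 0:
        raise ValidationError("Kh must be positive")
    expr, labels, clusters, pairs, gene_index = _prepare(raw, labels, db)
    means = _cluster_means(expr, labels, clusters)
    prob = _pair_probabilities(means, gene_index, pairs, Kh)
    return CommunicationTensor(prob=prob, clusters=clusters, pairs=pairs, Kh=Kh)


def permutation_significance(
    raw: CountMatrix,
    labels,
    db: LRDatabase,
    nperm: int = 100,
    seed: int = 0,
    Kh: float = 0.5,
) -> CommunicationTensor:
    """Attach permutation p-values to the communication probabilities.

    Cluster labels are globally permuted ``nperm`` times; for each
    (sender, receiver, pair) entry the p-value is
    ``(1 + #{permuted prob >= observed}) / (1 + nperm)``.
    """
    if nperm < 1:
        raise ValidationError("nperm must be >= 1")
    if Kh <= 0:
        raise ValidationError("Kh must be positive")
    expr, labels, clusters, pairs, gene_index = _prepare(raw, labels, db)
    # restrict to database genes: cluster means of other genes are never used
    rows = sorted({gene_index[g] for p in pairs for g in p.ligand_subunits + p.receptor_subunits})
    sub = expr[rows, :]
    sub_index = {raw.gene_names[r]: i for i, r in enumerate(rows)}

    observed = _pair_probabilities(
        _cluster_means(sub, labels, clusters), sub_index, pairs, Kh
    )
    rng = np.random.default_rng(seed)
    exceed = np.zeros_like(observed)
    for _ in range(nperm):
        perm = rng.permutation(labels)
        p = _pair_probabilities(
            _cluster_means(sub, perm, clusters), sub_index, pairs, Kh
        )
        exceed += p >= observed
    pvals = (1.0 + exceed) / (1.0 + nperm)
    return CommunicationTensor(
        prob=observed, clusters=clusters, pairs=pairs, Kh=Kh,
        pvals=pvals, nperm=nperm,
    )


def interaction_strengths(
    comm: CommunicationTensor, alpha: float = 0.05
) -> tuple[pd.DataFrame, SignalingRoles]:
    """Aggregate significant probabilities into strengths and roles.

    Pairs with ``p >= alpha`` are zeroed (if no p-values are attached all
    probabilities count). Returns a per-cluster table of total outgoing and
    incoming strength, plus per-pathway sender (row sums), receiver
    (column sums), influencer (sender + receiver) and mediator
    (betweenness of the cluster in the pathway's significant-probability
    digraph, edge distance ``1/prob``) scores.
    """
    prob = comm.prob.copy()
    if comm.pvals is not None:
        prob[comm.pvals >= alpha] = 0.0
    clusters = comm.clusters
    outgoing = prob.sum(axis=(1, 2))
    incoming = prob.sum(axis=(0, 2))
    strengths = pd.DataFrame(
        {"outgoing": outgoing, "incoming": incoming}, index=clusters
    )

    rows = []
    for pathway in dict.fromkeys(comm.pathway_of_pair):
        sel = [i for i, p in enumerate(comm.pairs) if p.pathway == pathway]
        mat = prob[:, :, sel].sum(axis=2)
        sender = mat.sum(axis=1)
        receiver = mat.sum(axis=0)
        G = nx.DiGraph()
        G.add_nodes_from(range(len(clusters)))
        for a in range(len(clusters)):
            for b in range(len(clusters)):
                if a != b and mat[a, b] > 0:
                    G.add_edge(a, b, distance=1.0 / mat[a, b])
        btw = nx.betweenness_centrality(G, weight="distance", normalized=False)
        for j, c in enumerate(clusters):
            rows.append(
                {
                    "pathway": pathway,
                    "cluster": c,
                    "sender": sender[j],
                    "receiver": receiver[j],
                    "mediator": btw[j],
                    "influencer": sender[j] + receiver[j],
                }
            )
    roles = SignalingRoles(
        pd.DataFrame(rows).set_index(["pathway", "cluster"])
        if rows
        else pd.DataFrame(
            columns=["sender", "receiver", "mediator", "influencer"]
        )
    )
    return strengths, roles


def information_flow(
    comm: CommunicationTensor, alpha: float = 0.05
) -> pd.Series:
    """Total significant communication probability per pathway."""
    prob = comm.prob.copy()
    if comm.pvals is not None:
        prob[comm.pvals >= alpha] = 0.0
    flows: dict[str, float] = {}
    for i, pair in enumerate(comm.pairs):
        flows[pair.pathway] = flows.get(pair.pathway, 0.0) + float(
            prob[:, :, i].sum()
        )
    return pd.Series(flows, name="flow")


def compare_conditions(
    comms: dict[str, CommunicationTensor], alpha: float = 0.05
) -> pd.DataFrame:
    """Compare per-pathway information flow across conditions.

    All conditions must share a ligand-receptor database. The table
    reports absolute and relative (flow / total flow within condition)
    flow per pathway and condition, and flags pathways whose flow is
    positive in exactly one condition as exclusive to it.
    """
    if len(comms) < 2:
        raise ValidationError("need >= 2 conditions to compare")
    keys = [
        {(p.pathway, p.ligand_subunits, p.receptor_subunits) for p in c.pairs}
        for c in comms.values()
    ]
    shared = set.intersection(*keys)
    if not shared:
        raise ValidationError("conditions share no ligand-receptor pairs")

    flows = {name: information_flow(c, alpha=alpha) for name, c in comms.items()}
    pathways = sorted({pw for f in flows.values() for pw in f.index})
    rows = []
    for pw in pathways:
        abs_flows = {name: float(f.get(pw, 0.0)) for name, f in flows.items()}
        totals = {name: float(f.sum()) for name, f in flows.items()}
        active = [name for name, v in abs_flows.items() if v > 0]
        row: dict = {"pathway": pw}
        for name in comms:
            row[f"flow_{name}"] = abs_flows[name]
            row[f"relative_{name}"] = (
                abs_flows[name] / totals[name] if totals[name] > 0 else 0.0
            )
        row["exclusive_to"] = active[0] if len(active) == 1 else ""
        rows.append(row)
    return pd.DataFrame(rows).set_index("pathway")
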