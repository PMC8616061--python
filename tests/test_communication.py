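import numpy as np
import pandas as pd
import pytest

from emplex import (
    CommunicationTensor,
    LRDatabase,
    SimConfig,
    communication_probability,
    compare_conditions,
    generate_emt_dataset,
    information_flow,
    interaction_strengths,
    permutation_significance,
)
from emplex.communication import LRPair
from emplex.errors import ValidationError
from emplex.io import CountMatrix


def toy_db():
    return LRDatabase([LRPair("P", ("L1",), ("R1",))])


def counts_with(l_by_cluster, r_by_cluster, n_per=30, seed=0):
    """Two genes (ligand L1, receptor R1) plus constant fillers, with
    cluster-specific means."""
    rng = np.random.default_rng(seed)
    k = len(l_by_cluster)
    cols = []
    labels = []
    for c in range(k):
        block = np.vstack(
            [
                rng.poisson(l_by_cluster[c], n_per),
                rng.poisson(r_by_cluster[c], n_per),
                rng.poisson(5.0, n_per),
                rng.poisson(5.0, n_per),
            ]
        )
        cols.append(block)
        labels += [c] * n_per
    vals = np.hstack(cols)
    cm = CountMatrix(
        vals,
        ["L1", "R1", "f1", "f2"],
        [f"c{i}" for i in range(vals.shape[1])],
    )
    return cm, np.array(labels)


def tensor(prob, clusters=None, pairs=None, pvals=None):
    prob = np.asarray(prob, float)
    return CommunicationTensor(
        prob=prob,
        clusters=clusters or list(range(prob.shape[0])),
        pairs=pairs or [LRPair("P", ("L1",), ("R1",))] * prob.shape[2],
        Kh=0.5,
        pvals=None if pvals is None else np.asarray(pvals, float),
        nperm=0 if pvals is None else 100,
    )


class TestHillProbability:
    def test_midpoint_half_and_closed_forms(self):
        # direct checks of the Hill transform L*R / (Kh + L*R)
        Kh = 0.5
        assert Kh / (Kh + Kh) == pytest.approx(0.5)  # L*R = Kh
        assert (1 * 1) / (Kh + 1) == pytest.approx(2 / 3)

    def test_zero_ligand_gives_zero_probability(self):
        cm, labels = counts_with([0.0, 5.0], [5.0, 5.0])
        comm = communication_probability(cm, labels, toy_db())
        i = 0
        assert comm.prob[0, :, i].max() == 0.0

    def test_monotone_in_ligand_and_receptor(self):
        cm, labels = counts_with([1.0, 3.0, 9.0], [4.0, 4.0, 4.0], seed=1)
        comm = communication_probability(cm, labels, toy_db())
        sender_probs = comm.prob[:, 0, 0]
        assert np.all(np.diff(sender_probs) > 0)
        assert comm.prob.max() <= 1.0

    def test_missing_subunits_dropped_with_warning(self):
        cm, labels = counts_with([5.0, 5.0], [5.0, 5.0])
        db = LRDatabase(
            [LRPair("P", ("L1",), ("R1",)), LRPair("Q", ("NOPE",), ("R1",))]
        )
        with pytest.warns(UserWarning, match="missing"):
            comm = communication_probability(cm, labels, db)
        assert [p.pathway for p in comm.pairs] == ["P"]

    def test_duplicate_database_entry_rejected(self):
        with pytest.raises(ValidationError):
            LRDatabase(
                [LRPair("P", ("L1",), ("R1",)), LRPair("P", ("L1",), ("R1",))]
            )

    def test_invalid_Kh_rejected(self):
        cm, labels = counts_with([5.0, 5.0], [5.0, 5.0])
        with pytest.raises(ValidationError):
            communication_probability(cm, labels, toy_db(), Kh=0.0)


class TestPermutation:
    def test_deterministic_given_seed(self):
        cm, labels = counts_with([1.0, 8.0], [8.0, 1.0])
        a = permutation_significance(cm, labels, toy_db(), nperm=50, seed=5)
        b = permutation_significance(cm, labels, toy_db(), nperm=50, seed=5)
        np.testing.assert_array_equal(a.pvals, b.pvals)

    def test_designed_pair_is_significant(self):
        hits = 0
        for seed in range(10):
            ds = generate_emt_dataset(SimConfig(seed=seed))
            comm = permutation_significance(
                ds.counts, ds.true_state, ds.lr_db, nperm=100, seed=seed
            )
            i = [p.pathway for p in comm.pairs].index("NotchToy")
            hits += comm.pvals[2, 3, i] <= 0.05  # designed I2 -> M edge
        assert hits >= 9

    def test_identical_clusters_not_significant(self):
        cm, labels = counts_with([5.0, 5.0, 5.0], [5.0, 5.0, 5.0], seed=2)
        comm = permutation_significance(cm, labels, toy_db(), nperm=100, seed=2)
        assert (comm.pvals < 0.05).mean() <= 0.2

    def test_nperm_must_be_positive(self):
        cm, labels = counts_with([5.0, 5.0], [5.0, 5.0])
        with pytest.raises(ValidationError):
            permutation_significance(cm, labels, toy_db(), nperm=0)


class TestStrengths:
    def test_single_edge_bookkeeping(self):
        prob = np.zeros((2, 2, 1))
        prob[0, 1, 0] = 0.4
        strengths, _ = interaction_strengths(tensor(prob))
        assert strengths.loc[0, "outgoing"] == pytest.approx(0.4)
        assert strengths.loc[1, "incoming"] == pytest.approx(0.4)
        assert strengths.loc[1, "outgoing"] == 0.0
        assert strengths.loc[0, "incoming"] == 0.0

    def test_symmetric_tensor_balances_roles(self, rng):
        base = rng.uniform(0, 0.5, size=(3, 3))
        prob = ((base + base.T) / 2)[:, :, None]
        strengths, _ = interaction_strengths(tensor(prob))
        np.testing.assert_allclose(
            strengths["outgoing"], strengths["incoming"]
        )

    def test_worked_two_cluster_sums(self):
        prob = np.zeros((2, 2, 1))
        prob[0, 1, 0] = 0.3
        prob[1, 0, 0] = 0.1
        prob[1, 1, 0] = 0.2
        strengths, roles = interaction_strengths(tensor(prob))
        np.testing.assert_allclose(strengths["outgoing"], [0.3, 0.3])
        np.testing.assert_allclose(strengths["incoming"], [0.1, 0.5])
        assert roles.table.loc[("P", 0), "influencer"] == pytest.approx(0.4)

    def test_significance_filter_zeroes_pairs(self):
        prob = np.full((2, 2, 1), 0.5)
        pvals = np.full((2, 2, 1), 0.5)
        pvals[0, 1, 0] = 0.01
        strengths, _ = interaction_strengths(tensor(prob, pvals=pvals), alpha=0.05)
        assert strengths.loc[0, "outgoing"] == pytest.approx(0.5)
        assert strengths.loc[1, "outgoing"] == 0.0


class TestFlows:
    def test_all_zero_tensor_has_zero_flow(self):
        flow = information_flow(tensor(np.zeros((2, 2, 2))))
        assert (flow == 0).all()

    def test_relative_flows_normalize(self):
        pairs = [LRPair("A", ("L1",), ("R1",)), LRPair("B", ("L2",), ("R2",))]
        prob = np.zeros((2, 2, 2))
        prob[0, 1, 0] = 0.6
        prob[0, 1, 1] = 0.3
        t1 = tensor(prob, pairs=pairs)
        t2 = tensor(prob * 0.5, pairs=pairs)
        table = compare_conditions({"x": t1, "y": t2})
        assert table.loc["A", "relative_x"] == pytest.approx(2 / 3)
        assert table.loc["B", "relative_x"] == pytest.approx(1 / 3)

    def test_exclusive_pathway_flagged(self):
        pairs = [LRPair("A", ("L1",), ("R1",)), LRPair("B", ("L2",), ("R2",))]
        p1 = np.zeros((2, 2, 2))
        p1[0, 1, 0] = 0.5
        p1[0, 1, 1] = 0.4
        p2 = np.zeros((2, 2, 2))
        p2[0, 1, 0] = 0.5  # pathway B silent in condition y
        table = compare_conditions(
            {"x": tensor(p1, pairs=pairs), "y": tensor(p2, pairs=pairs)}
        )
        assert table.loc["B", "exclusive_to"] == "x"
        assert table.loc["A", "exclusive_to"] == ""

    def test_disjoint_databases_rejected(self):
        t1 = tensor(np.zeros((2, 2, 1)), pairs=[LRPair("A", ("L1",), ("R1",))])
        t2 = tensor(np.zeros((2, 2, 1)), pairs=[LRPair("B", ("L2",), ("R2",))])
        with pytest.raises(ValidationError):
            compare_conditions({"x": t1, "y": t2})
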