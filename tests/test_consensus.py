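import warnings

import numpy as np
import pandas as pd
import pytest

from emplex import (
    build_consensus,
    infer_trajectory,
    select_k,
    soft_cluster,
)
from emplex.consensus import ConsensusResult, SoftMembership
from emplex.errors import ValidationError
from emplex.io import ExpressionMatrix


def block_similarity(sizes):
    """Oracle: perfect block-constant similarity. Its spectrum is the
    block sizes followed by zeros, so the eigengap sits at the block
    count."""
    n = sum(sizes)
    S = np.zeros((n, n))
    start = 0
    for b in sizes:
        S[start : start + b, start : start + b] = 1.0
        start += b
    eig = np.sort(np.linalg.eigvalsh(S))[::-1]
    return ConsensusResult(similarity=S, eigenvalues=eig, runs=1)


def two_group_matrix():
    """Two duplicated cell groups with identical expression per group."""
    a = np.array([5.0, 0.0, 2.0, 1.0])
    b = np.array([0.0, 5.0, 1.0, 2.0])
    vals = np.stack([a, a, a, b, b, b], axis=1)
    return ExpressionMatrix(vals, [f"g{i}" for i in range(4)], [f"c{i}" for i in range(6)])


class TestConsensus:
    def test_duplicated_groups_cocluster_perfectly(self):
        cons = build_consensus(two_group_matrix(), n_runs=10, k_range=(2,), seed=0)
        S = cons.similarity
        assert np.allclose(S[:3, :3], 1.0)
        assert np.allclose(S[3:, 3:], 1.0)
        assert S[:3, 3:].max() < 1.0

    def test_cell_permutation_equivariance(self, rng):
        # distinct cells (ties in the farthest-point init would make the
        # duplicated-cell case degenerate for k above the distinct count)
        vals = rng.normal(size=(4, 6))
        expr = ExpressionMatrix(
            vals, [f"g{i}" for i in range(4)], [f"c{i}" for i in range(6)]
        )
        perm = np.array([4, 0, 5, 2, 1, 3])
        permuted = ExpressionMatrix(
            expr.values[:, perm],
            expr.gene_names,
            [expr.cell_names[i] for i in perm],
        )
        a = build_consensus(expr, n_runs=12, k_range=(2, 3), seed=7)
        b = build_consensus(permuted, n_runs=12, k_range=(2, 3), seed=7)
        np.testing.assert_allclose(
            b.similarity, a.similarity[np.ix_(perm, perm)], atol=1e-12
        )

    def test_seed_determinism(self, default_expression):
        _, expr = default_expression
        a = build_consensus(expr, n_runs=5, seed=3)
        b = build_consensus(expr, n_runs=5, seed=3)
        np.testing.assert_array_equal(a.similarity, b.similarity)

    def test_nruns_must_be_positive(self):
        with pytest.raises(ValidationError):
            build_consensus(two_group_matrix(), n_runs=0)


class TestSelectK:
    @pytest.mark.parametrize("sizes,expect", [((3, 3, 3), 3), ((3, 3, 3, 3), 4)])
    def test_perfect_blocks_recover_block_count(self, sizes, expect):
        assert select_k(block_similarity(sizes), k_min=3, k_max=5) == expect

    def test_minimum_constraint_binds(self):
        # two blocks but the floor of three forces k = 3
        assert select_k(block_similarity((4, 4)), k_min=3, k_max=5) == 3

    def test_kmax_below_cell_count(self):
        with pytest.raises(ValidationError):
            select_k(block_similarity((3, 3)), k_min=3, k_max=6)


class TestSoftCluster:
    def test_perfect_blocks_give_hard_labels_and_no_transitions(self):
        cons = block_similarity((4, 4, 4))
        memb = soft_cluster(cons, 3, seed=0)
        labels = memb.hard_label
        assert len({tuple(labels[i * 4 : (i + 1) * 4]) for i in range(3)}) == 3
        for i in range(3):
            assert len(set(labels[i * 4 : (i + 1) * 4])) == 1
        assert memb.transition_flag.sum() == 0

    def test_transition_flag_thresholds(self):
        H = np.array([[0.5, 0.5, 0.0], [0.9, 0.1, 0.0]])
        memb = SoftMembership(
            H=H,
            hard_label=H.argmax(axis=1),
            transition_flag=np.array([True, False]),
            delta=0.1,
        )
        gap = np.sort(H, axis=1)
        gaps = gap[:, -1] - gap[:, -2]
        assert (gaps < 0.1).tolist() == [True, False]

    def test_k_bounds(self):
        cons = block_similarity((3, 3))
        with pytest.raises(ValidationError):
            soft_cluster(cons, 1)
        with pytest.raises(ValidationError):
            soft_cluster(cons, 6)


def membership(H, delta=0.2):
    H = np.asarray(H, float)
    H = H / H.sum(axis=1, keepdims=True)
    gap = np.sort(H, axis=1)
    return SoftMembership(
        H=H,
        hard_label=H.argmax(axis=1),
        transition_flag=(gap[:, -1] - gap[:, -2]) < delta,
        delta=delta,
    )


def scores_frame(e, m):
    return pd.DataFrame({"epithelial": e, "mesenchymal": m})


class TestTrajectory:
    def test_start_is_most_epithelial_least_mesenchymal(self):
        memb = membership([[0.8, 0.1, 0.1]] * 3 + [[0.1, 0.8, 0.1]] * 3 + [[0.1, 0.1, 0.8]] * 3)
        traj = infer_trajectory(memb, scores_frame([0.8, 0.5, 0.2], [0.1, 0.4, 0.7]))
        assert traj.start_cluster == 0

    def test_rank_sum_tie_is_error_listing_clusters(self):
        # cluster 0 wins epithelial, cluster 1 wins (lowest) mesenchymal
        memb = membership([[0.9, 0.05, 0.05]] * 2 + [[0.05, 0.9, 0.05]] * 2 + [[0.05, 0.05, 0.9]] * 2)
        with pytest.raises(ValidationError, match="tie"):
            infer_trajectory(memb, scores_frame([0.8, 0.5, 0.2], [0.4, 0.1, 0.7]))

    def test_max_weight_path_follows_transition_cells(self):
        # transition cells: {A,B} x10, {B,C} x7, {A,C} x1
        rows = []
        rows += [[0.9, 0.05, 0.05]] * 5 + [[0.05, 0.9, 0.05]] * 5 + [[0.05, 0.05, 0.9]] * 5
        rows += [[0.5, 0.45, 0.05]] * 10  # A-B
        rows += [[0.05, 0.5, 0.45]] * 7  # B-C
        rows += [[0.5, 0.05, 0.45]] * 1  # A-C
        memb = membership(rows)
        traj = infer_trajectory(
            memb, scores_frame([0.9, 0.5, 0.2], [0.1, 0.5, 0.8])
        )
        assert traj.cluster_order == [0, 1, 2]
        assert traj.edge_weights[(0, 1)] == 10
        assert traj.edge_weights[(1, 2)] == 7
        assert traj.edge_weights[(0, 2)] == 1

    def test_greedy_and_exhaustive_agree_on_clear_path(self):
        rows = (
            [[0.9, 0.05, 0.05]] * 3
            + [[0.05, 0.9, 0.05]] * 3
            + [[0.05, 0.05, 0.9]] * 3
            + [[0.5, 0.45, 0.05]] * 4
            + [[0.05, 0.5, 0.45]] * 2
        )
        memb = membership(rows)
        cs = scores_frame([0.9, 0.5, 0.2], [0.1, 0.5, 0.8])
        a = infer_trajectory(memb, cs, method="greedy")
        b = infer_trajectory(memb, cs, method="exhaustive")
        assert a.cluster_order == b.cluster_order == [0, 1, 2]

    def test_pseudotime_interpolation_formula(self):
        # hard cluster A at position 0 with h_A = 0.6, next-cluster
        # membership h_B = 0.4 -> pseudotime 0 + 0.4 / (0.6 + 0.4)
        rows = (
            [[0.6, 0.4, 0.0]]
            + [[0.9, 0.1, 0.0]] * 3
            + [[0.05, 0.9, 0.05]] * 3
            + [[0.05, 0.5, 0.45]] * 2
            + [[0.0, 0.1, 0.9]] * 3
        )
        memb = membership(rows, delta=0.15)
        traj = infer_trajectory(
            memb, scores_frame([0.9, 0.5, 0.2], [0.1, 0.5, 0.8])
        )
        assert traj.cluster_order == [0, 1, 2]
        assert traj.pseudotime[0] == pytest.approx(0.4)

    def test_pseudotime_nondecreasing_along_order(self, default_clustering):
        cons, memb = default_clustering
        k = memb.k
        cs = scores_frame(
            list(np.linspace(0.9, 0.2, k)), list(np.linspace(0.1, 0.8, k))
        )
        traj = infer_trajectory(memb, cs)
        pos = {c: i for i, c in enumerate(traj.cluster_order)}
        pt_by_pos = [
            traj.pseudotime[memb.hard_label == c].mean()
            for c in traj.cluster_order
        ]
        assert np.all(np.diff(pt_by_pos) > 0)
        for c in range(k):
            i = pos[c]
            sel = traj.pseudotime[memb.hard_label == c]
            assert np.all(sel >= i - 0.5 - 1e-9) and np.all(sel <= i + 0.5 + 1e-9)
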