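"""Parsimony scoring and tree search against exhaustive enumeration oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from metaclone.consensus import build_mutation_matrix
from metaclone.phylo import (
    canonical_newick,
    enumerate_topologies,
    fitch_score,
    mutation_jaccard,
    nj_start_tree,
    nni_neighbors,
    search_tree,
)


def matrix_from_sets(sets, include_germline=True):
    return build_mutation_matrix(sets, include_germline=include_germline)


def fitch_oracle(adj, presence: pd.DataFrame) -> int:
    """Minimum changes by exhaustive enumeration of internal-node states."""
    internal = [n for n in adj if not isinstance(n, str)]
    edges = set()
    for u in adj:
        for v in adj[u]:
            edges.add(frozenset((repr(u), repr(v))))
    edges = [tuple(e) for e in edges]
    node_of = {repr(n): n for n in adj}
    total = 0
    for col in presence.columns:
        leaf_state = {leaf: int(presence.loc[leaf, col]) for leaf in presence.index}
        best = None
        for assign in itertools.product((0, 1), repeat=len(internal)):
            state = {repr(n): s for n, s in zip(internal, assign)}
            state.update({repr(k): v for k, v in leaf_state.items()})
            changes = sum(state[a] != state[b] for a, b in edges)
            best = changes if best is None else min(best, changes)
        total += best
    return total


class TestMutationJaccard:
    def test_worked_example(self):
        m = matrix_from_sets({"T1": {"a", "b", "c"}, "T2": {"b", "c", "d"}})
        ji = mutation_jaccard(m)
        assert ji.loc["T1", "T2"] == pytest.approx(0.5)

    def test_identical_and_disjoint(self):
        m = matrix_from_sets({"T1": {"a"}, "T2": {"a"}, "T3": {"b"}})
        ji = mutation_jaccard(m)
        assert ji.loc["T1", "T2"] == 1.0
        assert ji.loc["T1", "T3"] == 0.0
        assert (np.diag(ji.to_numpy()) == 1.0).all()

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_set_arithmetic_oracle(self, seed):
        rng = np.random.default_rng(seed)
        sets = {
            f"T{i}": {f"m{j}" for j in range(12) if rng.random() < 0.5} | {f"keep{i}"}
            for i in range(5)
        }
        ji = mutation_jaccard(matrix_from_sets(sets))
        for a in sets:
            for b in sets:
                expect = len(sets[a] & sets[b]) / len(sets[a] | sets[b])
                assert ji.loc[a, b] == pytest.approx(expect)
                assert ji.loc[a, b] == ji.loc[b, a]
                assert 0 <= ji.loc[a, b] <= 1


class TestFitchScore:
    def test_star_like_case_each_mutation_changes_once(self):
        m = matrix_from_sets({"T1": {"m1", "m2"}, "T2": {"m1", "m3"}, "T3": {"m1"}})
        for adj in enumerate_topologies(list(m.presence.index)):
            assert fitch_score(adj, m.presence) == 3

    def test_topology_dependence_of_shared_character(self):
        presence = pd.DataFrame(
            {"m": [1, 1, 0, 0, 0]},
            index=["T1", "T2", "T3", "T4", "germline"],
        )
        split_together = None
        split_apart = None
        for adj in enumerate_topologies(list(presence.index)):
            nwk = canonical_newick(adj)
            s = fitch_score(adj, presence)
            # grouping T1,T2 as sisters costs 1 change; separating them costs 2
            if "(T1,T2)" in nwk and s == 1:
                split_together = s
            if s == 2:
                split_apart = s
        assert split_together == 1 and split_apart == 2

    def test_all_zero_column_contributes_nothing(self):
        presence = pd.DataFrame(
            {"m": [1, 0, 0], "z": [0, 0, 0]}, index=["T1", "T2", "germline"]
        )
        adj = next(enumerate_topologies(["T1", "T2", "germline"]))
        assert fitch_score(adj, presence) == fitch_score(adj, presence[["m"]])

    @pytest.mark.parametrize("n_leaves,seed", [(4, 0), (5, 1), (6, 2), (6, 3)])
    def test_matches_state_enumeration_oracle(self, n_leaves, seed):
        rng = np.random.default_rng(seed)
        leaves = [f"T{i}" for i in range(n_leaves - 1)] + ["germline"]
        presence = pd.DataFrame(
            rng.integers(0, 2, size=(n_leaves, 6)), index=leaves,
            columns=[f"m{j}" for j in range(6)],
        )
        presence.loc["germline"] = 0
        for adj in itertools.islice(enumerate_topologies(leaves), 12):
            assert fitch_score(adj, presence) == fitch_oracle(adj, presence)

    def test_invariant_under_leaf_order_permutation(self):
        rng = np.random.default_rng(4)
        leaves = ["T1", "T2", "T3", "T4", "T5"]
        presence = pd.DataFrame(
            rng.integers(0, 2, size=(5, 8)), index=leaves,
            columns=[f"m{j}" for j in range(8)],
        )
        adj = next(enumerate_topologies(leaves))
        perm = presence.loc[["T3", "T5", "T1", "T4", "T2"]]
        assert fitch_score(adj, presence) == fitch_score(adj, perm)

    def test_additive_over_column_blocks(self):
        rng = np.random.default_rng(5)
        leaves = ["T1", "T2", "T3", "T4"]
        presence = pd.DataFrame(
            rng.integers(0, 2, size=(4, 10)), index=leaves,
            columns=[f"m{j}" for j in range(10)],
        )
        adj = next(enumerate_topologies(leaves))
        total = fitch_score(adj, presence)
        assert total == (fitch_score(adj, presence.iloc[:, :4])
                         + fitch_score(adj, presence.iloc[:, 4:]))

    def test_non_binary_entry_raises(self):
        presence = pd.DataFrame({"m": [2, 0, 0]}, index=["T1", "T2", "T3"])
        adj = next(enumerate_topologies(["T1", "T2", "T3"]))
        with pytest.raises(ValueError, match="binary"):
            fitch_score(adj, presence)


class TestEnumeration:
    @pytest.mark.parametrize("n,count", [(3, 1), (4, 3), (5, 15), (6, 105)])
    def test_topology_counts_are_double_factorials(self, n, count):
        leaves = [f"T{i}" for i in range(n)]
        newicks = {canonical_newick(adj, leaves[0])
                   for adj in enumerate_topologies(leaves)}
        assert len(newicks) == count


class TestSearch:
    def test_exhaustive_recovers_perfect_split(self):
        sets = {
            "T1": {"s", "a"}, "T2": {"s", "a"},
            "T3": {"s", "b"}, "T4": {"s", "b"},
        }
        m = matrix_from_sets(sets)
        tree = search_tree(m.presence, mode="exhaustive")
        # 3 characters (s, a, b) each change exactly once on the true split
        assert tree.parsimony_score == 3
        assert "(T1,T2)" in tree.newick and "(T3,T4)" in tree.newick

    def test_exhaustive_rejected_above_leaf_limit(self):
        presence = pd.DataFrame(
            np.eye(9, dtype=int), index=[f"T{i}" for i in range(9)],
            columns=[f"m{i}" for i in range(9)],
        )
        with pytest.raises(ValueError, match="exhaustive"):
            search_tree(presence, mode="exhaustive")

    @pytest.mark.parametrize("seed", range(8))
    def test_nni_attains_exhaustive_optimum_on_small_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        leaves = [f"T{i}" for i in range(n - 1)] + ["germline"]
        presence = pd.DataFrame(
            rng.integers(0, 2, size=(n, 10)), index=leaves,
            columns=[f"m{j}" for j in range(10)],
        )
        presence.loc["germline"] = 0
        presence = presence.loc[:, presence.sum() > 0]
        best = search_tree(presence, mode="exhaustive").parsimony_score
        nni = search_tree(presence, mode="nni", seed=seed)
        assert nni.parsimony_score == best

    def test_truncal_only_matrix_scores_identically_on_all_topologies(self):
        presence = pd.DataFrame(
            {"m1": [1, 1, 1, 1, 0], "m2": [1, 1, 1, 1, 0]},
            index=["T1", "T2", "T3", "T4", "germline"],
        )
        scores = {fitch_score(adj, presence)
                  for adj in enumerate_topologies(list(presence.index))}
        assert scores == {2}

    def test_nni_never_worse_than_start_and_reproducible(self):
        rng = np.random.default_rng(11)
        leaves = [f"T{i}" for i in range(7)] + ["germline"]
        presence = pd.DataFrame(
            rng.integers(0, 2, size=(8, 14)), index=leaves,
            columns=[f"m{j}" for j in range(14)],
        )
        presence.loc["germline"] = 0
        start = fitch_score(nj_start_tree(presence), presence)
        t1 = search_tree(presence, mode="nni", seed=3)
        t2 = search_tree(presence, mode="nni", seed=3)
        assert t1.parsimony_score <= start
        assert t1.newick == t2.newick

    def test_nni_neighbors_preserve_leaf_set(self):
        leaves = ["T1", "T2", "T3", "T4", "T5"]
        adj = next(enumerate_topologies(leaves))
        for nb in nni_neighbors(adj):
            assert {n for n in nb if isinstance(n, str)} == set(leaves)
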