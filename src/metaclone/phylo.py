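"""Germline-rooted maximum-parsimony phylogeny from the binary mutation matrix.

Tumor-level trees are inferred from somatic presence/absence characters under
Fitch parsimony.  The mutation-free germline is included as an all-zero leaf
and used to root the reported tree.  Search is either exhaustive enumeration
of unrooted topologies (small leaf counts) or nearest-neighbor-interchange
hill climbing from a neighbor-joining start tree on Hamming distances.

Trees are held as adjacency dictionaries: leaves are their string labels,
internal nodes are integers, and every internal node of an unrooted binary
tree has degree three.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix
from skbio.tree import nj

from .core import GERMLINE_LABEL, MutationMatrix
from ._sets import jaccard_matrix

Adjacency = dict[object, set]

MAX_EXHAUSTIVE_LEAVES = 8


def mutation_jaccard(matrix: MutationMatrix) -> pd.DataFrame:
    """Pairwise Jaccard index of per-tumor mutation sets (germline excluded)."""
    presence = matrix.drop_germline()
    if presence.shape[0] < 2:
        raise ValueError("mutation Jaccard requires at least 2 samples")
    sets = {
        s: set(presence.columns[presence.loc[s].to_numpy() == 1])
        for s in presence.index
    }
    return jaccard_matrix(sets)


def _is_leaf(node) -> bool:
    return isinstance(node, str)


def _presence_frame(matrix) -> pd.DataFrame:
    if isinstance(matrix, MutationMatrix):
        return matrix.presence
    return matrix


def fitch_score(adj: Adjacency, matrix) -> int:
    """Fitch parsimony score: summed minimal state changes over all characters.

    ``matrix`` is a :class:`MutationMatrix` or a 0/1 DataFrame whose index
    labels equal the tree's leaves.  The score is computed on the unrooted
    topology (rooting at any leaf leaves it unchanged).
    """
    presence = _presence_frame(matrix)
    X = presence.to_numpy()
    if not np.isin(X, (0, 1)).all():
        raise ValueError("Fitch scoring requires binary characters")
    leaves = {n for n in adj if _is_leaf(n)}
    if leaves != set(presence.index):
        raise ValueError("tree leaves do not match matrix rows")
    leaf_row = {label: i for i, label in enumerate(presence.index)}
    changes = np.zeros(X.shape[1], dtype=np.int64)

    def visit(node, parent):
        if _is_leaf(node):
            return (X[leaf_row[node]] + 1).astype(np.uint8)
        children = [n for n in adj[node] if n != parent]
        mask = visit(children[0], node)
        for child in children[1:]:
            other = visit(child, node)
            inter = mask & other
            union_needed = inter == 0
            changes[union_needed] += 1
            mask = np.where(union_needed, mask | other, inter).astype(np.uint8)
        return mask

    root_leaf = presence.index[0]
    (neighbor,) = adj[root_leaf]
    mask = visit(neighbor, root_leaf)
    root_mask = (X[leaf_row[root_leaf]] + 1).astype(np.uint8)
    changes[(mask & root_mask) == 0] += 1
    return int(changes.sum())


def enumerate_topologies(leaves: list[str]):
    """Yield every unrooted binary topology over the given leaves by stepwise
    addition: (2n-5)!! trees for n leaves."""
    leaves = list(leaves)
    if len(leaves) < 3:
        raise ValueError("need at least 3 leaves")
    base: Adjacency = {0: {leaves[0], leaves[1], leaves[2]}}
    for leaf in leaves[:3]:
        base[leaf] = {0}

    def edges_of(adj):
        seen = set()
        for u, nbrs in adj.items():
            for v in nbrs:
                key = frozenset((id(u), id(v))) if False else None
                e = tuple(sorted((repr(u), repr(v))))
                if e not in seen:
                    seen.add(e)
                    yield (u, v)

    def insert(adj, next_internal, remaining):
        if not remaining:
            yield adj
            return
        leaf = remaining[0]
        for u, v in list(edges_of(adj)):
            new = {k: set(s) for k, s in adj.items()}
            w = next_internal
            new[u].discard(v)
            new[v].discard(u)
            new[u].add(w)
            new[v].add(w)
            new[w] = {u, v, leaf}
            new[leaf] = {w}
            yield from insert(new, next_internal + 1, remaining[1:])

    yield from insert(base, 1, leaves[3:])


def canonical_newick(adj: Adjacency, root_label: str | None = None) -> str:
    """Deterministic newick string: rooted at ``root_label`` (the germline
    leaf when present), subtrees sorted lexicographically at every node."""
    leaves = sorted(n for n in adj if _is_leaf(n))
    if root_label is None:
        root_label = GERMLINE_LABEL if GERMLINE_LABEL in adj else leaves[0]
    if root_label not in adj:
        raise ValueError(f"root label {root_label!r} is not a leaf of the tree")

    def nw(node, parent):
        if _is_leaf(node):
            return node
        subs = sorted(nw(c, node) for c in adj[node] if c != parent)
        return "(" + ",".join(subs) + ")"

    (neighbor,) = adj[root_label]
    return f"({root_label},{nw(neighbor, root_label)});"


def _suppress_degree_two(adj: Adjacency) -> Adjacency:
    adj = {k: set(v) for k, v in adj.items()}
    changed = True
    while changed:
        changed = False
        for node in list(adj):
            if not _is_leaf(node) and len(adj[node]) == 2:
                a, b = adj[node]
                adj[a].discard(node)
                adj[b].discard(node)
                adj[a].add(b)
                adj[b].add(a)
                del adj[node]
                changed = True
    return adj


def nj_start_tree(matrix) -> Adjacency:
    """Neighbor-joining topology on Hamming distances between matrix rows.

    Deterministic for a given row order; used only as an NNI starting point,
    so branch lengths are discarded.
    """
    presence = _presence_frame(matrix)
    labels = list(presence.index)
    if len(labels) == 3:
        adj: Adjacency = {0: set(labels)}
        for lf in labels:
            adj[lf] = {0}
        return adj
    dist = squareform(pdist(presence.to_numpy(float), metric="hamming"))
    # NJ needs distinct taxa; jitter exact duplicates deterministically
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            if dist[i, j] == 0:
                dist[i, j] = dist[j, i] = 1e-9
    tree = nj(DistanceMatrix(dist, ids=labels))
    adj: Adjacency = {}
    counter = itertools.count()
    ids = {}

    def node_id(node):
        if node.is_tip():
            return node.name
        if id(node) not in ids:
            ids[id(node)] = next(counter)
        return ids[id(node)]

    for node in tree.traverse(include_self=True):
        u = node_id(node)
        adj.setdefault(u, set())
        for child in node.children:
            v = node_id(child)
            adj.setdefault(v, set())
            adj[u].add(v)
            adj[v].add(u)
    return _suppress_degree_two(adj)


def _internal_edges(adj: Adjacency):
    seen = set()
    for u in adj:
        if _is_leaf(u):
            continue
        for v in adj[u]:
            if _is_leaf(v):
                continue
            key = frozenset((u, v))
            if key not in seen:
                seen.add(key)
                yield u, v


def nni_neighbors(adj: Adjacency):
    """Yield every topology one nearest-neighbor interchange away."""
    for u, v in _internal_edges(adj):
        b_candidates = sorted(adj[u] - {v}, key=repr)
        c_candidates = sorted(adj[v] - {u}, key=repr)
        b = b_candidates[1]
        for c in c_candidates:
            new = {k: set(s) for k, s in adj.items()}
            new[u].discard(b)
            new[b].discard(u)
            new[v].discard(c)
            new[c].discard(v)
            new[u].add(c)
            new[c].add(u)
            new[v].add(b)
            new[b].add(v)
            yield new


@dataclass
class Tree:
    """A parsimony tree: leaf labels, germline-rooted newick, Fitch score."""

    leaves: list[str]
    newick: str
    parsimony_score: int
    adjacency: Adjacency = field(repr=False, default_factory=dict)
    co_optimal: list[str] | None = None


def search_tree(
    matrix,
    mode: str = "nni",
    seed: int | None = None,
    return_all: bool = False,
) -> Tree:
    """Maximum-parsimony tree search over the binary mutation matrix.

    ``exhaustive`` enumerates every unrooted topology (allowed up to
    8 leaves) and returns a global optimum; ``nni`` hill-climbs by
    nearest-neighbor interchange from the neighbor-joining start tree and
    returns a local optimum whose score never exceeds the start's.  Ties are
    broken by the lexicographically smallest canonical newick.  The procedure
    is deterministic; ``seed`` is accepted for interface stability.
    """
    presence = _presence_frame(matrix)
    leaves = list(presence.index)
    if len(leaves) < 3:
        raise ValueError("tree search requires at least 3 leaves")
    if mode == "exhaustive":
        if len(leaves) > MAX_EXHAUSTIVE_LEAVES:
            raise ValueError(
                f"exhaustive search limited to {MAX_EXHAUSTIVE_LEAVES} leaves"
            )
        best_score = None
        best: list[str] = []
        best_adj = {}
        for adj in enumerate_topologies(leaves):
            s = fitch_score(adj, presence)
            if best_score is None or s < best_score:
                best_score, best = s, [canonical_newick(adj)]
                best_adj = {canonical_newick(adj): adj}
            elif s == best_score:
                nwk = canonical_newick(adj)
                if nwk not in best_adj:
                    best.append(nwk)
                    best_adj[nwk] = adj
        best.sort()
        return Tree(
            leaves=leaves, newick=best[0], parsimony_score=best_score,
            adjacency=best_adj[best[0]],
            co_optimal=sorted(set(best)) if return_all else None,
        )
    if mode != "nni":
        raise ValueError(f"unknown search mode {mode!r}")

    adj = nj_start_tree(presence)
    score = fitch_score(adj, presence)
    visited = {canonical_newick(adj)}
    sideways_budget = 20  # plateau walking before declaring a local optimum
    while True:
        candidates = []
        for cand in nni_neighbors(adj):
            s = fitch_score(cand, presence)
            if s <= score:
                nwk = canonical_newick(cand)
                if nwk not in visited:
                    candidates.append((s, nwk, cand))
        if not candidates:
            break
        candidates.sort(key=lambda c: (c[0], c[1]))
        s, nwk, cand = candidates[0]
        if s < score:
            sideways_budget = 20
        elif sideways_budget > 0:
            sideways_budget -= 1
        else:
            break
        adj, score = cand, s
        visited.add(nwk)
    return Tree(
        leaves=leaves, newick=canonical_newick(adj), parsimony_score=score,
        adjacency=adj, co_optimal=None,
    )
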