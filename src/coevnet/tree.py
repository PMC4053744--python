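"""Spanning-tree graphical models over interface columns.

A family's interface profile is a pair of tree-structured probabilistic
graphical models over the union of both proteins' interface columns: a
*positive* tree learned from simulated interacting pairs and a *negative*
tree learned from background-shuffled pairs.  Structure is the maximum-weight
spanning tree under pairwise mutual information (the Chow–Liu tree, the
canonical maximum-likelihood tree distribution); parameters are pseudocounted
node marginals and edge conditional tables over the 21-symbol alphabet
(20 residues + gap), so gapped query interfaces stay scorable.

Tie-breaking is deterministic throughout: candidate edges are sorted
lexicographically before extraction and the root is the smallest node id, so
learning is invariant to sample order.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .alphabet import ALPHABET, N_SYMBOLS, SYMBOL_INDEX, encode
from .interface import (
    AlignedSequencePair,
    ContactMap,
    InterfaceAssignment,
    Node,
    node_str,
    parse_node,
)
from .mcmc import SampleSet


# ---------------------------------------------------------------------------
# the tree model
# ---------------------------------------------------------------------------


@dataclass
class TreePGM:
    """Rooted spanning tree with a root marginal and per-edge CPTs.

    ``edges`` are (parent, child) pairs in a topological order from the root;
    ``edge_cpt[(parent, child)][x_p, x_c] = P(x_c | x_p)`` over 21 symbols.
    """

    nodes: tuple[Node, ...]
    root: Node
    edges: tuple[tuple[Node, Node], ...]
    node_marginal: np.ndarray  # (21,) marginal of the root
    edge_cpt: dict[tuple[Node, Node], np.ndarray]
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        self.nodes = tuple(sorted(self.nodes))
        self.node_marginal = np.asarray(self.node_marginal, dtype=float)
        if self.root not in self.nodes:
            raise ValueError("root must be one of the nodes")
        n = len(self.nodes)
        if len(self.edges) != n - 1:
            raise ValueError(f"{n} nodes require {n - 1} edges, got {len(self.edges)}")
        # connectivity/acyclicity: every non-root node appears exactly once as child
        children = [c for _, c in self.edges]
        if sorted(children) != sorted(set(self.nodes) - {self.root}):
            raise ValueError("edges must form a tree rooted at the root node")
        if not math.isclose(float(self.node_marginal.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("root marginal must sum to 1")
        for e, cpt in self.edge_cpt.items():
            cpt = np.asarray(cpt, dtype=float)
            if cpt.shape != (N_SYMBOLS, N_SYMBOLS):
                raise ValueError(f"CPT of edge {e} must be 21x21")
            if not np.allclose(cpt.sum(axis=1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows of edge {e} must sum to 1")
            self.edge_cpt[e] = cpt

    # --- scoring ----------------------------------------------------------

    def loglik(self, assignment: InterfaceAssignment) -> float:
        """log2-likelihood of an interface assignment under the tree."""
        assignment.check_nodes(self.nodes)
        sym = {n: SYMBOL_INDEX[assignment.residues[n]] for n in self.nodes}
        total = math.log2(float(self.node_marginal[sym[self.root]]))
        for (p, c), cpt in self.edge_cpt.items():
            total += math.log2(float(cpt[sym[p], sym[c]]))
        return total

    # --- sampling ---------------------------------------------------------

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Ancestral sampling: (n, n_nodes) int8 symbol matrix (node order = sorted)."""
        pos = {node: k for k, node in enumerate(self.nodes)}
        out = np.empty((n, len(self.nodes)), dtype=np.int8)
        root_cum = np.cumsum(self.node_marginal)
        u = rng.random(n)
        out[:, pos[self.root]] = np.minimum(
            np.searchsorted(root_cum, u, side="right"), N_SYMBOLS - 1
        )
        for (p, c), cpt in self.edges_topological():
            cum = np.cumsum(cpt, axis=1)
            parent_syms = out[:, pos[p]].astype(np.intp)
            u = rng.random(n)
            vals = np.empty(n, dtype=np.int8)
            for sym in np.unique(parent_syms):
                mask = parent_syms == sym
                vals[mask] = np.minimum(
                    np.searchsorted(cum[sym], u[mask], side="right"), N_SYMBOLS - 1
                )
            out[:, pos[c]] = vals
        return out

    def edges_topological(self):
        """Yield (edge, cpt) in an order where parents precede children."""
        placed = {self.root}
        pending = list(self.edges)
        while pending:
            progressed = False
            for e in list(pending):
                if e[0] in placed:
                    placed.add(e[1])
                    pending.remove(e)
                    progressed = True
                    yield e, self.edge_cpt[e]
            if not progressed:  # pragma: no cover - guarded by __post_init__
                raise ValueError("edges are not a tree rooted at the root")

    @property
    def undirected_edges(self) -> frozenset[frozenset[Node]]:
        return frozenset(frozenset(e) for e in self.edges)

    # --- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "nodes": [node_str(n) for n in self.nodes],
            "root": node_str(self.root),
            "edges": [[node_str(p), node_str(c)] for p, c in self.edges],
            "root_marginal": self.node_marginal.tolist(),
            "cpts": [self.edge_cpt[e].tolist() for e in self.edges],
            "pseudocount": self.pseudocount,
            "alphabet": ALPHABET,
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "TreePGM":
        edges = tuple((parse_node(p), parse_node(c)) for p, c in d["edges"])
        return cls(
            nodes=tuple(parse_node(s) for s in d["nodes"]),
            root=parse_node(d["root"]),
            edges=edges,
            node_marginal=np.asarray(d["root_marginal"], dtype=float),
            edge_cpt={e: np.asarray(cpt, float) for e, cpt in zip(edges, d["cpts"])},
            pseudocount=float(d.get("pseudocount", 0.5)),
        )


@dataclass
class InterfaceProfilePair:
    """Positive + negative tree profile of one family."""

    positive: TreePGM
    negative: TreePGM
    family_id: str = "family"

    def __post_init__(self) -> None:
        if set(self.positive.nodes) != set(self.negative.nodes):
            raise ValueError("positive and negative trees must share the node set")

    def to_dict(self) -> dict:
        return {
            "family_id": self.family_id,
            "positive": self.positive.to_dict(),
            "negative": self.negative.to_dict(),
        }

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh)

    @classmethod
    def load(cls, path: str | Path) -> "InterfaceProfilePair":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            positive=TreePGM.from_dict(d["positive"]),
            negative=TreePGM.from_dict(d["negative"]),
            family_id=d.get("family_id", "family"),
        )


# ---------------------------------------------------------------------------
# sample matrices and mutual information
# ---------------------------------------------------------------------------


def _as_pairs(samples: SampleSet | Sequence[AlignedSequencePair]) -> list[AlignedSequencePair]:
    return list(samples.samples) if isinstance(samples, SampleSet) else list(samples)


def node_matrix(
    samples: SampleSet | Sequence[AlignedSequencePair], nodes: Sequence[Node]
) -> np.ndarray:
    """(n_samples, n_nodes) int8 matrix of interface symbols."""
    pairs = _as_pairs(samples)
    out = np.empty((len(pairs), len(nodes)), dtype=np.int8)
    for r, pair in enumerate(pairs):
        a = encode(pair.seq_a)
        b = encode(pair.seq_b)
        for k, (tag, col) in enumerate(nodes):
            out[r, k] = a[col - 1] if tag == "A" else b[col - 1]
    return out


def _joint_counts(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    idx = x.astype(np.intp) * N_SYMBOLS + y.astype(np.intp)
    return np.bincount(idx, minlength=N_SYMBOLS * N_SYMBOLS).reshape(
        N_SYMBOLS, N_SYMBOLS
    ).astype(float)


def mi_from_counts(counts: np.ndarray, pseudocount: float = 0.0) -> float:
    """Mutual information (bits) of a pseudocounted joint count table."""
    joint = counts + pseudocount
    total = joint.sum()
    if total <= 0:
        raise ValueError("empty joint")
    p = joint / total
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float(np.sum(p[mask] * np.log2(p[mask] / (px @ py)[mask])))


def mutual_information(
    samples: SampleSet | Sequence[AlignedSequencePair],
    node_i: Node,
    node_j: Node,
    pseudocount: float = 0.5,
) -> float:
    """Pairwise MI (bits) between two interface nodes over the 21-symbol alphabet."""
    pairs = _as_pairs(samples)
    if not pairs:
        raise ValueError("need at least one sample")
    la, lb = pairs[0].length_a, pairs[0].length_b
    for node in (node_i, node_j):
        tag, col = node
        limit = la if tag == "A" else lb
        if tag not in ("A", "B") or not (1 <= col <= limit):
            raise ValueError(f"unknown node id {node}")
    m = node_matrix(pairs, [node_i, node_j])
    return mi_from_counts(_joint_counts(m[:, 0], m[:, 1]), pseudocount)


# ---------------------------------------------------------------------------
# structure + parameter learning
# ---------------------------------------------------------------------------


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, x, y) -> bool:
        rx, ry = self.find(x), self.find(y)
        if rx == ry:
            return False
        self.parent[ry] = rx
        return True


def learn_tree_from_matrix(
    matrix: np.ndarray, nodes: Sequence[Node], pseudocount: float = 0.5
) -> TreePGM:
    """Chow–Liu learning from a symbol matrix whose columns follow *nodes*."""
    nodes = sorted(nodes)
    n = len(nodes)
    if n == 0:
        raise ValueError("cannot learn a tree over zero nodes")
    if matrix.shape[0] < 2:
        raise ValueError("need at least two samples")
    if matrix.shape[1] != n:
        raise ValueError("matrix column count does not match node count")
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")

    root = nodes[0]

    if n == 1:
        counts = np.bincount(matrix[:, 0].astype(np.intp), minlength=N_SYMBOLS).astype(float)
        marg = (counts + pseudocount) / (counts.sum() + N_SYMBOLS * pseudocount)
        return TreePGM(tuple(nodes), root, (), marg, {}, pseudocount)

    # pairwise joints and MI weights
    joints: dict[tuple[int, int], np.ndarray] = {}
    weighted_edges = []
    for i in range(n):
        for j in range(i + 1, n):
            counts = _joint_counts(matrix[:, i], matrix[:, j])
            joints[(i, j)] = counts
            mi = mi_from_counts(counts, pseudocount)
            weighted_edges.append((mi, nodes[i], nodes[j], i, j))
    # max-weight spanning tree, lexicographic tie-break on (u, v)
    weighted_edges.sort(key=lambda t: (-t[0], t[1], t[2]))
    uf = _UnionFind(nodes)
    undirected: list[tuple[Node, Node, int, int]] = []
    for mi, u, v, i, j in weighted_edges:
        if uf.union(u, v):
            undirected.append((u, v, i, j))
        if len(undirected) == n - 1:
            break

    # orient away from the root (BFS over the undirected tree)
    adj: dict[Node, list[tuple[Node, int, int]]] = {x: [] for x in nodes}
    for u, v, i, j in undirected:
        adj[u].append((v, i, j))
        adj[v].append((u, j, i))
    edges: list[tuple[Node, Node]] = []
    edge_cols: dict[tuple[Node, Node], tuple[int, int]] = {}
    seen = {root}
    frontier = [root]
    while frontier:
        nxt = []
        for p in frontier:
            for c, pi, ci in sorted(adj[p], key=lambda t: t[0]):
                if c in seen:
                    continue
                seen.add(c)
                edges.append((p, c))
                edge_cols[(p, c)] = (pi, ci)
                nxt.append(c)
        frontier = nxt

    # parameters
    root_idx = nodes.index(root)
    counts = np.bincount(matrix[:, root_idx].astype(np.intp), minlength=N_SYMBOLS).astype(float)
    marg = (counts + pseudocount) / (counts.sum() + N_SYMBOLS * pseudocount)
    cpts: dict[tuple[Node, Node], np.ndarray] = {}
    for (p, c), (pi, ci) in edge_cols.items():
        jc = _joint_counts(matrix[:, pi], matrix[:, ci]) + pseudocount
        cpts[(p, c)] = jc / jc.sum(axis=1, keepdims=True)
    return TreePGM(tuple(nodes), root, tuple(edges), marg, cpts, pseudocount)


def learn_tree(
    samples: SampleSet | Sequence[AlignedSequencePair],
    contact_map: ContactMap,
    pseudocount: float = 0.5,
) -> TreePGM:
    """Learn a tree profile over the contact map's interface columns."""
    nodes = contact_map.nodes
    if len(nodes) == 0:
        raise ValueError("contact map has no interface columns")
    matrix = node_matrix(samples, sorted(nodes))
    return learn_tree_from_matrix(matrix, nodes, pseudocount)


def build_negative_samples(
    samples: SampleSet | Sequence[AlignedSequencePair], rng: np.random.Generator
) -> list[AlignedSequencePair]:
    """Derange the B-halves to destroy inter-protein correlations.

    A-sequences keep their order; B-sequences are permuted by a derangement
    (no fixed points), which preserves both marginal sequence distributions
    while removing every inter-protein dependency — the background model the
    negative tree is learned from.
    """
    pairs = _as_pairs(samples)
    n = len(pairs)
    if n < 2:
        raise ValueError("need at least two samples to derange")
    if n == 2:
        perm = np.array([1, 0])
    else:
        while True:
            perm = rng.permutation(n)
            if not np.any(perm == np.arange(n)):
                break
    return [
        AlignedSequencePair(pairs[k].seq_a, pairs[int(perm[k])].seq_b) for k in range(n)
    ]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------


def tree_loglik(assignment: InterfaceAssignment, tree: TreePGM) -> float:
    """log2 P(assignment) under the tree factorization."""
    return tree.loglik(assignment)


def score_interface(
    assignment: InterfaceAssignment, profile_pair: InterfaceProfilePair
) -> tuple[float, float]:
    """(L+, L-): log-likelihood under the positive and the negative tree."""
    return (
        tree_loglik(assignment, profile_pair.positive),
        tree_loglik(assignment, profile_pair.negative),
    )
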