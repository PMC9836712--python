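"""Neighbor-joining from a K2P matrix, with nonparametric column bootstrap.

The agglomeration is the standard Saitou–Nei Q-criterion. Two deliberate
numerical conventions: ties in the Q minimum are broken by the smallest
(i, j) index pair after lexicographic sorting of sample ids, and negative
branch-length estimates are clamped to zero with the deficit moved to the
sister branch. Bootstrap support is the percentage of column-resampled
replicates whose NJ tree contains each bipartition of the full-data tree.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import dendropy
import numpy as np

from .distances import DistanceMatrix, k2p_matrix
from .model import BarcodeAlignment, MISSING

__all__ = ["BootstrapConfig", "nj", "bootstrap_support", "tree_splits", "midpoint_root"]

_TS_PARTNER = np.array([2, 3, 0, 1], dtype=np.uint8)


@dataclass(frozen=True)
class BootstrapConfig:
    replicates: int = 1000
    seed: int = 0
    support_scale: float = 100.0
    max_dropped_frac: float = 0.10

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


@dataclass
class _SimpleTree:
    """Minimal unrooted tree: children adjacency from an arbitrary center."""

    ids: list[str]
    children: dict[int, list[tuple[int, float]]]
    center: int
    leafsets: dict[int, frozenset] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.leafsets:
            self._fill_leafsets(self.center)

    def _fill_leafsets(self, node: int) -> frozenset:
        if node < len(self.ids):
            ls = frozenset([self.ids[node]])
        else:
            ls = frozenset().union(
                *(self._fill_leafsets(c) for c, _ in self.children[node])
            )
        self.leafsets[node] = ls
        return ls

    def splits(self) -> set[frozenset]:
        """Nontrivial bipartitions, each canonicalised to the side without ids[0]."""
        ref = self.ids[0]
        full = frozenset(self.ids)
        out = set()
        for node, ls in self.leafsets.items():
            if node == self.center or len(ls) < 2 or len(ls) > len(self.ids) - 2:
                continue
            out.add(full - ls if ref in ls else ls)
        return out

    def newick(self, support: Mapping[frozenset, float] | None = None) -> str:
        full = frozenset(self.ids)
        ref = self.ids[0]

        def fmt(node: int) -> str:
            if node < len(self.ids):
                return self.ids[node]
            parts = ",".join(
                f"{fmt(c)}:{bl:.10g}" for c, bl in self.children[node]
            )
            label = ""
            if support is not None and node != self.center:
                ls = self.leafsets[node]
                key = full - ls if ref in ls else ls
                if key in support:
                    label = f"{support[key]:g}"
            return f"({parts}){label}"

        return fmt(self.center) + ";"


def _nj_core(D: np.ndarray, ids: list[str]) -> _SimpleTree:
    n = len(ids)
    if n < 3:
        raise ValueError("NJ needs at least 3 samples")
    D = D.astype(float).copy()
    nodes = list(range(n))  # active cluster -> node id
    children: dict[int, list[tuple[int, float]]] = {}
    next_id = n
    while len(nodes) > 3:
        m = D.shape[0]
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        flat = int(np.argmin(Q))  # row-major: smallest (i, j) on ties
        i, j = divmod(flat, m)
        if i > j:
            i, j = j, i
        vi = 0.5 * D[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        vj = D[i, j] - vi
        if vi < 0:
            vi, vj = 0.0, D[i, j]
        elif vj < 0:
            vi, vj = D[i, j], 0.0
        dnew = 0.5 * (D[i] + D[j] - D[i, j])
        children[next_id] = [(nodes[i], vi), (nodes[j], vj)]
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [next_id]
        next_id += 1
    a, b, c = 0, 1, 2
    va = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    vb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    vc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    children[next_id] = [
        (nodes[a], max(va, 0.0)),
        (nodes[b], max(vb, 0.0)),
        (nodes[c], max(vc, 0.0)),
    ]
    return _SimpleTree(ids=ids, children=children, center=next_id)


def _canonical_order(matrix: DistanceMatrix) -> DistanceMatrix:
    order = sorted(matrix.ids)
    return matrix.submatrix(order) if order != matrix.ids else matrix


def _to_dendropy(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True,
        suppress_internal_node_taxa=True,
    )
    tree.is_rooted = False
    return tree


def nj(matrix: DistanceMatrix) -> dendropy.Tree:
    """Unrooted NJ tree from a fully defined distance matrix."""
    if matrix.n_undefined_pairs:
        raise ValueError(
            f"{matrix.n_undefined_pairs} undefined pair(s) in the matrix; apply "
            "a saturation_policy (DistanceMatrix.apply_saturation_policy) first"
        )
    return _to_dendropy(_nj_core(_canonical_order(matrix).d, sorted(matrix.ids)).newick())


def tree_splits(tree: dendropy.Tree) -> set[frozenset]:
    """Nontrivial bipartitions of an (un)rooted dendropy tree, canonicalised."""
    leaves = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    full, ref = frozenset(leaves), leaves[0]
    out = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        ls = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(ls) < 2 or len(ls) > len(leaves) - 2:
            continue
        out.add(full - ls if ref in ls else ls)
    return out


def _pair_category_arrays(alignment: BarcodeAlignment
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(n_pairs, L) float32 indicator arrays: comparable, transition, transversion."""
    enc = alignment.encoded()
    ok = enc != MISSING
    n, L = enc.shape
    npairs = n * (n - 1) // 2
    OK = np.empty((npairs, L), dtype=np.float32)
    TS = np.empty((npairs, L), dtype=np.float32)
    TV = np.empty((npairs, L), dtype=np.float32)
    p = 0
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            diff = both & (enc[i] != enc[j])
            ts = diff & (_TS_PARTNER[enc[i]] == enc[j])
            OK[p] = both
            TS[p] = ts
            TV[p] = diff & ~ts
            p += 1
    return OK, TS, TV


def _squareform(cond: np.ndarray, n: int) -> np.ndarray:
    M = np.zeros((n, n))
    iu = np.triu_indices(n, k=1)
    M[iu] = cond
    return M + M.T


def bootstrap_support(alignment: BarcodeAlignment,
                      config: BootstrapConfig) -> dendropy.Tree:
    """NJ tree with bootstrap support (percent) as internal-node labels.

    Columns are resampled with replacement per replicate; replicates whose
    K2P matrix has undefined entries are dropped and counted, with an error
    if more than ``max_dropped_frac`` of replicates are lost.
    """
    order = sorted(alignment.ids)
    aln = BarcodeAlignment(
        sorted(alignment.records, key=lambda r: r.sample_id)
    ) if order != alignment.ids else alignment
    full = k2p_matrix(aln)
    if full.n_undefined_pairs:
        raise ValueError("full-data matrix has undefined pairs; resolve saturation first")
    base = _nj_core(full.d, order)
    target_splits = base.splits()
    counts = {s: 0 for s in target_splits}

    OK, TS, TV = _pair_category_arrays(aln)
    L = aln.length
    n = len(order)
    rng = np.random.default_rng(config.seed)
    dropped = 0
    valid = 0
    for _ in range(config.replicates):
        w = rng.multinomial(L, np.full(L, 1.0 / L)).astype(np.float32)
        okn = OK @ w
        if (okn == 0).any():
            dropped += 1
            continue
        P = (TS @ w) / okn
        Q = (TV @ w) / okn
        w1 = 1.0 - 2.0 * P - Q
        w2 = 1.0 - 2.0 * Q
        if (w1 <= 0).any() or (w2 <= 0).any():
            dropped += 1
            continue
        d = -0.5 * np.log(w1) - 0.25 * np.log(w2)
        rep = _nj_core(_squareform(d, n), order)
        for s in rep.splits():
            if s in counts:
                counts[s] += 1
        valid += 1
    if dropped > config.max_dropped_frac * config.replicates:
        raise ValueError(
            f"{dropped}/{config.replicates} bootstrap replicates dropped "
            "(undefined distances); data too saturated for NJ bootstrap"
        )
    if valid == 0:
        raise ValueError("no valid bootstrap replicates")
    support = {
        s: config.support_scale * c / valid for s, c in counts.items()
    }
    return _to_dendropy(base.newick(support=support))


def midpoint_root(tree: dendropy.Tree) -> dendropy.Tree:
    """Midpoint-rooted copy of a tree (for rooted-tree consumers like PTP)."""
    t = tree.clone(depth=1)
    t.reroot_at_midpoint(update_bipartitions=False)
    t.is_rooted = True
    for edge in t.preorder_edge_iter():  # guard float dust from rerooting
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
    return t
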