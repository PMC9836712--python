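"""Shared fixtures: tiny hand-checkable alignments and matrix builders."""

from __future__ import annotations

import numpy as np
import pytest

from otudelim.distances import DistanceMatrix
from otudelim.model import BarcodeAlignment, SequenceRecord


#: 4 x 6 toy alignment: columns are conserved, singleton, informative,
#: conserved, singleton, informative; pooled pairwise ts=10, tv=4.
TOY_SEQS = {
    "s1": "AAATCC",
    "s2": "AAATCG",
    "s3": "AAGTCC",
    "s4": "AGGTTG",
}


@pytest.fixture
def toy_alignment() -> BarcodeAlignment:
    return BarcodeAlignment(
        [SequenceRecord(k, v, species_label="spA") for k, v in TOY_SEQS.items()]
    )


def make_matrix(d: np.ndarray, ids: list[str] | None = None,
                defined: np.ndarray | None = None) -> DistanceMatrix:
    """Distance matrix with placeholder P/Q/n for partition-level tests."""
    n = d.shape[0]
    ids = ids or [f"t{i}" for i in range(n)]
    if defined is None:
        defined = np.ones((n, n), dtype=bool)
    return DistanceMatrix(
        ids, d.astype(float), np.zeros_like(d, dtype=float),
        np.zeros_like(d, dtype=float), np.full((n, n), 500, dtype=int), defined,
    )


def two_cluster_matrix(rng: np.random.Generator, n_a: int = 4, n_b: int = 4,
                       within: tuple[float, float] = (0.002, 0.01),
                       between: tuple[float, float] = (0.10, 0.12)) -> DistanceMatrix:
    n = n_a + n_b
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            same = (i < n_a) == (j < n_a)
            lo, hi = within if same else between
            d[i, j] = d[j, i] = rng.uniform(lo, hi)
    return make_matrix(d)


def random_additive_matrix(rng: np.random.Generator, n_taxa: int
                           ) -> tuple[np.ndarray, list[str], set[frozenset]]:
    """Random binary tree -> exact path-distance matrix + its splits."""
    ids = [f"t{i}" for i in range(n_taxa)]
    # random agglomeration builds the topology; edge lengths positive
    nodes = {i: frozenset([ids[i]]) for i in range(n_taxa)}
    dist = np.zeros((n_taxa, n_taxa))
    depth = {i: 0.0 for i in range(n_taxa)}  # leafset member depths handled via dist
    active = list(range(n_taxa))
    next_id = n_taxa
    leafsets = dict(nodes)
    member = {i: [i] for i in range(n_taxa)}  # cluster -> leaf indices
    extra = {i: {ids[i]: 0.0} for i in range(n_taxa)}  # leaf -> dist to cluster root
    splits: set[frozenset] = set()
    full = frozenset(ids)
    while len(active) > 1:
        i, j = rng.choice(len(active), size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        la = rng.uniform(0.5, 3.0)
        lb = rng.uniform(0.5, 3.0)
        for u in member[a]:
            for v in member[b]:
                dist[u, v] = dist[v, u] = (
                    extra[a][ids[u]] + la + extra[b][ids[v]] + lb
                )
        merged = leafsets[a] | leafsets[b]
        if 2 <= len(merged) <= n_taxa - 2:
            splits.add(merged if ids[0] not in merged else full - merged)
        new_extra = {}
        for u in member[a]:
            new_extra[ids[u]] = extra[a][ids[u]] + la
        for v in member[b]:
            new_extra[ids[v]] = extra[b][ids[v]] + lb
        member[next_id] = member[a] + member[b]
        leafsets[next_id] = merged
        extra[next_id] = new_extra
        active = [x for x in active if x not in (a, b)] + [next_id]
        next_id += 1
    return dist, ids, splits
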