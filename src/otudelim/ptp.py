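"""Maximum-likelihood Poisson-tree-process species delimitation.

The model assumes substitutions accumulate as a Poisson process whose
per-branch event counts follow two exponential branch-length classes on a
rooted, non-ultrametric gene tree: *speciation* branches (between species)
and *within-species* branches. A candidate delimitation is a set of
"transition nodes" — roots of within-species subtrees that tile the leaves.
Edges strictly below a transition node are within-species class; all other
edges are speciation class. Each class's rate is set to its ML value
(edge count / total edge length), giving per class

    logL = n * ln(n / total_length) - n

The search hill-climbs over transition-node sets from the one-species state
(which is exactly the one-class null model), moving one node per step and
taking the best improvement, with seeded random restarts. Because the
two-class model nests the null and its class assignment adapts to noise, a
multi-species result is only accepted when a likelihood-ratio test rejects
the one-class model; otherwise a single species is reported.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .model import Partition

__all__ = ["PtpModel", "PtpSearchConfig", "null_loglik", "ptp_ml", "loglik_for_partition"]


@dataclass(frozen=True)
class PtpSearchConfig:
    restarts: int = 10
    seed: int = 0
    #: floor for zero-length edges, in substitutions/site. Set near the
    #: resolution of the data (~1/alignment length): with an unboundedly
    #: small floor, a class of collapsed edges gets an unbounded rate and
    #: the degenerate everything-is-a-species state dominates the likelihood.
    min_branch: float = 1e-4
    #: likelihood-ratio acceptance of the two-class model over the one-class
    #: null: df ~ one extra rate + the data-adaptive placement of the rate
    #: shift; without this gate the adaptive class assignment splits even
    #: homogeneous one-rate trees
    lrt_df: int = 4
    lrt_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")


@dataclass
class PtpModel:
    lambda_speciation: float
    lambda_within: float
    species_subtrees: list[frozenset]
    log_likelihood: float
    n_species: int


class _TreeArrays:
    """Index-based view of a rooted tree for O(1) move evaluation.

    Node 0 is the root; every non-root node carries the length of the edge
    above it, floored at ``min_branch``. ``sub_edges``/``sub_len`` count the
    edges *strictly below* each node.
    """

    def __init__(self, tree: dendropy.Tree, min_branch: float) -> None:
        if not tree.is_rooted:
            raise ValueError("PTP requires a rooted tree")
        work = tree.clone(depth=1)
        n_poly = sum(
            1 for nd in work.preorder_node_iter() if len(nd.child_nodes()) > 2
        )
        if n_poly:
            warnings.warn(
                f"resolving {n_poly} polytomy(ies) arbitrarily with zero-length edges",
                stacklevel=3,
            )
            work.resolve_polytomies(update_bipartitions=False)
        nodes = list(work.preorder_node_iter())
        if len(nodes) < 3:
            raise ValueError("PTP needs a rooted tree with >= 2 leaves")
        index = {id(nd): k for k, nd in enumerate(nodes)}
        n = len(nodes)
        self.parent = np.full(n, -1, dtype=int)
        self.blen = np.zeros(n)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.leaf_label: list[str | None] = [None] * n
        for k, nd in enumerate(nodes):
            if nd.parent_node is not None:
                p = index[id(nd.parent_node)]
                self.parent[k] = p
                self.children[p].append(k)
                bl = nd.edge.length if nd.edge.length is not None else 0.0
                if bl < 0:
                    raise ValueError("negative branch length in input tree")
                self.blen[k] = max(bl, min_branch)
            if nd.is_leaf():
                self.leaf_label[k] = nd.taxon.label
        self.n_edges = n - 1
        self.total_len = float(self.blen[1:].sum())
        if self.total_len <= n * min_branch:
            raise ValueError("all branch lengths are (effectively) zero")
        # postorder accumulation of strict-subtree edge counts/lengths
        self.sub_edges = np.zeros(n, dtype=int)
        self.sub_len = np.zeros(n)
        for k in range(n - 1, -1, -1):
            for c in self.children[k]:
                self.sub_edges[k] += self.sub_edges[c] + 1
                self.sub_len[k] += self.sub_len[c] + self.blen[c]
        self.leaves_below: list[frozenset] = [frozenset()] * n
        for k in range(n - 1, -1, -1):
            if not self.children[k]:
                self.leaves_below[k] = frozenset([self.leaf_label[k]])
            else:
                self.leaves_below[k] = frozenset().union(
                    *(self.leaves_below[c] for c in self.children[k])
                )


def _class_loglik(n: int, length: float) -> float:
    if n == 0:
        return 0.0
    return n * math.log(n / length) - n


def _state_loglik(ta: _TreeArrays, n_w: int, l_w: float) -> float:
    n_s = ta.n_edges - n_w
    l_s = ta.total_len - l_w
    return _class_loglik(n_w, l_w) + _class_loglik(n_s, l_s)


def null_loglik(tree: dendropy.Tree, min_branch: float = 1e-4
                ) -> tuple[float, float]:
    """One-class baseline: all edges share a single exponential rate.

    Returns ``(lambda_hat, logL)`` with ``lambda_hat = E / total_length``.
    """
    ta = _TreeArrays(tree, min_branch)
    lam = ta.n_edges / ta.total_len
    return lam, _class_loglik(ta.n_edges, ta.total_len)


def _hill_climb(ta: _TreeArrays, frontier: set[int]) -> tuple[set[int], int, float, float]:
    n_w = int(sum(ta.sub_edges[s] for s in frontier))
    l_w = float(sum(ta.sub_len[s] for s in frontier))
    best = _state_loglik(ta, n_w, l_w)
    improved = True
    while improved:
        improved = False
        best_move: tuple[str, int] | None = None
        best_ll = best
        for s in sorted(frontier):
            if ta.children[s]:  # split s into its children
                dn = -len(ta.children[s])
                dl = -float(sum(ta.blen[c] for c in ta.children[s]))
                ll = _state_loglik(ta, n_w + dn, l_w + dl)
                if ll > best_ll + 1e-12:
                    best_ll, best_move = ll, ("split", s)
        parents = {int(ta.parent[s]) for s in frontier if ta.parent[s] >= 0}
        for p in sorted(parents):
            if all(c in frontier for c in ta.children[p]):
                dn = len(ta.children[p])
                dl = float(sum(ta.blen[c] for c in ta.children[p]))
                ll = _state_loglik(ta, n_w + dn, l_w + dl)
                if ll > best_ll + 1e-12:
                    best_ll, best_move = ll, ("merge", p)
        if best_move is not None:
            kind, node = best_move
            if kind == "split":
                frontier.discard(node)
                frontier.update(ta.children[node])
                n_w -= len(ta.children[node])
                l_w -= float(sum(ta.blen[c] for c in ta.children[node]))
            else:
                for c in ta.children[node]:
                    frontier.discard(c)
                frontier.add(node)
                n_w += len(ta.children[node])
                l_w += float(sum(ta.blen[c] for c in ta.children[node]))
            best = best_ll
            improved = True
    return frontier, n_w, l_w, best


def _threshold_frontier(ta: _TreeArrays, threshold: float) -> set[int]:
    """Maximal nodes whose subtrees only contain edges shorter than threshold.

    Cutting the tree at long edges is how a two-class structure looks when
    the rate classes are separated in branch length; these cuts make good
    deterministic search starts at every scale.
    """
    n = len(ta.children)
    submax = np.zeros(n)
    for k in range(n - 1, -1, -1):
        for c in ta.children[k]:
            submax[k] = max(submax[k], submax[c], ta.blen[c])
    frontier: set[int] = set()
    stack = [0]
    while stack:
        k = stack.pop()
        if submax[k] < threshold or not ta.children[k]:
            frontier.add(k)
        else:
            stack.extend(ta.children[k])
    return frontier


def _random_frontier(ta: _TreeArrays, rng: np.random.Generator) -> set[int]:
    frontier: set[int] = set()
    stack = [0]
    while stack:
        k = stack.pop()
        if ta.children[k] and rng.random() < 0.5:
            stack.extend(ta.children[k])
        else:
            frontier.add(k)
    return frontier


def ptp_ml(tree: dendropy.Tree, config: PtpSearchConfig = PtpSearchConfig()
           ) -> tuple[PtpModel, Partition]:
    """Best two-class PTP delimitation found by restarted hill climbing.

    The one-species state (the null model) is always among the starting
    points, so the returned log-likelihood is never below ``null_loglik``.
    """
    ta = _TreeArrays(tree, config.min_branch)
    rng = np.random.default_rng(config.seed)
    starts: list[set[int]] = [
        {0},  # one species: the null model
        {k for k in range(len(ta.children)) if not ta.children[k]},  # all singletons
    ]
    for q in np.linspace(0.05, 0.95, 19):
        starts.append(_threshold_frontier(ta, float(np.quantile(ta.blen[1:], q))))
    for _ in range(config.restarts):
        starts.append(_random_frontier(ta, rng))
    best: tuple[set[int], int, float, float] | None = None
    for s0 in starts:
        cand = _hill_climb(ta, set(s0))
        if best is None or cand[3] > best[3] + 1e-12:
            best = cand
    frontier, n_w, l_w, logl = best
    null = _class_loglik(ta.n_edges, ta.total_len)
    if len(frontier) > 1:
        from scipy.stats import chi2

        if 2.0 * (logl - null) < chi2.ppf(1.0 - config.lrt_alpha, config.lrt_df):
            # one-class model not rejected: report a single species
            frontier = {0}
            n_w, l_w, logl = ta.n_edges, ta.total_len, null
    n_s = ta.n_edges - n_w
    l_s = ta.total_len - l_w
    single_rate = ta.n_edges / ta.total_len
    model = PtpModel(
        lambda_speciation=(n_s / l_s) if n_s else single_rate,
        lambda_within=(n_w / l_w) if n_w else single_rate,
        species_subtrees=[ta.leaves_below[s] for s in sorted(frontier)],
        log_likelihood=logl,
        n_species=len(frontier),
    )
    partition = Partition.from_groups(
        [sorted(ls) for ls in model.species_subtrees],
        method_name="ptp_ml",
        parameters={"restarts": config.restarts, "seed": config.seed},
    ).canonicalize()
    return model, partition


def loglik_for_partition(tree: dendropy.Tree, partition: Partition,
                         min_branch: float = 1e-4) -> float:
    """Independently recompute the two-class logL implied by a partition.

    Each OTU is mapped to the MRCA subtree of its samples; edges strictly
    inside those subtrees are within-species class. Walks every edge
    explicitly, so it does not share the search's incremental bookkeeping.
    """
    ta = _TreeArrays(tree, min_branch)
    otu_of = partition.assignment
    n_nodes = len(ta.children)
    # a node is "within" iff all leaves below it belong to one OTU and its
    # parent also has a single-OTU leaf set of the same OTU
    otus_below: list[set] = [set() for _ in range(n_nodes)]
    for k in range(n_nodes - 1, -1, -1):
        if not ta.children[k]:
            otus_below[k] = {otu_of[ta.leaf_label[k]]}
        else:
            for c in ta.children[k]:
                otus_below[k] |= otus_below[c]
    n_w = l_w = 0
    for k in range(1, n_nodes):
        p = ta.parent[k]
        if len(otus_below[p]) == 1:
            n_w += 1
            l_w += ta.blen[k]
    return _state_loglik(ta, n_w, float(l_w))
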