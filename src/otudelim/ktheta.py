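"""The K/theta (4x) test for distinguishing clades, and tree-guided delimitation.

For a pair of clades, theta is the mean within-clade pairwise K2P distance
and K is the minimum between-clade pairwise distance. Clades with
K/theta >= 4 are treated as reciprocally monophyletic with >= 95%
probability. The denominator is configurable (largest, smallest, or pooled
clade theta); the conservative default is the largest.

Two special rules from barcoding practice are applied during tree traversal:
a clade of identical sequences (theta = 0) and a single-sample clade are
always split out as their own OTU.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal

import dendropy
import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .model import Partition

__all__ = ["KThetaResult", "k_theta", "ktheta_delimit", "ktheta_report"]

ThetaRule = Literal["max", "min", "pooled"]


@dataclass(frozen=True)
class KThetaResult:
    clade_a: frozenset
    clade_b: frozenset
    theta_a: float | None  # None for singleton clades
    theta_b: float | None
    K: float
    ratio: float  # under the selected theta_rule; inf when theta == 0 < K
    ratio_max: float
    ratio_min: float
    ratio_pooled: float
    distinct: bool | None  # None when both clades are singletons
    rule_applied: Literal["ratio", "theta_zero", "singleton"]
    theta_rule: ThetaRule
    threshold: float


def _within_vals(matrix: DistanceMatrix, clade: list[str]) -> np.ndarray:
    idx = [matrix.index(s) for s in clade]
    vals = [
        matrix.d[i, j]
        for a, i in enumerate(idx)
        for j in idx[a + 1:]
        if matrix.defined[i, j]
    ]
    return np.asarray(vals)


def _ratio(K: float, theta: float | None) -> float:
    if theta is None:
        return math.nan
    if theta == 0:
        return math.inf if K > 0 else 0.0
    return K / theta


def k_theta(matrix: DistanceMatrix, clade_a: Iterable[str], clade_b: Iterable[str],
            theta_rule: ThetaRule = "max", threshold: float = 4.0) -> KThetaResult:
    """K/theta verdict for one pair of disjoint clades."""
    a, b = sorted(set(clade_a)), sorted(set(clade_b))
    if not a or not b:
        raise ValueError("both clades must be nonempty")
    if set(a) & set(b):
        raise ValueError(f"clades overlap: {sorted(set(a) & set(b))}")
    ia = [matrix.index(s) for s in a]
    ib = [matrix.index(s) for s in b]
    cross_ok = matrix.defined[np.ix_(ia, ib)]
    if not cross_ok.any():
        raise ValueError("no defined between-clade pairs")
    K = float(matrix.d[np.ix_(ia, ib)][cross_ok].min())

    wa, wb = _within_vals(matrix, a), _within_vals(matrix, b)
    theta_a = float(wa.mean()) if len(a) > 1 and wa.size else None
    theta_b = float(wb.mean()) if len(b) > 1 and wb.size else None
    pooled = np.concatenate([wa, wb])
    theta_pooled = float(pooled.mean()) if pooled.size else None

    thetas = [t for t in (theta_a, theta_b) if t is not None]
    r_max = _ratio(K, max(thetas) if thetas else None)
    r_min = _ratio(K, min(thetas) if thetas else None)
    r_pooled = _ratio(K, theta_pooled)
    ratio = {"max": r_max, "min": r_min, "pooled": r_pooled}[theta_rule]

    has_singleton = len(a) == 1 or len(b) == 1
    if not thetas or (has_singleton and max(thetas) == 0):
        # no usable diversity scale on either side: the verdict is the
        # caller's policy (agglomerative callers merge and retest higher up)
        rule: str = "singleton"
        distinct = None
    elif max(thetas) == 0:
        # two multi-sample clades of identical haplotypes: any positive K
        # separates them (the theta = 0 separate-OTU convention)
        rule = "theta_zero"
        distinct = K > 0
    else:
        # with one singleton clade the defined sister theta is the only
        # scale available; the ratio test runs against it
        rule = "singleton" if has_singleton else "ratio"
        distinct = (ratio >= threshold) if math.isfinite(ratio) else K > 0
    return KThetaResult(
        clade_a=frozenset(a), clade_b=frozenset(b),
        theta_a=theta_a, theta_b=theta_b, K=K,
        ratio=ratio, ratio_max=r_max, ratio_min=r_min, ratio_pooled=r_pooled,
        distinct=distinct, rule_applied=rule,  # type: ignore[arg-type]
        theta_rule=theta_rule, threshold=threshold,
    )


def _leaves(node: dendropy.Node) -> list[str]:
    return [lf.taxon.label for lf in node.leaf_iter()]


def ktheta_delimit(tree: dendropy.Tree, matrix: DistanceMatrix,
                   theta_rule: ThetaRule = "max", threshold: float = 4.0,
                   results: list[KThetaResult] | None = None) -> Partition:
    """Agglomerative K/theta delimitation on a rooted tree.

    Post-order traversal: every leaf starts as its own candidate OTU; at
    each internal node whose children each resolved to a single candidate
    clade, the child clades are tested pairwise with :func:`k_theta` and
    merged into one OTU when no pair is distinct. Pairs with no usable
    theta (two singletons, or a singleton against a zero-diversity clade)
    merge and are retested higher up with more data, which is how
    single-sample clades end up as their own OTU exactly when their nearest
    clade is distinct. Once any child stays split, no merging happens above
    it. ``results`` (optional list) collects every pairwise test performed.
    """
    if not tree.is_rooted:
        raise ValueError("K/theta delimitation requires a rooted tree")
    tree_leaves = {lf.taxon.label for lf in tree.leaf_node_iter()}
    if tree_leaves != set(matrix.ids):
        diff = sorted(tree_leaves ^ set(matrix.ids))
        raise ValueError(f"tree/matrix leaf mismatch: {diff}")

    def visit(node: dendropy.Node) -> list[list[str]]:
        kids = node.child_nodes()
        if not kids:
            return [[node.taxon.label]]
        child_otus = [visit(c) for c in kids]
        if any(len(co) > 1 for co in child_otus):
            return [g for co in child_otus for g in co]
        clades = [co[0] for co in child_otus]
        split = False
        for x in range(len(clades)):
            for y in range(x + 1, len(clades)):
                res = k_theta(matrix, clades[x], clades[y],
                              theta_rule=theta_rule, threshold=threshold)
                if results is not None:
                    results.append(res)
                if res.distinct:
                    split = True
        if split:
            return clades
        return [[s for c in clades for s in c]]

    groups = visit(tree.seed_node)
    return Partition.from_groups(
        groups, method_name="ktheta",
        parameters={"theta_rule": theta_rule, "threshold": threshold},
    ).canonicalize(order=matrix.ids)


def ktheta_report(results: list[KThetaResult]) -> pd.DataFrame:
    """Tabular report of the pairwise tests a delimitation performed."""
    rows = []
    for r in results:
        rows.append(
            {
                "clade_a": ";".join(sorted(r.clade_a)),
                "clade_b": ";".join(sorted(r.clade_b)),
                "theta_a": r.theta_a, "theta_b": r.theta_b, "K": r.K,
                "ratio_max": r.ratio_max, "ratio_min": r.ratio_min,
                "ratio_pooled": r.ratio_pooled,
                "distinct": r.distinct, "rule_applied": r.rule_applied,
            }
        )
    return pd.DataFrame(rows)
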