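"""Automatic-barcode-gap partitioning of a pairwise distance matrix.

Sorted unique pairwise distances (with 0 prepended) are scanned for the
first spacing that (a) ends beyond the prior maximum intraspecific
divergence and (b) is wider than ``relative_gap_X`` times the largest
spacing among the distances below it. Samples are then partitioned by
single linkage at the midpoint of that gap, and the same rule is applied
recursively inside each component.

This is a deterministic variant of the ABGD gap detector: the original's
windowed slope statistic is replaced by the explicit consecutive-spacing
rule above, which is equivalent on clean gaps; ``relative_gap_X`` plays the
role of ABGD's X.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distances import DistanceMatrix
from .model import Partition

__all__ = ["AbgdConfig", "AbgdResult", "abgd_partition", "abgd_scan"]


@dataclass(frozen=True)
class AbgdConfig:
    prior_p: float = 0.01  # maximum prior intraspecific divergence (proportion)
    relative_gap_X: float = 1.5
    p_min: float = 0.001
    p_max: float = 0.1
    steps: int = 20
    recursion_limit: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.prior_p < 1:
            raise ValueError("prior_p must be in (0, 1)")
        if self.relative_gap_X <= 1:
            raise ValueError("relative_gap_X must be > 1")
        if self.p_min >= self.p_max:
            raise ValueError("p_min must be < p_max")

    def prior_grid(self) -> np.ndarray:
        return np.geomspace(self.p_min, self.p_max, self.steps)


@dataclass
class AbgdResult:
    partition: Partition
    prior_p: float
    gap_low: float | None  # None when no gap was found at the top level
    gap_high: float | None
    n_recursions: int
    warnings: list[str] = field(default_factory=list)

    @property
    def n_groups(self) -> int:
        return self.partition.n_otus


def _find_gap(dists: np.ndarray, prior_p: float, X: float
              ) -> tuple[float, float] | None:
    """First qualifying spacing in sorted unique distances (0 prepended)."""
    vals = np.unique(np.concatenate([[0.0], dists]))
    if len(vals) < 2:
        return None
    spacings = np.diff(vals)
    max_below = 0.0
    for k, sp in enumerate(spacings):
        if vals[k + 1] > prior_p and sp > X * max_below and max_below >= 0.0:
            return float(vals[k]), float(vals[k + 1])
        max_below = max(max_below, float(sp))
    return None


def _components(d: np.ndarray, threshold: float) -> list[list[int]]:
    """Connected components of the graph linking pairs with d < threshold."""
    n = d.shape[0]
    seen = np.zeros(n, dtype=bool)
    comps = []
    for start in range(n):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            u = stack.pop()
            comp.append(u)
            nxt = np.flatnonzero((d[u] < threshold) & ~seen)
            seen[nxt] = True
            stack.extend(nxt.tolist())
        comps.append(sorted(comp))
    return comps


def _partition_recursive(d: np.ndarray, ids: list[str], config: AbgdConfig,
                         depth: int, result: AbgdResult,
                         groups: list[list[str]]) -> None:
    iu = np.triu_indices(len(ids), k=1)
    gap = _find_gap(d[iu], config.prior_p, config.relative_gap_X) if len(ids) > 1 else None
    if gap is None or depth >= config.recursion_limit:
        if gap is not None:
            result.warnings.append(
                f"recursion_limit reached with an unexplored gap in a "
                f"{len(ids)}-sample component"
            )
        groups.append(list(ids))
        return
    if depth == 0:
        result.gap_low, result.gap_high = gap
    result.n_recursions = max(result.n_recursions, depth + 1)
    threshold = 0.5 * (gap[0] + gap[1])
    comps = _components(d, threshold)
    if len(comps) == 1:
        # the gap split nothing (can happen via chaining); stop refining here
        groups.append(list(ids))
        return
    for comp in comps:
        sub_ids = [ids[k] for k in comp]
        if len(comp) == 1:
            groups.append(sub_ids)
        else:
            _partition_recursive(d[np.ix_(comp, comp)], sub_ids, config,
                                 depth + 1, result, groups)


def abgd_partition(matrix: DistanceMatrix, config: AbgdConfig) -> AbgdResult:
    """Recursive barcode-gap partition of all samples.

    With no qualifying gap at the top level, all samples form a single group.
    A prior at or above the largest distance likewise yields one group (with
    a warning), since no gap can end beyond it.
    """
    if matrix.n_undefined_pairs:
        raise ValueError("matrix has undefined pairs; resolve saturation first")
    if len(matrix.ids) < 2:
        raise ValueError("ABGD needs at least 2 samples")
    result = AbgdResult(
        partition=Partition({}, method_name="abgd"),
        prior_p=config.prior_p, gap_low=None, gap_high=None, n_recursions=0,
    )
    if config.prior_p >= float(matrix.d.max()):
        result.warnings.append(
            "prior_p >= max pairwise distance; returning a single group"
        )
        groups: list[list[str]] = [list(matrix.ids)]
    else:
        groups = []
        _partition_recursive(matrix.d, list(matrix.ids), config, 0, result, groups)
    result.partition = Partition.from_groups(
        groups, method_name="abgd",
        parameters={"prior_p": config.prior_p, "relative_gap_X": config.relative_gap_X},
    ).canonicalize(order=matrix.ids)
    return result


def abgd_scan(matrix: DistanceMatrix, config: AbgdConfig
              ) -> list[tuple[float, AbgdResult]]:
    """Run :func:`abgd_partition` over the prior grid.

    The group count is expected to be non-increasing in the prior; violations
    are flagged in the result warnings rather than hidden.
    """
    out: list[tuple[float, AbgdResult]] = []
    prev_n = None
    for prior in config.prior_grid():
        cfg = AbgdConfig(
            prior_p=float(prior), relative_gap_X=config.relative_gap_X,
            p_min=config.p_min, p_max=config.p_max, steps=config.steps,
            recursion_limit=config.recursion_limit,
        )
        res = abgd_partition(matrix, cfg)
        if prev_n is not None and res.n_groups > prev_n:
            res.warnings.append(
                f"group count increased ({prev_n} -> {res.n_groups}) as the "
                "prior grew; distance distribution has no stable gap here"
            )
        prev_n = res.n_groups
        out.append((float(prior), res))
    return out
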