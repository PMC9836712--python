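"""Per-species barcode-gap analysis, the 2% threshold screen and the 10x rule.

For each morphospecies the *barcode gap* compares its maximum intraspecific
K2P distance against its minimum distance to any other species (the
nearest-neighbour distance). The dataset-level 10x rule declares species-level
structure when mean interspecific distance is at least 10 times the mean
intraspecific distance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .distances import DistanceMatrix

__all__ = ["GapRecord", "TenXResult", "gap_report", "ten_x_test", "intra_fraction_below"]

#: Hebert's heuristic intraspecific ceiling, as a proportion.
TWO_PERCENT = 0.02


@dataclass(frozen=True)
class GapRecord:
    """Barcode-gap summary for one morphospecies."""

    species: str
    n_samples: int
    max_intra: float | None  # None for singletons / all-undefined
    min_inter: float | None
    nearest_neighbor_species: str | None
    gap_present: bool | None  # None when either side undefined
    gap_margin: float | None  # min_inter - max_intra
    intra_gt_2pct: bool | None
    inter_lt_2pct: bool | None
    n_excluded_pairs: int


@dataclass(frozen=True)
class TenXResult:
    mean_intra: float
    mean_inter: float
    ratio: float
    passes_10x: bool
    threshold_used: float = 10.0


def _defined_vals(matrix: DistanceMatrix, idx_a: np.ndarray,
                  idx_b: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Defined distances within idx_a (idx_b None) or across idx_a x idx_b."""
    if idx_b is None:
        sub_d = matrix.d[np.ix_(idx_a, idx_a)]
        sub_ok = matrix.defined[np.ix_(idx_a, idx_a)]
        iu = np.triu_indices(len(idx_a), k=1)
        vals, ok = sub_d[iu], sub_ok[iu]
    else:
        vals = matrix.d[np.ix_(idx_a, idx_b)].ravel()
        ok = matrix.defined[np.ix_(idx_a, idx_b)].ravel()
    return vals[ok], int((~ok).sum())


def gap_report(matrix: DistanceMatrix, labels: Mapping[str, str]) -> list[GapRecord]:
    """One :class:`GapRecord` per species; singletons get max_intra=None."""
    species = sorted({labels[s] for s in matrix.ids})
    if len(species) < 2:
        raise ValueError("gap analysis needs at least 2 species")
    idx_of = {sp: np.array([matrix.index(s) for s in matrix.ids if labels[s] == sp])
              for sp in species}
    records = []
    for sp in species:
        ia = idx_of[sp]
        intra, excl = _defined_vals(matrix, ia)
        max_intra = float(intra.max()) if intra.size else None
        min_inter, nn = None, None
        for other in species:
            if other == sp:
                continue
            vals, e = _defined_vals(matrix, ia, idx_of[other])
            excl += e
            if vals.size:
                m = float(vals.min())
                if min_inter is None or m < min_inter:
                    min_inter, nn = m, other
        gap = (max_intra < min_inter) if (max_intra is not None and min_inter is not None) else None
        margin = (min_inter - max_intra) if gap is not None else None
        records.append(
            GapRecord(
                species=sp,
                n_samples=len(ia),
                max_intra=max_intra,
                min_inter=min_inter,
                nearest_neighbor_species=nn,
                gap_present=gap,
                gap_margin=margin,
                intra_gt_2pct=(max_intra > TWO_PERCENT) if max_intra is not None else None,
                inter_lt_2pct=(min_inter < TWO_PERCENT) if min_inter is not None else None,
                n_excluded_pairs=excl,
            )
        )
    return records


def ten_x_test(matrix: DistanceMatrix, labels: Mapping[str, str],
               threshold: float = 10.0) -> TenXResult:
    """Dataset-level mean inter/intra ratio against the 10x rule."""
    ids = matrix.ids
    n = len(ids)
    intra, inter = [], []
    for i in range(n):
        for j in range(i + 1, n):
            if not matrix.defined[i, j]:
                continue
            (intra if labels[ids[i]] == labels[ids[j]] else inter).append(matrix.d[i, j])
    if not intra:
        raise ValueError(
            "no defined intraspecific pairs (all species singletons?); see gap_report"
        )
    if not inter:
        raise ValueError("no defined interspecific pairs")
    mean_intra = float(np.mean(intra))
    mean_inter = float(np.mean(inter))
    ratio = mean_inter / mean_intra if mean_intra > 0 else math.inf
    return TenXResult(mean_intra, mean_inter, ratio, ratio >= threshold, threshold)


def intra_fraction_below(matrix: DistanceMatrix, labels: Mapping[str, str],
                         threshold: float = TWO_PERCENT) -> float:
    """Fraction of defined intraspecific distances with d <= threshold (inclusive)."""
    ids = matrix.ids
    vals = [
        matrix.d[i, j]
        for i in range(len(ids))
        for j in range(i + 1, len(ids))
        if matrix.defined[i, j] and labels[ids[i]] == labels[ids[j]]
    ]
    if not vals:
        raise ValueError("no defined intraspecific pairs")
    return float(np.mean(np.asarray(vals) <= threshold))


def records_to_frame(records: list[GapRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def gap_points(matrix: DistanceMatrix, labels: Mapping[str, str]) -> pd.DataFrame:
    """Long-format per-pair table (species, pair_type, d) for gap-map plots."""
    ids = matrix.ids
    rows = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if not matrix.defined[i, j]:
                continue
            same = labels[ids[i]] == labels[ids[j]]
            if same:
                rows.append({"species": labels[ids[i]], "pair_type": "intra",
                             "d": matrix.d[i, j]})
            else:
                rows.append({"species": labels[ids[i]], "pair_type": "inter",
                             "d": matrix.d[i, j]})
                rows.append({"species": labels[ids[j]], "pair_type": "inter",
                             "d": matrix.d[i, j]})
    return pd.DataFrame(rows)


def plot_gap_map(records: list[GapRecord], path: str | Path) -> None:
    """Optional scatter of max intra vs min inter distance per species."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    xs = [r.max_intra if r.max_intra is not None else 0.0 for r in records]
    ys = [r.min_inter for r in records]
    fig, ax = plt.subplots(figsize=(5, 5))
    ax.scatter(xs, ys)
    lim = max([*xs, *[y for y in ys if y is not None], 0.01]) * 1.1
    ax.plot([0, lim], [0, lim], "k--", lw=0.8)
    for r, x, y in zip(records, xs, ys):
        if y is not None:
            ax.annotate(r.species, (x, y), fontsize=6)
    ax.set_xlabel("max intraspecific K2P")
    ax.set_ylabel("min interspecific K2P (nearest neighbour)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
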