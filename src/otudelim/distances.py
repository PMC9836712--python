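"""Kimura two-parameter distances and grouped distance summaries.

The K2P distance corrects the observed transition proportion P and
transversion proportion Q for multiple hits:

    d = -1/2 ln(1 - 2P - Q) - 1/4 ln(1 - 2Q)

Pairs are compared with pairwise deletion (columns with any ambiguity or gap
in that pair are skipped). A pair is *undefined* when a log argument is
non-positive (saturation) or fewer than ``min_sites`` columns were compared;
undefined entries are flagged, never capped or silently dropped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

from .model import BarcodeAlignment, MISSING, _ENCODE

__all__ = [
    "K2PPair",
    "DistanceMatrix",
    "GroupDistanceSummary",
    "k2p_pair",
    "k2p_matrix",
    "group_distance_summary",
]

#: encoded-base transition partner (A<->G, C<->T)
_TS_PARTNER = np.array([2, 3, 0, 1], dtype=np.uint8)

SaturationPolicy = Literal["error", "drop_pair", "cap_at_max"]


class K2PPair(NamedTuple):
    d: float
    P: float
    Q: float
    n_compared: int
    defined: bool
    reason: str | None  # None when defined; 'saturation' | 'no_sites' | 'min_sites'


def _encode_seq(seq: str | np.ndarray) -> np.ndarray:
    if isinstance(seq, np.ndarray):
        return seq
    return _ENCODE[np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)]


def _k2p_from_counts(ts: float, tv: float, n: int, min_sites: int) -> K2PPair:
    if n == 0:
        return K2PPair(math.nan, math.nan, math.nan, 0, False, "no_sites")
    P, Q = ts / n, tv / n
    if n < min_sites:
        return K2PPair(math.nan, P, Q, n, False, "min_sites")
    w1, w2 = 1.0 - 2.0 * P - Q, 1.0 - 2.0 * Q
    if w1 <= 0 or w2 <= 0:
        return K2PPair(math.nan, P, Q, n, False, "saturation")
    d = -0.5 * math.log(w1) - 0.25 * math.log(w2) + 0.0  # +0.0 normalises -0.0
    return K2PPair(d, P, Q, n, True, None)


def k2p_pair(seq1: str | np.ndarray, seq2: str | np.ndarray,
             min_sites: int = 0) -> K2PPair:
    """K2P distance between two aligned sequences (pairwise deletion)."""
    a, b = _encode_seq(seq1), _encode_seq(seq2)
    if a.shape != b.shape:
        raise ValueError("sequences must have equal aligned lengths")
    ok = (a != MISSING) & (b != MISSING)
    n = int(ok.sum())
    aa, bb = a[ok], b[ok]
    diff = aa != bb
    ts = int((diff & (_TS_PARTNER[aa] == bb)).sum())
    tv = int(diff.sum()) - ts
    return _k2p_from_counts(ts, tv, n, min_sites)


@dataclass
class DistanceMatrix:
    """Symmetric pairwise K2P distances with per-pair P, Q and defined flags."""

    ids: list[str]
    d: np.ndarray
    P: np.ndarray
    Q: np.ndarray
    n_compared: np.ndarray
    defined: np.ndarray
    _index: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._index = {s: i for i, s in enumerate(self.ids)}

    def __len__(self) -> int:
        return len(self.ids)

    def index(self, sample_id: str) -> int:
        return self._index[sample_id]

    def get(self, a: str, b: str) -> float:
        return float(self.d[self.index(a), self.index(b)])

    def is_defined(self, a: str, b: str) -> bool:
        return bool(self.defined[self.index(a), self.index(b)])

    @property
    def n_undefined_pairs(self) -> int:
        iu = np.triu_indices(len(self.ids), k=1)
        return int((~self.defined[iu]).sum())

    def submatrix(self, keep: Sequence[str]) -> "DistanceMatrix":
        idx = np.array([self.index(s) for s in keep])
        return DistanceMatrix(
            list(keep),
            self.d[np.ix_(idx, idx)],
            self.P[np.ix_(idx, idx)],
            self.Q[np.ix_(idx, idx)],
            self.n_compared[np.ix_(idx, idx)],
            self.defined[np.ix_(idx, idx)],
        )

    def condensed(self) -> np.ndarray:
        """Upper-triangle distances in scipy 'condensed' order."""
        return self.d[np.triu_indices(len(self.ids), k=1)]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)

    def to_long(self) -> pd.DataFrame:
        rows = []
        n = len(self.ids)
        for i in range(n):
            for j in range(i + 1, n):
                rows.append(
                    {
                        "sample1": self.ids[i],
                        "sample2": self.ids[j],
                        "d": self.d[i, j],
                        "P": self.P[i, j],
                        "Q": self.Q[i, j],
                        "n_compared": int(self.n_compared[i, j]),
                        "defined": bool(self.defined[i, j]),
                    }
                )
        return pd.DataFrame(rows)

    def write_tsv(self, matrix_path: str | Path, pairs_path: str | Path | None = None) -> None:
        self.to_dataframe().to_csv(matrix_path, sep="\t")
        if pairs_path is not None:
            self.to_long().to_csv(pairs_path, sep="\t", index=False)

    def apply_saturation_policy(self, policy: SaturationPolicy = "drop_pair"
                                ) -> "DistanceMatrix":
        """Resolve undefined entries so distance-only consumers (e.g. NJ) can run.

        ``drop_pair`` removes the fewest samples needed to leave no undefined
        pair; ``cap_at_max`` sets undefined entries to the largest defined
        distance; ``error`` raises.
        """
        if not self.n_undefined_pairs:
            return self
        if policy == "error":
            raise ValueError(
                f"{self.n_undefined_pairs} undefined (saturated/short) pairs present"
            )
        if policy == "cap_at_max":
            cap = float(np.nanmax(np.where(self.defined, self.d, np.nan)))
            d = np.where(self.defined, self.d, cap)
            np.fill_diagonal(d, 0.0)
            return DistanceMatrix(
                list(self.ids), d, self.P, self.Q, self.n_compared,
                np.ones_like(self.defined),
            )
        # drop_pair: greedily remove the sample with most undefined partners
        bad = ~self.defined
        np.fill_diagonal(bad, False)
        keep = np.ones(len(self.ids), dtype=bool)
        while bad[np.ix_(keep, keep)].any():
            counts = np.where(keep, bad[:, keep].sum(axis=1), -1)
            keep[int(np.argmax(counts))] = False
        return self.submatrix([s for s, k in zip(self.ids, keep) if k])


def k2p_matrix(alignment: BarcodeAlignment, min_sites: int = 0) -> DistanceMatrix:
    """All-pairs K2P distances with pairwise deletion.

    Vectorised per pair; the matrix is symmetric by construction and the
    diagonal is 0. Undefined pairs are flagged in ``defined``.
    """
    enc = alignment.encoded()
    n = len(alignment)
    d = np.zeros((n, n))
    P = np.zeros((n, n))
    Q = np.zeros((n, n))
    nc = np.zeros((n, n), dtype=int)
    ok = enc != MISSING
    nc[np.diag_indices(n)] = ok.sum(axis=1)
    defined = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            both = ok[i] & ok[j]
            m = int(both.sum())
            a, b = enc[i, both], enc[j, both]
            diff = a != b
            ts = int((diff & (_TS_PARTNER[a] == b)).sum())
            tv = int(diff.sum()) - ts
            res = _k2p_from_counts(ts, tv, m, min_sites)
            d[i, j] = d[j, i] = res.d
            P[i, j] = P[j, i] = res.P
            Q[i, j] = Q[j, i] = res.Q
            nc[i, j] = nc[j, i] = res.n_compared
            defined[i, j] = defined[j, i] = res.defined
    return DistanceMatrix(list(alignment.ids), d, P, Q, nc, defined)


def _stats(vals: np.ndarray) -> dict[str, float]:
    if vals.size == 0:
        return {"n_pairs": 0, "mean": math.nan, "min": math.nan, "max": math.nan}
    return {
        "n_pairs": int(vals.size),
        "mean": float(vals.mean()),
        "min": float(vals.min()),
        "max": float(vals.max()),
    }


@dataclass
class GroupDistanceSummary:
    """Within/between distance statistics per group and group pair."""

    within: pd.DataFrame
    between: pd.DataFrame
    overall_within_mean: float
    overall_between_mean: float
    ratio: float  # between_mean / within_mean; nan when within undefined or 0
    n_undefined_excluded: int


def group_distance_summary(matrix: DistanceMatrix,
                           grouping: Mapping[str, str]) -> GroupDistanceSummary:
    """Summarise defined distances within and between groups.

    Singleton groups contribute no within-pairs but still get a row (with NaN
    stats); undefined pairs are excluded and counted.
    """
    missing = [s for s in matrix.ids if s not in grouping]
    if missing:
        raise ValueError(f"ungrouped sample(s): {missing}")
    groups = sorted({grouping[s] for s in matrix.ids})
    members = {g: [s for s in matrix.ids if grouping[s] == g] for g in groups}
    n_excluded = 0

    def pair_vals(ids_a: list[str], ids_b: list[str] | None) -> np.ndarray:
        nonlocal n_excluded
        vals = []
        if ids_b is None:  # within
            for x in range(len(ids_a)):
                for y in range(x + 1, len(ids_a)):
                    i, j = matrix.index(ids_a[x]), matrix.index(ids_a[y])
                    if matrix.defined[i, j]:
                        vals.append(matrix.d[i, j])
                    else:
                        n_excluded += 1
        else:
            for sa in ids_a:
                for sb in ids_b:
                    i, j = matrix.index(sa), matrix.index(sb)
                    if matrix.defined[i, j]:
                        vals.append(matrix.d[i, j])
                    else:
                        n_excluded += 1
        return np.asarray(vals)

    within_rows, all_within, all_between = [], [], []
    for g in groups:
        vals = pair_vals(members[g], None)
        all_within.append(vals)
        within_rows.append({"group": g, "n_samples": len(members[g]), **_stats(vals)})
    between_rows = []
    for a in range(len(groups)):
        for b in range(a + 1, len(groups)):
            vals = pair_vals(members[groups[a]], members[groups[b]])
            all_between.append(vals)
            between_rows.append(
                {"group_a": groups[a], "group_b": groups[b], **_stats(vals)}
            )
    w = np.concatenate(all_within) if all_within else np.array([])
    b = np.concatenate(all_between) if all_between else np.array([])
    wmean = float(w.mean()) if w.size else math.nan
    bmean = float(b.mean()) if b.size else math.nan
    ratio = bmean / wmean if w.size and wmean > 0 and b.size else math.nan
    return GroupDistanceSummary(
        within=pd.DataFrame(within_rows),
        between=pd.DataFrame(between_rows),
        overall_within_mean=wmean,
        overall_between_mean=bmean,
        ratio=ratio,
        n_undefined_excluded=n_excluded,
    )
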