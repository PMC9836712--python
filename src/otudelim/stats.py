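"""Descriptive alignment statistics: site classes, base composition, ts/tv.

Conventions: ambiguity codes and gaps are treated as missing data — excluded
per column (site classification, composition) or per pair (ts/tv counting).
The transition/transversion ratio R is the pooled count ratio over all
sample pairs, not a maximum-likelihood estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .model import BarcodeAlignment, MISSING

__all__ = ["SiteClassification", "CompositionSummary", "classify_sites", "sequence_summary"]


@dataclass(frozen=True)
class SiteClassification:
    """Counts of conserved / variable / parsimony-informative / singleton columns.

    Columns with fewer than 2 unambiguous bases are excluded from ``n_sites``.
    Invariants: conserved + variable == n_sites and
    parsimony_informative + singleton == variable.
    """

    n_sites: int
    conserved: int
    variable: int
    parsimony_informative: int
    singleton: int

    def percent(self, count: int) -> float:
        return 100.0 * count / self.n_sites if self.n_sites else float("nan")

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("conserved", self.conserved),
            ("variable", self.variable),
            ("parsimony_informative", self.parsimony_informative),
            ("singleton", self.singleton),
        ]
        return pd.DataFrame(
            {
                "site_class": [r[0] for r in rows],
                "count": [r[1] for r in rows],
                "percent": [round(self.percent(r[1]), 2) for r in rows],
            }
        )


@dataclass(frozen=True)
class CompositionSummary:
    """Pooled base composition, sequence-length range, and ts/tv ratio R."""

    freq_A: float
    freq_C: float
    freq_G: float
    freq_T: float
    mean_length: float
    min_length: int
    max_length: int
    transitions: int
    transversions: int
    ts_tv_ratio: float | None  # None when no transversions were observed

    @property
    def at_content(self) -> float:
        return self.freq_A + self.freq_T

    @property
    def gc_content(self) -> float:
        return self.freq_C + self.freq_G

    def to_frame(self) -> pd.DataFrame:
        items = {
            "freq_A": self.freq_A,
            "freq_C": self.freq_C,
            "freq_G": self.freq_G,
            "freq_T": self.freq_T,
            "at_content": self.at_content,
            "gc_content": self.gc_content,
            "mean_length": self.mean_length,
            "min_length": self.min_length,
            "max_length": self.max_length,
            "transitions": self.transitions,
            "transversions": self.transversions,
            "ts_tv_ratio": self.ts_tv_ratio if self.ts_tv_ratio is not None else float("nan"),
        }
        return pd.DataFrame({"statistic": list(items), "value": list(items.values())})


def _base_counts(enc: np.ndarray) -> np.ndarray:
    """(4, n_columns) counts of unambiguous A,C,G,T per column."""
    return np.stack([(enc == b).sum(axis=0) for b in range(4)])


def classify_sites(alignment: BarcodeAlignment) -> SiteClassification:
    """Classify alignment columns over their unambiguous bases.

    A column is conserved if exactly one state occurs; a variable column is
    parsimony-informative if at least two states each occur in at least two
    sequences, otherwise it is a singleton site.
    """
    counts = _base_counts(alignment.encoded())
    usable = counts.sum(axis=0) >= 2
    counts = counts[:, usable]
    n_states = (counts > 0).sum(axis=0)
    conserved = int((n_states == 1).sum())
    variable = int((n_states >= 2).sum())
    informative = int(((counts >= 2).sum(axis=0) >= 2).sum())
    singleton = variable - informative
    return SiteClassification(
        n_sites=int(usable.sum()),
        conserved=conserved,
        variable=variable,
        parsimony_informative=informative,
        singleton=singleton,
    )


def pairwise_ts_tv(alignment: BarcodeAlignment) -> tuple[int, int]:
    """Total transitions and transversions pooled over all sample pairs.

    Pairwise deletion of columns with any missing base in the pair. Computed
    column-wise: with per-column unambiguous counts nA,nC,nG,nT the pair
    totals are ts = nA*nG + nC*nT and tv = (nA+nG)*(nC+nT).
    """
    nA, nC, nG, nT = _base_counts(alignment.encoded())
    ts = int((nA * nG + nC * nT).sum())
    tv = int(((nA + nG) * (nC + nT)).sum())
    return ts, tv


def sequence_summary(alignment: BarcodeAlignment) -> CompositionSummary:
    """Pooled composition, ungapped length range, and the dataset-level R."""
    enc = alignment.encoded()
    totals = np.array([(enc == b).sum() for b in range(4)], dtype=float)
    grand = totals.sum()
    if grand == 0:
        raise ValueError("alignment contains no unambiguous bases")
    freqs = totals / grand
    lengths = [r.ungapped_length for r in alignment.records]
    ts, tv = pairwise_ts_tv(alignment)
    ratio = ts / tv if tv > 0 else None
    return CompositionSummary(
        freq_A=float(freqs[0]),
        freq_C=float(freqs[1]),
        freq_G=float(freqs[2]),
        freq_T=float(freqs[3]),
        mean_length=float(np.mean(lengths)),
        min_length=int(min(lengths)),
        max_length=int(max(lengths)),
        transitions=ts,
        transversions=tv,
        ts_tv_ratio=ratio,
    )


def write_reports(alignment: BarcodeAlignment, outdir: str | Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    classify_sites(alignment).to_frame().to_csv(outdir / "site_class.tsv", sep="\t", index=False)
    sequence_summary(alignment).to_frame().to_csv(outdir / "composition.tsv", sep="\t", index=False)
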