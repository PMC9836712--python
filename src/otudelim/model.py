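"""Core data model for barcode species delimitation.

A dataset is a :class:`BarcodeAlignment` (aligned COI-style sequences with
per-sample morphospecies labels); every delimitation method returns a
:class:`Partition` mapping samples to OTU ids.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np

#: IUPAC nucleotide codes (unambiguous + ambiguity) plus the gap symbol.
IUPAC_CODES = frozenset("ACGTRYSWKMBDHVN-")

#: Encoding used throughout: A=0, C=1, G=2, T=3; anything ambiguous or a gap
#: is MISSING and excluded by pairwise deletion.
BASE_ORDER = "ACGT"
MISSING = np.uint8(255)

_ENCODE = np.full(256, MISSING, dtype=np.uint8)
for _i, _b in enumerate(BASE_ORDER):
    _ENCODE[ord(_b)] = _i

#: Purine/pyrimidine class per encoded base (A,G purines; C,T pyrimidines).
PURINE = frozenset("AG")


class AlignmentError(ValueError):
    """Raised when sequences violate alignment invariants."""


class ParseError(ValueError):
    """Raised on malformed input files."""


@dataclass
class SequenceRecord:
    """One aligned barcode sequence with its specimen metadata."""

    sample_id: str
    sequence: str
    species_label: str | None = None
    locality: str | None = None

    def __post_init__(self) -> None:
        if not self.sample_id:
            raise ValueError("sample_id must be nonempty")
        if not self.sequence:
            raise ParseError(f"{self.sample_id}: empty sequence")
        seq = self.sequence.upper().replace("U", "T")
        bad = set(seq) - IUPAC_CODES
        if bad:
            raise ParseError(
                f"{self.sample_id}: non-IUPAC symbol(s) {sorted(bad)!r} in sequence"
            )
        self.sequence = seq

    @property
    def ungapped_length(self) -> int:
        return len(self.sequence) - self.sequence.count("-")


@dataclass
class BarcodeAlignment:
    """An aligned set of barcode sequences, the universal pipeline input."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise AlignmentError("an alignment needs at least 2 records")
        ids = [r.sample_id for r in self.records]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise AlignmentError(f"duplicate sample_id(s): {dup}")
        lengths = {len(r.sequence) for r in self.records}
        if len(lengths) != 1:
            raise AlignmentError(
                f"sequences have unequal lengths {sorted(lengths)}; input must be aligned"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    @property
    def length(self) -> int:
        """Number of alignment columns (bp)."""
        return len(self.records[0].sequence)

    @property
    def ids(self) -> list[str]:
        return [r.sample_id for r in self.records]

    @property
    def labels(self) -> dict[str, str | None]:
        return {r.sample_id: r.species_label for r in self.records}

    def require_labels(self) -> dict[str, str]:
        missing = [r.sample_id for r in self.records if r.species_label is None]
        if missing:
            raise AlignmentError(
                f"records without species_label: {missing}; attach metadata first"
            )
        return {r.sample_id: r.species_label for r in self.records}  # type: ignore[misc]

    def encoded(self) -> np.ndarray:
        """(n_samples, n_columns) uint8 matrix; ambiguity/gap -> MISSING."""
        rows = [
            np.frombuffer(r.sequence.encode("ascii"), dtype=np.uint8)
            for r in self.records
        ]
        return _ENCODE[np.vstack(rows)]

    def with_labels(self, labels: Mapping[str, str],
                    localities: Mapping[str, str] | None = None) -> "BarcodeAlignment":
        recs = []
        for r in self.records:
            recs.append(
                replace(
                    r,
                    species_label=labels.get(r.sample_id, r.species_label),
                    locality=(localities or {}).get(r.sample_id, r.locality),
                )
            )
        return BarcodeAlignment(recs)

    def subset(self, keep: Iterable[str]) -> "BarcodeAlignment":
        keep = set(keep)
        return BarcodeAlignment([r for r in self.records if r.sample_id in keep])


@dataclass
class Partition:
    """A sample -> OTU assignment, the universal delimitation output."""

    assignment: dict[str, int]
    method_name: str = ""
    parameters: dict = field(default_factory=dict)

    @property
    def n_otus(self) -> int:
        return len(set(self.assignment.values()))

    @property
    def samples(self) -> set[str]:
        return set(self.assignment)

    def groups(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for s, o in self.assignment.items():
            out.setdefault(o, []).append(s)
        return out

    def canonicalize(self, order: Sequence[str] | None = None) -> "Partition":
        """Renumber OTU ids 0..k-1 by first appearance in `order` (or insertion order)."""
        seq = list(order) if order is not None else list(self.assignment)
        remap: dict[int, int] = {}
        for s in seq:
            o = self.assignment[s]
            if o not in remap:
                remap[o] = len(remap)
        return Partition(
            {s: remap[o] for s, o in self.assignment.items()},
            method_name=self.method_name,
            parameters=dict(self.parameters),
        )

    def labels_for(self, ids: Sequence[str]) -> list[int]:
        return [self.assignment[i] for i in ids]

    @classmethod
    def from_groups(cls, groups: Iterable[Iterable[str]], method_name: str = "",
                    parameters: dict | None = None) -> "Partition":
        assignment: dict[str, int] = {}
        for k, grp in enumerate(groups):
            for s in grp:
                if s in assignment:
                    raise ValueError(f"sample {s!r} assigned to more than one OTU")
                assignment[s] = k
        return cls(assignment, method_name=method_name, parameters=parameters or {})

    @classmethod
    def from_labels(cls, labels: Mapping[str, str], method_name: str = "") -> "Partition":
        """Build a partition from arbitrary (e.g. morphospecies) labels."""
        key: dict[str, int] = {}
        assignment = {}
        for s, lab in labels.items():
            if lab not in key:
                key[lab] = len(key)
            assignment[s] = key[lab]
        return cls(assignment, method_name=method_name)
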