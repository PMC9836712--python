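"""Combining delimitation results and comparing them to morphology.

Partitions from different methods (including imported external ones such as
a BIN export) are combined by co-membership: *strict* consensus co-groups
two samples only when every method does, *majority* when more than half do
(followed by transitive closure, which is logged when it changes anything).
Each morphospecies is then classified against a partition as match, split,
merge, or mixed.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .model import Partition

__all__ = [
    "ConcordanceRecord",
    "consensus_partition",
    "partition_agreement",
    "agreement_table",
    "compare_to_morphology",
]

Status = Literal["match", "split", "merge", "mixed"]


@dataclass(frozen=True)
class ConcordanceRecord:
    species_label: str
    n_samples: int
    otus_touched: int
    status: Status
    partner_species: tuple[str, ...]  # other species sharing an OTU (merge/mixed)


def _check_same_samples(partitions: Sequence[Partition]) -> list[str]:
    base = partitions[0].samples
    for p in partitions[1:]:
        if p.samples != base:
            only_a = sorted(base - p.samples)
            only_b = sorted(p.samples - base)
            raise ValueError(
                f"partitions cover different samples; only in first: {only_a}, "
                f"only in other ({p.method_name!r}): {only_b}"
            )
    return sorted(base)


def consensus_partition(partitions: Sequence[Partition],
                        rule: Literal["strict", "majority"] = "strict") -> Partition:
    """Co-membership consensus of several partitions over identical samples."""
    if not partitions:
        raise ValueError("need at least one partition")
    samples = _check_same_samples(partitions)
    if rule == "strict":
        # samples co-grouped iff co-grouped in every method: group by the
        # tuple of per-method OTU ids (the common refinement)
        sig: dict[tuple, list[str]] = {}
        for s in samples:
            key = tuple(p.assignment[s] for p in partitions)
            sig.setdefault(key, []).append(s)
        part = Partition.from_groups(sig.values(), method_name=f"consensus_{rule}")
    elif rule == "majority":
        need = len(partitions) / 2.0
        adj = {s: set() for s in samples}
        for a, b in itertools.combinations(samples, 2):
            votes = sum(p.assignment[a] == p.assignment[b] for p in partitions)
            if votes > need:
                adj[a].add(b)
                adj[b].add(a)
        groups, seen = [], set()
        closure_used = False
        for s in samples:
            if s in seen:
                continue
            stack, comp = [s], []
            seen.add(s)
            while stack:
                u = stack.pop()
                comp.append(u)
                for v in adj[u]:
                    if v not in seen:
                        seen.add(v)
                        stack.append(v)
            for a, b in itertools.combinations(comp, 2):
                if b not in adj[a]:
                    closure_used = True
            groups.append(sorted(comp))
        if closure_used:
            warnings.warn(
                "majority co-membership was non-transitive; transitive closure applied",
                stacklevel=2,
            )
        part = Partition.from_groups(groups, method_name=f"consensus_{rule}")
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return part.canonicalize(order=samples)


def partition_agreement(p1: Partition, p2: Partition) -> dict:
    """Adjusted Rand index and identity flag for a pair of partitions."""
    samples = _check_same_samples([p1, p2])
    l1 = p1.labels_for(samples)
    l2 = p2.labels_for(samples)
    identical = (
        p1.canonicalize(order=samples).assignment
        == p2.canonicalize(order=samples).assignment
    )
    return {
        "method_a": p1.method_name,
        "method_b": p2.method_name,
        "adjusted_rand": float(adjusted_rand_score(l1, l2)),
        "identical": identical,
    }


def agreement_table(partitions: Sequence[Partition]) -> pd.DataFrame:
    rows = [
        partition_agreement(a, b)
        for a, b in itertools.combinations(partitions, 2)
    ]
    return pd.DataFrame(rows)


def compare_to_morphology(partition: Partition,
                          labels: Mapping[str, str]) -> list[ConcordanceRecord]:
    """Classify each morphospecies against the OTUs of a partition.

    match: the species is exactly one OTU containing no other species.
    split: the species spans several OTUs, none shared with another species.
    merge: one OTU, shared with at least one other species.
    mixed: several OTUs, at least one shared.
    """
    unlabeled = sorted(s for s in partition.samples if s not in labels)
    if unlabeled:
        raise ValueError(f"unlabeled sample(s): {unlabeled}")
    species = sorted({labels[s] for s in partition.samples})
    members = {sp: [s for s in partition.samples if labels[s] == sp] for sp in species}
    otus_of = {sp: {partition.assignment[s] for s in members[sp]} for sp in species}
    species_in_otu: dict[int, set[str]] = {}
    for s in partition.samples:
        species_in_otu.setdefault(partition.assignment[s], set()).add(labels[s])

    records = []
    for sp in species:
        touched = otus_of[sp]
        partners = sorted(
            set().union(*(species_in_otu[o] for o in touched)) - {sp}
        )
        shared = bool(partners)
        if len(touched) == 1:
            status: Status = "merge" if shared else "match"
        else:
            status = "mixed" if shared else "split"
        records.append(
            ConcordanceRecord(
                species_label=sp,
                n_samples=len(members[sp]),
                otus_touched=len(touched),
                status=status,
                partner_species=tuple(partners),
            )
        )
    return records


def concordance_frame(records: list[ConcordanceRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "species_label": r.species_label,
                "n_samples": r.n_samples,
                "otus_touched": r.otus_touched,
                "status": r.status,
                "partner_species": ";".join(r.partner_species),
            }
            for r in records
        ]
    )
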