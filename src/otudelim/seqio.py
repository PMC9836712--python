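"""Readers/writers for the external formats the pipeline consumes.

FASTA goes through Bio.SeqIO, newick through dendropy; metadata and
partition tables are plain TSV handled with pandas. Sequences are stored
uppercase with RNA 'U' mapped to 'T' on read.
"""

from __future__ import annotations

import warnings
from pathlib import Path
from typing import Mapping

import dendropy
import pandas as pd
from Bio import SeqIO

from .model import AlignmentError, BarcodeAlignment, ParseError, Partition, SequenceRecord

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_metadata",
    "write_metadata",
    "read_tree",
    "write_tree",
    "read_partition",
    "write_partition",
    "split_pipe_header",
]


def read_fasta(path: str | Path, strict: bool = True) -> BarcodeAlignment:
    """Read an aligned FASTA file into a :class:`BarcodeAlignment`.

    Labels are left unattached; use :func:`read_metadata` to join them.
    With ``strict`` (default) unequal sequence lengths raise
    :class:`AlignmentError` — barcode inputs are assumed pre-aligned.
    """
    path = Path(path)
    records = []
    try:
        for entry in SeqIO.parse(str(path), "fasta"):
            if not entry.id:
                raise ParseError(f"{path}: FASTA entry with empty header")
            records.append(SequenceRecord(sample_id=entry.id, sequence=str(entry.seq)))
    except ParseError:
        raise
    except ValueError as exc:  # Bio.SeqIO's malformed-record errors
        raise ParseError(f"{path}: {exc}") from exc
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    if not strict:
        # pad to common length so the container invariant holds
        maxlen = max(len(r.sequence) for r in records)
        for r in records:
            r.sequence = r.sequence.ljust(maxlen, "-")
    try:
        return BarcodeAlignment(records)
    except AlignmentError as exc:
        raise AlignmentError(f"{path}: {exc}") from exc


def write_fasta(alignment: BarcodeAlignment, path: str | Path, width: int = 70) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for r in alignment.records:
            fh.write(f">{r.sample_id}\n")
            for i in range(0, len(r.sequence), width):
                fh.write(r.sequence[i:i + width] + "\n")


def read_metadata(path: str | Path, alignment: BarcodeAlignment) -> BarcodeAlignment:
    """Join a sample metadata table onto an alignment by ``sample_id``.

    The table must have columns ``sample_id`` and ``species_label``
    (``locality`` optional). Every aligned sample must appear exactly once;
    extra table rows are accepted with a warning.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"sample_id", "species_label"}
    missing_cols = required - set(df.columns)
    if missing_cols:
        raise ParseError(f"{path}: missing column(s) {sorted(missing_cols)}")
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise ParseError(f"{path}: duplicate sample_id row(s): {sorted(set(dup))}")
    table_ids = set(df["sample_id"])
    missing = [i for i in alignment.ids if i not in table_ids]
    if missing:
        raise ParseError(f"{path}: sample(s) missing from metadata: {missing}")
    extra = table_ids - set(alignment.ids)
    if extra:
        warnings.warn(
            f"{path}: {len(extra)} metadata row(s) not present in the alignment",
            stacklevel=2,
        )
    labels = dict(zip(df["sample_id"], df["species_label"]))
    localities = (
        {k: v for k, v in zip(df["sample_id"], df["locality"]) if pd.notna(v)}
        if "locality" in df.columns
        else None
    )
    return alignment.with_labels(labels, localities)


def write_metadata(alignment: BarcodeAlignment, path: str | Path) -> None:
    rows = [
        {
            "sample_id": r.sample_id,
            "species_label": r.species_label if r.species_label is not None else "",
            "locality": r.locality if r.locality is not None else "",
        }
        for r in alignment.records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_tree(path: str | Path, rooted: bool | None = None) -> dendropy.Tree:
    """Read a newick tree with branch lengths.

    Rootedness is inferred from basal degree (2 children at the seed node
    means rooted) unless ``rooted`` overrides it. Internal-node labels
    (bootstrap or posterior supports) are kept verbatim.
    """
    try:
        tree = dendropy.Tree.get(
            path=str(path),
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises schema-specific error classes
        raise ParseError(f"{path}: {exc}") from exc
    leaves = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(leaves)) != len(leaves):
        dup = sorted({l for l in leaves if leaves.count(l) > 1})
        raise ParseError(f"{path}: duplicate leaf name(s): {dup}")
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            raise ParseError(f"{path}: negative branch length {edge.length}")
    if rooted is None:
        rooted = len(tree.seed_node.child_nodes()) == 2
    tree.is_rooted = rooted
    return tree


def require_branch_lengths(tree: dendropy.Tree, context: str = "this analysis") -> None:
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ParseError(f"branch lengths are required for {context} but are missing")


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(
        path=str(path),
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
        real_value_format_specifier=".9g",
    )


def read_partition(path: str | Path, method_name: str | None = None) -> Partition:
    """Read a ``sample_id<TAB>otu_id`` table (e.g. an exported BIN partition)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"sample_id", "otu_id"} <= set(df.columns):
        raise ParseError(f"{path}: expected columns sample_id, otu_id")
    dup = df["sample_id"][df["sample_id"].duplicated()].tolist()
    if dup:
        raise ParseError(f"{path}: duplicate sample_id row(s): {sorted(set(dup))}")
    part = Partition.from_labels(
        dict(zip(df["sample_id"], df["otu_id"])),
        method_name=method_name or Path(path).stem,
    )
    return part.canonicalize()


def write_partition(partition: Partition, path: str | Path) -> None:
    part = partition.canonicalize()
    df = pd.DataFrame(
        {"sample_id": list(part.assignment), "otu_id": list(part.assignment.values())}
    )
    df.to_csv(path, sep="\t", index=False)


def split_pipe_header(alignment: BarcodeAlignment) -> BarcodeAlignment:
    """Best-effort label extraction from ``accession|species`` style headers."""
    labels: dict[str, str] = {}
    for r in alignment.records:
        if "|" in r.sample_id:
            _, species = r.sample_id.split("|", 1)
            labels[r.sample_id] = species.strip().replace("_", " ")
    return alignment.with_labels(labels)
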