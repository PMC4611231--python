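"""Readers and writers for the standard interchange formats.

FASTQ (Sanger Phred+33 only), FASTA, Newick trees, TSV count tables, TSV
sample metadata, and square TSV distance matrices. Parsers reject malformed
input with located errors instead of silently coercing.
"""

from __future__ import annotations

import io as _io
import logging
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import skbio
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .containers import MAX_PHRED, CountTable, SequenceRead
from .errors import ParseError, ValidationError

logger = logging.getLogger("ribotide")


# ---------------------------------------------------------------------------
# FASTQ / FASTA
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> Iterator[SequenceRead]:
    """Stream reads from a Sanger (Phred+33) FASTQ file in file order.

    Raises :class:`ParseError` naming the offending record for truncated
    records, base/quality length mismatches, or quality characters outside
    the Phred+33 range.
    """
    path = Path(path)
    with open(path) as handle:
        record_no = 0
        try:
            for title, seq, qual in FastqGeneralIterator(handle):
                record_no += 1
                if len(seq) != len(qual):
                    raise ParseError(
                        f"{path}: record {record_no} ({title.split()[0]}): "
                        f"{len(seq)} bases but {len(qual)} quality characters"
                    )
                quals = tuple(ord(c) - 33 for c in qual)
                if quals and (min(quals) < 0 or max(quals) > MAX_PHRED):
                    raise ParseError(
                        f"{path}: record {record_no}: quality characters outside "
                        f"Phred+33 range 0..{MAX_PHRED}"
                    )
                read_id = title.split()[0] if title else f"record_{record_no}"
                yield SequenceRead(read_id, seq.upper(), quals)
        except ValueError as exc:  # malformed structure from the iterator
            raise ParseError(
                f"{path}: malformed FASTQ near record {record_no + 1}: {exc}"
            ) from exc


def write_fastq(reads: Iterable[SequenceRead], path: str | Path) -> int:
    """Write reads as Phred+33 FASTQ; returns the number written."""
    n = 0
    with open(path, "w") as handle:
        for read in reads:
            qual = "".join(chr(q + 33) for q in read.quals)
            handle.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")
            n += 1
    return n


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read FASTA into an ordered {id: sequence} map."""
    path = Path(path)
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ParseError(f"{path}: duplicate FASTA id {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as handle:
        for name, seq in seqs.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), width):
                handle.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Newick
# ---------------------------------------------------------------------------

def read_newick(
    path: str | Path, missing_length: float | None = 0.0
) -> skbio.TreeNode:
    """Read a rooted Newick tree with branch lengths.

    Nodes without a branch length get ``missing_length`` (default 0, with a
    warning); pass ``missing_length=None`` to make missing lengths an error.
    Negative branch lengths are rejected.
    """
    path = Path(path)
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ParseError(f"{path}: invalid Newick: {exc}") from exc
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if missing_length is None:
                raise ValidationError(
                    f"{path}: node {node.name!r} has no branch length"
                )
            node.length = missing_length
            n_missing += 1
        elif node.length < 0:
            raise ValidationError(
                f"{path}: negative branch length on node {node.name!r}"
            )
    if n_missing:
        logger.warning(
            "%s: %d branch lengths missing, defaulted to %s",
            path, n_missing, missing_length,
        )
    return tree


def parse_newick(text: str, missing_length: float | None = 0.0) -> skbio.TreeNode:
    """Parse a Newick string (same semantics as :func:`read_newick`)."""
    try:
        tree = skbio.TreeNode.read(_io.StringIO(text), format="newick")
    except Exception as exc:
        raise ParseError(f"invalid Newick: {exc}") from exc
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if missing_length is None:
                raise ValidationError(f"node {node.name!r} has no branch length")
            node.length = missing_length
        elif node.length < 0:
            raise ValidationError(f"negative branch length on node {node.name!r}")
    return tree


# ---------------------------------------------------------------------------
# Count tables, metadata, distance matrices
# ---------------------------------------------------------------------------

def read_count_table(path: str | Path) -> CountTable:
    """Read a TSV count table: header row of feature ids, first column sample ids."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:
        raise ParseError(f"{path}: cannot read TSV: {exc}") from exc
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()]
            where = bad[0] if len(bad) else "?"
            raise ValidationError(
                f"{path}: non-numeric count at sample {where!r}, feature {col!r}"
            )
    try:
        return CountTable(df)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_count_table(table: CountTable, path: str | Path) -> None:
    table.df.to_csv(path, sep="\t", index_label="sample_id")


def read_metadata(path: str | Path) -> pd.Series:
    """Read sample metadata TSV with columns ``sample_id`` and ``group``."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValidationError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValidationError(f"{path}: duplicate sample ids {dups}")
    return df.set_index("sample_id")["group"]


def read_distance_matrix(path: str | Path) -> skbio.DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError(f"{path}: row and column sample ids differ")
    try:
        return skbio.DistanceMatrix(df.to_numpy(float), ids=list(df.index))
    except Exception as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_distance_matrix(dm: skbio.DistanceMatrix, path: str | Path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(
        path, sep="\t", index_label="sample_id"
    )


# ---------------------------------------------------------------------------
# Seeded randomness
# ---------------------------------------------------------------------------

def spawn_rng(seed: int, *labels: str) -> np.random.Generator:
    """Derive an independent, reproducible RNG for a named pipeline stage.

    Hashing the stage labels into the seed sequence keeps stages decoupled:
    adding a draw in one stage never perturbs another.
    """
    entropy = [seed] + [int.from_bytes(lbl.encode(), "little") % (2**63) for lbl in labels]
    return np.random.default_rng(np.random.SeedSequence(entropy))
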