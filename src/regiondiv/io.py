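"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ parsing is delegated to Biopython, Newick to scikit-bio and
tabular formats to pandas; this module adds the strict validation the
downstream stages assume (unique ids, integer counts, rooted trees with
branch lengths, non-negative fluorescence) and normalises sequence case.
"""

from __future__ import annotations

import gzip
import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator
from skbio import TreeNode

from .types import OTUTable, PeakProfile, Read, ReadSet, validate_tree

__all__ = [
    "read_sequences",
    "write_fasta",
    "read_otu_table",
    "write_otu_table",
    "read_tree",
    "write_tree",
    "read_peak_profiles",
    "write_peak_profiles",
    "read_env_table",
]


class ParseError(ValueError):
    """Raised when an input file violates its format or an invariant."""


def _open_text(path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def read_sequences(path, format: str = "fasta",
                   region_label: str | None = None) -> ReadSet:
    """Load a FASTA or FASTQ file (optionally gzipped) into a ReadSet.

    Sequences are upper-cased; duplicate ids, empty files, empty
    sequences and FASTQ length mismatches raise :class:`ParseError`.
    """
    if format not in ("fasta", "fastq"):
        raise ValueError(f"unknown format {format!r}")
    reads: list[Read] = []
    with _open_text(path) as handle:
        try:
            if format == "fasta":
                for title, seq in SimpleFastaParser(handle):
                    rid = title.split()[0] if title.split() else title
                    reads.append(Read(id=rid, sequence=seq.upper()))
            else:
                for title, seq, qual in FastqGeneralIterator(handle):
                    rid = title.split()[0] if title.split() else title
                    reads.append(Read(
                        id=rid,
                        sequence=seq.upper(),
                        quality=tuple(ord(c) - 33 for c in qual),
                    ))
        except ValueError as exc:
            raise ParseError(f"{path}: {exc}") from exc
    if not reads:
        raise ParseError(f"{path}: no sequence records found")
    try:
        return ReadSet(reads=reads, region_label=region_label)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_fasta(readset: ReadSet, path) -> None:
    with open(path, "w") as fh:
        for read in readset:
            fh.write(f">{read.id}\n{read.sequence}\n")


def read_otu_table(path, region_label: str | None = None) -> OTUTable:
    """Read a tab-separated OTU table: rows are samples, columns OTUs.

    First column holds sample ids; the header row holds OTU ids.  Cells
    must be non-negative integers; ragged rows and non-integer cells
    raise :class:`ParseError`.
    """
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, header=0, dtype=str)
    except Exception as exc:  # pandas raises several types for bad input
        raise ParseError(f"{path}: {exc}") from exc
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ParseError(f"{path}: no data rows in OTU table")
    if df.isna().any().any():
        raise ParseError(f"{path}: ragged or missing cells in OTU table")
    try:
        counts = df.to_numpy(dtype=np.float64)
    except ValueError as exc:
        raise ParseError(f"{path}: non-numeric cell in OTU table: {exc}") from exc
    if not np.all(np.mod(counts, 1) == 0):
        raise ParseError(f"{path}: non-integer cell in OTU table")
    try:
        return OTUTable(
            sample_ids=[str(s) for s in df.index],
            otu_ids=[str(c) for c in df.columns],
            counts=counts.astype(np.int64),
            region_label=region_label,
        )
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_otu_table(table: OTUTable, path) -> None:
    table.to_dataframe().to_csv(path, sep="\t", index_label="sample_id")


def read_tree(path) -> TreeNode:
    """Read a rooted Newick tree with branch lengths on every edge."""
    try:
        tree = TreeNode.read(str(path), format="newick")
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    try:
        return validate_tree(tree, require_lengths=True)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from exc


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def tree_to_newick(tree: TreeNode) -> str:
    buf = _io.StringIO()
    tree.write(buf, format="newick")
    return buf.getvalue()


_PEAK_COLUMNS = ["sample_id", "fragment_length", "fluorescence"]


def read_peak_profiles(path) -> list[PeakProfile]:
    """Read ARISA peaks from CSV (sample_id, fragment_length, fluorescence).

    Returns one :class:`PeakProfile` per distinct sample id, in order of
    first appearance.
    """
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ParseError(f"{path}: {exc}") from exc
    missing = [c for c in _PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    for col in ("fragment_length", "fluorescence"):
        if not np.issubdtype(df[col].dtype, np.number):
            raise ParseError(f"{path}: non-numeric values in column {col!r}")
    profiles = []
    for sid in df["sample_id"].drop_duplicates():
        sub = df[df["sample_id"] == sid]
        try:
            profiles.append(PeakProfile(
                sample_id=str(sid),
                fragment_lengths=sub["fragment_length"].to_numpy(float),
                fluorescences=sub["fluorescence"].to_numpy(float),
            ))
        except ValueError as exc:
            raise ParseError(f"{path}: sample {sid!r}: {exc}") from exc
    return profiles


def write_peak_profiles(profiles, path) -> None:
    rows = []
    for prof in profiles:
        for length, fluo in zip(prof.fragment_lengths, prof.fluorescences):
            rows.append((prof.sample_id, length, fluo))
    pd.DataFrame(rows, columns=_PEAK_COLUMNS).to_csv(path, index=False)


def read_env_table(path) -> pd.DataFrame:
    """Environmental covariates: TSV with sample_id plus numeric columns."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    non_numeric = [c for c in df.columns
                   if not np.issubdtype(df[c].dtype, np.number)]
    if non_numeric:
        raise ParseError(f"{path}: non-numeric covariate columns {non_numeric}")
    return df
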