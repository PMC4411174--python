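"""Core in-memory containers shared by every pipeline stage.

The central currency is the :class:`OTUTable` — a dense samples x OTUs
integer count matrix.  Trees are plain :class:`skbio.TreeNode` objects
(rooted, with branch lengths); :func:`validate_tree` enforces the
invariants the diversity code relies on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

__all__ = [
    "Read",
    "ReadSet",
    "OTUTable",
    "PeakProfile",
    "validate_tree",
    "IUPAC_DNA",
]

# IUPAC nucleotide codes (upper case); sequences are normalised on read.
IUPAC_DNA = frozenset("ACGTNRYSWKMBDHV")


@dataclass(frozen=True)
class Read:
    """A single sequencing read; quality scores are optional (FASTA has none)."""

    id: str
    sequence: str
    quality: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")
        bad = set(self.sequence) - IUPAC_DNA
        if bad:
            raise ValueError(
                f"read {self.id!r}: non-IUPAC characters {sorted(bad)!r}"
            )
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.quality)} != "
                f"sequence length {len(self.sequence)}"
            )


@dataclass
class ReadSet:
    """An ordered collection of reads with unique ids."""

    reads: list[Read]
    region_label: str | None = None

    def __post_init__(self) -> None:
        ids = [r.id for r in self.reads]
        if len(ids) != len(set(ids)):
            seen: set[str] = set()
            dup = next(i for i in ids if i in seen or seen.add(i))
            raise ValueError(f"duplicate read id {dup!r}")

    def __len__(self) -> int:
        return len(self.reads)

    def __iter__(self):
        return iter(self.reads)


@dataclass
class OTUTable:
    """Dense non-negative integer count matrix, samples in rows."""

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    region_label: str | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.mod(self.counts, 1) == 0):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        else:
            self.counts = self.counts.astype(np.int64)
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(set(self.otu_ids)) != len(self.otu_ids):
            raise ValueError("duplicate OTU ids")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def row(self, sample_id: str) -> np.ndarray:
        return self.counts[self.sample_ids.index(sample_id)]

    def presence(self) -> np.ndarray:
        """Boolean samples x OTUs presence matrix."""
        return self.counts > 0

    def sample_sums(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=self.sample_ids, columns=self.otu_ids
        )

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, region_label: str | None = None
    ) -> "OTUTable":
        return cls(
            sample_ids=[str(s) for s in df.index],
            otu_ids=[str(o) for o in df.columns],
            counts=df.to_numpy(),
            region_label=region_label,
        )

    def drop_empty_otus(self) -> "OTUTable":
        keep = self.counts.sum(axis=0) > 0
        return OTUTable(
            sample_ids=list(self.sample_ids),
            otu_ids=[o for o, k in zip(self.otu_ids, keep) if k],
            counts=self.counts[:, keep],
            region_label=self.region_label,
        )


@dataclass
class PeakProfile:
    """ARISA electropherogram peaks for one sample.

    ``fragment_lengths`` are in nucleotide units; ``fluorescences`` are
    arbitrary non-negative intensity units.
    """

    sample_id: str
    fragment_lengths: np.ndarray = field(default_factory=lambda: np.empty(0))
    fluorescences: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        self.fragment_lengths = np.asarray(self.fragment_lengths, dtype=float)
        self.fluorescences = np.asarray(self.fluorescences, dtype=float)
        if self.fragment_lengths.shape != self.fluorescences.shape:
            raise ValueError("fragment_lengths and fluorescences differ in length")
        if (self.fragment_lengths <= 0).any():
            raise ValueError("fragment lengths must be > 0")
        if (self.fluorescences < 0).any():
            raise ValueError("fluorescence must be >= 0")

    @property
    def n_peaks(self) -> int:
        return int(self.fragment_lengths.size)


def validate_tree(tree: TreeNode, require_lengths: bool = True) -> TreeNode:
    """Check rootedness, unique tip labels and branch lengths of a tree.

    A tree whose root has more than two children is treated as unrooted
    and rejected: phylogenetic diversity is defined on a rooted topology.
    Branch lengths must be present and non-negative on every non-root
    edge (the root's own length, if any, is ignored by PD).
    """
    root = tree.root()
    n_children = len(root.children)
    if n_children > 2:
        raise ValueError(
            f"tree root has {n_children} children; an unrooted (trifurcating) "
            "topology is not accepted — provide a rooted tree"
        )
    tips = [t.name for t in tree.tips()]
    if len(tips) != len(set(tips)):
        raise ValueError("duplicate tip labels in tree")
    if any(t is None for t in tips):
        raise ValueError("unlabelled tip in tree")
    if require_lengths:
        for node in tree.traverse(include_self=False):
            if node.length is None:
                name = node.name or "<internal>"
                raise ValueError(f"missing branch length on edge above {name}")
            if node.length < 0:
                raise ValueError("negative branch length")
    return tree
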