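"""Greedy centroid clustering of equal-length trimmed reads into OTUs.

This is a deterministic, reproducible stand-in for UCLUST-style de novo
OTU picking: unique sequences are visited in decreasing total abundance
(ties broken lexicographically) and each joins the first existing
centroid whose Hamming identity reaches the sequence similarity
threshold (SST), else founds a new centroid.  Because trimmed reads are
fixed-length, identity is positional (no alignment); ``N`` matches
nothing, including another ``N``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .types import OTUTable, Read, ReadSet

__all__ = ["ClusteringResult", "pairwise_identity", "greedy_cluster",
           "merge_centroids"]


def pairwise_identity(a: str, b: str) -> float:
    """Fraction of positions that match; N never matches."""
    if len(a) != len(b):
        raise ValueError(f"sequences differ in length ({len(a)} vs {len(b)})")
    if not a:
        raise ValueError("empty sequences")
    matches = sum(1 for x, y in zip(a, b) if x == y and x != "N" and y != "N")
    return matches / len(a)


@dataclass
class ClusteringResult:
    sst: float
    centroids: ReadSet
    membership: dict[str, str]      # read id -> centroid id
    otu_table: OTUTable

    @property
    def n_otus(self) -> int:
        return len(self.centroids)


def greedy_cluster(sample_reads: dict[str, ReadSet], sst: float,
                   method: str = "first-fit") -> ClusteringResult:
    """Cluster per-sample read sets at the given identity threshold.

    ``method`` is ``"first-fit"`` (default: join the earliest-founded
    centroid that qualifies) or ``"best-fit"`` (join the qualifying
    centroid of highest identity, earliest founded on ties).
    """
    if not 0.0 < sst <= 1.0:
        raise ValueError("sst must lie in (0, 1]")
    if method not in ("first-fit", "best-fit"):
        raise ValueError(f"unknown method {method!r}")
    sample_ids = list(sample_reads)
    # dereplicate: sequence -> per-sample counts and member read ids
    seq_counts: dict[str, np.ndarray] = {}
    seq_members: dict[str, list[str]] = {}
    length = None
    for si, sample in enumerate(sample_ids):
        for read in sample_reads[sample]:
            if length is None:
                length = len(read.sequence)
            elif len(read.sequence) != length:
                raise ValueError("mixed read lengths; trim first")
            if read.sequence not in seq_counts:
                seq_counts[read.sequence] = np.zeros(len(sample_ids),
                                                     dtype=np.int64)
                seq_members[read.sequence] = []
            seq_counts[read.sequence][si] += 1
            seq_members[read.sequence].append(read.id)
    if not seq_counts:
        raise ValueError("no reads to cluster")

    order = sorted(seq_counts, key=lambda s: (-int(seq_counts[s].sum()), s))
    n_mask = np.frombuffer(b"N", dtype=np.uint8)[0]

    centroid_seqs: list[str] = []
    centroid_mat: np.ndarray | None = None
    assignment: list[int] = []
    for seq in order:
        row = np.frombuffer(seq.encode(), dtype=np.uint8)
        if centroid_seqs:
            valid = (centroid_mat != n_mask) & (row[None, :] != n_mask)
            matches = ((centroid_mat == row[None, :]) & valid).sum(axis=1)
            ident = matches / length
            qualifying = np.nonzero(ident >= sst)[0]
        else:
            qualifying = np.empty(0, dtype=int)
            ident = None
        if qualifying.size:
            if method == "first-fit":
                assignment.append(int(qualifying[0]))
            else:
                best = qualifying[np.argmax(ident[qualifying])]
                assignment.append(int(best))
        else:
            centroid_seqs.append(seq)
            new_row = row[None, :]
            centroid_mat = new_row if centroid_mat is None else \
                np.vstack([centroid_mat, new_row])
            assignment.append(len(centroid_seqs) - 1)

    width = max(4, len(str(len(centroid_seqs))))
    otu_ids = [f"OTU{i:0{width}d}" for i in range(len(centroid_seqs))]
    counts = np.zeros((len(sample_ids), len(otu_ids)), dtype=np.int64)
    membership: dict[str, str] = {}
    for seq, cid in zip(order, assignment):
        counts[:, cid] += seq_counts[seq]
        for rid in seq_members[seq]:
            membership[rid] = otu_ids[cid]
    centroids = ReadSet(reads=[Read(id=otu_ids[i], sequence=s)
                               for i, s in enumerate(centroid_seqs)])
    table = OTUTable(sample_ids=sample_ids, otu_ids=otu_ids, counts=counts)
    return ClusteringResult(sst=sst, centroids=centroids,
                            membership=membership, otu_table=table)


def merge_centroids(result: ClusteringResult, sst: float) -> ClusteringResult:
    """Re-cluster the centroids of an existing result at a looser threshold.

    Produces a partition *nested* inside the input one: OTUs are merged,
    never split, so OTU counts and per-sample richness are guaranteed
    non-increasing along a descending threshold sweep.  Centroids are
    visited in decreasing total abundance (ties lexicographic) and join
    the first merged centroid within ``sst`` identity.
    """
    if not 0.0 < sst <= 1.0:
        raise ValueError("sst must lie in (0, 1]")
    if sst > result.sst:
        raise ValueError("merge threshold must not exceed the original sst")
    table = result.otu_table
    totals = table.counts.sum(axis=0)
    seq_of = {r.id: r.sequence for r in result.centroids}
    order = sorted(range(len(table.otu_ids)),
                   key=lambda i: (-int(totals[i]), seq_of[table.otu_ids[i]]))
    length = len(next(iter(seq_of.values())))
    n_mask = np.frombuffer(b"N", dtype=np.uint8)[0]
    kept: list[int] = []
    kept_mat: np.ndarray | None = None
    remap: dict[int, int] = {}
    for idx in order:
        row = np.frombuffer(seq_of[table.otu_ids[idx]].encode(),
                            dtype=np.uint8)
        if kept:
            valid = (kept_mat != n_mask) & (row[None, :] != n_mask)
            ident = ((kept_mat == row[None, :]) & valid).sum(axis=1) / length
            hits = np.nonzero(ident >= sst)[0]
        else:
            hits = np.empty(0, dtype=int)
        if hits.size:
            remap[idx] = int(hits[0])
        else:
            remap[idx] = len(kept)
            kept.append(idx)
            new_row = row[None, :]
            kept_mat = new_row if kept_mat is None else \
                np.vstack([kept_mat, new_row])
    width = max(4, len(str(len(kept))))
    otu_ids = [f"OTU{i:0{width}d}" for i in range(len(kept))]
    counts = np.zeros((table.n_samples, len(kept)), dtype=np.int64)
    for idx, target in remap.items():
        counts[:, target] += table.counts[:, idx]
    old_new = {table.otu_ids[idx]: otu_ids[t] for idx, t in remap.items()}
    membership = {rid: old_new[cid] for rid, cid in result.membership.items()}
    centroids = ReadSet(reads=[
        Read(id=otu_ids[i], sequence=seq_of[table.otu_ids[idx]])
        for i, idx in enumerate(kept)])
    new_table = OTUTable(sample_ids=list(table.sample_ids), otu_ids=otu_ids,
                         counts=counts, region_label=table.region_label)
    return ClusteringResult(sst=sst, centroids=centroids,
                            membership=membership, otu_table=new_table)
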