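"""Anchored trimming of mixed-region reads into fixed-length subsets.

A read is screened for a conserved 11-mer anchor by exact match; reads
that fail the forward screen are rescanned as reverse complements.  The
retained window starts ``offset`` bases from the anchor start and spans
``trim_length`` bases; reads whose window runs past the read end are
counted as too short.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import Read, ReadSet

__all__ = ["AnchorSpec", "TrimReport", "find_anchor", "trim_read",
           "trim_dataset"]

_RC = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_RC)[::-1]


@dataclass(frozen=True)
class AnchorSpec:
    """Anchor and window geometry for one region.

    ``offset`` is the signed start of the retained segment relative to
    the anchor's first base; the default (11) keeps the segment that
    immediately follows the anchor.
    """

    region_name: str
    anchor_11mer: str
    trim_length: int
    offset: int = 11

    def __post_init__(self) -> None:
        if len(self.anchor_11mer) != 11:
            raise ValueError("anchor must be exactly 11 bases")
        if set(self.anchor_11mer) - set("ACGT"):
            raise ValueError("anchor must be non-degenerate A/C/G/T")
        if self.trim_length <= 0:
            raise ValueError("trim_length must be positive")


@dataclass
class RegionTrimCounts:
    input_reads: int = 0
    anchored_forward: int = 0
    anchored_reverse_complement: int = 0
    too_short: int = 0
    trimmed_out: int = 0

    def check(self) -> None:
        assert self.trimmed_out == (self.anchored_forward
                                    + self.anchored_reverse_complement
                                    - self.too_short)


@dataclass
class TrimReport:
    """Per-region accounting of the screen/rescan/trim stages."""

    regions: dict[str, RegionTrimCounts] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {name: vars(c).copy() for name, c in self.regions.items()}


def find_anchor(sequence: str, anchor: str) -> int | None:
    """0-based index of the leftmost exact anchor match, or None."""
    if len(anchor) != 11:
        raise ValueError("anchor must be exactly 11 bases")
    pos = sequence.find(anchor)
    return pos if pos >= 0 else None


def _window(sequence: str, pos: int, spec: AnchorSpec) -> str | None:
    start = pos + spec.offset
    end = start + spec.trim_length
    if start < 0 or end > len(sequence):
        return None
    return sequence[start:end]


def trim_read(read: Read, spec: AnchorSpec):
    """Trim one read; returns ``(segment or None, orientation)``.

    ``orientation`` is ``"fwd"``, ``"rc"`` or ``None`` (anchor absent);
    a found anchor with an out-of-bounds window yields ``(None,
    orientation)`` and counts as too short.
    """
    pos = find_anchor(read.sequence, spec.anchor_11mer)
    if pos is not None:
        return _window(read.sequence, pos, spec), "fwd"
    rc = reverse_complement(read.sequence)
    pos = find_anchor(rc, spec.anchor_11mer)
    if pos is not None:
        return _window(rc, pos, spec), "rc"
    return None, None


def trim_dataset(reads: ReadSet, specs: list[AnchorSpec]):
    """Trim every read against every region spec.

    A read may contribute to several regions.  Returns ``(per-region
    ReadSet, TrimReport)``; every region's trimmed reads all have length
    exactly ``trim_length``.
    """
    names = [s.region_name for s in specs]
    if len(names) != len(set(names)):
        raise ValueError("duplicate region names in anchor specs")
    report = TrimReport({name: RegionTrimCounts() for name in names})
    out: dict[str, list[Read]] = {name: [] for name in names}
    for spec in specs:
        counts = report.regions[spec.region_name]
        for read in reads:
            counts.input_reads += 1
            segment, orientation = trim_read(read, spec)
            if orientation == "fwd":
                counts.anchored_forward += 1
            elif orientation == "rc":
                counts.anchored_reverse_complement += 1
            else:
                continue
            if segment is None:
                counts.too_short += 1
                continue
            counts.trimmed_out += 1
            out[spec.region_name].append(Read(id=read.id, sequence=segment))
        counts.check()
    regions = {name: ReadSet(reads=out[name], region_label=name)
               for name in names}
    return regions, report
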