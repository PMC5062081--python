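"""Genomic-interval model and readers for BED, ChromHMM segmentations, and CR tables.

All coordinates are 0-based half-open ``[start, end)`` — the BED convention.
An interval's length is ``end - start``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

__all__ = [
    "GenomicInterval",
    "CREvent",
    "CRTable",
    "EnhancerTrack",
    "CR_TYPES",
    "STRONG_ENHANCER_STATES",
    "interval_length",
    "window_around",
    "overlap_bp",
    "read_bed",
    "write_bed",
    "read_cr_table",
]

#: Closed set of rearrangement types.
CR_TYPES = frozenset(
    {"deletion", "duplication", "inversion", "translocation", "insertion", "ring"}
)

#: ChromHMM labels retained by default: the strong-enhancer states of the
#: Broad 15-state model.
STRONG_ENHANCER_STATES = frozenset({"4_Strong_Enhancer", "5_Strong_Enhancer"})


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval ``[start, end)`` on one chromosome."""

    chrom: str
    start: int
    end: int
    strand: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}: "
                "require 0 <= start < end"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end


def interval_length(iv: GenomicInterval) -> int:
    """Length in base pairs: ``end - start``."""
    return iv.end - iv.start


def window_around(pos: int, width: int, chrom: str = "") -> GenomicInterval:
    """Interval of ``width`` bp centred on ``pos``, clipped at coordinate 0."""
    if width <= 0:
        raise ValueError(f"window width must be positive, got {width}")
    start = max(0, pos - width // 2)
    end = pos + width // 2
    return GenomicInterval(chrom, start, end)


@dataclass(frozen=True)
class CREvent:
    """A chromosomal rearrangement with its disease annotation."""

    cr_id: str
    interval: GenomicInterval
    cr_type: str
    disease: str = ""
    gene: str = ""
    pubmed_id: str = ""

    def __post_init__(self) -> None:
        if self.cr_type not in CR_TYPES:
            raise ValueError(
                f"unknown CR type {self.cr_type!r}; expected one of {sorted(CR_TYPES)}"
            )


def _merge_sorted(intervals: Sequence[GenomicInterval]) -> list[GenomicInterval]:
    merged: list[GenomicInterval] = []
    for iv in intervals:
        if merged and merged[-1].chrom == iv.chrom and iv.start <= merged[-1].end:
            if iv.end > merged[-1].end:
                merged[-1] = GenomicInterval(iv.chrom, merged[-1].start, iv.end)
        else:
            merged.append(GenomicInterval(iv.chrom, iv.start, iv.end))
    return merged


@dataclass
class EnhancerTrack:
    """A set of enhancer intervals, kept sorted by (chrom, start).

    Overlapping records are permitted as read; :meth:`merged` returns the
    coverage (union) representation used for all base-pair tallies.
    """

    intervals: list[GenomicInterval] = field(default_factory=list)
    source_states: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        self.intervals = sorted(self.intervals, key=lambda iv: (iv.chrom, iv.start, iv.end))

    def __len__(self) -> int:
        return len(self.intervals)

    def merged(self) -> "EnhancerTrack":
        return EnhancerTrack(_merge_sorted(self.intervals), self.source_states)

    def total_bp(self) -> int:
        """Total covered base pairs (union of intervals)."""
        return sum(len(iv) for iv in self.merged().intervals)


def overlap_bp(iv: GenomicInterval, track: EnhancerTrack) -> int:
    """Base pairs of the track's merged coverage intersecting ``iv``.

    A chromosome with no track records contributes 0; that is not an error.
    """
    total = 0
    for m in track.merged().intervals:
        if m.chrom != iv.chrom:
            continue
        lo = max(iv.start, m.start)
        hi = min(iv.end, m.end)
        if hi > lo:
            total += hi - lo
    return total


class BedParseError(ValueError):
    pass


def read_bed(path, state_filter: Optional[Iterable[str]] = None) -> EnhancerTrack:
    """Read a BED3+ file, optionally keeping only records whose name column
    matches ``state_filter`` (e.g. the ChromHMM strong-enhancer states).

    Coordinates are kept verbatim (BED is already 0-based half-open).
    """
    keep = frozenset(state_filter) if state_filter is not None else None
    intervals: list[GenomicInterval] = []
    states: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) < 3:
                raise BedParseError(f"{path}: line {lineno}: fewer than 3 BED columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise BedParseError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end or start < 0:
                raise BedParseError(
                    f"{path}: line {lineno}: invalid interval [{start}, {end})"
                )
            name = fields[3] if len(fields) > 3 else ""
            if keep is not None and name not in keep:
                continue
            if name:
                states.add(name)
            intervals.append(GenomicInterval(chrom, start, end))
    return EnhancerTrack(intervals, frozenset(states))


def write_bed(track: EnhancerTrack, path) -> None:
    with open(path, "w") as fh:
        name = "/".join(sorted(track.source_states)) if track.source_states else "."
        for iv in track.intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


@dataclass
class CRTable:
    """Result of parsing a CR table: accepted events plus a rejection record."""

    events: list[CREvent]
    rejected: pd.DataFrame  # columns: row, reason

    def __iter__(self):
        return iter(self.events)


_REQUIRED_CR_COLUMNS = ("chrom", "start", "end", "type")


def read_cr_table(path) -> CRTable:
    """Read a TSV of rearrangements (ClinVar-like).

    Required columns: chrom, start, end, type; optional: cr_id, disease,
    gene, pubmed. Coordinates are half-open ``[start, end)``. Rows that do
    not parse (unknown type, empty interval, bad coordinates) are rejected
    with a reason rather than aborting the read.
    """
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in _REQUIRED_CR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: CR table missing required column(s): {missing}")

    events: list[CREvent] = []
    rejects: list[dict] = []
    for i, row in df.iterrows():
        reason = None
        try:
            start, end = int(row["start"]), int(row["end"])
        except ValueError:
            rejects.append({"row": i, "reason": "non-integer coordinates"})
            continue
        cr_type = str(row["type"]).strip().lower()
        if cr_type not in CR_TYPES:
            reason = f"unknown type {row['type']!r}"
        elif start == end:
            reason = "empty interval"
        elif not (0 <= start < end):
            reason = "invalid coordinates"
        if reason is not None:
            rejects.append({"row": i, "reason": reason})
            continue
        cr_id = str(row.get("cr_id", "")) or str(i)
        events.append(
            CREvent(
                cr_id=cr_id,
                interval=GenomicInterval(str(row["chrom"]), start, end),
                cr_type=cr_type,
                disease=str(row.get("disease", "")),
                gene=str(row.get("gene", "")),
                pubmed_id=str(row.get("pubmed", "")),
            )
        )
    rejected = pd.DataFrame(rejects, columns=["row", "reason"])
    return CRTable(events=events, rejected=rejected)
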