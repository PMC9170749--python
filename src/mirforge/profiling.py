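"""Collapse, normalize and size-profile small-RNA libraries.

Reads are deduplicated into (sequence, count) records; library profiles report
per-length totals, unique counts and read relative abundance (RRA), plus the
fractions of the library falling in the miRNA (21-24 nt) and piRNA (26-29 nt)
size classes. The RRA/RPM denominator is the library's total retained reads
after N-filtering but before any length-window filter, so size-class profiles
see the full length distribution while miRNA discovery consumes the 18-25-nt
subset.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

import pandas as pd

from .seqio import to_rna

log = logging.getLogger(__name__)

MIRNA_CLASS = (21, 24)
PIRNA_CLASS = (26, 29)


@dataclass(frozen=True, slots=True)
class CollapsedRead:
    sequence: str  # RNA alphabet, uppercase
    count: int
    library_id: str = ""

    def __post_init__(self):
        if self.count < 1:
            raise ValueError("count must be >= 1")


@dataclass
class LibraryProfile:
    library_id: str
    total_reads: int
    per_length: Dict[int, Tuple[int, int, float]]  # length -> (total, unique, rra)
    mirna_class_fraction: float
    pirna_class_fraction: float
    uniqueness: Dict[int, float] = field(default_factory=dict)  # length -> unique/total

    def to_frame(self) -> pd.DataFrame:
        rows = [(self.library_id, ln, tot, uniq, rra)
                for ln, (tot, uniq, rra) in sorted(self.per_length.items())]
        return pd.DataFrame(rows, columns=["library_id", "length", "total",
                                           "unique", "rra"])


def collapse_reads(reads: Iterable[str], library_id: str = "") -> List[CollapsedRead]:
    """Collapse identical reads; N-containing reads are dropped (and counted).

    Output is sorted by descending count, then lexicographic sequence, and the
    counts sum to the number of retained input reads.
    """
    counter: Counter = Counter()
    dropped = 0
    total = 0
    for raw in reads:
        seq = to_rna(raw)
        total += 1
        if not seq or "N" in seq:
            dropped += 1
            continue
        counter[seq] += 1
    if total == 0:
        log.warning("collapse_reads: empty read stream for library %r", library_id)
    if dropped:
        log.warning("collapse_reads: dropped %d N-containing reads in %r",
                    dropped, library_id)
    return [CollapsedRead(sequence=s, count=c, library_id=library_id)
            for s, c in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))]


def length_filter(collapsed: Iterable[CollapsedRead], min_len: int = 18,
                  max_len: int = 25) -> List[CollapsedRead]:
    """Keep reads with min_len <= length <= max_len (bounds inclusive)."""
    if min_len > max_len:
        raise ValueError("min_len must be <= max_len")
    return [r for r in collapsed if min_len <= len(r.sequence) <= max_len]


def rpm(count: float, library_total: int) -> float:
    """Reads-per-million normalization."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    return count * 1e6 / library_total


def profile_library(collapsed: List[CollapsedRead],
                    library_id: str | None = None) -> LibraryProfile:
    """Per-length totals/unique counts/RRA and size-class fractions of a library."""
    if not collapsed:
        raise ValueError("cannot profile an empty library")
    lib = library_id if library_id is not None else collapsed[0].library_id
    totals: Counter = Counter()
    uniques: Counter = Counter()
    for r in collapsed:
        totals[len(r.sequence)] += r.count
        uniques[len(r.sequence)] += 1
    grand = sum(totals.values())
    per_length = {ln: (totals[ln], uniques[ln], totals[ln] / grand)
                  for ln in sorted(totals)}
    mirna = sum(rra for ln, (_, _, rra) in per_length.items()
                if MIRNA_CLASS[0] <= ln <= MIRNA_CLASS[1])
    pirna = sum(rra for ln, (_, _, rra) in per_length.items()
                if PIRNA_CLASS[0] <= ln <= PIRNA_CLASS[1])
    uniqueness = {ln: uniques[ln] / totals[ln] for ln in totals}
    return LibraryProfile(library_id=lib, total_reads=grand, per_length=per_length,
                          mirna_class_fraction=mirna, pirna_class_fraction=pirna,
                          uniqueness=uniqueness)


def profiles_to_frame(profiles: Iterable[LibraryProfile]) -> pd.DataFrame:
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
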