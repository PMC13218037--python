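"""Stringent read trimming and alignment filtering.

The goal is to strip generic sequencing noise (adapter read-through at the
read start, quality decay at the read end, low-quality tails) so that any
platform-specific mismatch excess left in the pileups can be attributed to
the sequencing chemistry rather than to ordinary error modes. The rules are
deliberately far stricter than pre-variant-calling QC:

* drop the final 5 bp of every read;
* drop the first 8 bp (101-bp reads) or 12 bp (151/250-bp reads);
* scan 10-bp windows left to right and cut the read at the left edge of the
  first window whose mean Phred quality falls below 25;
* keep only reads with >= 65 bp (101-bp class) or >= 100 bp (151/250-bp
  class) remaining;
* discard duplicates, non-proper pairs, supplementary alignments, MAPQ < 60,
  and any CIGAR containing indel or clipping operations.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace
from typing import Iterable, Iterator

import numpy as np

from .io import ReadRecord

#: CIGAR operations that disqualify a read (indels and clips)
DISALLOWED_CIGAR_OPS = frozenset("IDSH")

MIN_MAPQ = 60


@dataclass(frozen=True)
class TrimPolicy:
    tail_trim: int = 5
    head_trim: int = 8
    window: int = 10
    window_threshold: float = 25.0
    min_length: int = 65

    def __post_init__(self):
        for name in ("tail_trim", "head_trim", "window", "min_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    @classmethod
    def for_read_length_class(cls, read_length_class: int) -> "TrimPolicy":
        """Policy parameterized by raw read length: 8/65 for 101-bp reads,
        12/100 for 151- and 250-bp reads."""
        if read_length_class == 101:
            return cls(head_trim=8, min_length=65)
        if read_length_class in (151, 250):
            return cls(head_trim=12, min_length=100)
        raise ValueError(f"unsupported read length class {read_length_class}")


def fixed_trim(read: ReadRecord, policy: TrimPolicy) -> ReadRecord | None:
    """Remove the fixed head and the final ``tail_trim`` bases.

    Returns None (discard) when the read is shorter than the combined trims.
    The reference start is advanced by the head trim so trimmed reads stay
    correctly anchored for pileup counting.
    """
    n = len(read.bases)
    cut = policy.head_trim + policy.tail_trim
    if n < cut:
        return None
    end = n - policy.tail_trim
    return replace(
        read,
        bases=read.bases[policy.head_trim : end],
        quals=read.quals[policy.head_trim : end],
        pos0=read.pos0 + policy.head_trim if read.mapped else read.pos0,
    )


def quality_sliding_trim(read: ReadRecord, policy: TrimPolicy) -> ReadRecord:
    """Cut at the left edge of the first window with mean Phred < threshold.

    Windows of length ``policy.window`` advance one base at a time and must
    lie entirely within the read; a trailing segment shorter than one window
    is never scanned. If no window fails, the read is returned unchanged.
    """
    w = policy.window
    q = np.asarray(read.quals, dtype=float)
    if len(q) < w:
        return read
    means = np.convolve(q, np.ones(w), mode="valid") / w
    failing = np.nonzero(means < policy.window_threshold)[0]
    if failing.size == 0:
        return read
    cut = int(failing[0])
    return replace(read, bases=read.bases[:cut], quals=read.quals[:cut])


def length_filter(read: ReadRecord, policy: TrimPolicy) -> bool:
    """Keep iff at least ``min_length`` bases remain (inclusive)."""
    return len(read.bases) >= policy.min_length


def alignment_filter(read: ReadRecord) -> tuple[bool, str | None]:
    """(keep, reason): first failing rule wins, in the fixed order
    duplicate, proper-pair, supplementary, MAPQ, CIGAR."""
    if read.duplicate:
        return False, "duplicate"
    if not read.proper_pair:
        return False, "proper_pair"
    if read.supplementary:
        return False, "supplementary"
    if read.mapq < MIN_MAPQ:
        return False, "mapq"
    if any(op in DISALLOWED_CIGAR_OPS for op, _ in read.cigar):
        return False, "cigar"
    return True, None


def process_reads(
    reads: Iterable[ReadRecord],
    policy: TrimPolicy | None = None,
    stats: Counter | None = None,
) -> Iterator[ReadRecord]:
    """Full pipeline: alignment filter -> fixed trim -> quality trim -> length.

    A ``Counter`` passed as ``stats`` accumulates per-reason discard counts
    under keys 'unmapped', 'duplicate', 'proper_pair', 'supplementary',
    'mapq', 'cigar', 'too_short_for_trim', 'min_length', and 'kept'.
    """
    counts = stats if stats is not None else Counter()
    for read in reads:
        if not read.mapped:
            counts["unmapped"] += 1
            continue
        keep, reason = alignment_filter(read)
        if not keep:
            counts[reason] += 1
            continue
        pol = policy or TrimPolicy.for_read_length_class(read.read_length_class)
        trimmed = fixed_trim(read, pol)
        if trimmed is None:
            counts["too_short_for_trim"] += 1
            continue
        trimmed = quality_sliding_trim(trimmed, pol)
        if not length_filter(trimmed, pol):
            counts["min_length"] += 1
            continue
        counts["kept"] += 1
        yield trimmed
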