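"""Sequence-context views of a callset: COSMIC-style 96-channel trinucleotide
spectra, the 16-context N[T>G]N restriction, flanking base composition with a
genome-wide background, and ranked k-mer motifs.

All classification happens in the pyrimidine frame: for purine-referenced
calls the local sequence (context, window, or flank) is reverse-complemented
before classification, so errors on either strand of the same chemistry event
co-accumulate. The per-strand "as-read" view is available via ``orient``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from itertools import product

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .io import ReferenceGenome, VariantCall
from .sequence import BASES, PURINES, SBS_CLASSES, collapse_sbs, revcomp


class ContextUndefined(ValueError):
    """Raised when a context window contains N or crosses a contig edge."""


#: canonical channel order: class-major, then left/right flanking base
CHANNELS_96 = tuple(
    f"{l}[{cls}]{r}" for cls in SBS_CLASSES for l, r in product(BASES, BASES)
)
CHANNELS_16_TG = tuple(c for c in CHANNELS_96 if "[T>G]" in c)


def _oriented_flanks(
    genome: ReferenceGenome, call: VariantCall, flank: int, orient: str = "pyrimidine"
) -> tuple[str, str]:
    """(5', 3') flanking sequences of length ``flank`` in the requested frame.

    Raises ContextUndefined on N bases or a window crossing the contig edge.
    """
    contig = genome.contigs.get(call.contig)
    if contig is None:
        raise ContextUndefined(f"unknown contig {call.contig!r}")
    lo, hi = call.pos0 - flank, call.pos0 + 1 + flank
    if lo < 0 or hi > len(contig):
        raise ContextUndefined("window crosses contig edge")
    left = contig[lo : call.pos0]
    right = contig[call.pos0 + 1 : hi]
    if "N" in left or "N" in right or contig[call.pos0] == "N":
        raise ContextUndefined("N base in window")
    if orient == "pyrimidine" and call.ref in PURINES:
        left, right = revcomp(right), revcomp(left)
    return left, right


def trinucleotide_channel(genome: ReferenceGenome, call: VariantCall) -> str:
    """Pyrimidine-frame channel label like ``A[T>G]A`` for one SNV."""
    left, right = _oriented_flanks(genome, call, flank=1)
    return f"{left}[{collapse_sbs(call.ref, call.alt)}]{right}"


def spectrum(
    genome: ReferenceGenome,
    calls: list[VariantCall],
    mode: str = "96",
) -> pd.Series:
    """Channel -> count over a callset.

    ``mode='96'`` uses all channels; ``mode='16tg'`` restricts to the 16
    N[T>G]N channels (non-T>G calls are simply not counted). Unclassifiable
    calls (N in context, contig edge) are skipped; their number is stored in
    ``result.attrs['n_excluded']``.
    """
    if mode not in ("96", "16tg"):
        raise ValueError(f"unknown mode {mode!r}")
    channels = CHANNELS_96 if mode == "96" else CHANNELS_16_TG
    counts = pd.Series(0, index=list(channels), dtype=np.int64)
    excluded = 0
    for call in calls:
        try:
            channel = trinucleotide_channel(genome, call)
        except ContextUndefined:
            excluded += 1
            continue
        if channel in counts.index:
            counts[channel] += 1
    counts.attrs["n_excluded"] = excluded
    return counts


@dataclass
class CompositionProfile:
    """Per-offset base fractions around mutations, with Wilson 95% CIs.

    ``fractions``/``ci_low``/``ci_high`` are DataFrames indexed by offset
    (-flank..-1, 1..flank) with one column per base; ``background`` holds the
    genome-wide single-base fractions the figure-style dotted lines show.
    """

    fractions: pd.DataFrame
    ci_low: pd.DataFrame
    ci_high: pd.DataFrame
    background: dict[str, float]
    n: int
    n_excluded: int

    def gc_fraction_at(self, offset: int) -> float:
        return float(self.fractions.at[offset, "C"] + self.fractions.at[offset, "G"])

    @property
    def background_gc(self) -> float:
        return self.background["C"] + self.background["G"]


def base_composition(
    genome: ReferenceGenome,
    calls: list[VariantCall],
    flank: int = 5,
    orient: str = "pyrimidine",
) -> CompositionProfile:
    """Fraction of each nucleotide at every offset within ±flank of the calls."""
    offsets = [o for o in range(-flank, flank + 1) if o != 0]
    counts = pd.DataFrame(0, index=offsets, columns=list(BASES), dtype=np.int64)
    n = excluded = 0
    for call in calls:
        try:
            left, right = _oriented_flanks(genome, call, flank, orient)
        except ContextUndefined:
            excluded += 1
            continue
        n += 1
        window = left + right
        for off, base in zip(offsets, window):
            counts.at[off, base] += 1
    if n:
        fractions = counts / n
        low = counts.copy().astype(float)
        high = counts.copy().astype(float)
        for off in offsets:
            for b in BASES:
                lo, hi = proportion_confint(counts.at[off, b], n, method="wilson")
                low.at[off, b], high.at[off, b] = lo, hi
    else:
        fractions = counts.astype(float)
        low = high = fractions
    return CompositionProfile(
        fractions=fractions,
        ci_low=low,
        ci_high=high,
        background=genome.base_fractions(),
        n=n,
        n_excluded=excluded,
    )


def kmer_motifs(
    genome: ReferenceGenome,
    calls: list[VariantCall],
    k: int = 4,
    orientation: str = "downstream",
    orient: str = "pyrimidine",
) -> pd.Series:
    """Counts of the k-mer immediately 3' (downstream) or 5' (upstream) of
    each call in the pyrimidine frame, ranked by count with a lexicographic
    tie-break."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if orientation not in ("downstream", "upstream"):
        raise ValueError(f"unknown orientation {orientation!r}")
    tally: Counter[str] = Counter()
    excluded = 0
    for call in calls:
        try:
            left, right = _oriented_flanks(genome, call, k, orient)
        except ContextUndefined:
            excluded += 1
            continue
        tally[right if orientation == "downstream" else left] += 1
    ranked = sorted(tally.items(), key=lambda kv: (-kv[1], kv[0]))
    out = pd.Series(
        [c for _, c in ranked], index=[m for m, _ in ranked], dtype=np.int64
    )
    out.attrs["n_excluded"] = excluded
    return out
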