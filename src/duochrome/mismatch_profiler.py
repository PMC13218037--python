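"""Per-site mismatch pileups, AD-stratified spectra, and platform comparison.

A mismatch "site" is a (position, alternate allele) pair — one reference
position can contribute up to three sites. Sites are stratified by their
alternate allele depth (AD) and tallied per reverse-complement-collapsed
substitution class; this AD x class matrix is the unit the enrichment test
consumes.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass, replace
from typing import Iterable

import numpy as np
import pandas as pd

from .io import ReadRecord, ReferenceGenome, VariantCall
from .sequence import SBS_CLASSES, collapse_sbs

log = logging.getLogger(__name__)

DEFAULT_AD_MAX = 25


@dataclass(frozen=True)
class PileupMismatch:
    """A genomic site carrying a non-reference allele in one platform."""

    contig: str
    pos: int  # 1-based
    ref: str
    alt: str
    ad: int
    dp: int
    platform: str = ""

    def __post_init__(self):
        if not (1 <= self.ad <= self.dp):
            raise ValueError(f"require 1 <= ad <= dp, got ad={self.ad} dp={self.dp}")
        if self.ref == self.alt:
            raise ValueError("ref == alt is not a mismatch")

    @property
    def sbs_class(self) -> str:
        return collapse_sbs(self.ref, self.alt)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.contig, self.pos, self.alt)


@dataclass
class ADMatrix:
    """Mismatch-site counts indexed by SBS class x AD bin (1..ad_max).

    ADs above ``ad_max`` accumulate in the top bin so totals are conserved.
    """

    counts: pd.DataFrame
    platform: str = ""

    @property
    def ad_max(self) -> int:
        return int(self.counts.columns.max())

    def total_at(self, ad: int) -> int:
        return int(self.counts[ad].sum())

    def count(self, sbs_class: str, ad: int) -> int:
        return int(self.counts.at[sbs_class, ad])

    @property
    def n_sites(self) -> int:
        return int(self.counts.to_numpy().sum())


@dataclass
class PileupResult:
    sites: list[PileupMismatch]
    coverage: dict[str, np.ndarray]  # contig -> per-position kept-read depth

    def coverage_at(self, contig: str, pos: int) -> int:
        """Kept-read depth at a 1-based position (0 if contig unknown)."""
        arr = self.coverage.get(contig)
        if arr is None or not (1 <= pos <= len(arr)):
            return 0
        return int(arr[pos - 1])


def pileup_mismatches(
    reads: Iterable[ReadRecord],
    genome: ReferenceGenome,
    platform: str = "",
) -> PileupResult:
    """Count per-column non-reference bases over QC-passed reads.

    Reads must carry pure-match alignments (the upstream CIGAR filter
    guarantees a 1:1 base-to-reference correspondence). Positions whose
    reference base is N are excluded.
    """
    coverage: dict[str, np.ndarray] = {}
    refarrs: dict[str, np.ndarray] = {}
    mismatch: dict[tuple[str, int, str], int] = defaultdict(int)
    for read in reads:
        if read.contig not in genome.contigs:
            raise ValueError(f"read {read.name!r}: unknown contig {read.contig!r}")
        ref = genome.contigs[read.contig]
        if read.contig not in coverage:
            coverage[read.contig] = np.zeros(len(ref), dtype=np.int64)
            refarrs[read.contig] = np.frombuffer(ref.encode(), dtype="S1")
        n = len(read.bases)
        if read.pos0 < 0 or read.pos0 + n > len(ref):
            raise ValueError(
                f"read {read.name!r} maps beyond contig {read.contig!r} end"
            )
        coverage[read.contig][read.pos0 : read.pos0 + n] += 1
        seg = refarrs[read.contig][read.pos0 : read.pos0 + n]
        obs = np.frombuffer(read.bases.encode(), dtype="S1")
        for off in np.nonzero(obs != seg)[0]:
            refb = seg[off].decode()
            altb = obs[off].decode()
            if refb == "N" or altb not in "ACGT":
                continue
            mismatch[(read.contig, int(read.pos0 + off), altb)] += 1
    sites = []
    for (contig, pos0, alt), ad in sorted(mismatch.items()):
        refb = genome.contigs[contig][pos0]
        sites.append(
            PileupMismatch(
                contig=contig,
                pos=pos0 + 1,
                ref=refb,
                alt=alt,
                ad=ad,
                dp=int(coverage[contig][pos0]),
                platform=platform,
            )
        )
    return PileupResult(sites=sites, coverage=coverage)


def platform_specific_sites(
    a: list[PileupMismatch],
    b: list[PileupMismatch],
    cov_b: PileupResult | dict[str, np.ndarray] | None = None,
    min_other_depth: int = 1,
) -> list[PileupMismatch]:
    """Sites mismatched in ``a`` and absent from ``b``, where absence is
    verifiable: the other platform must cover the position with at least
    ``min_other_depth`` reads. Swap the arguments for b-specific sites."""
    b_keys = {s.key for s in b}
    if cov_b is not None and not isinstance(cov_b, PileupResult):
        cov_b = PileupResult(sites=[], coverage=cov_b)
    out = []
    for site in a:
        if site.key in b_keys:
            continue
        if cov_b is not None and cov_b.coverage_at(site.contig, site.pos) < min_other_depth:
            continue
        out.append(site)
    return out


def ad_spectrum(
    sites: Iterable[PileupMismatch | VariantCall],
    ad_max: int = DEFAULT_AD_MAX,
    platform: str = "",
) -> ADMatrix:
    """Tally sites into the 6-class x AD matrix, capping AD at ``ad_max``."""
    class_index = {c: i for i, c in enumerate(SBS_CLASSES)}
    arr = np.zeros((len(SBS_CLASSES), ad_max), dtype=np.int64)
    rows = np.fromiter(
        (class_index[collapse_sbs(s.ref, s.alt)] for s in sites), dtype=np.int64
    )
    cols = np.fromiter((min(max(s.ad, 1), ad_max) - 1 for s in sites), dtype=np.int64)
    np.add.at(arr, (rows, cols), 1)
    counts = pd.DataFrame(arr, index=list(SBS_CLASSES), columns=range(1, ad_max + 1))
    return ADMatrix(counts=counts, platform=platform)


def tg_fraction(m: ADMatrix, ad: int) -> float | None:
    """T>G sites as a fraction of all mismatch sites at one AD stratum.

    Returns None (undefined, deliberately not 0) when the stratum is empty.
    """
    total = m.total_at(ad)
    if total == 0:
        return None
    return m.count("T>G", ad) / total


def af_from_ad(ad: int, dp: int) -> float:
    """Allele fraction implied by an alternate depth at a total depth."""
    if dp <= 0:
        raise ValueError("dp must be positive")
    if not (0 <= ad <= dp):
        raise ValueError("require 0 <= ad <= dp")
    return ad / dp


def recalculate_ad(
    calls: list[VariantCall],
    reads: Iterable[ReadRecord],
    genome: ReferenceGenome,
    min_ad: int = 2,
) -> list[VariantCall]:
    """Replace each call's ad/dp with pileup counts from QC-passed reads and
    drop calls whose recomputed alternate depth falls below ``min_ad``."""
    result = pileup_mismatches(reads, genome)
    support = {s.key: s for s in result.sites}
    kept, dropped = [], 0
    for call in calls:
        site = support.get((call.contig, call.pos, call.alt))
        ad = site.ad if site is not None else 0
        dp = result.coverage_at(call.contig, call.pos)
        if ad < min_ad:
            dropped += 1
            continue
        kept.append(replace(call, ad=ad, dp=max(dp, ad)))
    if dropped:
        log.info("recalculate_ad: dropped %d/%d calls with alt AD < %d",
                 dropped, len(calls), min_ad)
    return kept


def downsample_sites(
    sites: list[PileupMismatch],
    source_cov: float,
    target_cov: float,
    seed: int,
) -> list[PileupMismatch]:
    """Binomially thin every site's reads to emulate a lower coverage.

    Supporting and non-supporting reads are each retained independently with
    probability target_cov/source_cov; sites losing all alternate support
    disappear, as they would at the lower coverage.
    """
    if not (0 < target_cov <= source_cov):
        raise ValueError("require 0 < target_cov <= source_cov")
    p = target_cov / source_cov
    if p == 1.0:
        return list(sites)
    rng = np.random.default_rng(seed)
    out = []
    for site in sites:
        ad = int(rng.binomial(site.ad, p))
        other = int(rng.binomial(site.dp - site.ad, p))
        if ad >= 1:
            out.append(replace(site, ad=ad, dp=ad + other))
    return out


def platform_exclusive_calls(
    a: list[VariantCall], b: list[VariantCall]
) -> list[VariantCall]:
    """Calls present in ``a`` with no (contig, pos, ref, alt) match in ``b``."""
    b_keys = {c.key for c in b}
    return [c for c in a if c.key not in b_keys]


# re-exported for the module surface
__all__ = [
    "PileupMismatch",
    "ADMatrix",
    "PileupResult",
    "collapse_sbs",
    "pileup_mismatches",
    "platform_specific_sites",
    "ad_spectrum",
    "tg_fraction",
    "af_from_ad",
    "recalculate_ad",
    "downsample_sites",
    "platform_exclusive_calls",
]
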