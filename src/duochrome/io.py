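"""File-format boundary: FASTA references, SAM/BAM alignments, VCF callsets,
and the simplified TSV mismatch-table dialect.

Internal coordinates are 0-based half-open everywhere; the 1-based convention
of VCF and of ``VariantCall.pos`` is converted at this boundary only. A TSV
table with columns (contig, pos, ref, alt, ad, dp, platform) is accepted
anywhere a VCF is, for desk-scale work.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, field, replace

import pandas as pd
import pyfaidx
import pysam

from .sequence import BASES

log = logging.getLogger(__name__)

TSV_SUFFIXES = (".tsv", ".txt", ".table")
#: INFO flag written on calls classified as two-color-chemistry artifacts
ARTIFACT_INFO_FLAG = "TG_ARTIFACT"


class FastaParseError(ValueError):
    pass


@dataclass
class ReferenceGenome:
    """Uppercased reference sequences keyed by contig name."""

    contigs: dict[str, str] = field(default_factory=dict)

    def fetch(self, contig: str, start: int, length: int) -> str:
        """Return ``length`` bases from 0-based ``start``; raises on overflow."""
        try:
            seq = self.contigs[contig]
        except KeyError:
            raise KeyError(f"unknown contig {contig!r}") from None
        if start < 0 or start + length > len(seq):
            raise IndexError(
                f"window [{start}, {start + length}) outside contig "
                f"{contig!r} of length {len(seq)}"
            )
        return seq[start : start + length]

    def base_at(self, contig: str, pos0: int) -> str:
        return self.fetch(contig, pos0, 1)

    def base_fractions(self) -> dict[str, float]:
        """Genome-wide fraction of each of A/C/G/T, N excluded."""
        counts = dict.fromkeys(BASES, 0)
        for seq in self.contigs.values():
            for b in BASES:
                counts[b] += seq.count(b)
        total = sum(counts.values())
        if total == 0:
            raise ValueError("genome contains no unambiguous bases")
        return {b: counts[b] / total for b in BASES}

    def __len__(self) -> int:
        return sum(len(s) for s in self.contigs.values())


@dataclass(frozen=True)
class VariantCall:
    """One biallelic SNV with its alternate ('ad') and total ('dp') depth."""

    contig: str
    pos: int  # 1-based, as in VCF
    ref: str
    alt: str
    ad: int
    dp: int
    platform: str = ""

    def __post_init__(self):
        if self.ref == self.alt or self.ref not in BASES or self.alt not in BASES:
            raise ValueError(f"invalid SNV {self.ref}>{self.alt}")
        if not (0 <= self.ad <= self.dp):
            raise ValueError(f"require 0 <= ad <= dp, got ad={self.ad} dp={self.dp}")

    @property
    def pos0(self) -> int:
        return self.pos - 1

    @property
    def af(self) -> float:
        """Alternate allele fraction ad/dp, always recomputed."""
        if self.dp == 0:
            return 0.0
        return self.ad / self.dp

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.contig, self.pos, self.ref, self.alt)


@dataclass
class ReadRecord:
    """One sequenced read plus the alignment attributes the filters consume."""

    name: str
    contig: str | None
    pos0: int  # 0-based leftmost reference coordinate
    bases: str
    quals: list[int]
    mapq: int
    mapped: bool = True
    proper_pair: bool = True
    supplementary: bool = False
    duplicate: bool = False
    cigar: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self):
        if len(self.bases) != len(self.quals):
            raise ValueError(
                f"read {self.name}: {len(self.bases)} bases vs {len(self.quals)} quals"
            )

    @property
    def read_length_class(self) -> int:
        """Nearest of the supported read lengths {101, 151, 250}."""
        return min((101, 151, 250), key=lambda c: abs(c - len(self.bases)))


def read_fasta(path: str | os.PathLike) -> ReferenceGenome:
    """Load a FASTA file into memory, uppercased, concatenating wrapped lines."""
    if os.path.getsize(path) == 0:
        log.warning("FASTA %s is empty; returning an empty genome", path)
        return ReferenceGenome({})
    try:
        fasta = pyfaidx.Fasta(
            str(path), as_raw=True, sequence_always_upper=True, rebuild=True
        )
    except (pyfaidx.FastaIndexingError, ValueError) as exc:
        raise FastaParseError(f"cannot parse FASTA {path}: {exc}") from exc
    genome = ReferenceGenome({name: str(fasta[name][:]) for name in fasta.keys()})
    fasta.close()
    return genome


def write_fasta(genome: ReferenceGenome, path: str | os.PathLike, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def _read_variants_tsv(path, platform: str) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    calls = []
    for row in df.itertuples(index=False):
        calls.append(
            VariantCall(
                contig=str(row.contig),
                pos=int(row.pos),
                ref=str(row.ref),
                alt=str(row.alt),
                ad=int(row.ad),
                dp=int(row.dp),
                platform=platform or str(getattr(row, "platform", "")),
            )
        )
    return calls


def read_variants(path: str | os.PathLike, platform: str = "") -> list[VariantCall]:
    """Extract biallelic SNVs from a VCF (or the TSV dialect) as VariantCalls.

    ad/dp come from the first sample's AD/DP FORMAT fields; the allele
    fraction is always recomputed as ad/dp and never trusted from the file.
    Multi-allelic records, indels, and records lacking both AD and DP are
    skipped and counted (logged at INFO).
    """
    if str(path).endswith(TSV_SUFFIXES):
        return _read_variants_tsv(path, platform)
    calls: list[VariantCall] = []
    skipped = 0
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                skipped += 1
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                skipped += 1
                continue
            if len(rec.samples) == 0:
                skipped += 1
                continue
            sample = rec.samples[0]
            ad_field = sample.get("AD")
            dp_field = sample.get("DP")
            if ad_field is None or ad_field[-1] is None:
                skipped += 1
                continue
            ad = int(ad_field[-1])
            dp = int(dp_field) if dp_field is not None else int(sum(a or 0 for a in ad_field))
            if dp < ad:
                dp = ad
            calls.append(
                VariantCall(rec.contig, rec.pos, ref, alt, ad=ad, dp=dp, platform=platform)
            )
    if skipped:
        log.info("read_variants(%s): skipped %d non-SNV/incomplete records", path, skipped)
    return calls


def write_variants(
    calls: list[VariantCall],
    path: str | os.PathLike,
    annotations: dict[tuple, bool] | None = None,
    contig_lengths: dict[str, int] | None = None,
    sample: str = "SAMPLE1",
) -> None:
    """Write calls as a single-sample VCF that round-trips through read_variants.

    ``annotations`` maps VariantCall.key -> bool; flagged calls carry the
    TG_ARTIFACT INFO flag.
    """
    calls = sorted(calls, key=lambda c: (c.contig, c.pos, c.alt))
    header = pysam.VariantHeader()
    header.add_line(
        f'##INFO=<ID={ARTIFACT_INFO_FLAG},Number=0,Type=Flag,'
        'Description="Classified as two-color-chemistry T>G artifact">'
    )
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    header.add_line('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lengths: dict[str, int] = dict(contig_lengths or {})
    for call in calls:
        lengths[call.contig] = max(lengths.get(call.contig, 0), call.pos + 1)
    for contig, length in lengths.items():
        header.add_line(f"##contig=<ID={contig},length={length}>")
    header.add_sample(sample)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in calls:
            rec = out.new_record(
                contig=call.contig,
                start=call.pos0,
                stop=call.pos,
                alleles=(call.ref, call.alt),
            )
            if annotations and annotations.get(call.key):
                rec.info[ARTIFACT_INFO_FLAG] = True
            rec.samples[sample]["AD"] = (call.dp - call.ad, call.ad)
            rec.samples[sample]["DP"] = call.dp
            out.write(rec)


CIGAR_OPS = "MIDNSHP=X"


def read_alignments(path: str | os.PathLike):
    """Yield a ReadRecord per record of a SAM/BAM file (unmapped included)."""
    mode = "rb" if str(path).endswith(".bam") else "r"
    with pysam.AlignmentFile(str(path), mode, check_sq=False) as af:
        for rec in af:
            if rec.query_qualities is None:
                raise ValueError(f"read {rec.query_name!r} has no quality string")
            yield ReadRecord(
                name=rec.query_name,
                contig=rec.reference_name,
                pos0=rec.reference_start if not rec.is_unmapped else -1,
                bases=rec.query_sequence.upper(),
                quals=list(rec.query_qualities),
                mapq=rec.mapping_quality,
                mapped=not rec.is_unmapped,
                proper_pair=rec.is_proper_pair,
                supplementary=rec.is_supplementary,
                duplicate=rec.is_duplicate,
                cigar=[(CIGAR_OPS[op], ln) for op, ln in (rec.cigartuples or [])],
            )


MISMATCH_COLUMNS = ["contig", "pos", "ref", "alt", "ad", "dp", "platform"]


def write_mismatch_table(sites, path: str | os.PathLike) -> None:
    """Write PileupMismatch/VariantCall-like records as the TSV dialect."""
    rows = [
        {
            "contig": s.contig,
            "pos": s.pos,
            "ref": s.ref,
            "alt": s.alt,
            "ad": s.ad,
            "dp": s.dp,
            "platform": s.platform,
        }
        for s in sites
    ]
    pd.DataFrame(rows, columns=MISMATCH_COLUMNS).to_csv(path, sep="\t", index=False)


def read_mismatch_table(path: str | os.PathLike):
    """Read the TSV dialect back; see :mod:`duochrome.mismatch_profiler`."""
    from .mismatch_profiler import PileupMismatch

    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    return [
        PileupMismatch(
            contig=str(r.contig),
            pos=int(r.pos),
            ref=str(r.ref),
            alt=str(r.alt),
            ad=int(r.ad),
            dp=int(r.dp),
            platform=str(r.platform),
        )
        for r in df.itertuples(index=False)
    ]


__all__ = [
    "ReferenceGenome",
    "VariantCall",
    "ReadRecord",
    "read_fasta",
    "write_fasta",
    "read_variants",
    "write_variants",
    "read_alignments",
    "read_mismatch_table",
    "write_mismatch_table",
    "ARTIFACT_INFO_FLAG",
    "FastaParseError",
]
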