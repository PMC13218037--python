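"""Synthetic paired-platform experiments with planted chemistry artifacts.

The generator emulates the structure the analysis assumes: two datasets from
the same sample, one per "platform", sharing a common set of true somatic
mutations, with the two-color platform additionally carrying a planted layer
of T>G/A>C mismatches. Planted artifacts occur only at N[T>G][TG]-eligible
reference positions (reference T followed by T or G, or the mirrored A
sites), preferentially where the ±5 bp flank is G/C-rich and where the
downstream trinucleotide is TCC, at alternate allele depths 2–10 with a mode
at 2–3. Every generated call carries a hidden ground-truth label so filter
performance can be measured exactly.

All randomness flows from one integer seed through named SeedSequence
substreams (reference, mutations, artifacts, pileups per platform, reads),
so outputs are byte-identical across runs with the same seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .io import (
    ReferenceGenome,
    VariantCall,
    write_fasta,
    write_mismatch_table,
    write_variants,
)
from .mismatch_profiler import PileupMismatch
from .sequence import COMPLEMENT, revcomp

CONTIG = "sim1"
_STREAMS = ("reference", "mutations", "artifacts", "pileups_nova", "pileups_hiseq", "reads")


@dataclass
class ExperimentConfig:
    """Study conditions for one synthetic paired-platform experiment.

    Defaults describe a desk-scale 30X pair: a 200 kb human-like (41% GC)
    reference, 600 true mutations at allele fractions 0.05-0.5, a 1e-3
    per-read background error rate, and an artifact layer hitting ~0.7% of
    eligible sites (~4x the true T>G count) with a strong G/C flank bias and
    a dominant downstream TCC motif.
    """

    genome_length: int = 200_000
    gc_fraction: float = 0.41
    depth_nova: int = 30
    depth_hiseq: int = 30
    n_true_mutations: int = 600
    af_min: float = 0.05
    af_max: float = 0.5
    error_rate: float = 1e-3
    artifact_rate: float = 0.007
    artifact_ad_min: int = 2
    artifact_ad_max: int = 10
    artifact_ad_geom_p: float = 0.4
    flank_gc_weight: float = 30.0
    motif: str = "TCC"
    motif_weight: float = 100.0
    seed: int = 0

    def __post_init__(self):
        for name in ("gc_fraction", "af_min", "af_max", "error_rate", "artifact_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not (0.0 < self.gc_fraction < 1.0):
            raise ValueError("gc_fraction must lie strictly in (0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory")

    def rngs(self) -> dict[str, np.random.Generator]:
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ExperimentConfig":
        return cls(**d)

    def save(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def load(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def simulate_reference(
    length: int, gc_fraction: float, seed: int | np.random.Generator
) -> ReferenceGenome:
    """i.i.d. reference with P(G) + P(C) = gc_fraction, one contig."""
    if length < 1000:
        raise ValueError("length must be >= 1000")
    if not (0.0 < gc_fraction < 1.0):
        raise ValueError("gc_fraction must lie in (0, 1)")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    at, gc = (1.0 - gc_fraction) / 2.0, gc_fraction / 2.0
    draws = rng.choice(np.frombuffer(b"ACGT", dtype="S1"), size=length, p=[at, gc, gc, at])
    return ReferenceGenome({CONTIG: draws.tobytes().decode()})


@dataclass(frozen=True)
class TrueMutation:
    """Platform-independent ground truth: locus, alleles, allele fraction."""

    pos: int  # 1-based
    ref: str
    alt: str
    af: float

    def materialize(self, depth: int, platform: str) -> VariantCall | None:
        ad = int(round(self.af * depth))
        if ad < 1:
            return None
        return VariantCall(
            CONTIG, self.pos, self.ref, self.alt,
            ad=min(ad, depth), dp=depth, platform=platform,
        )


def _draw_true_mutations(
    genome: ReferenceGenome,
    n: int,
    rng: np.random.Generator,
    af_range: tuple[float, float],
    spectrum_weights: dict[str, float] | None = None,
    edge_pad: int = 8,
) -> list[TrueMutation]:
    from .sequence import SBS_CLASSES

    seq = np.frombuffer(genome.contigs[CONTIG].encode(), dtype="S1")
    if n >= len(seq) / 10:
        raise ValueError("n must be below a tenth of the genome length")
    weights = np.array(
        [(spectrum_weights or {}).get(c, 1.0) for c in SBS_CLASSES], dtype=float
    )
    weights /= weights.sum()
    classes = rng.choice(len(SBS_CLASSES), size=n, p=weights)
    interior = np.arange(edge_pad, len(seq) - edge_pad)
    pools = {
        "T": interior[np.isin(seq[interior], [b"T", b"A"])],
        "C": interior[np.isin(seq[interior], [b"C", b"G"])],
    }
    need = {"T": int((classes >= 3).sum()), "C": int((classes < 3).sum())}
    chosen: dict[str, np.ndarray] = {}
    for pyr, count in need.items():
        if count > len(pools[pyr]):
            raise ValueError(
                f"cannot place {count} mutations on {len(pools[pyr])} {pyr}/"
                f"{COMPLEMENT[pyr]} positions without collisions"
            )
        chosen[pyr] = rng.choice(pools[pyr], size=count, replace=False)
    afs = rng.uniform(af_range[0], af_range[1], size=n)
    cursors = {"T": 0, "C": 0}
    out = []
    for cls_idx, af in zip(classes, afs):
        cls = SBS_CLASSES[cls_idx]
        pyr = cls[0]
        pos0 = int(chosen[pyr][cursors[pyr]])
        cursors[pyr] += 1
        ref = seq[pos0].decode()
        alt = cls[2] if ref == pyr else COMPLEMENT[cls[2]]
        out.append(TrueMutation(pos=pos0 + 1, ref=ref, alt=alt, af=float(af)))
    return out


def simulate_true_mutations(
    genome: ReferenceGenome,
    n: int,
    depth: int,
    seed: int | np.random.Generator,
    af_range: tuple[float, float] = (0.05, 0.5),
    spectrum_weights: dict[str, float] | None = None,
    platform: str = "",
) -> list[VariantCall]:
    """Distinct-position SNVs with class frequencies following
    ``spectrum_weights`` (uniform over the six classes by default) and
    ad = round(af * depth)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    muts = _draw_true_mutations(genome, n, rng, af_range, spectrum_weights)
    calls = [m.materialize(depth, platform) for m in muts]
    return [c for c in calls if c is not None]


def eligible_artifact_positions(
    genome: ReferenceGenome, edge_pad: int = 8
) -> np.ndarray:
    """0-based positions eligible for the artifact layer: reference T whose
    3' neighbor is T or G, or reference A whose 5' neighbor is A or C (the
    reverse-complement mirror), away from contig edges."""
    seq = np.frombuffer(genome.contigs[CONTIG].encode(), dtype="S1")
    i = np.arange(edge_pad, len(seq) - edge_pad)
    t_sites = (seq[i] == b"T") & np.isin(seq[i + 1], [b"T", b"G"])
    a_sites = (seq[i] == b"A") & np.isin(seq[i - 1], [b"A", b"C"])
    return i[t_sites | a_sites]


def inject_artifacts(
    genome: ReferenceGenome,
    platform_calls: list[VariantCall],
    config: ExperimentConfig,
    rng: np.random.Generator | None = None,
) -> tuple[list[VariantCall], dict[tuple, str]]:
    """Add the two-color-platform artifact layer to one callset.

    Returns (augmented calls, truth) where truth maps each call key to
    'true' or 'artifact'. Artifact loci are sampled from the eligible
    N[T>G][TG] positions with weight
    ``flank_gc_weight ** (#G/C within ±5) * motif_weight ** [downstream == motif]``
    and alternate depths from a truncated geometric on [ad_min, ad_max].
    """
    rng = rng if rng is not None else config.rngs()["artifacts"]
    seq_str = genome.contigs[CONTIG]
    seq = np.frombuffer(seq_str.encode(), dtype="S1")
    eligible = eligible_artifact_positions(genome)
    taken = {c.pos0 for c in platform_calls}
    eligible = eligible[~np.isin(eligible, np.fromiter(taken, dtype=np.int64, count=len(taken)))] \
        if taken else eligible
    if len(eligible) == 0:
        raise ValueError("no eligible N[T>G][TG] positions for the artifact layer")
    n_art = int(rng.binomial(len(eligible), config.artifact_rate))
    truth = {c.key: "true" for c in platform_calls}
    if n_art == 0:
        return list(platform_calls), truth
    if n_art > len(eligible):
        raise ValueError(f"only {len(eligible)} eligible sites for {n_art} artifacts")

    gc = np.isin(seq, [b"C", b"G"]).astype(np.int64)
    cum = np.concatenate([[0], np.cumsum(gc)])
    flank_gc = (cum[np.minimum(eligible + 6, len(seq))] - cum[np.maximum(eligible - 5, 0)]
                ) - gc[eligible]
    logw = flank_gc * np.log(config.flank_gc_weight)
    k = len(config.motif)
    is_t = seq[eligible] == b"T"
    motif_rc = revcomp(config.motif)
    # downstream (3', pyrimidine frame) motif match, vectorized per offset
    match_t = np.ones(len(eligible), dtype=bool)
    match_a = np.ones(len(eligible), dtype=bool)
    for j in range(k):
        match_t &= seq[eligible + 1 + j] == config.motif[j].encode()
        match_a &= seq[eligible - k + j] == motif_rc[j].encode()
    has_motif = np.where(is_t, match_t, match_a)
    logw = logw + np.where(has_motif, np.log(config.motif_weight), 0.0)
    w = np.exp(logw - logw.max())
    sites = rng.choice(eligible, size=n_art, replace=False, p=w / w.sum())

    ks = np.arange(config.artifact_ad_min, config.artifact_ad_max + 1)
    p = config.artifact_ad_geom_p
    ad_probs = (1 - p) ** (ks - ks[0]) * p
    ad_probs /= ad_probs.sum()
    ads = rng.choice(ks, size=n_art, p=ad_probs)

    augmented = list(platform_calls)
    for pos0, ad in zip(sites, ads):
        ref = seq_str[pos0]
        alt = "G" if ref == "T" else "C"
        call = VariantCall(
            CONTIG, int(pos0) + 1, ref, alt,
            ad=int(min(ad, config.depth_nova)), dp=config.depth_nova,
            platform="nova",
        )
        augmented.append(call)
        truth[call.key] = "artifact"
    return augmented, truth


def simulate_pileups(
    genome: ReferenceGenome,
    calls: list[VariantCall],
    depth: int,
    error_rate: float,
    seed: int | np.random.Generator,
    platform: str = "",
) -> list[PileupMismatch]:
    """Per-site mismatch pileups: every call contributes its ad out of a
    Binomial(2*depth, 1/2)-distributed site depth (mean ``depth``), and
    every other position independently gains error reads at ``error_rate``
    per read, spread uniformly over the three alternate bases."""
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq_str = genome.contigs[CONTIG]
    L = len(seq_str)
    dp_arr = rng.binomial(2 * depth, 0.5, size=L)
    call_pos = {c.pos0 for c in calls}
    sites: list[PileupMismatch] = []
    if error_rate > 0:
        n_err = rng.binomial(dp_arr, error_rate)
        for pos0 in np.nonzero(n_err)[0]:
            pos0 = int(pos0)
            ref = seq_str[pos0]
            if ref == "N" or pos0 in call_pos:
                continue
            alts = [b for b in "ACGT" if b != ref]
            # each error read picks an alternate independently
            split = rng.multinomial(int(n_err[pos0]), [1 / 3] * 3)
            for alt, ad in zip(alts, split):
                if ad >= 1:
                    sites.append(
                        PileupMismatch(
                            CONTIG, pos0 + 1, ref, alt,
                            ad=int(ad), dp=int(max(dp_arr[pos0], ad)),
                            platform=platform,
                        )
                    )
    for c in calls:
        dp = int(max(dp_arr[c.pos0], c.ad))
        sites.append(
            PileupMismatch(CONTIG, c.pos, c.ref, c.alt, ad=c.ad, dp=dp, platform=platform)
        )
    sites.sort(key=lambda s: (s.pos, s.alt))
    return sites


@dataclass
class PlatformData:
    calls: list[VariantCall]
    pileups: list[PileupMismatch]
    truth: dict[tuple, str]  # call key -> 'true' | 'artifact'


@dataclass
class SimulatedExperiment:
    config: ExperimentConfig
    genome: ReferenceGenome
    true_mutations: list[TrueMutation]
    nova: PlatformData
    hiseq: PlatformData


def simulate_paired_experiment(
    config: ExperimentConfig, outdir: str | Path | None = None
) -> SimulatedExperiment:
    """Generate the full paired design: shared true mutations on both
    platforms, the artifact layer on the two-color platform only, and
    per-platform pileups. With ``outdir`` set, writes FASTA, per-platform
    VCFs, pileup TSVs, and truth TSVs (deterministic under the seed)."""
    rngs = config.rngs()
    genome = simulate_reference(config.genome_length, config.gc_fraction, rngs["reference"])
    muts = _draw_true_mutations(
        genome, config.n_true_mutations, rngs["mutations"], (config.af_min, config.af_max)
    )
    nova_true = [c for m in muts if (c := m.materialize(config.depth_nova, "nova"))]
    hiseq_calls = [c for m in muts if (c := m.materialize(config.depth_hiseq, "hiseq"))]
    nova_calls, nova_truth = inject_artifacts(genome, nova_true, config, rngs["artifacts"])
    hiseq_truth = {c.key: "true" for c in hiseq_calls}
    nova = PlatformData(
        calls=nova_calls,
        pileups=simulate_pileups(
            genome, nova_calls, config.depth_nova, config.error_rate,
            rngs["pileups_nova"], platform="nova",
        ),
        truth=nova_truth,
    )
    hiseq = PlatformData(
        calls=hiseq_calls,
        pileups=simulate_pileups(
            genome, hiseq_calls, config.depth_hiseq, config.error_rate,
            rngs["pileups_hiseq"], platform="hiseq",
        ),
        truth=hiseq_truth,
    )
    exp = SimulatedExperiment(
        config=config, genome=genome, true_mutations=muts, nova=nova, hiseq=hiseq
    )
    if outdir is not None:
        _write_experiment(exp, Path(outdir))
    return exp


def _write_experiment(exp: SimulatedExperiment, outdir: Path) -> None:
    import pandas as pd

    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(exp.genome, outdir / "reference.fa")
    lengths = {CONTIG: len(exp.genome.contigs[CONTIG])}
    for name, data in (("nova", exp.nova), ("hiseq", exp.hiseq)):
        write_variants(data.calls, outdir / f"calls_{name}.vcf", contig_lengths=lengths)
        write_mismatch_table(data.pileups, outdir / f"pileups_{name}.tsv")
        pd.DataFrame(
            [
                {"contig": k[0], "pos": k[1], "ref": k[2], "alt": k[3], "label": v}
                for k, v in data.truth.items()
            ]
        ).to_csv(outdir / f"truth_{name}.tsv", sep="\t", index=False)
    exp.config.save(outdir / "config.yaml")


def write_sam_fixture(
    genome: ReferenceGenome,
    path: str | Path,
    coverage: int = 5,
    read_length: int = 101,
    seed: int | np.random.Generator = 0,
    mismatches: list[tuple[int, str, int]] | None = None,
) -> int:
    """Write a clean SAM of forward-strand reads tiling the reference.

    Reads carry proper-pair flags, MAPQ 60, pure-match CIGARs, and qualities
    in the 33-40 range so the whole file passes the read QC stage.
    ``mismatches`` plants (pos0, alt, n_reads) substitutions on reads
    covering the position. Returns the number of reads written.
    """
    import pysam

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seq = genome.contigs[CONTIG]
    if len(seq) < read_length:
        raise ValueError("contig shorter than one read")
    step = max(1, read_length // max(coverage, 1))
    starts = list(range(0, len(seq) - read_length + 1, step))
    reads = []
    for i, start in enumerate(starts):
        bases = list(seq[start : start + read_length])
        reads.append([f"read{i}", start, bases])
    for pos0, alt, n_reads in mismatches or []:
        covering = [r for r in reads if r[1] <= pos0 < r[1] + read_length]
        for r in covering[:n_reads]:
            r[2][pos0 - r[1]] = alt
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": CONTIG, "LN": len(seq)}],
    }
    with pysam.AlignmentFile(str(path), "wh", header=header) as out:
        for name, start, bases in reads:
            a = pysam.AlignedSegment(out.header)
            a.query_name = name
            a.query_sequence = "".join(bases)
            a.reference_id = 0
            a.reference_start = start
            a.mapping_quality = 60
            a.cigarstring = f"{read_length}M"
            a.flag = 0x1 | 0x2 | 0x40  # paired, proper pair, first in pair
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(33 + q) for q in rng.integers(33, 41, size=read_length))
            )
            out.write(a)
    return len(reads)
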