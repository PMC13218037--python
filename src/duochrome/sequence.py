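"""Shared nucleotide-level helpers: complements, strand collapsing, SBS classes.

Single-base substitutions are reported in the pyrimidine frame: a purine
reference allele and its alternate are complemented so that T>G and A>C
(indistinguishable with respect to the strand on which the error occurred)
fall in the same class.
"""

from __future__ import annotations

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

PYRIMIDINES = frozenset("CT")
PURINES = frozenset("AG")
BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

#: the six reverse-complement-collapsed substitution classes
SBS_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")


def complement(base: str) -> str:
    try:
        return COMPLEMENT[base]
    except KeyError:
        raise ValueError(f"not a nucleotide: {base!r}") from None


def revcomp(seq: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def collapse_sbs(ref: str, alt: str) -> str:
    """Map an ordered (ref, alt) SNV pair to its pyrimidine-referenced class.

    Purine-referenced pairs are complemented (A>C becomes T>G); pairs already
    referenced to C or T pass through unchanged.
    """
    if ref not in BASES or alt not in BASES:
        raise ValueError(f"ref/alt must be one of A,C,G,T: got {ref!r}>{alt!r}")
    if ref == alt:
        raise ValueError(f"ref and alt are identical: {ref!r}")
    if ref in PURINES:
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
    return f"{ref}>{alt}"


def is_pyrimidine(base: str) -> bool:
    return base in PYRIMIDINES
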