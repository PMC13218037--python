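# Methods

This note documents the statistical machinery, the synthetic study
conditions, and the design choices made where the design was genuinely open.
Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The artifact and the analysis model

Two-color sequencing chemistry encodes G as the absence of signal, so signal
loss during imaging reads as G. The downstream symptom is an excess of
T>G/A>C mismatches ("T>G" after collapsing reverse complements) specific to
the two-color platform, concentrated at low alternate allele depths (AD
2–10), at N[T>G][TG] trinucleotides, with G/C-enriched flanking sequence and
a characteristic downstream TCC motif. The package's analysis model is a
paired design: two datasets of the same sample, one per platform, in which
any systematic mismatch difference surviving stringent QC is attributed to
chemistry.

## Read QC

Trimming parameters (tail 5 bp; head 8 bp for 101-bp reads or 12 bp for
151/250-bp reads; 10-bp windows cut at mean Phred < 25; minimum retained
length 65 or 100 bp) and alignment filters (duplicates, non-proper pairs,
supplementary alignments, MAPQ < 60, any indel/clipping CIGAR operation) are
fixed constants of the protocol, deliberately far stricter than
pre-variant-calling QC. Numerical choices:

- *Sliding window*: step 1, windows fully inside the read, no partial
  trailing window; the cut is at the leftmost base of the first failing
  window. "Average quality" is the arithmetic mean of Phred scores, not the
  mean error probability.
- *Minimum length* is inclusive (≥).
- Filter order (duplicate, proper-pair, supplementary, MAPQ, CIGAR) is fixed
  only so discard-reason codes are reproducible; the kept set is
  order-invariant.
- Head/tail trims commute; quality windows are scanned on the fixed-trimmed
  read.

## Mismatch profiling

A mismatch *site* is a (position, alternate allele) pair, so one position
can contribute up to three sites; each carries its supporting read count
(AD) and total kept-read depth (DP). Sites are tallied into a 6-class ×
AD matrix; ADs above the cap (default 25) accumulate in the top bin so
totals are conserved. Platform-specific sites require the other platform to
cover the position (`min_other_depth`, default 1 read) — absence is
meaningless without coverage. Coverage downsampling thins supporting and
non-supporting reads independently and binomially with p =
target/source, dropping sites whose thinned AD reaches 0. Positions with
reference N are excluded throughout, as all context definitions are
undefined over N.

## Enrichment testing

Per AD stratum, the pooled two-proportion z-statistic (no continuity
correction, matching the plain pooled form) with a two-sided standard-normal
p-value. Degenerate strata (pooled proportion 0 or 1) are reported as z = 0,
p = 1. The multiple-testing family is the set of testable AD strata of one
platform-pair comparison; q-values are Benjamini–Hochberg by default, with
Storey's single-λ estimator (λ = 0.5) as a config option. The AD = 1 row is
computed but flagged *disregarded* and excluded from the family: single-read
mismatches are dominated by ordinary sequencing/alignment error and are
never called as variants. Strata empty on either platform are *untestable*.

## Sequence context

All context operations work in the pyrimidine frame: for purine-referenced
calls the local sequence is reverse-complemented before classification, so
T>G and A>C events co-accumulate; a per-strand "as-read" orientation is
available where the strand-resolved view matters. The 96-channel spectrum
follows the class-major COSMIC-style ordering. Base composition uses ±5 bp
windows (read as "10-base windows"), Wilson 95% intervals (stable at small
n), and a genome-wide background computed over the full reference excluding
N. k-mer ranking breaks count ties lexicographically for determinism.

## PWM likelihood-ratio filter

Per collapsed class and platform, a PWM is built from the 8-base windows
around training calls: 4 bases per side, *excluding* the variant base — the
variant base is constant within a class and carries no information — with
Laplace pseudocount 1 guaranteeing finite log-ratios. A call's window w is
scored by the natural-log likelihood ratio of the two-color over the
four-color PWM. Because the PWM factorizes over positions, the distribution
of this score for windows drawn from the four-color PWM is computed
*exactly* by convolving eight 4-outcome distributions (≤ 4^8 atoms, merged
at 1e-12); the p-value is the tie-inclusive upper tail, and calls with
p < α (default 0.05) are flagged. The filter is applied to all six classes
by default — the artifact dominates T>G but the procedure is generic — and
restricting `classes` gives a conservative variant. Unextractable windows
(contig edge, N) pass through unflagged with an `unevaluated` status.

**Known limitation — finite-training calibration.** The null is exact for
windows drawn from the four-color PWM, but both PWMs are estimates. Two
consequences, both measured in the test suite: (1) scoring the two-color
*training* callset itself (the default workflow, which mirrors correcting
the same callset the PWM came from) is anticonservative at small training
sizes, because the numerator PWM overfits its own windows; (2) even for
held-out background calls the flagged fraction sits somewhat above α at
small n (≈12% at ~40 windows/class, ≈6.7% at ~650/class in the suite's
measurements) and converges to α as training callsets grow. With
genome-scale training callsets this bias is negligible; with hundreds of
windows, expect the true-call flag rate to exceed α modestly. Training and
test callsets may coincide; passing a held-out set to `correct_callset` is
the recommended variant when calibration matters.

## Synthetic study conditions

Defaults of `ExperimentConfig` define the study conditions used throughout
the tests and the acceptance script:

| parameter | default | rationale |
|---|---|---|
| genome_length | 200 kb | desk-scale; large enough for ~60 k eligible artifact sites |
| gc_fraction | 0.41 | human-like background |
| depth (both platforms) | 30X | standard WGS depth in the artifact-relevant range |
| n_true_mutations | 600 | ~100 per class; uniform class spectrum |
| true AF | U(0.05, 0.5) | broad low-VAF mosaic range; AD ≥ 2 at 30X |
| error_rate | 1e-3 | post-QC per-read background error |
| artifact_rate | 0.007 | ~400 artifacts ≈ 4× the true T>G count |
| artifact AD | truncated geometric, 2–10, p = 0.4 | mode at AD 2–3 |
| flank_gc_weight | 30 per G/C in ±5 | see below |
| motif / motif_weight | TCC / 100 | dominant downstream motif |

Pileup depth per site is Binomial(2·depth, ½) (mean = depth, clipped to
≥ AD at call sites); background errors hit each read independently at
`error_rate`, spread uniformly over the three alternates, giving mostly
AD = 1 sites. All randomness flows from one seed through named
`SeedSequence` substreams (reference, mutations, artifacts, per-platform
pileups, reads), making outputs byte-identical per seed.

**What the generator deliberately exaggerates.** The planted artifact's
sequence bias (near-saturating flank G/C enrichment and a heavily weighted
TCC motif) is much stronger than the modest composition shift seen in real
two-color data. This compression is intentional: the PWM filter's
separability scales with training-set size, and real analyses train on
genome-scale callsets (10⁴–10⁵ windows) while the desk-scale conditions
provide only ~400 artifact windows. The planted effect size was calibrated
once against the generator's own recovery harness (≥90% artifact removal
with ≥90% true-call retention across seeds) and then frozen. Passing tests
therefore demonstrate correctness of the machinery and recoverability of a
strong planted signal — not that real-data artifacts of arbitrary subtlety
are removable at these training sizes.

**What the generator does not emulate:** fragment-length structure, PCR
duplicates, mapping ambiguity, strand orientation of reads (SAM fixtures
are forward-strand), diploid genotypes, and inter-sample variability in
artifact severity.

## Problem sizes

The test suite and acceptance script run everything at the desk-scale
conditions above: 100 replicates for the FDR-calibration and power checks,
20 replicates for filter recovery, 2×10⁵–10⁶ draws for Monte-Carlo
cross-checks of exact computations. These sizes were chosen so the whole
analysis re-runs from scratch in minutes on a single CPU while keeping
binomial standard errors well inside the asserted tolerances.
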