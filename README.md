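# duochrome

QC and correction tooling for the **two-color-chemistry T>G/A>C sequencing
artifact**. Illumina's NovaSeq-generation instruments encode bases with two
dyes (T green, C red, A both, G neither), so a loss of signal is
indistinguishable from a G call. The practical consequence is a recurrent
excess of low-allele-depth T>G (and, on the opposite strand, A>C) mismatches
that is absent from four-color (HiSeq-generation) data of the same sample.
At germline allele fractions the artifact is negligible, but in mosaic /
low-VAF somatic studies — variants supported by a handful of reads, called
without a matched normal — it lands exactly where real mutations live.

`duochrome` is aimed at analysts of such low-VAF callsets. It implements:

- **Stringent read QC** — fixed head (8 bp for 101-bp reads, 12 bp for
  151/250-bp reads) and 5 bp tail trimming, a 10-bp sliding-window cut at
  mean Phred < 25, a minimum retained length (65 / 100 bp), and alignment
  filters (proper pairs only, no supplementary or duplicate alignments,
  MAPQ ≥ 60, pure-match CIGARs) — isolating chemistry effects from ordinary
  noise.
- **AD-stratified mismatch profiling** — per-site pileup mismatches
  collapsed into the six pyrimidine-referenced SBS classes and binned by
  alternate allele depth (AD 1–25), platform-specific site calling, and
  binomial coverage downsampling.
- **Per-AD enrichment testing** — for each AD stratum, with x T>G sites of
  n total mismatch sites per platform, the pooled two-proportion statistic

  ```
  z = (p1 − p2) / sqrt( p̂(1−p̂) (1/n1 + 1/n2) ),   p̂ = (x1+x2)/(n1+n2)
  ```

  with two-sided normal p-values and Benjamini–Hochberg q-values (q < 0.05).
- **Sequence-context analysis** — COSMIC-style 96-channel trinucleotide
  spectra, the 16-context N[T>G]N view, flanking base composition with
  Wilson CIs against the genome background, and ranked flanking k-mers.
- **PWM likelihood-ratio filtering** — per class, 8-base windows (±4,
  variant base excluded, pyrimidine frame) around training calls from each
  platform give two position weight matrices; a call with window w is scored
  by `LLR(w) = log P_PWM2c(w) − log P_PWM4c(w)` and tested against the
  *exact* distribution of LLR under the four-color PWM (a convolution of
  eight 4-outcome distributions); calls with p < 0.05 in the two-color-
  favoring tail are flagged as artifacts and removed.
- **A synthetic paired-platform generator** — same-sample callsets on two
  platforms sharing true mutations, with a planted two-color artifact layer
  at N[T>G][TG] sites (AD 2–10, G/C-rich ±5 flanks, downstream TCC motif)
  and hidden ground-truth labels, so the whole pipeline is testable without
  any external data.

## Worked example

```python
from duochrome.synthetic_data import ExperimentConfig, simulate_paired_experiment
from duochrome.mismatch_profiler import ad_spectrum, tg_fraction
from duochrome.enrichment_stats import per_ad_enrichment
from duochrome.pwm_filter import correct_callset

exp = simulate_paired_experiment(ExperimentConfig(seed=1))
nova, hiseq = ad_spectrum(exp.nova.pileups), ad_spectrum(exp.hiseq.pileups)
print(tg_fraction(nova, 3), tg_fraction(hiseq, 3))
table = per_ad_enrichment(nova, hiseq)
print(sorted(table.index[table.significant]))
result = correct_callset(exp.nova.calls, exp.genome, exp.nova.calls, exp.hiseq.calls)
print(result.summary.loc["T>G"])
```

At seed 1 this prints a T>G fraction of mismatch sites at AD = 3 of **0.75**
on the two-color platform versus **0.20** on the four-color platform,
significant enrichment at ADs **[2, 3, 4, 5, 6, 7, 8]** and nowhere above
AD 10, and a T>G correction row of 524 calls before → 112 after (4.68-fold
reduction). Scored against the generator's hidden labels, the filter removes
**95.3%** of the planted artifacts while retaining **98.7%** of true calls,
leaving the corrected T>G count within **1.12×** of the artifact-free
platform. The `examples/` directory walks through each stage
(`python examples/01_simulate_paired_experiment.py`, …) with a narrative
line per number.

A thin CLI mirrors the library:

```
duochrome-qc simulate --out sim/              # synthetic experiment on disk
duochrome-qc enrich --nova sim/pileups_nova.tsv --hiseq sim/pileups_hiseq.tsv --out enrich.tsv
duochrome-qc run-all --seed 1 --out report/   # everything, plus a manifest
```

## Layout

- `src/duochrome/` — `io`, `read_qc`, `mismatch_profiler`,
  `enrichment_stats`, `context_spectra`, `pwm_filter`, `synthetic_data`,
  `cli`
- `docs/methods.md` — models, assumptions, parameter choices, limitations
- `examples/` — one narrative script per capability
- `tests/` — unit, property, and end-to-end acceptance tests
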