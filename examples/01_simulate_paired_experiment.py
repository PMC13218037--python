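"""Generate a synthetic paired-platform experiment and inspect its layers.

One sample is "sequenced" twice: a four-color platform carrying only true
mutations plus background error, and a two-color platform that additionally
gains planted T>G/A>C artifact calls at N[T>G][TG] contexts.
"""

from duochrome.synthetic_data import ExperimentConfig, simulate_paired_experiment

config = ExperimentConfig(seed=1)
exp = simulate_paired_experiment(config)

n_art = sum(1 for v in exp.nova.truth.values() if v == "artifact")
print(f"genome: {config.genome_length:,} bp at GC {config.gc_fraction}")
print(f"shared true mutations: {len(exp.true_mutations)}")
print(f"two-color callset:  {len(exp.nova.calls)} calls "
      f"({n_art} planted artifacts, {len(exp.nova.calls) - n_art} true)")
print(f"four-color callset: {len(exp.hiseq.calls)} calls (all true)")
print(f"pileup mismatch sites: {len(exp.nova.pileups)} vs {len(exp.hiseq.pileups)}")
print()
print("The two-color platform carries the same biology plus an artifact "
      "layer at low allele depths; everything downstream tries to find and "
      "remove exactly that layer.")
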