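"""AD-stratified T>G enrichment: the pooled two-proportion z-test per
allele-depth stratum with Benjamini-Hochberg FDR control.

The signature of the two-color artifact is an excess of T>G mismatch sites
at low allele depths (2-5) on one platform only.
"""

from duochrome.enrichment_stats import per_ad_enrichment
from duochrome.mismatch_profiler import ad_spectrum, tg_fraction
from duochrome.synthetic_data import ExperimentConfig, simulate_paired_experiment

exp = simulate_paired_experiment(ExperimentConfig(seed=1))
nova = ad_spectrum(exp.nova.pileups, platform="nova")
hiseq = ad_spectrum(exp.hiseq.pileups, platform="hiseq")

print(f"T>G fraction of mismatch sites at AD=3: "
      f"{tg_fraction(nova, 3):.2f} (two-color) vs {tg_fraction(hiseq, 3):.2f} (four-color)")

table = per_ad_enrichment(nova, hiseq)
cols = ["x_nova", "n_nova", "x_hiseq", "n_hiseq", "z", "q_value", "significant"]
print(table.loc[1:12, cols].to_string(float_format=lambda v: f"{v:.3g}"))
sig = sorted(table.index[table.significant])
print(f"\nsignificant ADs (q < 0.05): {sig}")
print("The AD=1 row is always disregarded: single-read mismatches are "
      "dominated by ordinary sequencing error. Enrichment confined to low "
      "ADs is the artifact's fingerprint.")
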