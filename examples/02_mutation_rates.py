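"""Per-sample mutation rates in TFBSs, exons and flanking regions.

Computes the rate (mutated nucleotides / region length) per sample in
TFBSs, exons and their 100/500/1000-nt flanks, the expectation under 150
chromosome-preserving shuffles, and the paired Wilcoxon comparison of
TFBS vs exon rates across samples.
"""

from cisnet.pipeline import load_cohort, rates_report
from cisnet.simulate import SimulationConfig, write_cohort

cohort = write_cohort("scratch/example_cohort", SimulationConfig(seed=7))
data = load_cohort(cohort)
table, tests = rates_report(data, n_shuffles=150, seed=7)

cols = ["rate_tfbs", "rate_exons", "expected_rate_tfbs"]
print(table[["sample", "n_mutations"] + cols].head(8).to_string(index=False))
print(f"\ncohort mean TFBS rate:     {table['rate_tfbs'].mean():.2e}")
print(f"cohort mean exon rate:     {table['rate_exons'].mean():.2e}")
print(f"shuffle-expected TFBS rate:{table['expected_rate_tfbs'].mean():.2e}")
print(f"paired Wilcoxon TFBS vs exons: p = {tests['wilcoxon_tfbs_vs_exons_p']:.3g}")
# A TFBS rate above the shuffle expectation means mutations concentrate
# in binding sites beyond what random placement on the same chromosomes
# would give -- here driven by the planted cis-regulatory mutations.
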