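"""Simulate a synthetic cancer cohort with planted cis-regulatory drivers.

Builds a small genome with TFBS/exon/TSS annotations, a weighted gene
network, somatic mutations, RNA-seq counts, CNA and survival, then prints
the planted ground truth.  Every file the analysis pipeline reads is
written to ./scratch/example_cohort.
"""

from cisnet.simulate import SimulationConfig, read_truth, write_cohort

cfg = SimulationConfig(seed=7)
outdir = write_cohort("scratch/example_cohort", cfg)
truth = read_truth(outdir / "truth.tsv")

print(f"cohort written to {outdir}")
print(f"planted drivers: {', '.join(truth.drivers)}")
for d in truth.drivers:
    dirs = truth.affected_partners[d]
    n_up = sum(1 for v in dirs.values() if v == 1)
    print(
        f"  {d}: mutated in {len(truth.driver_samples[d])} samples, "
        f"{len(dirs)} affected partners ({n_up} up, {len(dirs) - n_up} down)"
    )
# Each driver carries TFBS mutations in its listed samples; its own
# expression shifts in cis and the listed partners shift in trans by
# effect_size (2 sd by default) -- the signal the pipeline must find.
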