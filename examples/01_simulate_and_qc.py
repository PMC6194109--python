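"""Simulate a Y-STR cohort and apply the biallelic QC filter.

Generates a 407-male cohort under the stepwise mutation model with four
engineered two-peak (biallelic) artifact samples, then removes them the
way a forensic lab would before reporting haplotype statistics.
"""

from ystrkit import SimConfig, qc_filter_biallelic, reduce_for_rst, simulate_cohort

cfg = SimConfig(seed=42, n_samples=407, biallelic_artifact_count=4)
cohort, truth = simulate_cohort(cfg)
kept, discarded = qc_filter_biallelic(cohort)
reduced = reduce_for_rst(kept)

print(f"simulated samples:        {len(cohort)}")
print(f"discarded (biallelic):    {len(discarded)}  -> {discarded}")
print(f"retained after QC:        {len(kept)}")
print(f"after DYS385a/b + microvariant reduction: {len(reduced)} samples, "
      f"{len(reduced.panel)} loci")
# The retained count is what every downstream statistic is computed on; the
# reduced cohort (integer repeats only) feeds the R_ST / network analyses.
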