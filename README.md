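# ystrkit

Population-genetic and forensic analysis of Y-chromosomal STR haplotypes,
built around the 23-locus PowerPlex Y23 panel (21 single-copy loci plus the
duplicated DYS385a/b, reported as an unordered allele pair; microvariant
alleles such as `13.2` are first-class). The package is aimed at forensic
and population geneticists who need the standard Y-STR statistics as a
tested, scriptable library rather than a chain of GUI tools, and it ships
a stepwise-mutation-model simulator so every analysis can be exercised and
validated end to end on synthetic cohorts of known truth.

## What it computes

**Diversity / forensic statistics** — from counting-method frequency
spectra, with *n* samples, allele frequencies *pᵢ* and haplotype
frequencies *hᵢ*:

- genetic diversity per locus: GD = n/(n−1) · (1 − Σᵢ pᵢ²)
- haplotype diversity: HD = n/(n−1) · (1 − Σᵢ hᵢ²)
- discrimination capacity: DC = (number of distinct haplotypes) / n
- combined match probability: CMP = Σᵢ hᵢ², so HD ≡ n/(n−1)·(1 − CMP)

**Population structure** — R_ST-style AMOVA with the Slatkin sum of
squared repeat-count differences as the molecular distance: one-level and
hierarchical (region-grouped) variance components, Φ_ST / Φ_SC / Φ_CT with
permutation p-values, pairwise population Φ_ST matrices, Nei (1972)
standard genetic distance, and a SAMOVA-style search for the population
grouping maximizing Φ_CT (exhaustive for small problems, simulated
annealing otherwise).

**Ordination & geography** — classical PCoA, Sammon-stress MDS (PCoA
initialization, monotone step-halving descent), great-circle distances and
the Mantel permutation test of geography against genetic distance (exact
enumeration when the label count permits).

**Haplogroup prediction** — a naive-Bayes classifier on per-haplogroup STR
allele frequencies with the conventional assignment contract: fitness
score ≥ 40 and posterior ≥ 95 %, otherwise UNASSIGNED.

**Haplotype networks** — minimum spanning networks (all tied MST edges
retained) on full-panel haplotypes, and median-joining networks on the
reduced integer panel with locus weights binned from repeat variance
([0,0.2)→10 … ≥0.8→2).

**Simulator** — star-genealogy single-step SMM cohorts: configurable
haplogroup mix (default 51.5 % R1a / 16.2 % H / 15.8 % L plus minor
lineages), 12 populations in 4 geographic regions, rare microvariants, an
exact number of engineered biallelic artifacts, and a two-population
divergence mode for structure-recovery experiments.

## Worked example

```python
from ystrkit import (SimConfig, simulate_cohort, qc_filter_biallelic,
                     forensic_summary)

cohort, truth = simulate_cohort(SimConfig(seed=42, n_samples=407,
                                          biallelic_artifact_count=4))
kept, discarded = qc_filter_biallelic(cohort)
print(len(kept), len(discarded))     # 403 4
fs = forensic_summary(kept)
print(f"{fs.hd:.10f} {fs.dc:.11f} {fs.cmp:.10f}")
# 0.9976790983 0.93300248139 0.0047965322
```

403 of 407 simulated males survive the two-peak QC filter; the haplotype
diversity near 1 and the combined match probability near 1/n say that two
unrelated males almost never share a 23-locus haplotype, and DC is the
fraction of men carrying a profile seen only once. The `examples/`
directory holds one short script per capability (simulation & QC, forensic
statistics, AMOVA/R_ST/SAMOVA, ordination & Mantel, haplogroup calls,
networks, and the one-command pipeline); each prints the numbers it
computes with a line on what they mean. A thin CLI wraps the pipeline:

```bash
ystrkit simulate --seed 42 -n 407 -o cohort.csv
ystrkit stats cohort.csv
ystrkit run --config pipeline.yaml -o outdir/
```

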