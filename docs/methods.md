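# Methods

## Data model

A cohort is a panel of STR loci plus one record per genotyped male. Alleles
are exact integer pairs (full repeats, partial repeat bases): `13.2` is
`(13, 2)`, never the float 13.2, so haplotype identity, collapsing and CSV
round-trips are exact. DYS385a/b is a single duplicated locus stored as a
canonically ascending unordered pair; it participates in haplotype identity
and allele-identity statistics (both pair members are counted) but never in
repeat-difference distances, where subtracting alleles of a duplicated,
unphaseable locus is not well defined.

Two filters define the analysis subsets:

- **QC filter**: any sample showing more than one allele at a single-copy
  locus (a two-peak artifact) is removed; the DYS385a/b pair never triggers
  removal. Idempotent; retained + discarded always equals the input size.
- **Reduction for repeat-difference analyses**: the DYS385a/b column is
  dropped first, then samples carrying microvariant alleles at the
  *retained* loci are removed (a partial repeat has no integer step
  distance). A microvariant confined to the dropped DYS385a/b column does
  not cost the sample, since it cannot affect any distance computed
  afterwards.

Forensic statistics (GD, HD, DC, CMP) use the full 23-locus haplotype,
microvariants and DYS385a/b included; R_ST, SAMOVA and median-joining
networks use the reduced integer panel. Values are kept at full precision
and rounded only for display.

### A note on HD/CMP bookkeeping

HD and CMP computed on the same haplotype spectrum are algebraically
locked: HD = n/(n−1)·(1 − CMP), with CMP = Σ(cᵢ/n)² over multiplicities
cᵢ. Published reports sometimes pair an HD with a CMP that cannot both
arise from one spectrum under these formulas (e.g. a CMP computed with the
number of *distinct* haplotypes as denominator). This package computes
both statistics from one spectrum with the printed formulas and asserts
the identity to 1e−12 in its test suite; it makes no attempt to emulate
alternative denominators.

## AMOVA and R_ST

The molecular distance between two reduced haplotypes is the Slatkin-style
sum over loci of squared repeat differences, making the AMOVA Φ statistics
R_ST analogues. Sums of squares come from pairwise distances (SS of a
group = sum of intra-group pairwise distances divided by group size); mean
squares are equated to their expectations with the usual unequal-size
coefficients, in both the one-level (populations within total) and the
three-level (groups / populations in groups / individuals) layouts.

Numerical choices:

- Negative variance-component estimates are **kept** internally (they are
  informative about estimator behavior near the null and required for the
  brute-force oracle equality tested at 1e−9); a display helper clamps at
  zero. A consequence worth knowing: two populations with identical
  haplotype multisets give Φ_ST slightly *below* zero at finite n, because
  the observed among-population sum of squares is exactly zero while its
  expectation under the null is positive.
- Permutation tests (p = (1 + #{Φ* ≥ Φ}) / (1 + B)): individuals among
  populations for Φ_ST; whole populations among groups for Φ_CT;
  individuals among populations within their group for Φ_SC. Seeds are
  mandatory whenever permutations are requested; defaults use 200–1000
  permutations depending on context.
- Φ = 0 is reported when total variance is exactly zero (all haplotypes
  identical) instead of 0/0.

Pairwise population Φ_ST is literally the two-population AMOVA restricted
to each pair, so the matrix agrees with the full routine exactly.

**Nei (1972) standard distance** D = −ln I, with the identity I built from
homozygosity/shared-allele sums averaged over loci. Being allele-identity
based it uses the full panel, DYS385a/b contributing both pair members. A
pair of populations with (near-)zero shared identity would give an
infinite distance; the distance is capped at ln 10³ ≈ 6.9 with a warning,
which keeps toy datasets with disjoint allele sets usable.

**SAMOVA-style search**: the grouping of populations into k groups
maximizing Φ_CT. When the number of k-block set partitions is ≤ 10⁴ the
search is exhaustive (and therefore exact); otherwise simulated annealing
with geometric cooling (rate 0.95, 100 moves per temperature, restart
best-of-N), deterministic given the seed. The group count k is an explicit
argument rather than being fixed to the number of geographic regions.

## Ordination and geography

**PCoA**: double-centered squared-distance Gram matrix, `eigh`
eigendecomposition. Explained percentages are shares of the *positive*
eigenvalues only; negative eigenvalues (non-Euclidean input) are excluded
from the denominator, with a warning when |λ_min| exceeds 5 % of λ_max.
Requesting more axes than there are positive eigenvalues is an error.

**Sammon MDS** minimizes stress E = (Σδ)⁻¹ Σ (δᵢⱼ−dᵢⱼ)²/δᵢⱼ by gradient
descent with a step-halving line search (initial step scale 0.3), started
from the PCoA configuration. Step halving makes the recorded stress
sequence monotone non-increasing by construction, and the PCoA start makes
the procedure deterministic; random restarts (seeded) are available but
off by default. Zero off-diagonal input distances are rejected — collapse
duplicates first — because the stress weights divide by δᵢⱼ.

**Mantel test**: Pearson correlation over off-diagonal upper-triangle
entries; the permutation p-value relabels one matrix. When n! does not
exceed the requested permutation count the enumeration is exhaustive and
the p-value exact (identity included in the reference set); otherwise
seeded random permutations with the add-one estimator. The squared
correlation is reported alongside r for the regression framing of
geography against genetic distance — the two framings share the
correlation, so no separate regression machinery is maintained. Geographic
distances are great-circle (haversine, Earth radius 6371 km) between
population sampling coordinates.

## Haplogroup prediction

Naive Bayes over per-haplogroup, per-locus allele frequency tables:
likelihood(g) = Π_l f_{g,l}(a_l), posteriors from (default equal) priors.
The reported fitness score is the per-locus-normalized geometric mean,
score = 100·(Π_l f_{g,l}(a_l)/max_a f_{g,l}(a))^{1/L}: it is 100 exactly
when every allele is modal for the called haplogroup and collapses toward
0 as alleles leave the haplogroup's observed support. A sample is assigned
only when score ≥ 40 **and** posterior ≥ 95 %; otherwise UNASSIGNED. These
thresholds reproduce the conventional STR-predictor assignment contract;
the score's operational definition is this package's own, and the shipped
frequency model is a synthetic fixture estimated from simulated labeled
cohorts — no claim is made to reproduce any published predictor's internal
tables.

Smoothing: additive pseudocount (default 10⁻³) over each locus's observed
support, so each stored distribution sums to 1; alleles outside the
support fall back to the raw pseudocount. DYS385a/b is modeled as an
unordered pair with pair-frequency tables; an unseen pair falls back to
the product of single-allele marginals (×2 for heterozygous pairs). At
least 15 loci must overlap between haplotype and model.

## Networks

Distances: full-panel MSN uses absolute differences of allele numeric
values (microvariants contribute fractional steps; the DYS385a/b pair is
scored as the minimum over the two pairings of summed absolute
differences). MJ networks use locus-weighted absolute integer repeat
differences on the reduced panel.

**Weights** are integers binned from per-locus repeat variance (sample
variance, ddof = 1): [0,0.2)→10, [0.2,0.4)→8, [0.4,0.6)→6, [0.6,0.8)→4,
≥0.8→2. The bins are half-open on the left as a deterministic tie rule
(0.2 → 8, 0.8 → 2). The variance scope is an argument: by default weights
are computed on the whole dataset even when a network is drawn for one
haplogroup's carriers, matching the common convention; a subset scope is
one keyword away.

**MSN**: identical haplotypes collapse into one node carrying multiplicity
and a per-population breakdown; an edge of length w is retained iff its
endpoints are not connected by strictly shorter links — exactly the union
of all minimum spanning trees, so tied alternatives survive.

**MJ**: iterate (1) ε-relaxed MSN over the current node set (ε = 0
default); (2) propose per-locus consensus vectors (majority value, else
the middle value — for ordered repeat counts the middle value minimizes
the weighted three-way distance) of connected node triples, in
deterministic lexicographic order; (3) accept a candidate only if it
strictly shortens the node set's minimum spanning length; (4) prune median
nodes whose removal no longer lengthens it; repeat to a fixpoint. Median
generation is capped (default 500) and the input is guarded at 200
distinct haplotypes; observed haplotypes are never removed. The
accept-only-if-shorter rule guarantees the invariant that median addition
never lengthens the minimum spanning length, and on three-haplotype star
cases the result matches exhaustive Steiner-point enumeration.

## Simulator

Star genealogy: every sample is an independent lineage from its
haplogroup's founder, with branch length (generations) drawn
exponential(mean). Each locus accumulates Poisson(depth × rate) mutations
of ±1 repeat (single-step symmetric SMM, no multi-step events). Defaults,
chosen once as the package's study conditions:

| parameter | default | rationale |
|---|---|---|
| n_samples | 407 | cohort scale of a multi-state sampling campaign |
| haplogroup mix | R1a .515, H .162, L .158, Q .05, J2b .04, J2a1 .03, J1 .02, G2a .015, R1b .01 | dominant South-Asian paternal lineages with a minor-lineage tail |
| genealogy_depth_mean | 300 generations | haplogroup founder ages of several thousand years |
| mutation rates | 2×10⁻³/locus/generation; DYS570, DYS576 at 10⁻² | typical Y-STR rates; those two are the panel's rapidly mutating loci |
| microvariant_rate | 0.02 per sample | microvariants are rare and concentrated at prone loci (DYS458, DYS385a/b) |
| biallelic_artifact_count | 4 (exact) | controllable QC-filter fixture |
| populations | 12 state-level locations in 4 regions, equal weights | multi-region sampling design |

Founder haplotypes are generated once from an internal fixed seed (offsets
of ±3 repeats around panel-typical modal alleles, redrawn until pairwise
distinct), so they are a stable fixture independent of the cohort seed.
Population labels are assigned independently of haplogroup, so the default
cohort is deliberately panmictic-like — within-population variance ≈ 100 %,
pairwise R_ST ≈ 0, no geography signal. Structure experiments use the
two-population mode: both populations inherit one founder, drift
independently for a configurable number of generations (a shared
population branch), then individuals branch off privately; expected Φ_ST
rises with divergence time, which the tests verify as a monotone median
over replicates.

What the simulator does **not** emulate — and hence what passing tests do
not show about real data: coalescent-correlated genealogies within
populations (star branches only), multi-step mutations, locus-specific
allele ranges and stutter, haplogroup–geography clines, related
individuals, and genotyping error beyond the injected two-peak artifacts.
Recovery results (e.g. classifier accuracy ≥ 90 % at shallow depth) are
statements about this generative model, not about any real predictor or
population.

## Problem sizes used in the shipped checks

The test suite and acceptance script run at desk scale by design: identity
suites use 100 cohorts of n = 30; AMOVA oracle equivalence uses 50 random
cohorts of ≤ 12 samples plus nulls at 50 per population; divergence
recovery uses 20 replicates at each of 0/50/200/1000 generations with
n = 50; classifier recovery trains on n = 3000 and tests on n = 1000–2000;
the engineered QC fixture is the full 407-sample configuration. These
sizes make every check exact or tight while keeping the whole suite under
a minute of compute for the statistical core.

## Known limitations

- AMOVA p-values use the add-one permutation estimator and are therefore
  bounded below by 1/(B+1).
- The SAMOVA annealer is a heuristic outside the exhaustive regime; only
  the exhaustive branch is guaranteed optimal.
- Nei distance capping introduces an arbitrary (documented) ceiling for
  disjoint allele sets; comparisons among capped values are not
  meaningful.
- The MJ implementation targets the small, per-lineage networks used in
  practice (≤ 200 distinct haplotypes); it is not optimized for
  genome-scale inputs.
- Missing data are rejected at parse time rather than modeled.
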