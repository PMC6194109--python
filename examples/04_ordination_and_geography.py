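"""Nei distance, PCoA, Sammon MDS and the geography-genetics Mantel test.

Populations are embedded in 2-D from their Nei (1972) genetic distances;
the Mantel test then asks whether genetic distance tracks great-circle
geographic distance (isolation by distance).
"""

from ystrkit import (
    SimConfig, geographic_distance_matrix, mantel_test, nei_distance, pcoa,
    pairwise_rst, qc_filter_biallelic, reduce_for_rst, sammon_mds, simulate_cohort,
)
from ystrkit.structure import clamp_negative

cohort, _ = simulate_cohort(SimConfig(seed=7, n_samples=300, biallelic_artifact_count=0))
kept, _ = qc_filter_biallelic(cohort)
reduced = reduce_for_rst(kept)

nei = nei_distance(kept)
pc = pcoa(nei, k=2)
print("PCoA of Nei distances: coordinate 1 explains "
      f"{pc.explained[0]:.1f}%, coordinate 2 {pc.explained[1]:.1f}%")

mds = sammon_mds(nei, k=2)
print(f"Sammon MDS stress = {mds.stress:.4g} after {mds.iterations} iterations")

rst, _ = pairwise_rst(reduced)
locations = {}
for s in reduced.samples:
    locations.setdefault(s.population, (s.lat, s.lon))
geo = geographic_distance_matrix({p: locations[p] for p in rst.labels})
test = mantel_test(geo, clamp_negative(rst), permutations=999, seed=3)
print(f"geography vs R_ST: r = {test.correlation:+.3f}, "
      f"R^2 = {test.r_squared:.3f}, p = {test.p_value:.3f}")
# Population labels are assigned independently of haplogroup in the
# simulator, so no isolation-by-distance signal is expected.
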