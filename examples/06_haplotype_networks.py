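"""Minimum-spanning and median-joining haplotype networks.

The MSN shows how observed haplotypes relate by mutational steps; the MJ
network additionally infers unobserved intermediate (median) haplotypes,
using locus weights binned from per-locus repeat variance so that stable
loci count more.
"""

from ystrkit import (
    SimConfig, collapse_and_msn, locus_weights_from_variance, mj_network,
    qc_filter_biallelic, reduce_for_rst, simulate_cohort,
)
from ystrkit.simulate import truth_labels

cohort, truth = simulate_cohort(SimConfig(seed=9, n_samples=200, biallelic_artifact_count=0))
kept, _ = qc_filter_biallelic(cohort)
reduced = reduce_for_rst(kept)

msn = collapse_and_msn(kept)
print(f"MSN: {msn.n_observed} haplotype nodes "
      f"({len(kept)} samples collapsed), {msn.graph.number_of_edges()} edges")

weights = locus_weights_from_variance(reduced)  # variance scope: whole dataset
print("locus weights (10 = most stable):",
      sorted(set(weights.weights.values()), reverse=True))

labels = truth_labels(truth)
h_ids = [s.sample_id for s in reduced.samples if labels[s.sample_id] == "H"]
mj = mj_network(reduced.subset(h_ids), weights=weights)
print(f"MJ network of the H lineage: {mj.n_observed} observed + "
      f"{mj.n_medians} inferred median nodes, "
      f"spanning length {mj.minimum_spanning_length()}")
# mj.write_graphml("mj_H.graphml") exports the network for Cytoscape/Gephi.
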