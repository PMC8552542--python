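"""CDR3 amino-acid similarity network of a graft-infiltrating repertoire.

Nodes are unique productive CDR3 sequences (top 10,000 clonotypes); edges
join inner segments (flanking 3 residues trimmed) at Levenshtein distance 1.
Donor-reactive clone families form dense clusters, raising modularity, and
donor-reactive nodes tend to sit centrally (betweenness).
"""

import numpy as np

from allotrace import (
    CohortConfig,
    analyze_sample,
    donor_reactive_network_summary,
    donor_reactive_sequences,
)
from allotrace.donor_reactivity import DonorReactiveSet
from allotrace.synthetic import generate_subject
from allotrace.types import Timepoint

config = CohortConfig(
    clonotypes_per_compartment=1500,
    tissue_clonotypes=1000,
    depth_blood=30_000,
    depth_tissue=10_000,
    seed=2,
)
subject = generate_subject(config, "R1", rejector=True, rng=np.random.default_rng(2))
tissue = next(s for s in subject.samples if s.meta.timepoint is Timepoint.TISSUE)

dr = DonorReactiveSet(
    "R1", tissue.meta.compartment,
    entries={k: 20.0 for k in subject.truth.dr_union()},
)
net = analyze_sample(tissue, dr=dr)
summary = donor_reactive_network_summary(net, donor_reactive_sequences(tissue, dr))

print(f"nodes: {net.n_nodes}, edges: {net.n_edges}")
print(f"modularity: {net.modularity:.3f}, edge density: {100 * net.edge_density:.4f}%")
print(f"donor-reactive clones included in the network: {summary.pct_dr_in_network:.1f}%")
print(
    f"top betweenness node donor-reactive: {summary.top_node_donor_reactive} "
    f"(frequency rank {summary.top_node_frequency_rank})"
)
print(
    f"donor-reactive subgraph modularity {summary.dr_subgraph_modularity:.3f} "
    f"vs whole network {summary.network_modularity:.3f}"
)
# Cluster structure comes from the planted clone families (single-substitution
# CDR3 variants sharing a V gene), mirroring convergent alloreactive responses.
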