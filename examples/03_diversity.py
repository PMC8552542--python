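"""Diversity statistics of blood and MLR repertoires.

Clonality (0 = maximally diverse, 1 = monoclonal), R20 (fraction of top
clones holding 20% of the repertoire; small = immunodominant), and the
power-law slope of the bulk clone-size spectrum (steeper absolute slope =
more distinct low-frequency clones).
"""

import numpy as np

from allotrace import CohortConfig, diversity_report
from allotrace.synthetic import generate_subject
from allotrace.types import Compartment

config = CohortConfig(clonotypes_per_compartment=3000, depth_blood=60_000, seed=1)
subject = generate_subject(config, "S1", rejector=False, rng=np.random.default_rng(1))

print(f"{'sample':38s} {'S':>5s} {'clonality':>9s} {'R20':>6s} {'|slope|':>8s}")
for sample in subject.samples:
    if sample.meta.compartment is not Compartment.CD4:
        continue
    rep = diversity_report(sample)
    print(
        f"{sample.meta.label:38s} {rep.n_clonotypes:5d} "
        f"{rep.clonality:9.4f} {rep.r20:6.3f} {rep.powerlaw_abs_slope:8.3f}"
    )
# The MLR-stimulated sample concentrates mass in the enriched donor-reactive
# clones, so its clonality is the highest of the three.  (The simulated MLR
# keeps the non-responding background, so it stays more diverse than a real
# sorted responder well would be.)
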