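"""Exact multiple-merger coalescent rates and the continuous-time simulator.

A Lambda-coalescent merges b of n blocks at rate
lambda_{n,b} = int p^{b-2} (1-p)^{n-b} Lambda(dp); a Xi-coalescent allows
simultaneous mergers driven by a paint-box on a mass partition.
"""

import numpy as np

import asymcoal as ac

# Bolthausen-Sznitman (Lambda = uniform): lambda_{b,b} = 1/(b-1)
for b in (2, 3, 4, 5):
    print(f"Bolthausen-Sznitman lambda_{{{b},{b}}} = "
          f"{ac.lambda_rate(b, b, ac.BOLTHAUSEN_SZNITMAN):.4f}  (exact 1/{b-1})")

# Xi-coalescent with one two-interval atom: simultaneous pair merges possible
Xi = ac.XiMeasure([(ac.MassPartition([0.5, 0.5]), 1.0)])
Q = ac.xi_rate_matrix(4, Xi)
print("\nXi rates on partitions of [4] (per block-size profile):")
print(Q.to_tsv())
# the (2,2) profile is a simultaneous double pair merge -- impossible for any
# Lambda-coalescent, the signature of a genuine Xi limit

rng = np.random.default_rng(1)
trace = ac.simulate_lambda_coalescent(8, ac.BOLTHAUSEN_SZNITMAN, rng)
sizes = [len(p) for p in trace.partitions]
print(f"Bolthausen-Sznitman jump chain from 8 lineages: block counts {sizes}, "
      f"absorbed at time {trace.times[-1]:.3f} (coalescent units)")
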