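"""Simulate sample genealogies of neutral populations forward in time.

Classical Wright-Fisher (every parent equally likely) versus a skewed-offspring
Eldon-Wakeley population where one random individual occasionally replaces a
large fraction of the next generation.
"""

import numpy as np

import asymcoal as ac

# Wright-Fisher, N = 100: a pair of lineages coalesces after ~Geometric(1/N)
# generations, so the mean MRCA time should be close to N.
wf = ac.UniformFrequency(100)
times = [ac.simulate_genealogy(wf, 2, seed=s).times[-1] for s in range(300)]
print(f"Wright-Fisher N=100, n=2: mean MRCA time = {np.mean(times):.1f} generations "
      f"(expected ~100)")

# Eldon-Wakeley with sweep fractions from the uniform measure: multiple
# lineages can merge in a single generation (multiple-merger genealogy).
params = ac.EldonWakeleyParams(ac.BOLTHAUSEN_SZNITMAN, epsilon=0.5, N=100)
model = ac.EldonWakeleyOffspring(params)
trace = ac.simulate_genealogy(model, 6, seed=7)
print(f"Eldon-Wakeley N=100, n=6: MRCA in {trace.times[-1]:.0f} generations; "
      f"block counts along the trace: {trace.block_counts()}")
print("Newick tree (branch lengths in generations):")
print(" ", trace.to_newick())
# a drop of more than one block in a step is a simultaneous multiple merger
drops = np.diff(trace.block_counts())
print(f"largest single-generation merger: {-drops.min() + 1} lineages at once")
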