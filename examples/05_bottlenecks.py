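"""Recurrent demographic bottlenecks and their limit coalescent.

With probability ~ 1/a_N per generation the population collapses to k
reproducing individuals (k ~ F); when bottleneck mergers dominate the
background coalescence (hat_c_N * a_N -> 0), the limit genealogy merges
lineages by a paint-box on the bottleneck frequencies at rate F(k), on the
time scale a_N.
"""

import numpy as np

import asymcoal as ac

params = ac.BottleneckParams(
    F={2: 1.0},                      # bottlenecks always collapse to 2 ancestors
    a_N=lambda n: n**0.5,            # bottleneck probability 1/sqrt(N)
    b_N=lambda n: max(2, int(round(n**0.25))),
    nu_bar=ac.SymmetricBottleneckLaw(),  # survivors share offspring equally
)

N = 10_000
Qbar, report = ac.bottleneck_limit_rates(params, n=3)
print(f"time-scale regime: {report['regime']} "
      f"(hat_c_N * a_N = {report['ell_estimate']:.4f} at the largest grid N)")
print("limit coagulation rates on partitions of [3]:")
print(Qbar.to_tsv())

model = ac.BottleneckFrequency(params, N)
rng = np.random.default_rng(2)
merged = sum(len(ac.awf_increment(model.sample(rng), 2, rng)) == 1
             for _ in range(20_000))
target = 0.5 / N**0.5 + (1 - 1 / N**0.5) / N
print(f"per-generation pair-merge probability: {merged/20_000:.5f} "
      f"(bottleneck share + background = {target:.5f})")

# Dirichlet-type bottleneck: survivors get i.i.d. normalized weights instead
dirichlet = ac.NormalizedWeightsBottleneckLaw()
Q2, _ = ac.bottleneck_limit_rates(
    ac.BottleneckParams(F={3: 1.0}, a_N=lambda n: n**0.5,
                        b_N=lambda n: max(3, int(round(n**0.25))),
                        nu_bar=dirichlet),
    n=2, rng=rng, mc_atoms=512,
)
print(f"Dirichlet bottleneck (k=3): pair-merge limit rate = "
      f"{Q2.total_rate():.3f} (E[sum (W_i/S)^2] = 1/2 for exponential weights)")
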