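"""The biallelic coalescent likelihood, checked two ways.

Computes the probability of single-character allele-count patterns on a
three-species tree analytically (integrating over gene trees and
mutational histories), and confirms a few of them against brute-force
gene-tree simulation.
"""

import numpy as np

from genphy.likelihood import ModelParams, character_probability
from genphy.simulate import evolve_character, sample_gene_tree
from genphy.tree import parse_tree

tree = parse_tree("((A:0.01,B:0.01):0.02,C:0.03);")
params = ModelParams(ne_mu=0.002)  # shared mutation-scaled population size

print("pattern (red copies per diploid)   analytic      simulated")
rng = np.random.default_rng(1)
n_sim = 20_000
sim = {}
for _ in range(n_sim):
    g = sample_gene_tree(tree, params.ne_mu, 2, rng)
    pat = evolve_character(g, rng=rng)
    key = tuple(pat[s][1] for s in "ABC")
    sim[key] = sim.get(key, 0) + 1

for reds in [(0, 0, 0), (1, 0, 0), (1, 1, 0), (2, 2, 0), (1, 1, 1)]:
    p = character_probability(
        tree, params, {s: (2, r) for s, r in zip("ABC", reds)}
    )
    print(f"  A={reds[0]} B={reds[1]} C={reds[2]}                 "
          f"{p:.5f}      {sim.get(reds, 0) / n_sim:.5f}")

total = sum(
    character_probability(tree, params, {s: (2, r) for s, r in zip("ABC", reds)})
    for reds in np.ndindex(3, 3, 3)
)
print(f"\nsum over all 27 patterns: {total:.12f} (total probability)")

# the 0.004 calibration: with ne_mu = 0.001 a diploid individual is
# heterozygous at ~0.4% of characters
het = character_probability(parse_tree("(A:0.01,B:0.01);"),
                            ModelParams(ne_mu=0.001), {"A": (2, 1)})
print(f"heterozygosity at ne_mu=0.001: {het:.5f} "
      f"(closed form 4*ne/(1+8*ne) = {4 * 0.001 / 1.008:.5f})")
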