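"""Pulling through a second DNA captured by the ring.

When the ring entraps both the surface-tethered λ-DNA and a 7.2 kb
plasmid, force applied to the plasmid is transmitted through the ring to
the λ-DNA V.  Stretching the extra chain slows the effective force ramp,
so rupture happens at slightly lower force than when the bead pulls the
ring directly.  Per event the disengagement orientation parameter δ is
drawn at random between the head-like and hinge-like values.
"""

import numpy as np

from ringrupture import BondModel, PullingProtocol, simulate_rupture_distribution, simulate_two_dna_pull

n = 2000
two = simulate_two_dna_pull(
    PullingProtocol(seed=2), 2e-3, {1.23: 0.5, 1.61: 0.5}, n=n
)
print(f"two-DNA pull     (n={n}): mean = {two.mean:5.1f} pN, median = {two.median:5.1f} pN")

singles = []
for i, d in enumerate((1.23, 1.61)):
    s = simulate_rupture_distribution(PullingProtocol(seed=3 + i), BondModel(2e-3, d), n=n // 2)
    singles.append(s.mean)
print(f"matched single-DNA pulls : mean = {np.mean(singles):5.1f} pN")
print("\nThe two-DNA mean sits a few pN below the matched single-DNA mean,")
print("reproducing the reduced rupture forces measured for DNA-DNA tethers.")
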