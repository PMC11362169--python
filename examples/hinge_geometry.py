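"""Hinge analysis on a synthetic two-helix pair with known ground truth.

Builds an ideal helical hairpin, rotates the second helix by 25 degrees
about z through a pivot atom, and shows that the dihedral difference map
localises the hinge while the screw decomposition of the fitted
rigid-body transform recovers the rotation exactly.
"""

import numpy as np

import hdxconf as hc
from hdxconf.structure import ResidueSelection

a, b, truth = hc.make_toy_hinge_structures(n_res_per_helix=12, hinge_angle=25.0,
                                           hinge_axis=(0, 0, 1), seed=1)

diff = hc.dihedral_difference(hc.compute_dihedrals(a), hc.compute_dihedrals(b))
moved = diff[(diff["dphi"] > 1e-6) | (diff["dpsi"] > 1e-6)]
print("residues with backbone dihedral changes:",
      [int(r) for _, r in moved.index])
# the change is confined to the pivot — the hinge is a local deformation

helix2 = ResidueSelection((("A", 13, 24),))
transform, rmsd, n = hc.superpose(a, b, helix2)
screw = hc.screw_decompose(transform)
print(f"second-helix fit: rmsd {rmsd:.2e} A over {n} CA")
print(f"screw axis: angle {screw.angle:.3f} deg about "
      f"{np.round(screw.axis, 3).tolist()} (truth: {truth.params['hinge_angle']} deg "
      f"about {truth.params['hinge_axis'].tolist()})")

helix1 = ResidueSelection((("A", 1, 12),))
acute, _ = hc.inter_helix_angle(hc.helix_axis(b, helix1), hc.helix_axis(b, helix2))
print(f"inter-helix angle after the hinge motion: {acute:.1f} deg")
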