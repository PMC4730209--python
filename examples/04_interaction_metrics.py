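"""Geometric and energetic metrics on constructed fixtures.

Builds fixtures with known ground truth: an aromatic ring pair at a
prescribed geometry, a spherical cluster with waters placed inside and
outside the buried-water shell, and charge/LJ probes with closed-form
energies.
"""

import numpy as np

from pepagg import (
    interpeptide_energies,
    buried_waters,
    make_cluster_with_waters,
    make_ring_pair,
    radius_of_gyration,
    ring_geometry,
)
from pepagg.metrics import assign_lj_params
from pepagg.model import Atom, AtomRole, Frame, Topology

# ring-pair geometry: R_cen / theta / gamma are recovered from coordinates
frame, _ = make_ring_pair(r_cen=4.2, theta=30.0, gamma=60.0)
geom = ring_geometry(frame, np.arange(6), np.arange(6, 12))
print(f"ring pair: R_cen={geom.r_cen:.3f} Å, theta={geom.theta:.1f}°, gamma={geom.gamma:.1f}°")

# buried waters: 5 placed inside 0.75 Rg, 20 outside
frame, top = make_cluster_with_waters(10.0, 300, 5, 20, seed=1)
rg, _ = radius_of_gyration(frame, np.arange(300))
count, _ = buried_waters(frame, top, ["A"])
print(f"cluster Rg={rg:.2f} Å; buried waters found: {count} (constructed: 5)")

# Coulomb probe: two +1e charges at 3.320636 Å give exactly 100 kcal/mol
pair = Topology(
    [
        Atom(i, c, 1, "BDS", "B1", AtomRole.SIDECHAIN, "C", 1.7, partial_charge=1.0)
        for i, c in enumerate("AB")
    ]
)
probe = Frame(time=0.0, coordinates=[[0, 0, 0], [3.320636, 0, 0]], box=[1000.0] * 3)
for eps in (1.0, 80.0):
    e = interpeptide_energies(probe, pair, dielectric=eps, include_vdw=False)
    print(f"Coulomb at dielectric {eps:5.1f}: {e.coulomb_total:8.3f} kcal/mol")

# LJ minimum: energy at r = 2^(1/6) sigma equals -epsilon
lj = assign_lj_params(pair, epsilon=0.5, sigma=3.4)
at_min = Frame(time=0.0, coordinates=[[0, 0, 0], [2 ** (1 / 6) * 3.4, 0, 0]], box=[1000.0] * 3)
print(f"vdW at the 12-6 minimum: {interpeptide_energies(at_min, lj).vdw_total:.3f} kcal/mol")
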