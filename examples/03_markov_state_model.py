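"""Markov state model of cluster-size dynamics.

The transition matrix counts, between consecutive saved frames of the
early aggregation phase, how many peptides move from an i-mer to a
j-mer.  Propagating the row-normalised matrix from the all-monomer start
shows the characteristic pathway: dimers-to-tetramers accumulate first,
then larger clusters take over.
"""

import numpy as np

from pepagg import (
    SimulationParams,
    analyze_trajectory,
    build_msm,
    make_grid_configuration,
    propagate,
    simulate_sticky_spheres,
)
from pepagg.msm import empirical_distribution

start = make_grid_configuration(n_peptides=8, spacing=16.0, box_edge=40.0)
params = SimulationParams(
    n_peptides=8, box_edge=40.0, epsilon_attract=8.0,
    n_steps=100_000, save_interval=2_000, seed=13,
)
lab = analyze_trajectory(simulate_sticky_spheres(start, params))

model = build_msm(lab, lag=1, window_fraction=0.5)
pi = propagate(model.P, empirical_distribution(lab, 0), 200)

print("step   monomer   2-4mer   5+mer")
for k in (0, 5, 10, 20, 50, 100, 200):
    print(
        f"{k:4d} {pi[k, 0]:9.3f} {pi[k, 1:4].sum():8.3f} {pi[k, 4:].sum():7.3f}"
    )
print(
    f"\nPopulations stay normalised (max drift "
    f"{np.abs(pi.sum(axis=1) - 1).max():.1e}); the 2-4mer fraction peaks "
    "early before larger clusters dominate."
)
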