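# pepagg

Cluster, Markov-state and interaction analysis of multi-peptide
aggregation trajectories — with a synthetic sticky-sphere generator so
every stage is testable against known ground truth.

## The problem

Whether a peptide stays in solution or aggregates is governed by its
amino acids, and multi-peptide simulations can rank residues by
aggregation propensity: systems of 27 identical tetra-peptides in a
periodic box either collapse into amorphous clusters (hydrophobic and
aromatic residues), form small transient clusters (Ala, Pro, Ser, Thr),
or stay monomeric (Asp, Glu, Lys, Arg).  `pepagg` is for computational
biophysicists who want the *analysis* half of such studies as a tested,
reusable library:

* **Contact clustering** — two peptides are connected when any inter-chain
  atom pair is closer than the sum of its vdW radii (plus an optional
  padding); clusters are connected components.  Per frame, with `CS_i`
  the size of the cluster containing peptide `i`,

      MCS = (1/N) Σ_i CS_i = (1/N) Σ_clusters s²

  runs from 1 (all monomers) to N (one cluster).  Monomer and
  monomer+dimer counts, trailing-window averages, and robustness sweeps
  over the contact padding {0…2.8 Å} and required pair count {1…3} are
  first-class outputs.
* **Cluster-size Markov state model** — transition counts
  `T(i,j) = Σ_{p,t} [CS_{p,t}=i ∧ CS_{p,t+lag}=j]` over an early-phase
  window, row-normalised to P, propagated as `π(n) = π(0) Pⁿ`.
* **Interaction metrics** — radius of gyration and buried waters
  (within 0.75 Rg of a cluster's centre of gravity), geometric H-bond
  detection with peptide/water partner classes and water-mediated
  bridges, aromatic ring-pair geometry (R_cen, θ, γ) with
  face-to-face / T-stack classification, and pairwise inter-peptide
  Coulomb (`332.0636 q_a q_b / ε r`) and 12-6 vdW energy sums.
* **Scale correlations** — an embedded 18-residue table pairing
  aggregation metrics with experimental solubility and hydrophobicity
  scales, and the Pearson analysis relating them.
* **Synthetic generator** — 27 four-bead peptides on a 23 Å grid in a
  100 Å periodic cube (~45 mM), evolved by overdamped Langevin dynamics
  with a tunable short-range attraction (kT units) and screened
  electrostatic repulsion.  Deterministic per seed.

See `docs/methods.md` for models, defaults and limitations.

## Worked example

```python
from pepagg import (SimulationParams, analyze_trajectory, builtin_scales,
                    make_grid_configuration, pearson, simulate_sticky_spheres)
from pepagg.scales import CorrelationSpec

# aggregation of a small sticky system
start = make_grid_configuration(n_peptides=8, spacing=16.0, box_edge=40.0)
params = SimulationParams(n_peptides=8, box_edge=40.0, epsilon_attract=8.0,
                          n_steps=100_000, save_interval=10_000, seed=7)
lab = analyze_trajectory(simulate_sticky_spheres(start, params))
print(lab.mcs_series[0], lab.mcs_series[-1])   # 1.0 8.0

# how well does aggregation track experimental hydrophobicity?
res = pearson(CorrelationSpec("averaged_mcs", "hydrophobicity"))
print(round(res.r, 2), res.n_used)             # 0.79 18
```

The first line shows the strongly sticky 8-peptide system going from all
monomers (MCS 1.0) to a single cluster (MCS 8.0) within the run.  The
second shows that across the 18 residues, window-averaged mean cluster
size correlates at r = 0.79 with the transfer hydrophobicity scale —
more hydrophobic residues aggregate more.

The `examples/` directory holds one short script per capability
(simulation, cluster statistics, MSM, geometric/energetic metrics, scale
correlations, full pipeline); each prints what it computes and what the
numbers mean.  A command-line interface mirrors the pipeline:

```bash
pepagg simulate --n-peptides 8 --epsilon 6 --n-steps 5000 --out traj.pdb
pepagg cluster --traj traj.pdb --out mcs.csv
pepagg correlate --x averaged_mcs --y hydrophobicity
pepagg run config.toml
```

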