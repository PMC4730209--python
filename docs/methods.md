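# Methods

`pepagg` analyses multi-peptide aggregation trajectories: it identifies
clusters by van der Waals contact, tracks mean cluster size (MCS) and
monomer counts, fits a cluster-size Markov state model (MSM), computes
per-cluster geometric and energetic metrics, and correlates aggregation
metrics against experimental solubility/hydrophobicity scales.  Because
realistic all-atom multi-peptide trajectories are expensive and rarely
shared, the package ships a synthetic sticky-sphere generator that
reproduces the relevant phenomenology with known ground truth.

## Cluster definition and statistics

Two peptides are in **contact** when at least `min_pairs` inter-chain atom
pairs satisfy

    d(a, b) < r_vdW(a) + r_vdW(b) + padding

with strict inequality, minimum-image distances in the periodic box, and
water atoms excluded.  Defaults are `padding = 0 Å`, `min_pairs = 1`.
Clusters are connected components of the peptide contact graph (scipy's
`csgraph`; candidate pairs from a periodic `cKDTree` queried at the
largest possible threshold, then filtered per pair).  With `CS_i` the size
of the cluster containing peptide `i`,

    MCS = (1/N) Σ_i CS_i = (1/N) Σ_clusters s²,

ranging from 1 (all monomers) to N (one cluster).  The identity between
the two forms is asserted per frame in the tests, and components are
cross-checked against a brute-force transitive-closure oracle.  Headline
numbers average per-frame values over a trailing window (default: last
10 % of the trajectory).  Robustness sweeps vary `padding` over
{0, 0.7, 1.4, 2.1, 2.8} Å and `min_pairs` over {1, 2, 3}; MCS is provably
monotone in both (adjacency superset/subset), which the suite asserts
frame by frame.

Element vdW radii default to the Bondi (1964) compilation; the radius set
is selectable because published contact analyses rarely state theirs.

## Markov state model

States are cluster sizes 1..N.  The count matrix

    T(i, j) = #{(peptide p, frame t) : CS_{p,t} = i and CS_{p,t+lag} = j}

is accumulated inside a build window (default: the leading 20 % of the
trajectory, i.e. the early aggregation phase) at `lag = 1` saved frame.
Row-normalising T gives the row-stochastic P; rows with zero counts get a
self-transition of 1, which keeps P stochastic without inventing dynamics
for unvisited sizes.  Populations propagate as `pi(n) = pi(0) P^n` with
`pi(0)` the observed size distribution of the first window frame.  The
suite checks row sums to 1e-12, population conservation to 1e-9 over 10³
steps, the count identity `ΣT = N (frames − lag)`, and — on aggregating
runs — the qualitative pathway in which the 2-4-mer fraction transiently
rises before ≥10-mer states dominate.  No detailed-balance enforcement,
implied-timescale analysis or error bars: the model is a plain
row-normalised count matrix.

## Geometric and energetic metrics

* **Radius of gyration / centre of gravity**: weighted RMS distance from
  the weighted centre; unit weights by default (appropriate for bead
  systems), masses may be passed.  Groups are first made contiguous
  across periodic boundaries by shifting atoms whole box vectors toward
  the first atom (valid while a cluster spans less than half the box).
* **Buried waters**: waters whose oxygen lies within `0.75 × Rg` of a
  cluster's centre of gravity, minimum image.  The factor is
  configurable; fixtures with waters constructed strictly inside/outside
  the shell give exact expected counts.
* **Hydrogen bonds**: geometric criterion with defaults
  donor–acceptor ≤ 3.5 Å, hydrogen–acceptor ≤ 2.5 Å, donor-H-acceptor
  angle ≥ 90°; when the donor carries no explicit hydrogen (heavy-atom
  or bead models) the heavy-atom distance alone decides.  Bonds are
  classed P-P (peptide–peptide) or P-W (peptide–water) and, on the
  peptide side, SC/MC by sidechain vs mainchain role (capping groups
  count as mainchain).  A **water-mediated bridge** (P-W-P) is one water
  H-bonded to atoms on two different peptide chains.  Per-residue tables
  divide time-averaged counts by the total peptide residue count (caps
  excluded); the denominator convention (all residues, not only polar
  ones) is configurable in effect by scaling.
* **Aromatic ring geometry**: for two rings, `R_cen` is the distance
  between geometric centres, `theta` the angle between ring 1's best-fit
  plane normal (SVD) and the centre–centre vector, `gamma` the angle
  between the two normals, both folded into [0°, 90°].  Pairs with
  `R_cen < 5.5 Å` are classified face-to-face (`gamma` and `theta`
  ≤ 30°), T-stack (`gamma` ≥ 60°), or other.  The 30°/60° class
  boundaries are conventional, not canonical, and are configurable.
* **Inter-peptide energies**: pairwise sums over atoms of different
  peptides, minimum image, no cutoff.  Coulomb
  `332.0636 q_a q_b / (ε_r r)` kcal/mol with a uniform dielectric
  (1.0 or 80.0 are the interesting settings); vdW
  `4 ε_ab [(σ_ab/r)¹² − (σ_ab/r)⁶]` with Lorentz–Berthelot combination.
  This is a deliberately transparent surrogate for implicit-solvent
  energetics: no generalized Born term, no Ewald summation.  It
  reproduces the diagnostic sign pattern — like-charged clusters have
  positive (destabilising) Coulomb sums, sticky neutral clusters negative
  vdW sums.

## Synthetic sticky-sphere generator

The generator emulates the reference study geometry: 27 tetra-peptide-like
bodies (4 beads each, one bead per residue, 3.8 Å virtual bonds) placed in
identical orientation on a 23 Å cubic grid centred in a 100 Å periodic
cube — about 45 mM, a volume of 10⁶ Å³.  Dynamics are overdamped
(Brownian) Langevin per bead:

    dx = (D dt / kT) F + sqrt(2 D dt) ξ,   kT = 1,

with forces from (i) a truncated-and-shifted 12-6 attraction of depth
`epsilon_attract` (kT), size `sigma = 3.5 Å`, cutoff `2.5 σ` between beads
of different peptides, (ii) a Yukawa repulsion
`q_a q_b l_B exp(−r/λ)/r` (Bjerrum length 7 Å, screening length 10 Å
default) between charged beads of different peptides, and (iii) stiff
harmonic bonds (25 kT/Å²) along each chain.  Beads carry a 2.0 Å contact
radius, so the 3.93 Å 12-6 minimum of two touching beads falls just
inside the 4.0 Å contact threshold.

Numerical choices: `dt = 0.02 ps`; effective bead diffusivity
`D = 1.0 Å²/ps`, chosen for desk-scale mixing times (overdamped dynamics
only fixes time scales through D, so this is a clock choice, not a
thermodynamic claim); the deterministic displacement per bead per step is
clipped at `0.1 σ`, the standard Brownian-dynamics guard against the
steep 12-6 core (the noise term is never modified); a step displacement
exceeding half the box still raises an error advising a smaller `dt`.
Noise is pre-drawn per step and bead, in fixed order, from a single
seeded numpy generator, so a given parameter set and seed reproduces the
frame sequence bit for bit; the compiled inner loop does not touch the
RNG.  Frames are saved every `save_interval` steps (default 20 000,
i.e. every 400 ps).

Regimes used throughout tests and the acceptance script, fixed once from
the simulator's own relaxation behaviour:

* **sticky-neutral** (`epsilon_attract = 8 kT`, no charge, 2×10⁶ steps):
  aggregates into a single 27-peptide cluster; the last-window MCS
  reaches the 23–27 band.  The slowest step is the final cluster–cluster
  merge, because free-draining beads give a cluster a diffusivity of
  D/n_beads — a known harshness of the surrogate relative to
  hydrodynamic reality.
* **charged-repulsive** (1 e/bead, no attraction, 2×10⁵ steps): MCS stays
  exactly 1.0; all 27 peptides remain monomeric.
* **weakly-sticky** (`epsilon_attract = 3 kT`, 2.5×10⁵ steps): partial
  clustering whose window MCS roughly doubles when the peptide count is
  doubled at fixed volume — the concentration-dependence analogue.

Geometric fixtures carry exact ground truth: ring pairs constructed at a
prescribed (R_cen, theta, gamma) are recovered by the analyzer to 1e-4;
uniform-ball clusters approach `Rg = a √(3/5)`; waters are placed
strictly inside or outside the buried-water shell.

**What the generator does not emulate**: explicit water, residue
chemistry beyond a stickiness/charge knob, secondary structure,
hydrodynamic interactions, or any force-field realism.  Passing tests
therefore demonstrate that the *analysis machinery* is correct and that
the analysis pipeline responds to controlled aggregation behaviour as
expected — not that the simulator predicts real peptide solubility.

## Scale correlations

The embedded table pairs, for the 18 natural amino acids other than Gly
and Cys, window-averaged MCS and monomer counts from homotetrapeptide
simulations with five experimental per-residue scales (amino-acid water
solubility in g/kg, hydropathy, hydrophilicity in kcal/mol, transfer
hydrophobicity in kcal/mol, and a protein-solubility contribution scale
in mg/ml that is unavailable for eight residues).  Pearson r is computed
over pairwise-complete rows (the only policy under which the published
coefficients are computable at all), with named exclusion presets for the
documented variants: amino-acid solubility without the extreme Pro row,
protein solubility without Asn.  Reported values are rounded to 2
decimals to match the source precision; full precision is retained in
JSON output.  Spearman rank correlation is available as a diagnostic.

Recomputing every published coefficient from the embedded table
reproduces 13 of 14 at 2 decimal places.  The exception is
r(MCS, hydrophilicity): the table yields −0.481 where −0.47 was
published.  Since the published correlations were evidently computed from
unrounded metric values while the table prints MCS at one decimal, the
published value is not recoverable from the printed inputs; the
corresponding test is left failing rather than loosened, and this note is
the record of why.

## Pipeline and reproducibility

`run_pipeline` executes simulate → cluster → MSM → metrics → correlate
from a single TOML config validated by pydantic (unknown keys are
rejected; keys that belong to an MD engine get a pointed message).  One
global seed derives per-stage seeds via numpy's `SeedSequence`; every
output carries a config hash, and rerunning a config byte-reproduces the
bundle.  Failures abort with the stage name, preserving partial outputs.

## Known limitations

* The simulator's free-draining kinetics make late-stage cluster merging
  artificially slow; run lengths were chosen to absorb this, but very
  unlucky seeds can still leave a two-cluster state at the end of a
  sticky run.
* Donor/acceptor flags from PDB input use an element-level heuristic, not
  connectivity-derived chemistry; explicit-hydrogen topologies are
  handled, but exotic residues may need a charge/flag table.
* Energy sums are direct minimum-image pair sums intended for
  cluster-vs-dispersed comparisons, not absolute solvation energetics.
* Periodic unwrapping of a group assumes its extent is below half the box
  edge; a percolating cluster would violate this.
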