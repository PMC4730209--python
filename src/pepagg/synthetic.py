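"""Synthetic trajectories and geometric fixtures with known ground truth.

The centrepiece is an overdamped (Brownian) Langevin simulator of "sticky
sphere" bead-chain peptides in a periodic cube.  It is a deliberately
minimal surrogate for explicit-solvent MD of multi-tetrapeptide systems:
27 four-bead chains start on a 23 Å grid in a ~10^6 Å^3 box (≈ 40 mM) and
aggregate or stay dispersed depending on a short-range attraction depth
(kT units) and a screened electrostatic repulsion.  It makes no claim of
thermodynamic fidelity to any amino acid; its job is to produce
trajectories whose clustering behaviour is controlled and known.

Per-step update for each bead::

    dx = (D * dt / kT) * F + sqrt(2 * D * dt) * xi,   kT = 1

with F the negative gradient of

* a truncated-and-shifted 12-6 potential (depth ``epsilon_attract``, size
  ``sigma``, cutoff ``2.5 * sigma``) between beads of *different* peptides,
* a Yukawa repulsion ``q_a q_b l_B exp(-r/lambda)/r`` (Bjerrum length
  7.0 Å) between charged beads of different peptides,
* stiff harmonic bonds along each chain,

under minimum-image periodic boundaries.  The same seed always yields the
bit-identical frame sequence: noise is pre-drawn from one seeded numpy
generator in fixed per-step, per-bead order.
"""

from __future__ import annotations

import string
from dataclasses import dataclass

import numpy as np
from numba import njit

from .model import Atom, AtomRole, Frame, Topology, Trajectory, minimum_image

__all__ = [
    "SimulationParams",
    "make_grid_configuration",
    "simulate_sticky_spheres",
    "make_ring_pair",
    "make_cluster_with_waters",
    "mean_squared_displacement",
    "BEAD_VDW_RADIUS",
    "BOND_LENGTH",
]

#: contact radius assigned to every synthetic bead (Å); two beads touch when
#: closer than 2 * BEAD_VDW_RADIUS under the default contact criterion
BEAD_VDW_RADIUS = 2.0
#: intra-chain bead spacing (Å), roughly a Cα-Cα virtual bond
BOND_LENGTH = 3.8
#: harmonic bond stiffness (kT/Å^2); kept soft enough that the overdamped
#: update stays stable at the default diffusivity and time step
BOND_K = 25.0
#: Bjerrum length of water at 300 K (Å); sets the Yukawa prefactor scale
BJERRUM_LENGTH = 7.0

_CHAIN_ALPHABET = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _chain_label(i: int) -> str:
    if i < len(_CHAIN_ALPHABET):
        return _CHAIN_ALPHABET[i]
    return f"x{i}"


@dataclass
class SimulationParams:
    """Knobs of the sticky-sphere Brownian simulator.

    Defaults emulate the reference multi-peptide setup: 27 four-bead
    peptides in a 100 Å periodic cube (≈ 45 mM), frames saved every
    ``save_interval`` steps.  ``epsilon_attract`` (kT) controls stickiness,
    ``charge_per_bead`` (e) with ``screening_length`` (Å) controls
    electrostatic repulsion.  ``diffusion_coeff`` is an effective bead
    diffusivity in Å²/ps chosen for desk-scale mixing times.
    """

    n_peptides: int = 27
    beads_per_peptide: int = 4
    box_edge: float = 100.0
    epsilon_attract: float = 0.0
    sigma: float = 3.5
    charge_per_bead: float = 0.0
    screening_length: float = 10.0
    diffusion_coeff: float = 1.0
    dt: float = 0.02
    n_steps: int = 2_000_000
    save_interval: int = 20_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be > 0")
        if self.box_edge <= 2 * self.sigma:
            raise ValueError("box_edge must exceed 2*sigma")
        if self.save_interval < 1:
            raise ValueError("save_interval must be >= 1")
        if self.n_peptides < 1 or self.beads_per_peptide < 1:
            raise ValueError("need at least one peptide with at least one bead")


def _bead_topology(
    n_peptides: int,
    beads_per_peptide: int,
    charge_per_bead: float = 0.0,
) -> Topology:
    atoms = []
    aid = 0
    for p in range(n_peptides):
        chain = _chain_label(p)
        for b in range(beads_per_peptide):
            atoms.append(
                Atom(
                    atom_id=aid,
                    chain_id=chain,
                    residue_index=b + 1,
                    residue_name="BDS",
                    atom_name=f"B{b + 1}",
                    role=AtomRole.SIDECHAIN,
                    element="C",
                    vdw_radius=BEAD_VDW_RADIUS,
                    partial_charge=charge_per_bead,
                )
            )
            aid += 1
    return Topology(atoms)


def make_grid_configuration(
    n_peptides: int = 27,
    spacing: float = 23.0,
    box_edge: float = 100.0,
    beads_per_peptide: int = 4,
) -> tuple[Frame, Topology]:
    """Place peptide chains, in identical (parallel) orientation, on a cubic
    grid centred in the box.

    The grid has ``ceil(n^(1/3))`` sites per edge at the given spacing; the
    default (27 peptides, 23 Å spacing, 100 Å box) corresponds to a peptide
    concentration of about 45 mM.
    """
    m = int(np.ceil(n_peptides ** (1 / 3) - 1e-9))
    if spacing * m > box_edge:
        raise ValueError(
            f"grid of {m} sites/edge at {spacing} Å does not fit a {box_edge} Å box"
        )
    sites = []
    for ix in range(m):
        for iy in range(m):
            for iz in range(m):
                sites.append((ix, iy, iz))
    sites = np.array(sites[:n_peptides], dtype=np.float64) * spacing
    # re-centre the occupied grid in the box
    span = sites.max(axis=0) if len(sites) else np.zeros(3)
    centers = sites - span / 2.0 + box_edge / 2.0

    local = np.zeros((beads_per_peptide, 3))
    local[:, 0] = (np.arange(beads_per_peptide) - (beads_per_peptide - 1) / 2.0) * BOND_LENGTH

    coords = (centers[:, None, :] + local[None, :, :]).reshape(-1, 3)
    top = _bead_topology(n_peptides, beads_per_peptide)
    frame = Frame(time=0.0, coordinates=coords, box=np.full(3, box_edge))
    return frame, top


@njit(cache=True)
def _run_chunk(
    pos, noise, box, pep_idx, eps, sigma2, rc2,
    qq, inv_lam, yuk_rc2, bond_k, bond_r0, bonds, mobility, max_move
):  # pragma: no cover - exercised through simulate_sticky_spheres
    n = pos.shape[0]
    steps = noise.shape[0]
    forces = np.zeros((n, 3))
    max_disp = 0.0
    bx, by, bz = box[0], box[1], box[2]
    hx, hy, hz = 0.5 * bx, 0.5 * by, 0.5 * bz
    amp = np.sqrt(2.0 * mobility)
    has_lj = eps > 0.0
    has_yuk = qq != 0.0
    for s in range(steps):
        forces[:, :] = 0.0
        if has_lj or has_yuk:
            for i in range(n):
                xi, yi, zi = pos[i, 0], pos[i, 1], pos[i, 2]
                pi = pep_idx[i]
                for j in range(i + 1, n):
                    if pi == pep_idx[j]:
                        continue
                    # branch-based minimum image: positions live in [0, box)
                    dx = xi - pos[j, 0]
                    if dx > hx:
                        dx -= bx
                    elif dx < -hx:
                        dx += bx
                    dy = yi - pos[j, 1]
                    if dy > hy:
                        dy -= by
                    elif dy < -hy:
                        dy += by
                    dz = zi - pos[j, 2]
                    if dz > hz:
                        dz -= bz
                    elif dz < -hz:
                        dz += bz
                    r2 = dx * dx + dy * dy + dz * dz
                    fmag = 0.0
                    if has_lj and r2 < rc2:
                        sr2 = sigma2 / r2
                        sr6 = sr2 * sr2 * sr2
                        sr12 = sr6 * sr6
                        # -dU/dr / r  (attractive 12-6, truncated & shifted)
                        fmag += 4.0 * eps * (12.0 * sr12 - 6.0 * sr6) / r2
                    if has_yuk and r2 < yuk_rc2:
                        r = np.sqrt(r2)
                        u = qq * np.exp(-r * inv_lam) / r
                        fmag += u * (inv_lam + 1.0 / r) / r
                    if fmag != 0.0:
                        forces[i, 0] += fmag * dx
                        forces[i, 1] += fmag * dy
                        forces[i, 2] += fmag * dz
                        forces[j, 0] -= fmag * dx
                        forces[j, 1] -= fmag * dy
                        forces[j, 2] -= fmag * dz
        for b in range(bonds.shape[0]):
            i = bonds[b, 0]
            j = bonds[b, 1]
            dx = pos[i, 0] - pos[j, 0]
            if dx > hx:
                dx -= bx
            elif dx < -hx:
                dx += bx
            dy = pos[i, 1] - pos[j, 1]
            if dy > hy:
                dy -= by
            elif dy < -hy:
                dy += by
            dz = pos[i, 2] - pos[j, 2]
            if dz > hz:
                dz -= bz
            elif dz < -hz:
                dz += bz
            r = np.sqrt(dx * dx + dy * dy + dz * dz)
            if r > 0.0:
                fmag = -bond_k * (r - bond_r0) / r
                forces[i, 0] += fmag * dx
                forces[i, 1] += fmag * dy
                forces[i, 2] += fmag * dz
                forces[j, 0] -= fmag * dx
                forces[j, 1] -= fmag * dy
                forces[j, 2] -= fmag * dz
        for i in range(n):
            fx = mobility * forces[i, 0]
            fy = mobility * forces[i, 1]
            fz = mobility * forces[i, 2]
            # clip the deterministic move: tames the steep 12-6 core without
            # touching the noise, standard practice in Brownian dynamics
            fnorm = np.sqrt(fx * fx + fy * fy + fz * fz)
            if fnorm > max_move:
                scale = max_move / fnorm
                fx *= scale
                fy *= scale
                fz *= scale
            ddx = fx + amp * noise[s, i, 0]
            ddy = fy + amp * noise[s, i, 1]
            ddz = fz + amp * noise[s, i, 2]
            d2 = ddx * ddx + ddy * ddy + ddz * ddz
            if d2 > max_disp:
                max_disp = d2
            pos[i, 0] = (pos[i, 0] + ddx) % bx
            pos[i, 1] = (pos[i, 1] + ddy) % by
            pos[i, 2] = (pos[i, 2] + ddz) % bz
    return np.sqrt(max_disp)


def simulate_sticky_spheres(
    start: tuple[Frame, Topology] | Frame,
    params: SimulationParams,
    topology: Topology | None = None,
) -> Trajectory:
    """Run the Brownian sticky-sphere simulator from a starting frame.

    Returns a trajectory whose first frame is the (wrapped) start at t=0,
    followed by one frame every ``save_interval`` steps.  Raises if a
    single-step displacement ever exceeds half the box edge, which signals
    an unstable ``dt``.
    """
    if isinstance(start, tuple):
        frame, top = start
    else:
        frame, top = start, topology
    if top is None:
        raise ValueError("topology required")
    if frame.n_atoms != top.n_atoms:
        raise ValueError("start frame does not match topology")

    box = np.full(3, params.box_edge, dtype=np.float64)
    pos = np.mod(frame.coordinates.copy(), box)
    pep_idx = top.peptide_index.copy()
    if np.any(pep_idx < 0):
        raise ValueError("simulator expects a water-free bead topology")

    bonds = []
    for p in range(top.n_peptides):
        idx = top.peptide_atom_indices(p)
        for a, b in zip(idx[:-1], idx[1:]):
            bonds.append((a, b))
    bonds = np.asarray(bonds, dtype=np.int64).reshape(-1, 2)

    q = params.charge_per_bead
    qq = q * q * BJERRUM_LENGTH
    lam = params.screening_length
    rc = 2.5 * params.sigma
    mobility = params.diffusion_coeff * params.dt
    rng = np.random.default_rng(params.seed)

    frames = [Frame(time=0.0, coordinates=pos.copy(), box=box.copy())]
    step = 0
    while step < params.n_steps:
        chunk = min(params.save_interval, params.n_steps - step)
        noise = rng.standard_normal((chunk, top.n_atoms, 3))
        max_disp = _run_chunk(
            pos, noise, box, pep_idx,
            params.epsilon_attract, params.sigma ** 2, rc * rc,
            qq, 1.0 / lam, (6.0 * lam) ** 2, BOND_K, BOND_LENGTH, bonds,
            mobility, 0.1 * params.sigma,
        )
        if max_disp > params.box_edge / 2.0:
            raise RuntimeError(
                f"unstable integration: step displacement {max_disp:.1f} Å exceeds "
                f"half the box edge; reduce dt (currently {params.dt} ps)"
            )
        step += chunk
        if step % params.save_interval == 0 or step == params.n_steps:
            frames.append(
                Frame(time=step * params.dt, coordinates=pos.copy(), box=box.copy())
            )
    return Trajectory(top, frames)


_RING_ATOM_NAMES = ["CG", "CD1", "CE1", "CZ", "CE2", "CD2"]
#: hexagon vertex radius for a 1.40 Å edge (regular hexagon: radius = edge)
_RING_RADIUS = 1.40


def _hexagon(center: np.ndarray, normal: np.ndarray, phase: float = 0.0) -> np.ndarray:
    normal = normal / np.linalg.norm(normal)
    # orthonormal in-plane axes
    ref = np.array([1.0, 0.0, 0.0])
    if abs(normal @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(normal, ref)
    u /= np.linalg.norm(u)
    v = np.cross(normal, u)
    ang = phase + np.arange(6) * np.pi / 3.0
    return center + _RING_RADIUS * (np.outer(np.cos(ang), u) + np.outer(np.sin(ang), v))


def make_ring_pair(
    r_cen: float, theta: float, gamma: float, box_edge: float = 1000.0
) -> tuple[Frame, Topology]:
    """Two regular aromatic hexagons (edge 1.40 Å) at a prescribed geometry.

    ``r_cen`` is the centre–centre distance (Å); ``theta`` the angle between
    ring 1's normal and the centre–centre vector; ``gamma`` the angle
    between the two normals (both in degrees, folded into [0°, 90°]).
    """
    if r_cen <= 0:
        raise ValueError("r_cen must be > 0")
    if not (0 <= theta <= 90 and 0 <= gamma <= 90):
        raise ValueError("theta and gamma must lie in [0, 90] degrees")
    th = np.deg2rad(theta)
    gm = np.deg2rad(gamma)
    c1 = np.zeros(3)
    n1 = np.array([0.0, 0.0, 1.0])
    c2 = c1 + r_cen * np.array([np.sin(th), 0.0, np.cos(th)])
    n2 = np.array([np.sin(gm), 0.0, np.cos(gm)])

    shift = np.full(3, box_edge / 2.0)
    coords = np.vstack([_hexagon(c1, n1) + shift, _hexagon(c2, n2) + shift])
    atoms = []
    for ring, chain in enumerate("AB"):
        for k, name in enumerate(_RING_ATOM_NAMES):
            atoms.append(
                Atom(
                    atom_id=ring * 6 + k,
                    chain_id=chain,
                    residue_index=1,
                    residue_name="PHE",
                    atom_name=name,
                    role=AtomRole.SIDECHAIN,
                    element="C",
                    vdw_radius=1.70,
                )
            )
    frame = Frame(time=0.0, coordinates=coords, box=np.full(3, box_edge))
    return frame, Topology(atoms)


def make_cluster_with_waters(
    cluster_radius: float,
    n_cluster_atoms: int,
    n_waters_inside: int,
    n_waters_outside: int,
    seed: int = 0,
    box_edge: float | None = None,
) -> tuple[Frame, Topology]:
    """A spherical blob of peptide beads plus waters placed strictly inside
    (< 0.75 Rg of the blob's centre of gravity) or strictly outside.

    The constructed inside/outside split is exact ground truth for the
    buried-water counter.
    """
    if min(cluster_radius, n_cluster_atoms) <= 0:
        raise ValueError("need a positive cluster_radius and at least one cluster atom")
    if n_waters_inside < 0 or n_waters_outside < 0:
        raise ValueError("water counts must be >= 0")
    rng = np.random.default_rng(seed)
    if box_edge is None:
        box_edge = max(40.0, 10.0 * cluster_radius)

    def _uniform_ball(n: int, radius: float) -> np.ndarray:
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = radius * rng.random(n) ** (1 / 3)
        return v * r[:, None]

    center = np.full(3, box_edge / 2.0)
    cluster = center + _uniform_ball(n_cluster_atoms, cluster_radius)
    cog = cluster.mean(axis=0)
    rg = np.sqrt(np.mean(np.sum((cluster - cog) ** 2, axis=1)))
    r_in = 0.75 * rg

    def _shell(n: int, lo: float, hi: float) -> np.ndarray:
        v = rng.standard_normal((n, 3))
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        r = rng.uniform(lo, hi, size=n)
        return cog + v * r[:, None]

    inside = _shell(n_waters_inside, 0.0, 0.999 * r_in)
    hi = min(0.45 * box_edge, max(3.0 * r_in, r_in + 10.0))
    outside = _shell(n_waters_outside, 1.001 * r_in, hi)

    atoms = []
    for i in range(n_cluster_atoms):
        atoms.append(
            Atom(
                atom_id=i,
                chain_id="A",
                residue_index=i + 1,
                residue_name="BDS",
                atom_name="B1",
                role=AtomRole.SIDECHAIN,
                element="C",
                vdw_radius=BEAD_VDW_RADIUS,
            )
        )
    for w in range(n_waters_inside + n_waters_outside):
        atoms.append(
            Atom(
                atom_id=n_cluster_atoms + w,
                chain_id="W",
                residue_index=w + 1,
                residue_name="HOH",
                atom_name="OW",
                role=AtomRole.WATER,
                element="O",
                vdw_radius=1.52,
                is_donor=True,
                is_acceptor=True,
            )
        )
    coords = np.vstack([cluster, inside.reshape(-1, 3), outside.reshape(-1, 3)])
    frame = Frame(time=0.0, coordinates=coords, box=np.full(3, box_edge))
    return frame, Topology(atoms)


def mean_squared_displacement(traj: Trajectory, lag: int = 1) -> float:
    """MSD (Å²) at a frame lag, unwrapping through the minimum image.

    Valid while per-lag displacements stay below half the box edge, which
    holds for free diffusion over modest lags.
    """
    if lag < 1 or lag >= traj.n_frames:
        raise ValueError("lag must be in [1, n_frames)")
    box = traj.frames[0].box
    # unwrap frame-to-frame, then sum consecutive displacements per lag
    steps = [
        minimum_image(traj.frames[k + 1].coordinates - traj.frames[k].coordinates, box)
        for k in range(traj.n_frames - 1)
    ]
    steps = np.stack(steps)
    csum = np.cumsum(steps, axis=0)
    disp = np.concatenate([csum[lag - 1 : lag], csum[lag:] - csum[:-lag]], axis=0)
    return float(np.mean(np.sum(disp ** 2, axis=2)))
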