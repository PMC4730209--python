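"""Per-cluster geometric and energetic metrics.

Covers the radius of gyration and buried-water count of a peptide cluster,
geometric hydrogen-bond detection with peptide/water partner classes and
water-mediated bridges, aromatic ring-pair geometry (R_cen, theta, gamma)
with face-to-face / T-stack classification, and pairwise inter-peptide
Coulomb and 12-6 vdW energy sums.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .model import AtomRole, Frame, Topology, Trajectory, minimum_image

__all__ = [
    "radius_of_gyration",
    "buried_waters",
    "HBondCriteria",
    "HBond",
    "detect_hbonds",
    "water_mediated_bridges",
    "hbond_per_residue_table",
    "RingGeometry",
    "ring_geometry",
    "find_aromatic_rings",
    "stacking_census",
    "EnergyBreakdown",
    "interpeptide_energies",
    "assign_lj_params",
    "COULOMB_CONSTANT",
]

#: Coulomb prefactor giving kcal/mol from e² / Å
COULOMB_CONSTANT = 332.0636


def _unwrap_group(coords: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Make a compact group contiguous across periodic boundaries.

    Atoms are shifted by whole box vectors toward the first atom; valid for
    groups whose extent is below half the box edge.
    """
    ref = coords[0]
    return ref + minimum_image(coords - ref, box)


def radius_of_gyration(
    frame: Frame,
    atom_indices: np.ndarray | list[int],
    weights: np.ndarray | None = None,
) -> tuple[float, np.ndarray]:
    """Weighted radius of gyration (Å) and centre of gravity of an atom set.

    Weights default to unity (appropriate for coarse bead systems); pass
    masses for a mass-weighted centre.
    """
    idx = np.asarray(atom_indices)
    if idx.size == 0:
        raise ValueError("radius_of_gyration of an empty atom set")
    coords = _unwrap_group(frame.coordinates[idx], frame.box)
    w = np.ones(len(idx)) if weights is None else np.asarray(weights, dtype=float)
    center = (coords * w[:, None]).sum(axis=0) / w.sum()
    rg2 = (w * np.sum((coords - center) ** 2, axis=1)).sum() / w.sum()
    return float(np.sqrt(rg2)), center


def buried_waters(
    frame: Frame,
    topology: Topology,
    cluster: list[int | str],
    factor: float = 0.75,
) -> tuple[int, list[tuple[str, int]]]:
    """Count waters within ``factor`` × Rg of a cluster's centre of gravity.

    ``cluster`` lists peptide indices or chain ids; the water site is its
    oxygen (or sole) atom; distances use the minimum image.
    """
    if len(cluster) == 0:
        raise ValueError("cluster must contain at least one peptide")
    atom_idx = np.concatenate([topology.peptide_atom_indices(p) for p in cluster])
    rg, center = radius_of_gyration(frame, atom_idx)
    cutoff = factor * rg
    found: list[tuple[str, int]] = []
    for chain, res, widx in topology.water_residues():
        oxygens = [i for i in widx if topology.atoms[i].element == "O"]
        site = oxygens[0] if oxygens else widx[0]
        d = minimum_image(frame.coordinates[site] - center, frame.box)
        if np.linalg.norm(d) < cutoff:
            found.append((chain, res))
    return len(found), found


# ---------------------------------------------------------------------------
# hydrogen bonds

@dataclass(frozen=True)
class HBondCriteria:
    """Geometric H-bond thresholds (HBPLUS-like defaults)."""

    donor_acceptor_max: float = 3.5
    hydrogen_acceptor_max: float = 2.5
    angle_min: float = 90.0  # donor-H-acceptor, degrees
    covalent_h_max: float = 1.25  # H considered bonded to donor below this


@dataclass(frozen=True)
class HBond:
    donor: int
    acceptor: int
    hydrogen: int | None
    partner_class: str  # "P-P" or "P-W"
    chains: tuple[str, str]
    role_class: str | None  # "SC-SC" / "MC-MC" / "SC-MC" for P-P, else None


def _role_tag(role: AtomRole) -> str:
    # capping groups count with the mainchain
    return "SC" if role is AtomRole.SIDECHAIN else "MC"


def _pair_role_class(r1: AtomRole, r2: AtomRole) -> str:
    tags = sorted([_role_tag(r1), _role_tag(r2)])
    return "SC-MC" if tags == ["MC", "SC"] else f"{tags[0]}-{tags[0]}"


def detect_hbonds(
    frame: Frame,
    topology: Topology,
    criteria: HBondCriteria = HBondCriteria(),
) -> list[HBond]:
    """Geometric hydrogen bonds in one frame.

    A donor-acceptor pair (distinct residues) is a bond when the heavy-atom
    distance is within ``donor_acceptor_max`` and, whenever the donor
    carries an explicit hydrogen, some hydrogen also satisfies the
    H···acceptor distance and donor-H-acceptor angle.  Water-water pairs
    are not recorded; each bond is classed P-P or P-W.
    """
    atoms = topology.atoms
    coords = frame.coordinates
    box = frame.box
    donors = np.array([i for i, a in enumerate(atoms) if a.is_donor])
    acceptors = np.array([i for i, a in enumerate(atoms) if a.is_acceptor])
    if len(donors) == 0 or len(acceptors) == 0:
        return []

    hydrogens = np.array([i for i, a in enumerate(atoms) if a.element == "H"], dtype=int)
    h_of: dict[int, list[int]] = {int(d): [] for d in donors}
    if len(hydrogens):
        d_tree = cKDTree(np.mod(coords[donors], box), boxsize=box)
        h_pos = np.mod(coords[hydrogens], box)
        for hk, near in enumerate(d_tree.query_ball_point(h_pos, criteria.covalent_h_max)):
            for dk in near:
                h_of[int(donors[dk])].append(int(hydrogens[hk]))

    a_tree = cKDTree(np.mod(coords[acceptors], box), boxsize=box)
    d_tree = cKDTree(np.mod(coords[donors], box), boxsize=box)
    bonds: list[HBond] = []
    for dk, near in enumerate(
        d_tree.query_ball_tree(a_tree, criteria.donor_acceptor_max)
    ):
        d = int(donors[dk])
        ad, aa_ = atoms[d], None
        for ak in near:
            a = int(acceptors[ak])
            aa_ = atoms[a]
            if a == d:
                continue
            if (ad.chain_id, ad.residue_index) == (aa_.chain_id, aa_.residue_index):
                continue
            if ad.role is AtomRole.WATER and aa_.role is AtomRole.WATER:
                continue
            dvec = minimum_image(coords[a] - coords[d], box)
            if np.linalg.norm(dvec) >= criteria.donor_acceptor_max:
                continue
            h_used: int | None = None
            if h_of.get(d):
                ok = False
                for h in h_of[d]:
                    ha = np.linalg.norm(minimum_image(coords[a] - coords[h], box))
                    if ha > criteria.hydrogen_acceptor_max:
                        continue
                    v1 = minimum_image(coords[d] - coords[h], box)
                    v2 = minimum_image(coords[a] - coords[h], box)
                    cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
                    ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
                    if ang >= criteria.angle_min:
                        ok = True
                        h_used = h
                        break
                if not ok:
                    continue
            waterish = ad.role is AtomRole.WATER or aa_.role is AtomRole.WATER
            bonds.append(
                HBond(
                    donor=d,
                    acceptor=a,
                    hydrogen=h_used,
                    partner_class="P-W" if waterish else "P-P",
                    chains=(ad.chain_id, aa_.chain_id),
                    role_class=None if waterish else _pair_role_class(ad.role, aa_.role),
                )
            )
    return bonds


def water_mediated_bridges(
    hbonds: list[HBond], topology: Topology
) -> list[tuple[tuple[str, int], int, int, str]]:
    """P-W-P bridges: one water H-bonded to atoms on two different peptide
    chains.  Returns (water residue, peptide atom 1, peptide atom 2,
    role class) per bridge."""
    partners: dict[tuple[str, int], set[int]] = {}
    for hb in hbonds:
        if hb.partner_class != "P-W":
            continue
        da = topology.atoms[hb.donor]
        aa = topology.atoms[hb.acceptor]
        if da.role is AtomRole.WATER:
            wkey, patom = (da.chain_id, da.residue_index), hb.acceptor
        else:
            wkey, patom = (aa.chain_id, aa.residue_index), hb.donor
        partners.setdefault(wkey, set()).add(patom)
    bridges = []
    for wkey, atoms_set in sorted(partners.items()):
        alist = sorted(atoms_set)
        for i in range(len(alist)):
            for j in range(i + 1, len(alist)):
                a1, a2 = topology.atoms[alist[i]], topology.atoms[alist[j]]
                if a1.chain_id == a2.chain_id:
                    continue
                bridges.append(
                    (wkey, alist[i], alist[j], _pair_role_class(a1.role, a2.role))
                )
    return bridges


def hbond_per_residue_table(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    criteria: HBondCriteria = HBondCriteria(),
) -> pd.DataFrame:
    """Time-averaged H-bond counts per residue, split by partner and role.

    Rows SC-SC / MC-MC / SC-MC; columns P-P (inter-peptide, distinct
    chains), P-W, P-W-P.  The denominator is the total peptide residue
    count (peptides × residues per peptide, caps excluded).
    """
    top = traj.topology
    residues = {
        (a.chain_id, a.residue_index)
        for a in top.atoms
        if a.role in (AtomRole.MAINCHAIN, AtomRole.SIDECHAIN)
    }
    n_res = len(residues)
    if n_res == 0:
        raise ValueError("topology has no peptide residues")
    classes = ["SC-SC", "MC-MC", "SC-MC"]
    acc = {(rc, col): 0.0 for rc in classes for col in ("P-P", "P-W", "P-W-P")}
    frames = [
        f for f in traj.frames
        if window is None or window[0] <= f.time <= window[1]
    ]
    if not frames:
        raise ValueError("window selects no frames")
    for frame in frames:
        hbonds = detect_hbonds(frame, top, criteria)
        for hb in hbonds:
            if hb.partner_class == "P-P":
                if hb.chains[0] != hb.chains[1] and hb.role_class in classes:
                    acc[(hb.role_class, "P-P")] += 1
            else:
                da = top.atoms[hb.donor]
                aa = top.atoms[hb.acceptor]
                pep = aa if da.role is AtomRole.WATER else da
                acc[(_pair_role_class(pep.role, pep.role), "P-W")] += 1
        for _, _, _, rc in water_mediated_bridges(hbonds, top):
            if rc in classes:
                acc[(rc, "P-W-P")] += 1
    data = {
        col: [acc[(rc, col)] / len(frames) / n_res for rc in classes]
        for col in ("P-P", "P-W", "P-W-P")
    }
    return pd.DataFrame(data, index=classes)


# ---------------------------------------------------------------------------
# aromatic ring geometry

@dataclass(frozen=True)
class RingGeometry:
    r_cen: float
    theta: float  # degrees, folded into [0, 90]
    gamma: float  # degrees, folded into [0, 90]


def _ring_plane(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    center = coords.mean(axis=0)
    rel = coords - center
    _, s, vt = np.linalg.svd(rel)
    if len(s) < 3 or s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("ring atoms are collinear; no plane is defined")
    return center, vt[2]


def _fold(angle_deg: float) -> float:
    a = angle_deg % 180.0
    return 180.0 - a if a > 90.0 else a


def ring_geometry(
    frame: Frame, ring1: np.ndarray | list[int], ring2: np.ndarray | list[int]
) -> RingGeometry:
    """R_cen / theta / gamma descriptors of a ring pair.

    Centres are geometric; normals come from the SVD best-fit plane; theta
    is the angle between ring 1's normal and the centre–centre vector and
    gamma the angle between the two normals, both folded into [0°, 90°].
    """
    c1_raw = frame.coordinates[np.asarray(ring1)]
    c2_raw = frame.coordinates[np.asarray(ring2)]
    box = frame.box
    c1u = _unwrap_group(c1_raw, box)
    # bring ring 2 to ring 1's periodic image
    c2u = _unwrap_group(c2_raw, box)
    shift = minimum_image(c2u.mean(axis=0) - c1u.mean(axis=0), box) - (
        c2u.mean(axis=0) - c1u.mean(axis=0)
    )
    c2u = c2u + shift
    center1, n1 = _ring_plane(c1u)
    center2, n2 = _ring_plane(c2u)
    cc = center2 - center1
    r_cen = float(np.linalg.norm(cc))
    if r_cen < 1e-12:
        theta = 0.0
    else:
        cost = np.clip(n1 @ cc / r_cen, -1, 1)
        theta = _fold(float(np.degrees(np.arccos(cost))))
    cosg = np.clip(n1 @ n2, -1, 1)
    gamma = _fold(float(np.degrees(np.arccos(cosg))))
    return RingGeometry(r_cen=r_cen, theta=theta, gamma=gamma)


_RING_TEMPLATES = {
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TRP": ["CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
    "HIE": ["CG", "ND1", "CD2", "CE1", "NE2"],
    "HIP": ["CG", "ND1", "CD2", "CE1", "NE2"],
}


def find_aromatic_rings(topology: Topology) -> list[np.ndarray]:
    """Atom-index groups of aromatic sidechain rings, by residue."""
    groups: dict[tuple[str, int], dict[str, int]] = {}
    for i, a in enumerate(topology.atoms):
        if a.residue_name.upper() in _RING_TEMPLATES:
            groups.setdefault((a.chain_id, a.residue_index), {})[a.atom_name.upper()] = i
    rings = []
    for (chain, res), name_map in sorted(groups.items()):
        template = _RING_TEMPLATES[
            topology.atoms[next(iter(name_map.values()))].residue_name.upper()
        ]
        if all(n in name_map for n in template):
            rings.append(np.array([name_map[n] for n in template]))
    return rings


def stacking_census(
    traj: Trajectory,
    window: tuple[float, float] | None = None,
    r_cen_max: float = 5.5,
    face_angle_max: float = 30.0,
    t_stack_gamma_min: float = 60.0,
    rings: list[np.ndarray] | None = None,
) -> pd.DataFrame:
    """Classify close aromatic ring pairs per frame.

    Pairs with R_cen below ``r_cen_max`` are face-to-face when both gamma
    and theta stay within ``face_angle_max``, T-stacked when gamma exceeds
    ``t_stack_gamma_min``, and "other" in between.
    """
    if rings is None:
        rings = find_aromatic_rings(traj.topology)
    rows = []
    for frame in traj.frames:
        if window is not None and not (window[0] <= frame.time <= window[1]):
            continue
        face = tstack = other = 0
        for i in range(len(rings)):
            for j in range(i + 1, len(rings)):
                geom = ring_geometry(frame, rings[i], rings[j])
                if geom.r_cen >= r_cen_max:
                    continue
                if geom.gamma <= face_angle_max and geom.theta <= face_angle_max:
                    face += 1
                elif geom.gamma >= t_stack_gamma_min:
                    tstack += 1
                else:
                    other += 1
        rows.append(
            {"time": frame.time, "face_to_face": face, "t_stack": tstack, "other": other}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# inter-peptide energies

@dataclass
class EnergyBreakdown:
    pairs: pd.DataFrame  # peptide_i, peptide_j, coulomb, vdw (kcal/mol)
    coulomb_total: float
    vdw_total: float
    dielectric: float


def assign_lj_params(topology: Topology, epsilon: float, sigma: float) -> Topology:
    """Copy of a topology with uniform per-atom 12-6 parameters."""
    return Topology([replace(a, lj_epsilon=epsilon, lj_sigma=sigma) for a in topology.atoms])


def interpeptide_energies(
    frame: Frame,
    topology: Topology,
    dielectric: float = 1.0,
    include_vdw: bool = True,
) -> EnergyBreakdown:
    """Pairwise inter-peptide Coulomb and 12-6 vdW energy sums (kcal/mol).

    Coulomb: 332.0636 q_a q_b / (ε r) per atom pair.  vdW: 4 ε_ab
    [(σ_ab/r)^12 − (σ_ab/r)^6] with Lorentz-Berthelot combination; requires
    per-atom LJ parameters.  Minimum-image distances, no cutoff, waters
    excluded, intra-peptide pairs excluded.
    """
    top = topology
    sel = np.nonzero(~top.is_water)[0]
    if include_vdw:
        missing = [
            top.atoms[i].atom_id
            for i in sel
            if top.atoms[i].lj_epsilon is None or top.atoms[i].lj_sigma is None
        ]
        if missing:
            raise ValueError(
                f"{len(missing)} atoms lack LJ parameters (e.g. atom ids {missing[:5]}); "
                "assign_lj_params() or load a parameter set first"
            )
        lj_eps = np.array([top.atoms[i].lj_epsilon for i in sel])
        lj_sig = np.array([top.atoms[i].lj_sigma for i in sel])
    q = top.charges[sel]
    pep = top.peptide_index[sel]
    coords = frame.coordinates[sel]
    box = frame.box

    n_pep = top.n_peptides
    coul = np.zeros((n_pep, n_pep))
    vdw = np.zeros((n_pep, n_pep))
    iu, ju = np.triu_indices(len(sel), k=1)
    inter = pep[iu] != pep[ju]
    iu, ju = iu[inter], ju[inter]
    d = minimum_image(coords[iu] - coords[ju], box)
    r = np.linalg.norm(d, axis=1)
    e_c = COULOMB_CONSTANT * q[iu] * q[ju] / (dielectric * r)
    np.add.at(coul, (np.minimum(pep[iu], pep[ju]), np.maximum(pep[iu], pep[ju])), e_c)
    if include_vdw:
        eps_ab = np.sqrt(lj_eps[iu] * lj_eps[ju])
        sig_ab = 0.5 * (lj_sig[iu] + lj_sig[ju])
        sr6 = (sig_ab / r) ** 6
        e_v = 4.0 * eps_ab * (sr6 ** 2 - sr6)
        np.add.at(vdw, (np.minimum(pep[iu], pep[ju]), np.maximum(pep[iu], pep[ju])), e_v)

    rows = []
    for i in range(n_pep):
        for j in range(i + 1, n_pep):
            if coul[i, j] != 0.0 or vdw[i, j] != 0.0:
                rows.append(
                    {
                        "peptide_i": top.peptide_ids[i],
                        "peptide_j": top.peptide_ids[j],
                        "coulomb": coul[i, j],
                        "vdw": vdw[i, j],
                    }
                )
    pairs = pd.DataFrame(rows, columns=["peptide_i", "peptide_j", "coulomb", "vdw"])
    return EnergyBreakdown(
        pairs=pairs,
        coulomb_total=float(coul.sum()),
        vdw_total=float(vdw.sum()),
        dielectric=dielectric,
    )
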