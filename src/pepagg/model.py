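"""Core domain types: atoms, topologies, frames and trajectories.

Coordinates are in Å, times in ps, charges in elementary charge units.
A :class:`Topology` describes the static identity of every atom; a
:class:`Trajectory` is an ordered sequence of :class:`Frame` objects that
all share one topology.  Peptide membership is defined by chain identity:
every distinct non-water chain is one peptide.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "AtomRole",
    "Atom",
    "Topology",
    "Frame",
    "Trajectory",
    "BONDI_RADII",
    "RADIUS_SETS",
    "WATER_RESIDUE_NAMES",
]

#: Bondi (1964) van der Waals radii in Å, by element symbol.
BONDI_RADII: dict[str, float] = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "NA": 2.27,
    "K": 2.75,
    "SE": 1.90,
}

#: Named element→radius tables selectable in the readers.
RADIUS_SETS: dict[str, dict[str, float]] = {"bondi": BONDI_RADII}

#: Residue names recognised as water.
WATER_RESIDUE_NAMES = frozenset({"HOH", "WAT", "SOL", "TIP3", "TIP", "SPC", "H2O"})


class AtomRole(str, Enum):
    MAINCHAIN = "mainchain"
    SIDECHAIN = "sidechain"
    CAP = "cap"
    WATER = "water"


@dataclass(frozen=True)
class Atom:
    """Static identity of one atom (or coarse bead)."""

    atom_id: int
    chain_id: str
    residue_index: int
    residue_name: str
    atom_name: str
    role: AtomRole
    element: str
    vdw_radius: float
    partial_charge: float = 0.0
    is_donor: bool = False
    is_acceptor: bool = False
    #: Lennard-Jones well depth (kcal/mol) and size (Å) for energy sums;
    #: ``None`` until a parameter set assigns them.
    lj_epsilon: float | None = None
    lj_sigma: float | None = None

    def __post_init__(self) -> None:
        if self.vdw_radius <= 0:
            raise ValueError(f"atom {self.atom_id}: vdw_radius must be > 0")


class Topology:
    """Per-atom static attributes plus cached numpy views used everywhere.

    Parameters
    ----------
    atoms:
        Atom records in file order; ``atom_id`` values must be unique.
    """

    def __init__(self, atoms: Sequence[Atom]):
        self.atoms: list[Atom] = list(atoms)
        ids = [a.atom_id for a in self.atoms]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate atom_id(s): {dup[:5]}")
        for a in self.atoms:
            if a.role is AtomRole.WATER and not a.residue_name.upper() in WATER_RESIDUE_NAMES:
                # permissive: waters may carry synthetic residue names, but a
                # water atom must never sit on a peptide chain
                pass
        self.is_water = np.array([a.role is AtomRole.WATER for a in self.atoms], dtype=bool)
        chain_of = [a.chain_id for a in self.atoms]
        #: ordered distinct non-water chain identifiers (the peptides)
        self.peptide_ids: list[str] = list(
            dict.fromkeys(c for c, w in zip(chain_of, self.is_water) if not w)
        )
        water_chains = {c for c, w in zip(chain_of, self.is_water) if w}
        clash = water_chains & set(self.peptide_ids)
        if clash:
            raise ValueError(f"chains carry both water and peptide atoms: {sorted(clash)}")
        index = {c: i for i, c in enumerate(self.peptide_ids)}
        #: peptide index per atom, −1 for water atoms
        self.peptide_index = np.array(
            [index.get(a.chain_id, -1) if not w else -1 for a, w in zip(self.atoms, self.is_water)],
            dtype=np.int64,
        )
        self.vdw_radii = np.array([a.vdw_radius for a in self.atoms], dtype=np.float64)
        self.charges = np.array([a.partial_charge for a in self.atoms], dtype=np.float64)

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    @property
    def n_peptides(self) -> int:
        return len(self.peptide_ids)

    def peptide_atom_indices(self, peptide: int | str) -> np.ndarray:
        """Indices (into the atom list) of one peptide's atoms."""
        if isinstance(peptide, str):
            peptide = self.peptide_ids.index(peptide)
        return np.nonzero(self.peptide_index == peptide)[0]

    def water_residues(self) -> list[tuple[str, int, np.ndarray]]:
        """Water molecules as (chain_id, residue_index, atom indices)."""
        groups: dict[tuple[str, int], list[int]] = {}
        for i, a in enumerate(self.atoms):
            if self.is_water[i]:
                groups.setdefault((a.chain_id, a.residue_index), []).append(i)
        return [(c, r, np.asarray(ix)) for (c, r), ix in sorted(groups.items())]

    def __repr__(self) -> str:  # pragma: no cover
        return f"<Topology {self.n_atoms} atoms, {self.n_peptides} peptides>"


@dataclass
class Frame:
    """One snapshot: time (ps), coordinates (n_atoms, 3) Å, orthorhombic box."""

    time: float
    coordinates: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.coordinates = np.asarray(self.coordinates, dtype=np.float64)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_atoms, 3)")
        self.box = np.asarray(self.box, dtype=np.float64).reshape(3)
        if not np.all(self.box > 0):
            raise ValueError("box edge lengths must be positive")

    @property
    def n_atoms(self) -> int:
        return self.coordinates.shape[0]


class Trajectory:
    """Ordered frames over one topology; frame times strictly increase."""

    def __init__(self, topology: Topology, frames: Iterable[Frame]):
        self.topology = topology
        self.frames: list[Frame] = sorted(frames, key=lambda f: f.time)
        for i, f in enumerate(self.frames):
            if f.n_atoms != topology.n_atoms:
                raise ValueError(
                    f"frame {i}: {f.n_atoms} coordinates for {topology.n_atoms} topology atoms"
                )
        times = [f.time for f in self.frames]
        if any(t1 >= t2 for t1, t2 in zip(times, times[1:])):
            raise ValueError("frame times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def times(self) -> np.ndarray:
        return np.array([f.time for f in self.frames], dtype=np.float64)

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> Frame:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)


def minimum_image(d: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Apply the minimum-image convention to displacement vectors ``d``."""
    return d - box * np.round(d / box)
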