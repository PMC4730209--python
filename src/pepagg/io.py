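"""Readers and writers: PDB (single- and multi-model), extended XYZ, CSV.

PDB files are parsed and emitted through biotite; the extended-XYZ dialect
used here carries the frame time on the comment line as ``t=<ps>`` and the
periodic box as ``box="lx ly lz"``, e.g.::

    4
    t=10.0 box="100.0 100.0 100.0"
    C 1.0 0.0 0.0
    ...

Roles are inferred from atom and residue names: backbone atom names map to
``mainchain``, capping residues (ACE/NME/NMA) to ``cap``, water residues to
``water`` and everything else to ``sidechain``.  Donor/acceptor flags use an
element-level heuristic (N donates, O accepts, hydroxyl and water oxygens do
both) that suffices for geometric hydrogen-bond counting.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from .model import (
    Atom,
    AtomRole,
    Frame,
    RADIUS_SETS,
    Topology,
    Trajectory,
    WATER_RESIDUE_NAMES,
)

__all__ = [
    "load_topology",
    "load_trajectory",
    "write_trajectory",
    "write_timeseries",
    "load_charge_table",
]

_MAINCHAIN_NAMES = {"N", "CA", "C", "O", "H", "HN", "HA", "OXT", "H1", "H2", "H3"}
_CAP_RESIDUES = {"ACE", "NME", "NMA"}
_HYDROXYL_NAMES = {"OG", "OG1", "OH", "OW"}


def _infer_role(atom_name: str, residue_name: str) -> AtomRole:
    residue_name = residue_name.upper()
    if residue_name in WATER_RESIDUE_NAMES:
        return AtomRole.WATER
    if residue_name in _CAP_RESIDUES:
        return AtomRole.CAP
    if atom_name.upper() in _MAINCHAIN_NAMES:
        return AtomRole.MAINCHAIN
    return AtomRole.SIDECHAIN


def _donor_acceptor(element: str, atom_name: str, role: AtomRole) -> tuple[bool, bool]:
    element = element.upper()
    if role is AtomRole.WATER:
        if element == "O":
            return True, True
        return False, False
    if element == "N":
        return True, True
    if element == "O":
        donor = atom_name.upper() in _HYDROXYL_NAMES
        return donor, True
    return False, False


def load_charge_table(path: str | os.PathLike) -> dict[tuple[str, str], float]:
    """Read a TSV of (atom_name, residue_name, charge) into a lookup dict."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"atom_name", "residue_name", "charge"}
    if not required.issubset(df.columns):
        raise ValueError(f"charge table needs columns {sorted(required)}")
    return {
        (str(r.atom_name).upper(), str(r.residue_name).upper()): float(r.charge)
        for r in df.itertuples()
    }


def load_topology(
    structure_file: str | os.PathLike,
    radius_set: str = "bondi",
    charge_table: str | os.PathLike | None = None,
) -> Topology:
    """Build a :class:`Topology` from the first model of a PDB file.

    Every atom receives a positive vdW radius from the named element table;
    an element absent from the table is a hard error naming the atom.
    """
    try:
        radii = RADIUS_SETS[radius_set]
    except KeyError:
        raise ValueError(f"unknown radius_set {radius_set!r}; have {sorted(RADIUS_SETS)}")
    charges = load_charge_table(charge_table) if charge_table is not None else {}

    pdb = PDBFile.read(str(structure_file))
    arr = pdb.get_structure(model=1)
    atoms: list[Atom] = []
    for i in range(arr.array_length()):
        name = str(arr.atom_name[i]).strip()
        res = str(arr.res_name[i]).strip()
        element = str(arr.element[i]).strip().upper()
        if not element:
            element = name[0].upper()
        role = _infer_role(name, res)
        if element not in radii:
            raise ValueError(
                f"atom {i} ({name} in {res}): element {element!r} has no radius "
                f"in set {radius_set!r}"
            )
        donor, acceptor = _donor_acceptor(element, name, role)
        atoms.append(
            Atom(
                atom_id=i,
                chain_id=str(arr.chain_id[i]).strip() or "A",
                residue_index=int(arr.res_id[i]),
                residue_name=res,
                atom_name=name,
                role=role,
                element=element,
                vdw_radius=radii[element],
                partial_charge=charges.get((name.upper(), res.upper()), 0.0),
                is_donor=donor,
                is_acceptor=acceptor,
            )
        )
    return Topology(atoms)


def _pdb_frames(
    path: str | os.PathLike, default_box: np.ndarray | None
) -> tuple[list[np.ndarray], np.ndarray]:
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure()
    if isinstance(stack, struc.AtomArray):  # single model
        coords = [stack.coord]
        box_mat = stack.box
    else:
        coords = [stack.coord[m] for m in range(stack.stack_depth())]
        box_mat = stack.box[0] if stack.box is not None else None
    if box_mat is not None:
        box = np.diag(np.asarray(box_mat))
    elif default_box is not None:
        box = np.asarray(default_box, dtype=np.float64)
    else:
        raise ValueError(f"{path}: no CRYST1 box record and no box= override given")
    return [np.asarray(c, dtype=np.float64) for c in coords], box


def _read_xyz(path: str | os.PathLike) -> list[tuple[float | None, np.ndarray, np.ndarray | None]]:
    frames = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            time = None
            box = None
            for token in comment.replace('"', " ").split():
                if token.startswith("t="):
                    time = float(token[2:])
            if 'box="' in comment:
                inner = comment.split('box="', 1)[1].split('"', 1)[0]
                box = np.array([float(x) for x in inner.split()])
            coords = np.empty((n, 3))
            for i in range(n):
                parts = fh.readline().split()
                coords[i] = [float(x) for x in parts[1:4]]
            frames.append((time, coords, box))
    return frames


def load_trajectory(
    topology: Topology,
    coord_files: Sequence[str | os.PathLike] | str | os.PathLike,
    format: str | None = None,
    default_interval: float = 10.0,
    box: Sequence[float] | None = None,
) -> Trajectory:
    """Read one or more coordinate files into a :class:`Trajectory`.

    Frames lacking time metadata (all PDB frames, XYZ frames without a
    ``t=`` tag) are assigned sequential times at ``default_interval`` ps.
    Frames with explicit times are sorted by time.
    """
    if isinstance(coord_files, (str, os.PathLike)):
        coord_files = [coord_files]
    default_box = None if box is None else np.asarray(box, dtype=np.float64)

    raw: list[tuple[float | None, np.ndarray, np.ndarray | None]] = []
    for path in coord_files:
        fmt = format or ("xyz" if str(path).endswith((".xyz", ".extxyz")) else "pdb")
        if fmt == "pdb":
            coords_list, file_box = _pdb_frames(path, default_box)
            raw.extend((None, c, file_box) for c in coords_list)
        elif fmt == "xyz":
            raw.extend(_read_xyz(path))
        else:
            raise ValueError(f"unknown trajectory format {fmt!r}")

    frames = []
    for k, (time, coords, fbox) in enumerate(raw):
        if coords.shape[0] != topology.n_atoms:
            raise ValueError(
                f"frame {k}: {coords.shape[0]} atoms, topology has {topology.n_atoms}"
            )
        use_box = fbox if fbox is not None else default_box
        if use_box is None:
            raise ValueError(f"frame {k}: no box information available")
        frames.append(
            Frame(
                time=time if time is not None else k * default_interval,
                coordinates=coords,
                box=use_box,
            )
        )
    return Trajectory(topology, frames)


def write_trajectory(
    traj: Trajectory,
    out: str | os.PathLike,
    format: str | None = None,
) -> None:
    """Write a trajectory as multi-model PDB or extended XYZ."""
    out = Path(out)
    fmt = format or ("xyz" if out.suffix in {".xyz", ".extxyz"} else "pdb")
    top = traj.topology
    if fmt == "xyz":
        with open(out, "w") as fh:
            for f in traj.frames:
                fh.write(f"{top.n_atoms}\n")
                bx = " ".join(f"{b:.6f}" for b in f.box)
                fh.write(f't={f.time:.6f} box="{bx}"\n')
                for a, xyz in zip(top.atoms, f.coordinates):
                    fh.write(
                        f"{a.element} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}\n"
                    )
        return
    if fmt != "pdb":
        raise ValueError(f"unknown trajectory format {fmt!r}")

    arr = struc.AtomArray(top.n_atoms)
    arr.chain_id = np.array([a.chain_id[:4] for a in top.atoms])
    arr.res_id = np.array([a.residue_index for a in top.atoms])
    arr.res_name = np.array([a.residue_name[:5] for a in top.atoms])
    arr.atom_name = np.array([a.atom_name[:6] for a in top.atoms])
    arr.element = np.array([a.element for a in top.atoms])
    arr.hetero = np.array([a.role is AtomRole.WATER for a in top.atoms])
    coords = np.stack([f.coordinates for f in traj.frames])
    stack = struc.from_template(arr, coords.astype(np.float32))
    stack.box = np.stack([np.diag(traj.frames[0].box.astype(np.float32))] * traj.n_frames)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(out))


def write_timeseries(table: pd.DataFrame, out: str | os.PathLike) -> None:
    """Write a labeled time series as CSV (time column first, ps units)."""
    if table.shape[1] == 0 or (table.shape[1] == 1 and "time" in table.columns):
        raise ValueError("time series table has no metric columns")
    cols = list(table.columns)
    if "time" in cols:
        cols = ["time"] + [c for c in cols if c != "time"]
    table[cols].to_csv(out, index=False, float_format="%.8g")
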