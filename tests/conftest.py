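"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from pepagg.model import Atom, AtomRole, Frame, Topology


def brute_force_components(adjacency: np.ndarray) -> np.ndarray:
    """Reference connected components by transitive closure (O(n^3))."""
    n = adjacency.shape[0]
    reach = adjacency.astype(bool) | np.eye(n, dtype=bool)
    for _ in range(n):
        reach = reach | (reach @ reach)
    labels = np.full(n, -1)
    nxt = 0
    for i in range(n):
        if labels[i] == -1:
            labels[reach[i]] = nxt
            nxt += 1
    return labels


def brute_force_contacts(frame: Frame, top: Topology, padding: float, min_pairs: int) -> np.ndarray:
    """Reference peptide adjacency by an explicit double loop over atoms."""
    n = top.n_peptides
    box = frame.box
    counts = np.zeros((n, n), dtype=int)
    sel = np.nonzero(~top.is_water)[0]
    for ai in sel:
        for aj in sel:
            pi, pj = top.peptide_index[ai], top.peptide_index[aj]
            if ai >= aj or pi == pj:
                continue
            d = frame.coordinates[ai] - frame.coordinates[aj]
            d -= box * np.round(d / box)
            if np.linalg.norm(d) < top.vdw_radii[ai] + top.vdw_radii[aj] + padding:
                counts[pi, pj] += 1
                counts[pj, pi] += 1
    return counts >= min_pairs


def point_topology(n_chains: int, radius: float = 1.70, charge: float = 0.0) -> Topology:
    """One single-atom peptide per chain; the smallest usable topology."""
    return Topology(
        [
            Atom(
                atom_id=i,
                chain_id=f"c{i}",
                residue_index=1,
                residue_name="BDS",
                atom_name="B1",
                role=AtomRole.SIDECHAIN,
                element="C",
                vdw_radius=radius,
                partial_charge=charge,
            )
            for i in range(n_chains)
        ]
    )


TOY_PDB = """\
CRYST1  100.000  100.000  100.000  90.00  90.00  90.00 P 1           1
ATOM      1  N   ALA A   1      10.000  10.000  10.000  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.400  10.000  10.000  1.00  0.00           C
ATOM      3  CB  ALA A   1      12.000  11.200  10.000  1.00  0.00           C
ATOM      4  CA  ALA B   1      20.000  10.000  10.000  1.00  0.00           C
END
"""

WATER_PDB = """\
CRYST1   50.000   50.000   50.000  90.00  90.00  90.00 P 1           1
HETATM    1  O   HOH W   1      10.000  10.000  10.000  1.00  0.00           O
HETATM    2  H1  HOH W   1      10.960  10.000  10.000  1.00  0.00           H
HETATM    3  H2  HOH W   1       9.700  10.930  10.000  1.00  0.00           H
END
"""


@pytest.fixture
def toy_pdb(tmp_path):
    path = tmp_path / "toy.pdb"
    path.write_text(TOY_PDB)
    return path


@pytest.fixture
def water_pdb(tmp_path):
    path = tmp_path / "water.pdb"
    path.write_text(WATER_PDB)
    return path
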