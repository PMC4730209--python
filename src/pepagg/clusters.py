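"""vdW-contact clustering of peptides and mean-cluster-size statistics.

Two peptides are in contact when at least ``min_pairs`` inter-chain atom
pairs sit closer (strict ``<``, minimum image) than the sum of their vdW
radii plus ``padding``.  Clusters are the connected components of the
resulting peptide contact graph.  For a frame with per-peptide cluster
sizes CS_i the mean cluster size is

    MCS = (sum_i CS_i) / N  =  (sum_clusters s^2) / N

which runs from 1 (all monomers) to N (a single cluster of all peptides).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .model import Frame, Topology, Trajectory

__all__ = [
    "ContactSpec",
    "ClusterLabeling",
    "contact_graph",
    "cluster_sizes",
    "analyze_trajectory",
    "window_average",
    "parameter_sweep",
]


@dataclass(frozen=True)
class ContactSpec:
    """Contact criterion: threshold padding (Å) and required atom-pair count."""

    padding: float = 0.0
    min_pairs: int = 1

    def __post_init__(self) -> None:
        if self.padding < 0:
            raise ValueError("padding must be >= 0")
        if self.min_pairs < 1:
            raise ValueError("min_pairs must be >= 1")


def contact_graph(
    frame: Frame, topology: Topology, spec: ContactSpec = ContactSpec()
) -> np.ndarray:
    """Symmetric, irreflexive peptide adjacency matrix (N × N bool).

    Water atoms never contribute.  Neighbour candidates come from a periodic
    k-d tree queried at the largest possible threshold; each candidate pair
    is then checked against its own radius sum.
    """
    n_pep = topology.n_peptides
    adj = np.zeros((n_pep, n_pep), dtype=bool)
    sel = np.nonzero(~topology.is_water)[0]
    if n_pep < 2 or len(sel) == 0:
        return adj
    box = frame.box
    coords = np.mod(frame.coordinates[sel], box)
    # cKDTree requires points strictly inside [0, box)
    coords = np.where(coords >= box, 0.0, coords)
    radii = topology.vdw_radii[sel]
    pep = topology.peptide_index[sel]
    r_max = 2.0 * radii.max() + spec.padding
    tree = cKDTree(coords, boxsize=box)
    pairs = tree.query_pairs(r=r_max, output_type="ndarray")
    if len(pairs) == 0:
        return adj
    i, j = pairs[:, 0], pairs[:, 1]
    inter = pep[i] != pep[j]
    i, j = i[inter], j[inter]
    d = coords[i] - coords[j]
    d -= box * np.round(d / box)
    dist = np.linalg.norm(d, axis=1)
    hit = dist < radii[i] + radii[j] + spec.padding
    pi, pj = pep[i[hit]], pep[j[hit]]
    if len(pi) == 0:
        return adj
    lo, hi = np.minimum(pi, pj), np.maximum(pi, pj)
    keys, counts = np.unique(lo * n_pep + hi, return_counts=True)
    good = counts >= spec.min_pairs
    lo, hi = keys[good] // n_pep, keys[good] % n_pep
    adj[lo, hi] = True
    adj[hi, lo] = True
    return adj


def cluster_sizes(adjacency: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Connected-component labels and per-peptide cluster sizes CS_i."""
    n = adjacency.shape[0]
    if n == 0:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    graph = coo_matrix(adjacency)
    _, labels = connected_components(graph, directed=False)
    sizes = np.bincount(labels)
    return labels.astype(np.int64), sizes[labels].astype(np.int64)


@dataclass
class ClusterLabeling:
    """Per-frame cluster assignment and the derived aggregation series."""

    times: np.ndarray
    labels: np.ndarray  # (n_frames, N) component id per peptide
    cs: np.ndarray      # (n_frames, N) cluster size per peptide
    n_peptides: int
    peptide_ids: list[str] = field(default_factory=list)

    @property
    def mcs_series(self) -> np.ndarray:
        return self.cs.mean(axis=1)

    @property
    def monomer_series(self) -> np.ndarray:
        return (self.cs == 1).sum(axis=1)

    @property
    def monomer_dimer_series(self) -> np.ndarray:
        return (self.cs <= 2).sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "mcs": self.mcs_series,
                "monomers": self.monomer_series,
                "monomers_dimers": self.monomer_dimer_series,
            }
        )


def analyze_trajectory(
    traj: Trajectory, spec: ContactSpec = ContactSpec()
) -> ClusterLabeling:
    """Apply the contact criterion and component labelling to every frame."""
    if traj.n_frames < 1:
        raise ValueError("trajectory has no frames")
    n = traj.topology.n_peptides
    labels = np.zeros((traj.n_frames, n), dtype=np.int64)
    cs = np.zeros((traj.n_frames, n), dtype=np.int64)
    for k, frame in enumerate(traj.frames):
        adj = contact_graph(frame, traj.topology, spec)
        labels[k], cs[k] = cluster_sizes(adj)
    return ClusterLabeling(
        times=traj.times,
        labels=labels,
        cs=cs,
        n_peptides=n,
        peptide_ids=list(traj.topology.peptide_ids),
    )


def window_average(
    labeling: ClusterLabeling, t_start: float, t_end: float
) -> tuple[float, float]:
    """Mean MCS and mean monomer count over frames with t_start ≤ t ≤ t_end."""
    mask = (labeling.times >= t_start) & (labeling.times <= t_end)
    if not mask.any():
        raise ValueError(f"no frames in window [{t_start}, {t_end}] ps")
    return (
        float(labeling.mcs_series[mask].mean()),
        float(labeling.monomer_series[mask].mean()),
    )


def last_fraction_window(labeling: ClusterLabeling, fraction: float = 0.1) -> tuple[float, float]:
    """Time window covering the trailing ``fraction`` of the trajectory."""
    t0, t1 = float(labeling.times[0]), float(labeling.times[-1])
    return t1 - fraction * (t1 - t0), t1


def parameter_sweep(
    traj: Trajectory,
    paddings: list[float] = (0.0, 0.7, 1.4, 2.1, 2.8),
    pair_counts: list[int] = (1, 2, 3),
    window_fraction: float = 0.1,
) -> pd.DataFrame:
    """Robustness sweep of the contact criterion.

    Returns one row per (padding, min_pairs) with the final and
    window-averaged MCS, plus the full per-frame MCS series attached in the
    ``labeling`` column for monotonicity checks.
    """
    if not len(paddings) or not len(pair_counts):
        raise ValueError("padding and pair-count grids must be non-empty")
    rows = []
    for pad in paddings:
        for mp in pair_counts:
            lab = analyze_trajectory(traj, ContactSpec(padding=pad, min_pairs=mp))
            t0, t1 = last_fraction_window(lab, window_fraction)
            avg_mcs, avg_mono = window_average(lab, t0, t1)
            rows.append(
                {
                    "padding": pad,
                    "min_pairs": mp,
                    "final_mcs": float(lab.mcs_series[-1]),
                    "window_mcs": avg_mcs,
                    "window_monomers": avg_mono,
                    "labeling": lab,
                }
            )
    return pd.DataFrame(rows)
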