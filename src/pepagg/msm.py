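"""Markov state model over cluster-size states 1..N.

The transition count matrix T(i, j) counts peptides whose cluster size is
i at frame t and j at frame t+lag, summed over all peptides and all valid
t in the build window.  Row-normalising T gives the row-stochastic P;
populations propagate as pi(n) = pi(0) P^n.  States never visited get a
self-transition of 1 so that P stays stochastic without inventing
dynamics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .clusters import ClusterLabeling

__all__ = [
    "MSMModel",
    "count_transitions",
    "transition_matrix",
    "propagate",
    "build_msm",
]


@dataclass
class MSMModel:
    states: np.ndarray        # cluster sizes 1..N
    counts: np.ndarray        # N x N integer transition counts
    P: np.ndarray             # N x N row-stochastic matrix
    lag: int
    build_window: tuple[float, float]

    def to_dict(self) -> dict:
        return {
            "states": self.states.tolist(),
            "counts": self.counts.tolist(),
            "P": self.P.tolist(),
            "lag": self.lag,
            "build_window": list(self.build_window),
        }


def count_transitions(
    labeling: ClusterLabeling,
    lag: int = 1,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """N × N transition count matrix at a frame lag within a time window."""
    if lag < 1:
        raise ValueError("lag must be >= 1")
    times = labeling.times
    if window is None:
        mask = np.ones(len(times), dtype=bool)
    else:
        mask = (times >= window[0]) & (times <= window[1])
    idx = np.nonzero(mask)[0]
    if len(idx) < lag + 1:
        raise ValueError(
            f"window holds {len(idx)} frames; need at least lag+1 = {lag + 1}"
        )
    n = labeling.n_peptides
    T = np.zeros((n, n), dtype=np.int64)
    src = labeling.cs[idx[:-lag]].ravel() - 1
    dst = labeling.cs[idx[lag:]].ravel() - 1
    np.add.at(T, (src, dst), 1)
    return T


def transition_matrix(T: np.ndarray) -> np.ndarray:
    """Row-normalise a count matrix; unvisited states self-transition."""
    T = np.asarray(T, dtype=np.float64)
    if np.any(T < 0):
        raise ValueError("transition counts must be non-negative")
    row = T.sum(axis=1)
    P = np.where(row[:, None] > 0, T / np.where(row[:, None] > 0, row[:, None], 1.0), 0.0)
    for k in np.nonzero(row == 0)[0]:
        P[k, k] = 1.0
    return P


def propagate(P: np.ndarray, pi0: np.ndarray, n_steps: int) -> np.ndarray:
    """Population sequence pi(0..n); each row sums to 1.

    ``pi0`` must be normalised to 1 within 1e-6.
    """
    P = np.asarray(P, dtype=np.float64)
    pi0 = np.asarray(pi0, dtype=np.float64)
    if abs(pi0.sum() - 1.0) > 1e-6:
        raise ValueError(f"pi0 sums to {pi0.sum():.8f}, not 1")
    if P.shape[0] != P.shape[1] or len(pi0) != P.shape[0]:
        raise ValueError("dimension mismatch between P and pi0")
    out = np.empty((n_steps + 1, len(pi0)))
    out[0] = pi0
    for k in range(1, n_steps + 1):
        out[k] = out[k - 1] @ P
    return out


def empirical_distribution(labeling: ClusterLabeling, frame_index: int = 0) -> np.ndarray:
    """Observed cluster-size-state distribution of one frame."""
    n = labeling.n_peptides
    counts = np.bincount(labeling.cs[frame_index] - 1, minlength=n)
    return counts / counts.sum()


def build_msm(
    labeling: ClusterLabeling,
    lag: int = 1,
    window: tuple[float, float] | None = None,
    window_fraction: float = 0.2,
) -> MSMModel:
    """Convenience builder: counts in the leading ``window_fraction`` of the
    trajectory (mirroring a transition matrix fit to the early aggregation
    phase) unless an absolute window is given."""
    if window is None:
        t0, t1 = float(labeling.times[0]), float(labeling.times[-1])
        window = (t0, t0 + window_fraction * (t1 - t0))
    T = count_transitions(labeling, lag=lag, window=window)
    P = transition_matrix(T)
    return MSMModel(
        states=np.arange(1, labeling.n_peptides + 1),
        counts=T,
        P=P,
        lag=lag,
        build_window=window,
    )
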