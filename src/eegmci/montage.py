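"""Standard 10-20 scalp montage: channel order, 2-D positions, adjacency.

The default 20-channel layout matches a wireless dry/semi-dry clinical system
(19 standard 10-20 sites plus Oz), referenced to linked mastoids.  Channels
are ordered anterior-to-posterior, left-to-right; this fixed ordering is also
the default row order of the channel x frequency / channel x time grids used
by the cluster statistics, where consecutive rows count as neighbours.
"""

from __future__ import annotations

import numpy as np

#: Default channel order (anterior -> posterior, left -> right).
CHANNELS_1020: tuple[str, ...] = (
    "Fp1", "Fp2",
    "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "Oz", "O2",
)

# Approximate 2-D positions on the unit head disc (x: left- right+, y: ant+ post-).
_POS = {
    "Fp1": (-0.31, 0.95), "Fp2": (0.31, 0.95),
    "F7": (-0.81, 0.59), "F3": (-0.35, 0.55), "Fz": (0.0, 0.52),
    "F4": (0.35, 0.55), "F8": (0.81, 0.59),
    "T3": (-1.0, 0.0), "C3": (-0.42, 0.0), "Cz": (0.0, 0.0),
    "C4": (0.42, 0.0), "T4": (1.0, 0.0),
    "T5": (-0.81, -0.59), "P3": (-0.35, -0.55), "Pz": (0.0, -0.52),
    "P4": (0.35, -0.55), "T6": (0.81, -0.59),
    "O1": (-0.31, -0.95), "Oz": (0.0, -0.92), "O2": (0.31, -0.95),
}


def channel_positions(channels: tuple[str, ...] = CHANNELS_1020) -> np.ndarray:
    """Return an (n_channels, 2) array of scalp positions."""
    return np.array([_POS[ch] for ch in channels], dtype=float)


def neighbor_matrix(
    channels: tuple[str, ...] = CHANNELS_1020, max_dist: float = 0.62
) -> np.ndarray:
    """Boolean (n, n) scalp-neighbour matrix from inter-electrode distance.

    Two channels are neighbours when their planar distance is below
    ``max_dist`` (in unit-head-radius units).  The default threshold links
    each site to its immediate 10-20 neighbours without skipping a ring.
    """
    pos = channel_positions(channels)
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    adj = (d > 0) & (d < max_dist)
    return adj


def chain_matrix(n_channels: int) -> np.ndarray:
    """Adjacency of the default linear (montage-ordered) channel chain."""
    adj = np.zeros((n_channels, n_channels), dtype=bool)
    idx = np.arange(n_channels - 1)
    adj[idx, idx + 1] = True
    adj[idx + 1, idx] = True
    return adj


def topography(center: tuple[float, float], width: float,
               channels: tuple[str, ...] = CHANNELS_1020) -> np.ndarray:
    """Gaussian scalp weighting centred at ``center`` (unit-disc coords)."""
    pos = channel_positions(channels)
    d2 = np.sum((pos - np.asarray(center)) ** 2, axis=1)
    return np.exp(-d2 / (2.0 * width**2))
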