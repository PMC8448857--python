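"""Electrode layouts and sensor adjacency.

The default layout is a 63-electrode extended 10-20 cap (TMS-compatible
actiCAP-style grid, FCz reference and Fpz ground not recorded).  Positions
come from the idealized ``standard_1020`` montage shipped with MNE; they are
used for two things only: the occipital gain map of the simulator and the
channel-neighborhood graph of the cluster permutation test.
"""

from __future__ import annotations

import functools

import numpy as np

#: 63-channel extended 10-20 layout (default montage).
CHANNELS_63: tuple[str, ...] = (
    "Fp1", "Fp2", "AF7", "AF3", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FT9", "FT7", "FC5", "FC3", "FC1", "FC2", "FC4", "FC6", "FT8", "FT10",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "TP9", "TP7", "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6", "TP8",
    "TP10",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2", "PO9",
)

#: Reduced occipito-parietal montage for fast tests and demos.
CHANNELS_8: tuple[str, ...] = (
    "PO7", "PO3", "POz", "PO4", "PO8", "O1", "Oz", "O2",
)


@functools.lru_cache(maxsize=8)
def channel_positions(ch_names: tuple[str, ...] = CHANNELS_63) -> np.ndarray:
    """Return (n_channels, 3) head-frame positions in meters.

    Parameters
    ----------
    ch_names
        Channel labels; every label must exist in the idealized extended
        10-20 montage.
    """
    import mne

    mne.set_log_level("ERROR")
    montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    unknown = [c for c in ch_names if c not in pos]
    if unknown:
        raise ValueError(f"channels not in the 10-20 layout: {unknown}")
    return np.array([pos[c] for c in ch_names])


def adjacency_matrix(
    ch_names: tuple[str, ...] = CHANNELS_63, scale: float = 1.3
) -> np.ndarray:
    """Boolean channel-neighborhood matrix for cluster formation.

    Two sensors are neighbors when their scalp distance is below
    ``scale`` times the median nearest-neighbor distance of the layout.
    The diagonal is False and the matrix is symmetric.
    """
    pos = channel_positions(tuple(ch_names))
    d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    nn = d.min(axis=1)
    adj = d < scale * np.median(nn)
    return adj & adj.T


def occipital_gain_map(
    ch_names: tuple[str, ...] = CHANNELS_63,
    source_channels: tuple[str, str] = ("O2", "PO4"),
    sigma: float = 0.05,
) -> np.ndarray:
    """Gaussian falloff gain from a virtual right-occipital source.

    The source sits at the midpoint of ``source_channels`` (near the
    stimulated right-occipital sites); gains are normalized so the maximum
    over channels is 1.  ``sigma`` is the spatial spread in meters.
    """
    pos = channel_positions(tuple(ch_names))
    idx = [ch_names.index(c) for c in source_channels]
    src = pos[idx].mean(axis=0)
    d = np.linalg.norm(pos - src, axis=1)
    gain = np.exp(-(d**2) / (2.0 * sigma**2))
    return gain / gain.max()
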