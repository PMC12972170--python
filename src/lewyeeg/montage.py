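"""Electrode montages.

Two montages are supported: the 30-channel 10-10 set used by the main cohort
and the 19-channel 10-20 set used by cross-validation recordings.  Positions
come from the standard 10-05 template montage shipped with MNE-Python and are
radially projected onto the scalp sphere of the spherical head model, which is
how a template montage is normally fitted to a sphere.
"""

from __future__ import annotations

import warnings

import numpy as np

MONTAGE_10_10_30 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FT7", "FC3", "FCz", "FC4", "FT8",
    "T7", "C3", "Cz", "C4", "T8",
    "TP7", "CP3", "CPz", "CP4", "TP8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "Oz", "O2",
)

MONTAGE_10_20_19 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8",
    "O1", "O2",
)

MONTAGES = {"10-10-30": MONTAGE_10_10_30, "10-20-19": MONTAGE_10_20_19}

_cache: dict[str, np.ndarray] = {}


def electrode_directions(labels) -> np.ndarray:
    """Unit vectors (n_channels, 3) from head centre to each electrode.

    Axes follow the MNE head frame: +x right, +y anterior, +z superior.
    """
    key = "|".join(labels)
    if key in _cache:
        return _cache[key].copy()
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            mon = mne.channels.make_standard_montage("standard_1005")
        except ValueError:  # montage renamed in newer MNE
            mon = mne.channels.make_standard_montage("colin27_1005")
    pos = mon.get_positions()["ch_pos"]
    missing = [ch for ch in labels if ch not in pos]
    if missing:
        raise ValueError(f"labels not in the 10-05 template montage: {missing}")
    xyz = np.array([pos[ch] for ch in labels], dtype=float)
    u = xyz / np.linalg.norm(xyz, axis=1, keepdims=True)
    _cache[key] = u
    return u.copy()


def resolve_montage(name_or_labels) -> tuple[tuple[str, ...], np.ndarray]:
    """Return (labels, unit directions) for a montage name or label list."""
    if isinstance(name_or_labels, str):
        if name_or_labels not in MONTAGES:
            raise ValueError(
                f"unknown montage {name_or_labels!r}; options: {sorted(MONTAGES)}"
            )
        labels = MONTAGES[name_or_labels]
    else:
        labels = tuple(name_or_labels)
    return labels, electrode_directions(labels)
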