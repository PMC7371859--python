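"""Idealized 64-channel 10-10 sensor template.

Positions are generated on a unit sphere (head-centered, arbitrary units)
from the standard 10-10 labelling rules: the sagittal row position sets the
front-back arc angle, the electrode number sets the lateral arc angle.
The geometry is an idealization -- it is intended for neighbor definitions,
topography weighting and channel-set selection, not for source modeling.

Coordinate convention: +x right, +y anterior, +z superior; vertex (Cz) at
(0, 0, 1).
"""

from __future__ import annotations

import numpy as np

# Sagittal rows with their midline arc angle (degrees anterior of vertex)
# and the lateral electrode numbers present in the 64-channel cap.
_ROWS: list[tuple[str, float, list[int]]] = [
    ("Fp", 72.0, [1, 2]),
    ("AF", 54.0, [7, 3, 0, 4, 8]),
    ("F", 36.0, [7, 5, 3, 1, 0, 2, 4, 6, 8]),
    ("FC", 18.0, [9, 7, 5, 3, 1, 0, 2, 4, 6, 8, 10]),
    ("C", 0.0, [7, 5, 3, 1, 0, 2, 4, 6, 8]),
    ("CP", -18.0, [9, 7, 5, 3, 1, 0, 2, 4, 6, 8, 10]),
    ("P", -36.0, [7, 5, 3, 1, 0, 2, 4, 6, 8]),
    ("PO", -54.0, [7, 3, 0, 4, 8]),
    ("O", -72.0, [1, 0, 2]),
]

# 10-10 temporal-row aliases: C7/C8 are called T7/T8, FC9.. are FT9 etc.
_ALIASES = {"C7": "T7", "C8": "T8", "FC7": "FT7", "FC8": "FT8",
            "FC9": "FT9", "FC10": "FT10", "CP7": "TP7", "CP8": "TP8",
            "CP9": "TP9", "CP10": "TP10"}

#: default Euclidean neighbor radius on the unit-sphere template
DEFAULT_NEIGHBOR_DIST = 0.45

#: channel rows regarded as posterior for alpha-peak picking and PLV summaries
POSTERIOR_PREFIXES = ("P", "PO", "O")
#: frontal rows used to build the virtual EOG channel
FRONTAL_PREFIXES = ("Fp", "AF")
#: temporal channels carrying the simulated sham auditory transient
TEMPORAL_CHANNELS = ("T7", "T8", "TP7", "TP8", "TP9", "TP10", "FT7", "FT8")


def _lateral_angle(number: int) -> float:
    """Lateral arc angle (deg) for a 10-10 electrode number (0 == z-line)."""
    if number == 0:
        return 0.0
    return 18.0 * ((number + 1) // 2)


def _label(prefix: str, number: int) -> str:
    name = f"{prefix}z" if number == 0 else f"{prefix}{number}"
    return _ALIASES.get(name, name)


def standard_64() -> tuple[list[str], np.ndarray]:
    """Return (labels, positions) of the shipped 64-channel 10-10 template."""
    labels: list[str] = []
    pos: list[np.ndarray] = []
    for prefix, beta_deg, numbers in _ROWS:
        beta = np.deg2rad(beta_deg)
        # midline point after tilting the vertex toward the front
        mid = np.array([0.0, np.sin(beta), np.cos(beta)])
        for num in numbers:
            lam = np.deg2rad(_lateral_angle(num))
            if num % 2 == 1:  # odd numbers on the left (-x)
                lam = -lam
            # rotate about the anterior-posterior (y) axis toward the ear
            rot = np.array([
                [np.cos(lam), 0.0, np.sin(lam)],
                [0.0, 1.0, 0.0],
                [-np.sin(lam), 0.0, np.cos(lam)],
            ])
            labels.append(_label(prefix, num))
            pos.append(rot @ mid)
    positions = np.asarray(pos, dtype=float)
    assert len(labels) == 64
    return labels, positions


#: 32-channel subset used by the phantom recordings
STANDARD_32 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "FC5", "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10",
    "P7", "P3", "Pz", "P4", "P8", "PO7", "PO3", "PO4", "PO8", "Oz",
]


def row_of(label: str) -> str:
    """Sagittal row prefix of a 10-10 label ('PO3' -> 'PO')."""
    for alias, canonical in [(v, k) for k, v in _ALIASES.items()]:
        if label == alias:
            label = canonical
            break
    return label.rstrip("z0123456789")


def posterior_channels(labels: list[str]) -> list[str]:
    return [c for c in labels if row_of(c) in POSTERIOR_PREFIXES]


def frontal_channels(labels: list[str]) -> list[str]:
    return [c for c in labels if row_of(c) in FRONTAL_PREFIXES]
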