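"""Scalp montage: the 29 analyzed channels, ROI clusters and template positions.

The montage is a 10-20/10-10 subset recorded with a Neuroscan cap. Eight
regions of interest (left/right x frontal/parietal/temporal/occipital) cover
26 of the 29 channels; the three midline channels (Fz, Pz, Oz) belong to no
ROI and enter only the connectivity analysis.
"""

from __future__ import annotations

import numpy as np

#: The 29 scalp channels retained for analysis, in recording order.
CHANNELS: tuple[str, ...] = (
    "C3", "C4", "F3", "F4", "F7", "F8", "Fp1", "Fp2",
    "FC1", "FC2", "FC5", "FC6", "Fz", "T7", "T8",
    "P3", "P4", "Pz", "CP1", "CP2", "CP5", "CP6",
    "Oz", "P7", "P8", "O1", "O2", "PO3", "PO4",
)

#: Region-of-interest clusters. Channel names match ``CHANNELS``.
ROI_MAP: dict[str, tuple[str, ...]] = {
    "right_parietal": ("C4", "CP6", "CP2", "P4"),
    "right_frontal": ("FC2", "FC6", "F4", "Fp2"),
    "right_occipital": ("PO4", "O2"),
    "right_temporal": ("F8", "T8", "P8"),
    "left_parietal": ("P3", "CP1", "CP5", "C3"),
    "left_frontal": ("Fp1", "F3", "FC5", "FC1"),
    "left_temporal": ("P7", "T7", "F7"),
    "left_occipital": ("O1", "PO3"),
}

#: Short ROI labels used in feature names (LP-alpha etc.).
ROI_ABBREV: dict[str, str] = {
    "left_frontal": "LF", "right_frontal": "RF",
    "left_parietal": "LP", "right_parietal": "RP",
    "left_temporal": "LT", "right_temporal": "RT",
    "left_occipital": "LO", "right_occipital": "RO",
}

#: Midline channels outside every ROI.
MIDLINE: tuple[str, ...] = ("Fz", "Pz", "Oz")

ROI_NAMES: tuple[str, ...] = tuple(ROI_MAP)


def roi_of(channel: str) -> str | None:
    """Return the ROI containing *channel*, or None for midline channels."""
    for roi, chs in ROI_MAP.items():
        if channel in chs:
            return roi
    if channel in MIDLINE:
        return None
    raise KeyError(f"unknown channel {channel!r}")


def channel_positions(channels: tuple[str, ...] = CHANNELS) -> np.ndarray:
    """Template 3-D electrode positions (meters, head frame), shape (n, 3).

    Positions come from the standard 10-05 template montage; the cap was not
    digitized, so template coordinates stand in for true electrode locations.
    """
    import mne

    try:
        mont = mne.channels.make_standard_montage("colin27_1005")
    except ValueError:  # older template name
        mont = mne.channels.make_standard_montage("standard_1005")
    pos = mont.get_positions()["ch_pos"]
    missing = [c for c in channels if c not in pos]
    if missing:
        raise KeyError(f"channels without template positions: {missing}")
    return np.array([pos[c] for c in channels])


def validate_channel_set(channels) -> None:
    """Raise ValueError unless *channels* is exactly the analyzed montage."""
    chs = tuple(channels)
    if len(chs) != len(set(chs)):
        raise ValueError("channel set contains duplicates")
    if set(chs) != set(CHANNELS):
        extra = set(chs) - set(CHANNELS)
        miss = set(CHANNELS) - set(chs)
        raise ValueError(f"channel set mismatch: extra={sorted(extra)}, missing={sorted(miss)}")
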