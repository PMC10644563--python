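"""Band power and relative band power per channel and ROI (feature set 1).

Per 2-s epoch, a Hann-windowed single-segment periodogram (0.5 Hz grid at
500 Hz) is integrated over the five canonical bands; each band's absolute
power is divided by the five-band total to give relative power, which is then
averaged over the channels of each ROI. Relativizing per channel *before*
ROI averaging keeps every ROI's five-band vector summing to exactly 1 and is
robust to inter-channel amplitude differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from . import montage
from .preprocess import EpochArray


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [lo, hi) in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self):
        if not 0 <= self.lo < self.hi:
            raise ValueError(f"invalid band edges [{self.lo}, {self.hi})")


#: The five canonical bands. Edges are half-open [lo, hi) so the shared
#: boundaries (4, 8, 13, 30 Hz) are counted exactly once.
DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 8.0),
    BandDefinition("alpha", 8.0, 13.0),
    BandDefinition("beta", 13.0, 30.0),
    BandDefinition("gamma", 30.0, 80.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def psd_epoch(ep: EpochArray) -> tuple[np.ndarray, np.ndarray]:
    """One-sided PSD per epoch and channel.

    Uses a Hann-windowed periodogram over the whole epoch (one Welch segment),
    so a 1000-sample epoch at 500 Hz gives a 0.5 Hz frequency grid.

    Returns
    -------
    freqs : (n_freqs,) array in Hz
    psd : (n_epochs, n_channels, n_freqs) array in µV²/Hz
    """
    if ep.n_samples < 8:
        raise ValueError("epoch too short for a PSD estimate")
    freqs, psd = signal.welch(
        ep.data, fs=ep.fs, window="hann", nperseg=ep.n_samples,
        noverlap=0, detrend=False, scaling="density", axis=-1,
    )
    return freqs, psd


def band_power(freqs: np.ndarray, psd: np.ndarray, band: BandDefinition) -> np.ndarray:
    """Absolute power (µV²) in ``[band.lo, band.hi)``: the PSD integral.

    ``psd`` may have any leading shape; the last axis must match ``freqs``.
    """
    if band.hi > freqs[-1] + (freqs[1] - freqs[0]):
        raise ValueError(f"band {band.name} exceeds the spectral range")
    mask = (freqs >= band.lo) & (freqs < band.hi)
    if not mask.any():
        raise ValueError(f"band {band.name} [{band.lo}, {band.hi}) contains no frequency bins")
    df = freqs[1] - freqs[0]
    return psd[..., mask].sum(axis=-1) * df


def relative_power(abs_powers: np.ndarray) -> np.ndarray:
    """Normalize band powers to fractions of their total.

    ``abs_powers`` has the bands on the last axis. Raises if any total is
    zero (relative power undefined).
    """
    abs_powers = np.asarray(abs_powers, dtype=float)
    if (abs_powers < 0).any():
        raise ValueError("negative band power")
    total = abs_powers.sum(axis=-1, keepdims=True)
    if (total == 0).any():
        raise ValueError("all band powers zero; relative power undefined")
    return abs_powers / total


def feature_name(roi: str, band: str) -> str:
    """Feature-set-1 column name, e.g. ``LP-alpha``."""
    return f"{montage.ROI_ABBREV[roi]}-{band}"


def roi_relative_power(
    ep: EpochArray,
    rois: dict[str, tuple[str, ...]] | None = None,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
) -> pd.DataFrame:
    """Per-epoch ROI x band relative power table.

    Returns a DataFrame indexed by ``(subject_id, epoch)`` (epoch = original
    epoch index before rejection) with one column per ROI x band, named
    ``<ROI>-<band>`` (e.g. ``LP-alpha``). Every ROI's five band columns sum
    to 1 in each row.
    """
    rois = dict(montage.ROI_MAP if rois is None else rois)
    ch_index = {c: i for i, c in enumerate(ep.channels)}
    for roi, chs in rois.items():
        missing = [c for c in chs if c not in ch_index]
        if missing:
            raise KeyError(f"ROI {roi!r} references missing channel(s) {missing}")

    freqs, psd = psd_epoch(ep)
    # (epochs, channels, bands)
    powers = np.stack([band_power(freqs, psd, b) for b in bands], axis=-1)
    rel = relative_power(powers)

    cols, data = [], []
    for roi, chs in rois.items():
        idx = [ch_index[c] for c in chs]
        roi_rel = rel[:, idx, :].mean(axis=1)  # (epochs, bands)
        for k, b in enumerate(bands):
            cols.append(feature_name(roi, b.name))
            data.append(roi_rel[:, k])
    index = pd.MultiIndex.from_arrays(
        [np.repeat(ep.subject_id, ep.n_epochs), np.asarray(ep.kept_epoch_indices)],
        names=["subject_id", "epoch"],
    )
    return pd.DataFrame(dict(zip(cols, data)), index=index)


def subject_aggregate(table: pd.DataFrame) -> pd.DataFrame:
    """Mean over a subject's retained epochs: one row per subject."""
    return table.groupby(level="subject_id", sort=True).mean()


def power_long_format(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format view: subject_id, epoch, roi, band, relative_power."""
    long = table.stack().rename("relative_power").reset_index()
    long.columns = ["subject_id", "epoch", "feature", "relative_power"]
    parts = long["feature"].str.split("-", expand=True)
    long["roi"], long["band"] = parts[0], parts[1]
    return long[["subject_id", "epoch", "roi", "band", "relative_power"]]
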