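"""Preprocessing chain for continuous resting-state EEG.

The chain mirrors standard clinical resting-EEG practice: zero-phase
band-pass (0.1-80 Hz) and notch (49-51 Hz) filtering, downsampling to
500 Hz, spherical-spline interpolation of bad channels, segmentation into
non-overlapping 2-s epochs, amplitude-based epoch rejection at +/-80 µV, and
common-average re-referencing. Rejection runs on the original reference so
that a large artifact on one channel cannot leak into all channels through
the average before it is caught.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal

from . import montage


@dataclass
class Recording:
    """Continuous multichannel EEG in µV.

    ``signal`` is (n_channels, n_samples); ``history`` records every
    mutation so the applied pipeline order is auditable.
    """

    subject_id: str
    channels: tuple[str, ...]
    fs: float
    signal: np.ndarray
    reference: str = "Pz"
    history: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.channels = tuple(self.channels)
        self.signal = np.asarray(self.signal, dtype=np.float64)
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channels):
            raise ValueError(
                f"signal shape {self.signal.shape} does not match "
                f"{len(self.channels)} channels"
            )
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def _evolve(self, signal: np.ndarray, step: str, **changes) -> "Recording":
        return replace(
            self, signal=signal, history=[*self.history, step], **changes
        )


@dataclass
class EpochArray:
    """Fixed-length epochs, (n_epochs, n_channels, n_samples) in µV."""

    subject_id: str
    channels: tuple[str, ...]
    fs: float
    epoch_length_s: float
    data: np.ndarray
    kept_epoch_indices: np.ndarray
    history: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.channels = tuple(self.channels)
        self.data = np.asarray(self.data, dtype=np.float64)
        self.kept_epoch_indices = np.asarray(self.kept_epoch_indices, dtype=int)
        if self.data.ndim != 3:
            raise ValueError("epoch data must be (epochs, channels, samples)")
        if self.data.shape[1] != len(self.channels):
            raise ValueError("channel-axis mismatch")
        if self.data.shape[2] != round(self.epoch_length_s * self.fs):
            raise ValueError("sample count does not match epoch_length_s x fs")
        if len(self.kept_epoch_indices) != self.data.shape[0]:
            raise ValueError("kept_epoch_indices length mismatch")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


def filter_recording(
    rec: Recording,
    band_lo: float = 0.1,
    band_hi: float = 80.0,
    notch_lo: float = 49.0,
    notch_hi: float = 51.0,
    order: int = 4,
) -> Recording:
    """Zero-phase Butterworth band-pass then band-stop (notch).

    Both filters are 4th-order designs applied forward-backward
    (``sosfiltfilt``), so the effective magnitude order doubles and the phase
    response is exactly zero — phase distortion would bias downstream
    phase-coupling estimates.
    """
    nyq = rec.fs / 2
    if not 0 < band_lo < band_hi:
        raise ValueError("require 0 < band_lo < band_hi")
    if band_hi >= nyq:
        raise ValueError(f"band_hi={band_hi} must be below Nyquist ({nyq} Hz)")
    if not band_lo < notch_lo < notch_hi < band_hi:
        raise ValueError("notch band must lie inside the pass band")
    sos_bp = signal.butter(order, [band_lo, band_hi], btype="bandpass", fs=rec.fs, output="sos")
    sos_bs = signal.butter(order, [notch_lo, notch_hi], btype="bandstop", fs=rec.fs, output="sos")
    # scipy's default reflection padding is far too short for a 0.1 Hz corner
    # (settling time ~ 1/band_lo seconds); without it the edges ring.
    padlen = min(rec.n_samples - 1, int(round(3 * rec.fs / band_lo)))
    out = signal.sosfiltfilt(sos_bp, rec.signal, axis=1, padlen=padlen)
    out = signal.sosfiltfilt(sos_bs, out, axis=1, padlen=padlen)
    return rec._evolve(
        out,
        f"filter(bandpass={band_lo}-{band_hi}Hz, notch={notch_lo}-{notch_hi}Hz, "
        f"butterworth order={order}, zero-phase)",
    )


def downsample(rec: Recording, target_fs: float = 500.0) -> Recording:
    """Polyphase resampling with anti-alias filtering.

    The target rate must exceed 160 Hz so the gamma band (up to 80 Hz)
    remains representable.
    """
    if target_fs <= 160:
        raise ValueError("target_fs must exceed 160 Hz to keep the gamma band")
    if target_fs == rec.fs:
        return rec._evolve(rec.signal.copy(), f"downsample({target_fs}Hz, identity)")
    if target_fs > rec.fs:
        raise ValueError("target_fs above the current rate; refusing to upsample")
    from fractions import Fraction

    frac = Fraction(target_fs / rec.fs).limit_denominator(1000)
    out = signal.resample_poly(rec.signal, frac.numerator, frac.denominator, axis=1)
    return rec._evolve(out, f"downsample({rec.fs}->{target_fs}Hz, polyphase)", fs=float(target_fs))


def interpolate_bad_channels(
    rec: Recording,
    bad: list[str],
    positions: np.ndarray | None = None,
) -> Recording:
    """Replace bad channels by spherical-spline estimates from the rest.

    Uses the Perrin spherical-spline interpolation as implemented in MNE
    (stiffness m=4). ``positions`` are per-channel 3-D coordinates; by
    default the standard 10-05 template is used. Good channels are untouched.
    """
    bad = list(bad)
    if not bad:
        return rec._evolve(rec.signal.copy(), "interpolate(bad=[])")
    unknown = [c for c in bad if c not in rec.channels]
    if unknown:
        raise KeyError(f"bad channels not in recording: {unknown}")
    n_good = len(rec.channels) - len(bad)
    if n_good < 4:
        raise ValueError("need at least 4 good channels for spline interpolation")

    import mne
    from mne.channels.interpolation import _make_interpolation_matrix

    if positions is None:
        positions = montage.channel_positions(rec.channels)
    positions = np.asarray(positions, dtype=float)
    if positions.shape != (len(rec.channels), 3):
        raise ValueError("positions must be (n_channels, 3)")

    good_idx = np.array([i for i, c in enumerate(rec.channels) if c not in bad])
    bad_idx = np.array([i for i, c in enumerate(rec.channels) if c in bad])
    with np.errstate(all="ignore"):
        interp = _make_interpolation_matrix(positions[good_idx], positions[bad_idx])
    out = rec.signal.copy()
    out[bad_idx] = interp @ rec.signal[good_idx]
    return rec._evolve(out, f"interpolate(bad={sorted(bad)}, spherical-spline m=4)")


def rereference_average(rec: Recording) -> Recording:
    """Common average reference: subtract the instantaneous cross-channel mean."""
    if len(rec.channels) < 2:
        raise ValueError("average reference needs at least 2 channels")
    out = rec.signal - rec.signal.mean(axis=0, keepdims=True)
    return rec._evolve(out, "rereference(common-average)", reference="common_average")


def epoch(rec: Recording, epoch_length_s: float = 2.0) -> EpochArray:
    """Cut into consecutive non-overlapping epochs; trailing remainder dropped."""
    n_per = epoch_length_s * rec.fs
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError("epoch_length_s x fs must be an integer sample count")
    n_per = int(round(n_per))
    n_epochs = rec.n_samples // n_per
    if n_epochs < 1:
        raise ValueError(
            f"recording ({rec.duration_s:.3f}s) shorter than one epoch ({epoch_length_s}s)"
        )
    data = rec.signal[:, : n_epochs * n_per].reshape(len(rec.channels), n_epochs, n_per)
    data = np.moveaxis(data, 0, 1).copy()
    return EpochArray(
        subject_id=rec.subject_id,
        channels=rec.channels,
        fs=rec.fs,
        epoch_length_s=epoch_length_s,
        data=data,
        kept_epoch_indices=np.arange(n_epochs),
        history=[*rec.history, f"epoch({epoch_length_s}s, non-overlapping)"],
    )


def reject_epochs(ep: EpochArray, threshold_uv: float = 80.0) -> EpochArray:
    """Drop epochs where any sample on any channel exceeds |threshold_uv|."""
    if threshold_uv <= 0:
        raise ValueError("threshold must be positive")
    peak = np.abs(ep.data).max(axis=(1, 2))
    keep = peak <= threshold_uv
    if not keep.any():
        raise ValueError(
            f"all {ep.n_epochs} epochs exceed +/-{threshold_uv} µV "
            f"(min peak {peak.min():.1f} µV); nothing to analyze"
        )
    n_rej = int((~keep).sum())
    return EpochArray(
        subject_id=ep.subject_id,
        channels=ep.channels,
        fs=ep.fs,
        epoch_length_s=ep.epoch_length_s,
        data=ep.data[keep],
        kept_epoch_indices=ep.kept_epoch_indices[keep],
        history=[*ep.history, f"reject(threshold={threshold_uv}µV, rejected={n_rej})"],
    )


def rereference_epochs_average(ep: EpochArray) -> EpochArray:
    """Common average reference applied within each epoch.

    CAR is a per-sample linear map, so applying it after epoching equals
    applying it to the continuous data; doing it after rejection keeps the
    rejection decision on the recording reference.
    """
    data = ep.data - ep.data.mean(axis=1, keepdims=True)
    return EpochArray(
        subject_id=ep.subject_id,
        channels=ep.channels,
        fs=ep.fs,
        epoch_length_s=ep.epoch_length_s,
        data=data,
        kept_epoch_indices=ep.kept_epoch_indices.copy(),
        history=[*ep.history, "rereference(common-average)"],
    )


def preprocess_recording(
    rec: Recording,
    band: tuple[float, float] = (0.1, 80.0),
    notch: tuple[float, float] = (49.0, 51.0),
    target_fs: float = 500.0,
    bad_channels: list[str] | None = None,
    epoch_length_s: float = 2.0,
    reject_uv: float = 80.0,
) -> EpochArray:
    """Full chain: filter -> downsample -> interpolate -> epoch -> reject -> CAR."""
    rec = filter_recording(rec, band[0], band[1], notch[0], notch[1])
    rec = downsample(rec, target_fs)
    rec = interpolate_bad_channels(rec, bad_channels or [])
    ep = epoch(rec, epoch_length_s)
    ep = reject_epochs(ep, reject_uv)
    return rereference_epochs_average(ep)
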