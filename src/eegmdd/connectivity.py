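"""Weighted phase lag index (wPLI) connectivity (feature set 2).

wPLI measures phase coupling weighted by the magnitude of the imaginary
cross-spectrum:

    wPLI = | E[ Im S_xy ] | / E[ |Im S_xy| ]

over repeated observations of the complex cross-spectrum S_xy. Because only
the imaginary part enters, zero-lag (volume-conduction) coupling contributes
nothing, and amplitude rescaling of either channel cancels in the ratio.

Observation units: at the subject level one observation per retained 2-s
epoch (Hann-windowed FFT of the whole epoch, cross-spectra summed over the
band's frequency bins); at the epoch level — needed because each classifier
sample is a single epoch — observations are 0.5-s Hann segments with 50%
overlap inside the epoch. Summing the cross-spectrum over band bins before
the ratio avoids degenerate zero-denominator bins.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import signal as sps

from . import montage
from .preprocess import EpochArray
from .spectral import DEFAULT_BANDS, BandDefinition


def wpli(cross_terms: np.ndarray, axis: int = 0) -> np.ndarray:
    """wPLI of complex cross-spectral observations along ``axis``.

    Returns |mean Im| / mean |Im|, with the 0/0 case (identical or perfectly
    zero-lag signals) defined as 0. Values lie in [0, 1].
    """
    cross_terms = np.asarray(cross_terms)
    if cross_terms.shape[axis] < 2:
        raise ValueError("wPLI needs at least 2 observations")
    im = cross_terms.imag
    num = np.abs(im.mean(axis=axis))
    den = np.abs(im).mean(axis=axis)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return out


def _segment_fft(data: np.ndarray, fs: float, nperseg: int, noverlap: int) -> tuple[np.ndarray, np.ndarray]:
    """Hann-windowed segment FFTs.

    data: (..., n_channels, n_samples) ->
    (freqs, X) with X of shape (..., n_segments, n_channels, n_freqs).
    """
    n_samples = data.shape[-1]
    if nperseg > n_samples:
        raise ValueError("segment longer than the data")
    step = nperseg - noverlap
    starts = range(0, n_samples - nperseg + 1, step)
    win = sps.get_window("hann", nperseg)
    segs = np.stack([data[..., s : s + nperseg] * win for s in starts], axis=-3)
    X = np.fft.rfft(segs, axis=-1)
    freqs = np.fft.rfftfreq(nperseg, 1.0 / fs)
    return freqs, X


def cross_spectra(
    ep: EpochArray,
    band: BandDefinition,
    nperseg: int | None = None,
    noverlap: int | None = None,
) -> np.ndarray:
    """Per-observation band cross-spectra for all channel pairs.

    Returns a complex array (n_obs, n_channels, n_channels), Hermitian in the
    channel axes, where each observation's S_ij is the cross-spectrum summed
    over the band's frequency bins. With ``nperseg=None`` each epoch is one
    observation (whole-epoch window); otherwise epochs are subdivided into
    Hann segments and every (epoch, segment) is an observation.
    """
    if nperseg is None:
        nperseg = ep.n_samples
        noverlap = 0
    if noverlap is None:
        noverlap = nperseg // 2
    freqs, X = _segment_fft(ep.data, ep.fs, nperseg, noverlap)
    mask = (freqs >= band.lo) & (freqs < band.hi)
    if not mask.any():
        raise ValueError(f"band {band.name} has no frequency bins at this resolution")
    Xb = X[..., mask]  # (epochs, segs, ch, bins)
    S = np.einsum("escf,esdf->escd", Xb, Xb.conj())
    n_ch = len(ep.channels)
    return S.reshape(-1, n_ch, n_ch)


def wpli_matrix(
    ep: EpochArray,
    band: BandDefinition,
    nperseg: int | None = None,
    noverlap: int | None = None,
) -> np.ndarray:
    """Symmetric (n_ch, n_ch) wPLI matrix; diagonal set to NaN."""
    S = cross_spectra(ep, band, nperseg=nperseg, noverlap=noverlap)
    mat = wpli(S, axis=0)
    mat = 0.5 * (mat + mat.T)  # numerically symmetrize (Im antisymmetric)
    np.fill_diagonal(mat, np.nan)
    return mat


def region_pairs(rois: dict[str, tuple[str, ...]] | None = None) -> list[tuple[str, str]]:
    """The 28 unordered region pairs, in a fixed canonical order."""
    rois = dict(montage.ROI_MAP if rois is None else rois)
    return list(itertools.combinations(rois.keys(), 2))


def region_aggregate(
    channel_matrix: np.ndarray,
    channels: tuple[str, ...],
    rois: dict[str, tuple[str, ...]] | None = None,
) -> pd.DataFrame:
    """8x8 region-pair wPLI: arithmetic mean over cross-region channel pairs."""
    rois = dict(montage.ROI_MAP if rois is None else rois)
    ch_index = {c: i for i, c in enumerate(channels)}
    names = list(rois.keys())
    out = pd.DataFrame(np.nan, index=names, columns=names, dtype=float)
    for a, b in itertools.combinations(names, 2):
        ia = [ch_index[c] for c in rois[a]]
        ib = [ch_index[c] for c in rois[b]]
        val = float(np.mean(channel_matrix[np.ix_(ia, ib)]))
        out.loc[a, b] = out.loc[b, a] = val
    return out


def pair_feature_name(roi_a: str, roi_b: str, band: str) -> str:
    """Feature-set-2 column name, e.g. ``LP~RO-alpha``."""
    return f"{montage.ROI_ABBREV[roi_a]}~{montage.ROI_ABBREV[roi_b]}-{band}"


def subject_wpli_features(
    ep: EpochArray,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    rois: dict[str, tuple[str, ...]] | None = None,
) -> pd.Series:
    """Subject-level 140-feature vector (28 region pairs x 5 bands).

    Observations pooled over all retained epochs (one per epoch).
    """
    rois = dict(montage.ROI_MAP if rois is None else rois)
    values, names = [], []
    for band in bands:
        mat = wpli_matrix(ep, band)
        agg = region_aggregate(mat, ep.channels, rois)
        for a, b in itertools.combinations(rois.keys(), 2):
            names.append(pair_feature_name(a, b, band.name))
            values.append(agg.loc[a, b])
    return pd.Series(values, index=names, name=ep.subject_id)


def epoch_wpli_features(
    ep: EpochArray,
    bands: tuple[BandDefinition, ...] = DEFAULT_BANDS,
    rois: dict[str, tuple[str, ...]] | None = None,
    nperseg: int | None = None,
) -> pd.DataFrame:
    """Epoch-level 140-feature table (rows = epochs).

    Within each epoch, observations are 0.5-s Hann segments with 50% overlap
    (seven per 2-s epoch at 500 Hz); coarser spectral resolution is the price
    of having per-epoch features at all.
    """
    rois = dict(montage.ROI_MAP if rois is None else rois)
    if nperseg is None:
        nperseg = max(8, int(round(ep.fs * 0.5)))
    noverlap = nperseg // 2
    ch_index = {c: i for i, c in enumerate(ep.channels)}
    roi_names = list(rois.keys())
    pair_idx = [
        (np.array([ch_index[c] for c in rois[a]]), np.array([ch_index[c] for c in rois[b]]))
        for a, b in itertools.combinations(roi_names, 2)
    ]

    cols: dict[str, np.ndarray] = {}
    for band in bands:
        S = cross_spectra(ep, band, nperseg=nperseg, noverlap=noverlap)
        n_obs = S.shape[0] // ep.n_epochs
        S = S.reshape(ep.n_epochs, n_obs, len(ep.channels), len(ep.channels))
        mats = wpli(S, axis=1)  # (epochs, ch, ch)
        mats = 0.5 * (mats + np.swapaxes(mats, 1, 2))
        for (a, b), (ia, ib) in zip(itertools.combinations(roi_names, 2), pair_idx):
            cols[pair_feature_name(a, b, band.name)] = mats[:, ia][:, :, ib].mean(axis=(1, 2))
    index = pd.MultiIndex.from_arrays(
        [np.repeat(ep.subject_id, ep.n_epochs), np.asarray(ep.kept_epoch_indices)],
        names=["subject_id", "epoch"],
    )
    return pd.DataFrame(cols, index=index)


def wpli_long_format(table: pd.DataFrame) -> pd.DataFrame:
    """Long-format view: subject_id, [epoch,] region_a, region_b, band, wpli."""
    long = table.stack().rename("wpli").reset_index()
    feat = long.columns[-2]
    parts = long[feat].str.extract(r"(\w+)~(\w+)-(\w+)")
    long["region_a"], long["region_b"], long["band"] = parts[0], parts[1], parts[2]
    keep = [c for c in ("subject_id", "epoch") if c in long] + ["region_a", "region_b", "band", "wpli"]
    return long[keep]
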