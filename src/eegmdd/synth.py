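"""Synthetic resting-state EEG cohorts with plantable group effects.

Each subject's signal is a sum of five narrowband oscillators (4th-order
Butterworth band-filtered Gaussian noise, one per canonical band), a 1/f
background, and optional shared sources that realize phase coupling between
region pairs. Group differences are planted as per-ROI relative-power
multipliers and per-region-pair phase-coupling strengths; the defaults mirror
the group pattern the analysis is meant to detect in first-episode
drug-naive MDD: higher occipital delta/theta, lower posterior alpha, weaker
alpha-band and stronger gamma-band inter-regional coupling.

All randomness flows from a single root seed via per-subject derived seeds,
so a cohort is a pure function of its configuration.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import signal as sps

from . import montage
from .preprocess import Recording

GROUPS = ("MDD", "HC")

#: Baseline oscillator amplitudes (standard deviation, µV) per band. Alpha
#: dominates, as in eyes-closed resting EEG; totals keep an artifact-free
#: signal far below the 80 µV rejection threshold.
BASE_BAND_AMPLITUDE_UV: dict[str, float] = {
    "delta": 5.0, "theta": 3.5, "alpha": 6.0, "beta": 2.5, "gamma": 1.5,
}

BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0), "theta": (4.0, 8.0), "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0), "gamma": (30.0, 80.0),
}

#: Background 1/f noise amplitude (µV, std).
BACKGROUND_AMPLITUDE_UV = 3.0

#: Per-subject log-normal amplitude jitter (sd of log multiplier, shared by
#: all channels of a band). Provides realistic between-subject variability so
#: group statistics are non-degenerate.
SUBJECT_JITTER_LOG_SD = 0.10

#: Posterior ROIs where the planted alpha reduction applies.
_POSTERIOR = ("left_occipital", "right_occipital", "left_parietal", "right_parietal")


def default_band_effects() -> dict:
    """Planted relative-power multipliers: group -> band -> ROI -> multiplier.

    MDD: occipital delta x1.5, right-occipital theta x1.4, posterior alpha
    x0.67. Unlisted entries default to 1. Magnitudes are calibrated so the
    differences are detectable at 15 subjects per group.
    """
    return {
        "HC": {},
        "MDD": {
            "delta": {"left_occipital": 1.5, "right_occipital": 1.5},
            "theta": {"right_occipital": 1.4},
            "alpha": {roi: 0.67 for roi in _POSTERIOR},
        },
    }


def default_coupling_effects() -> dict:
    """Planted phase coupling: group -> band -> (roi_a, roi_b) -> strength.

    Alpha coupling is weaker and gamma coupling stronger in MDD, planted on
    a set of long-range homologous and fronto-posterior pairs.
    """
    pairs = (
        ("left_occipital", "right_occipital"),
        ("left_parietal", "right_parietal"),
        ("left_frontal", "left_occipital"),
        ("right_frontal", "right_occipital"),
        ("left_frontal", "right_frontal"),
    )
    return {
        "HC": {
            "alpha": {p: 0.6 for p in pairs},
            "gamma": {p: 0.1 for p in pairs},
        },
        "MDD": {
            "alpha": {p: 0.25 for p in pairs},
            "gamma": {p: 0.45 for p in pairs},
        },
    }


@dataclass
class CohortConfig:
    """Generator configuration; the defaults are the study conditions."""

    n_per_group: int = 15
    duration_s: float = 600.0
    fs: float = 1000.0
    channel_set: tuple[str, ...] = montage.CHANNELS
    band_effects: dict = field(default_factory=default_band_effects)
    coupling_effects: dict = field(default_factory=default_coupling_effects)
    artifact_rate: float = 0.5  # expected artifact transients per minute
    artifact_amplitude_uv: float = 150.0
    noise_exponent: float = 1.0
    subject_jitter_log_sd: float = SUBJECT_JITTER_LOG_SD
    seed: int = 0

    def __post_init__(self):
        self.channel_set = tuple(self.channel_set)
        montage.validate_channel_set(self.channel_set)
        if self.fs < 160:
            raise ValueError("fs must be at least 2 x 80 Hz")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")
        if self.duration_s * self.fs < 2 * self.fs:
            raise ValueError("duration must allow at least one 2-s epoch")
        if self.artifact_rate < 0:
            raise ValueError("artifact_rate must be non-negative")
        for group, bands in self.band_effects.items():
            for band, rois in bands.items():
                for roi, mult in rois.items():
                    if mult <= 0:
                        raise ValueError(
                            f"band multiplier must be positive: {group}/{band}/{roi}"
                        )
        for group, bands in self.coupling_effects.items():
            for band, pairs in bands.items():
                for pair, c in pairs.items():
                    if not 0 <= c <= 1:
                        raise ValueError(
                            f"coupling strength must be in [0,1]: {group}/{band}/{pair}"
                        )


@dataclass(frozen=True)
class SubjectMetadata:
    subject_id: str
    group: str
    sex: str
    age: float
    hamd17: int

    def __post_init__(self):
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")
        if self.hamd17 < 0:
            raise ValueError("HAMD-17 score must be >= 0")


def _narrowband_noise(rng: np.random.Generator, shape, fs: float, lo: float, hi: float) -> np.ndarray:
    """Unit-variance Gaussian noise band-limited to [lo, hi].

    Generated with padding of a few low-frequency cycles at both ends, which
    is trimmed after filtering: otherwise the filter's settling transients
    dominate after normalization and masquerade as artifacts.
    """
    pad = int(round(4 * fs / lo))
    padded_shape = (*shape[:-1], shape[-1] + 2 * pad)
    white = rng.standard_normal(padded_shape)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, white, axis=-1)[..., pad:-pad]
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd

def _one_over_f_noise(
    rng: np.random.Generator, shape, exponent: float, fs: float, f_floor: float = 0.5
) -> np.ndarray:
    """Unit-variance noise with a 1/f^exponent power spectrum above f_floor.

    The spectrum plateaus below ``f_floor`` (Hz): unbounded sub-0.1-Hz power
    would be removed by the analysis high-pass anyway, but its size would
    leave large filter transients at the recording edges.
    """
    white = rng.standard_normal(shape)
    spec = np.fft.rfft(white, axis=-1)
    f = np.fft.rfftfreq(shape[-1], 1.0 / fs)
    scale = np.zeros_like(f)
    scale[1:] = np.maximum(f[1:], f_floor) ** (-exponent / 2.0)
    x = np.fft.irfft(spec * scale, n=shape[-1], axis=-1)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


def _effect_multiplier(effects: dict, group: str, band: str, roi: str | None) -> float:
    if roi is None:
        return 1.0
    return float(effects.get(group, {}).get(band, {}).get(roi, 1.0))


def generate_subject(config: CohortConfig, group: str, subject_seed: int) -> Recording:
    """One subject's continuous 29-channel recording in µV.

    Deterministic given ``(config, group, subject_seed)``. The random stream
    does not depend on the group label, so two groups with identical effect
    maps and the same seed produce signals with identical expected band power.
    """
    if group not in GROUPS:
        raise ValueError(f"unknown group {group!r}; expected one of {GROUPS}")
    n_samples = int(round(config.duration_s * config.fs))
    if n_samples < 2 * config.fs:
        raise ValueError("duration too short for one 2-s epoch")
    channels = config.channel_set
    n_ch = len(channels)
    rois = [montage.roi_of(c) for c in channels]

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, int(subject_seed), 11]))

    # Per-subject, per-band amplitude jitter (shared across channels).
    jitter = {
        band: float(np.exp(rng.normal(0.0, config.subject_jitter_log_sd)))
        for band in BASE_BAND_AMPLITUDE_UV
    }

    total = np.zeros((n_ch, n_samples))
    # union of coupling specs over groups, so the draw count is group-independent
    all_coupled_pairs = {
        band: sorted(
            {p for g in GROUPS for p in config.coupling_effects.get(g, {}).get(band, {})}
        )
        for band in BASE_BAND_AMPLITUDE_UV
    }

    for band, (lo, hi) in BAND_EDGES.items():
        own = _narrowband_noise(rng, (n_ch, n_samples), config.fs, lo, hi)
        f_center = 0.5 * (lo + hi)
        lag = max(1, int(round(config.fs / (4.0 * f_center))))

        coupling_var = np.zeros(n_ch)
        coupled = np.zeros((n_ch, n_samples))
        for pair in all_coupled_pairs[band]:
            shared = _narrowband_noise(rng, (n_samples,), config.fs, lo, hi)
            c = float(config.coupling_effects.get(group, {}).get(band, {}).get(pair, 0.0))
            if c == 0.0:
                continue
            roi_a, roi_b = pair
            lagged = np.roll(shared, lag)
            w = np.sqrt(c)
            for i, roi in enumerate(rois):
                if roi == roi_a:
                    coupled[i] += w * shared
                    coupling_var[i] += c
                elif roi == roi_b:
                    coupled[i] += w * lagged
                    coupling_var[i] += c

        own_w = np.sqrt(np.clip(1.0 - coupling_var, 0.0, None))
        band_sig = own * own_w[:, None] + coupled
        # renormalize channels whose summed coupling variance exceeded 1
        over = coupling_var > 1
        if over.any():
            band_sig[over] /= np.sqrt(coupling_var[over])[:, None]

        amp = BASE_BAND_AMPLITUDE_UV[band] * jitter[band]
        mults = np.array(
            [_effect_multiplier(config.band_effects, group, band, roi) for roi in rois]
        )
        total += band_sig * (amp * mults)[:, None]

    total += BACKGROUND_AMPLITUDE_UV * _one_over_f_noise(
        rng, (n_ch, n_samples), config.noise_exponent, config.fs
    )

    rec = Recording(
        subject_id=f"sub-{group}{subject_seed:03d}",
        channels=channels,
        fs=config.fs,
        signal=total,
        reference="Pz",
        history=[f"synth(group={group}, seed={config.seed}/{subject_seed})"],
    )
    if config.artifact_rate > 0:
        rec, _ = inject_artifacts(
            rec,
            rate_per_min=config.artifact_rate,
            amplitude_uv=config.artifact_amplitude_uv,
            seed=int(
                np.random.SeedSequence([config.seed, int(subject_seed), 13]).generate_state(1)[0]
            ),
        )
    return rec


def inject_artifacts(
    rec: Recording,
    rate_per_min: float,
    amplitude_uv: float = 150.0,
    seed: int = 0,
    width_s: float = 0.2,
) -> tuple[Recording, list[tuple[int, int]]]:
    """Add transient high-amplitude segments (raised-cosine bumps).

    Segment count is Poisson with mean ``rate_per_min x minutes``. Each
    transient is placed at a random onset on a random subset of channels with
    peak added amplitude ``amplitude_uv``, which must exceed the 80 µV
    rejection threshold so downstream rejection can catch it.

    Returns the modified recording and the list of (start, stop) sample spans.
    """
    if rate_per_min < 0:
        raise ValueError("rate must be non-negative")
    if amplitude_uv <= 80:
        raise ValueError("artifact amplitude must exceed the 80 µV threshold")
    if rate_per_min == 0:
        return rec, []
    rng = np.random.default_rng(seed)
    minutes = rec.duration_s / 60.0
    n_art = rng.poisson(rate_per_min * minutes)
    width = max(4, int(round(width_s * rec.fs)))
    bump = amplitude_uv * 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / (width - 1)))
    out = rec.signal.copy()
    spans: list[tuple[int, int]] = []
    for _ in range(n_art):
        start = int(rng.integers(0, max(1, rec.n_samples - width)))
        n_hit = int(rng.integers(1, min(4, len(rec.channels)) + 1))
        hit = rng.choice(len(rec.channels), size=n_hit, replace=False)
        sign = rng.choice([-1.0, 1.0])
        out[hit, start : start + width] += sign * bump
        spans.append((start, start + width))
    new = rec._evolve(out, f"inject_artifacts(n={n_art}, amp={amplitude_uv}µV)")
    return new, spans


def _sample_metadata(rng: np.random.Generator, group: str, subject_id: str) -> SubjectMetadata:
    """Demographics drawn from the study cohort's moments.

    MDD: age ~ N(22.7, 2.1), HAMD-17 ~ N(21.9, 6.9) truncated at the >= 17
    inclusion cut-off, 14/36 male. HC: age ~ N(25.2, 6.9), 14/31 male,
    HAMD-17 in the non-depressed range.
    """
    if group == "MDD":
        age = float(np.clip(rng.normal(22.7, 2.1), 18, 45))
        sex = "male" if rng.random() < 14 / 36 else "female"
        hamd = 16
        while hamd < 17:
            hamd = int(round(rng.normal(21.9, 6.9)))
    else:
        age = float(np.clip(rng.normal(25.2, 6.9), 18, 45))
        sex = "male" if rng.random() < 14 / 31 else "female"
        hamd = int(np.clip(round(rng.normal(2.0, 1.5)), 0, 7))
    return SubjectMetadata(subject_id=subject_id, group=group, sex=sex, age=round(age, 1), hamd17=hamd)


def generate_cohort(
    config: CohortConfig,
    out_dir: str | Path | None = None,
) -> list[tuple[Recording, SubjectMetadata]]:
    """Generate ``2 x n_per_group`` subjects (MDD first, then HC).

    With ``out_dir`` given, writes one EDF per subject plus ``metadata.csv``
    (columns subject_id, group, sex, age, hamd17).
    """
    if config.n_per_group < 1:
        raise ValueError("n_per_group must be >= 1")
    cohort: list[tuple[Recording, SubjectMetadata]] = []
    for group in ("MDD", "HC"):
        for i in range(config.n_per_group):
            subject_seed = i if group == "MDD" else config.n_per_group + i
            rec = generate_subject(config, group, subject_seed)
            meta_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, subject_seed, 17])
            )
            cohort.append((rec, _sample_metadata(meta_rng, group, rec.subject_id)))

    if out_dir is not None:
        import pandas as pd

        from .edf import write_edf

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for rec, meta in cohort:
            write_edf(out / f"{meta.subject_id}.edf", rec)
        pd.DataFrame(
            [
                {
                    "subject_id": m.subject_id, "group": m.group, "sex": m.sex,
                    "age": m.age, "hamd17": m.hamd17,
                }
                for _, m in cohort
            ]
        ).to_csv(out / "metadata.csv", index=False)
    return cohort
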