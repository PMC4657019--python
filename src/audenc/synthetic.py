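"""Synthetic inputs with known ground truth.

Everything the pipeline consumes can be generated here: sounds with
log-frequency spectral profiles balanced over 7 azimuths, voxels with
joint frequency x azimuth Gaussian tuning, per-sound response amplitudes
Y = W R + noise, event-related BOLD time series (TR = 2.8 s, jittered
interstimulus intervals of 2/3/4 TRs) under a known HRF, and binaural
audio with imposed per-band ILD and ITD.  Known parameters make every
downstream stage testable by recovery.

All randomness flows through one seeded ``numpy.random.Generator``;
regeneration under the same seed is bit-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import model_spaces
from .encoding import TuningMatrix
from .features import FMAX_HZ, FMIN_HZ, center_frequencies, octave_bin_centers
from .hrf import double_gamma_hrf
from .model_spaces import AZIMUTHS_DEG, FeatureMatrix, build_joint


@dataclass
class SoundEvent:
    """One stimulus: spectral profile, azimuth label, split, optional onset."""

    sound_id: str
    split: str
    azimuth_deg: float
    profile: np.ndarray
    onset_tr: int | None = None

    def __post_init__(self) -> None:
        if self.split not in ("train", "test"):
            raise ValueError("split must be 'train' or 'test'")
        self.profile = np.asarray(self.profile, dtype=float)


@dataclass
class GroundTruthVoxel:
    """Separable Gaussian tuning in log2(frequency) x azimuth.

    ``center_frequency`` in Hz within [180, 7040]; ``center_azimuth`` in
    degrees within [-90, 90]; bandwidths in octaves / degrees; additive
    response noise has standard deviation ``noise_sd``.
    """

    center_frequency: float
    center_azimuth: float
    freq_bandwidth: float
    azimuth_bandwidth: float
    gain: float = 1.0
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if not (FMIN_HZ <= self.center_frequency <= FMAX_HZ):
            raise ValueError(
                f"center_frequency {self.center_frequency} Hz outside "
                f"[{FMIN_HZ}, {FMAX_HZ}]"
            )
        if not (-90.0 <= self.center_azimuth <= 90.0):
            raise ValueError("center_azimuth must lie in [-90, 90] deg")
        if self.freq_bandwidth <= 0 or self.azimuth_bandwidth <= 0:
            raise ValueError("tuning bandwidths must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def tuning_grid(self) -> np.ndarray:
        """Tuning evaluated on the joint-model 6 x 7 (frequency x azimuth) grid."""
        f = octave_bin_centers(model_spaces.N_JOINT_FREQ_BINS)
        df = np.log2(f / self.center_frequency) / self.freq_bandwidth
        da = (AZIMUTHS_DEG - self.center_azimuth) / self.azimuth_bandwidth
        return self.gain * np.outer(np.exp(-0.5 * df**2), np.exp(-0.5 * da**2))

    def tuning_vector(self) -> np.ndarray:
        """Grid flattened to 42 entries in the joint model's column order."""
        return self.tuning_grid().T.ravel()


@dataclass
class SyntheticDataset:
    """Events plus ground-truth joint features, tuning, and noisy responses."""

    events: list
    W_true: FeatureMatrix
    R_true: TuningMatrix
    Y: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        if self.Y.shape[0] != len(self.events):
            raise ValueError("Y must have one row per event")
        if self.Y.shape[1] != self.R_true.n_voxels:
            raise ValueError("Y must have one column per voxel")

    def split_indices(self, split: str) -> np.ndarray:
        return np.array([i for i, e in enumerate(self.events) if e.split == split])

    def azimuths(self, split: str | None = None) -> np.ndarray:
        events = self.events if split is None else [
            e for e in self.events if e.split == split
        ]
        return np.array([e.azimuth_deg for e in events])


def _random_profile(rng: np.random.Generator, n_channels: int = 128) -> np.ndarray:
    """Mixture of 1-3 Gaussian bumps in log-frequency, widths 0.3-1.5 octaves."""
    log_f = np.log2(center_frequencies(n_channels))
    lo, hi = np.log2(FMIN_HZ), np.log2(FMAX_HZ)
    n_bumps = int(rng.integers(1, 4))
    profile = np.zeros(n_channels)
    for _ in range(n_bumps):
        center = rng.uniform(lo, hi)
        width = rng.uniform(0.3, 1.5)
        amp = rng.uniform(0.5, 1.0)
        profile += amp * np.exp(-0.5 * ((log_f - center) / width) ** 2)
    return profile


def generate_sound_set(
    n_train: int, n_test: int, n_azimuths: int = 7, seed: int = 0
) -> list:
    """Balanced train/test sound sets over the azimuth grid.

    Each azimuth receives n_train/n_azimuths training and n_test/n_azimuths
    test sounds; every sound carries a synthetic log-frequency spectral
    profile (mixture of band-limited bumps over 180-7040 Hz).
    """
    if n_train % n_azimuths or n_test % n_azimuths:
        raise ValueError(
            f"n_azimuths={n_azimuths} must divide both n_train={n_train} "
            f"and n_test={n_test} for a balanced design"
        )
    if n_azimuths == 7:
        azimuth_grid = AZIMUTHS_DEG
    else:
        azimuth_grid = np.linspace(-90.0, 90.0, n_azimuths)

    rng = np.random.default_rng(seed)
    events: list[SoundEvent] = []
    for split, n in (("train", n_train), ("test", n_test)):
        azimuths = np.tile(azimuth_grid, n // n_azimuths)
        azimuths = azimuths[rng.permutation(n)]
        for i in range(n):
            events.append(
                SoundEvent(
                    sound_id=f"{split}_{i:03d}",
                    split=split,
                    azimuth_deg=float(azimuths[i]),
                    profile=_random_profile(rng),
                )
            )
    return events


def random_voxels(
    n_voxels: int,
    seed: int = 0,
    noise_sd: float = 0.05,
    on_grid: bool = False,
) -> list:
    """Random jointly tuned voxels; ``on_grid`` snaps centers to the 6x7 grid."""
    rng = np.random.default_rng(seed)
    voxels = []
    for _ in range(n_voxels):
        if on_grid:
            cf = float(rng.choice(octave_bin_centers(model_spaces.N_JOINT_FREQ_BINS)))
            ca = float(rng.choice(AZIMUTHS_DEG))
        else:
            cf = float(2.0 ** rng.uniform(np.log2(FMIN_HZ), np.log2(FMAX_HZ)))
            ca = float(rng.uniform(-90.0, 90.0))
        voxels.append(
            GroundTruthVoxel(
                center_frequency=cf,
                center_azimuth=ca,
                freq_bandwidth=float(rng.uniform(0.5, 1.5)),
                azimuth_bandwidth=float(rng.uniform(25.0, 45.0)),
                gain=1.0,
                noise_sd=noise_sd,
            )
        )
    return voxels


def generate_responses(events: list, voxels: list, seed: int = 0) -> SyntheticDataset:
    """Y = W_joint(events) R_true + Gaussian noise, with R_true from voxel tuning."""
    if not voxels:
        raise ValueError("voxel list is empty")
    for e in events:
        if e.profile is None or np.asarray(e.profile).size != 128:
            raise ValueError(f"event {e.sound_id} lacks a 128-channel profile")

    rng = np.random.default_rng(seed)
    W = build_joint([e.profile for e in events], [e.azimuth_deg for e in events])
    R = np.column_stack([v.tuning_vector() for v in voxels])
    noise_sd = np.array([v.noise_sd for v in voxels])
    Y = W.values @ R + rng.standard_normal((len(events), len(voxels))) * noise_sd

    R_true = TuningMatrix(
        R,
        np.zeros(len(voxels)),
        model_kind="joint",
        label_frequency=W.label_frequency,
        label_azimuth=W.label_azimuth,
    )
    return SyntheticDataset(events=list(events), W_true=W, R_true=R_true, Y=Y, seed=seed)


def generate_timeseries(
    dataset: SyntheticDataset,
    tr: float = 2.8,
    hrf: np.ndarray | None = None,
    jitter_trs: tuple = (2, 3, 4),
    noise_sd: float = 0.0,
    seed: int = 0,
    lead_in_trs: int = 2,
):
    """Event-related voxel time series from the dataset's response amplitudes.

    Events are presented in random order at interstimulus intervals drawn
    from ``jitter_trs`` (in TRs); each voxel's series is the sum over events
    of beta x shifted HRF plus white noise.  ``hrf`` is one kernel shared by
    all voxels or a (taps x voxels) array of per-voxel kernels (to exercise
    per-voxel deconvolution).  Returns ``(values, event_table)`` where
    ``values`` is (TRs x voxels) and the table records onsets in TR units.
    """
    if hrf is None:
        hrf = double_gamma_hrf(tr)
    hrf = np.asarray(hrf, dtype=float)
    if hrf.ndim == 2 and hrf.shape[1] != dataset.Y.shape[1]:
        raise ValueError("per-voxel HRF must have one column per voxel")
    rng = np.random.default_rng(seed)

    n_events = len(dataset.events)
    order = rng.permutation(n_events)
    isis = rng.choice(np.asarray(list(jitter_trs), dtype=int), size=n_events - 1)
    onsets = lead_in_trs + np.concatenate([[0], np.cumsum(isis)])

    n_taps = hrf.shape[0]
    n_trs = int(onsets[-1] + n_taps + 2)
    n_voxels = dataset.Y.shape[1]
    values = np.zeros((n_trs, n_voxels))
    rows = []
    for onset, idx in zip(onsets, order):
        event = dataset.events[idx]
        if hrf.ndim == 1:
            values[onset : onset + n_taps] += np.outer(hrf, dataset.Y[idx])
        else:
            values[onset : onset + n_taps] += hrf * dataset.Y[idx]
        rows.append(
            {
                "sound_id": event.sound_id,
                "split": event.split,
                "azimuth_deg": event.azimuth_deg,
                "onset_tr": int(onset),
            }
        )
    if noise_sd > 0:
        values += rng.standard_normal(values.shape) * noise_sd

    event_table = pd.DataFrame(rows)
    return values, event_table


def _carrier_spectrum(
    carrier_spec, freqs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Complex left-channel spectrum on the rfft grid.

    ``carrier_spec``: None for broadband noise (100-7500 Hz), a 2-tuple
    (lo, hi) for bandpass noise, or a list/array of tone frequencies for a
    random-phase multi-tone complex.
    """
    spectrum = np.zeros(freqs.size, dtype=complex)
    if carrier_spec is None or (
        isinstance(carrier_spec, tuple) and len(carrier_spec) == 2
    ):
        lo, hi = carrier_spec if carrier_spec is not None else (100.0, 7500.0)
        band = (freqs >= lo) & (freqs <= hi)
        phases = rng.uniform(0, 2 * np.pi, int(band.sum()))
        spectrum[band] = np.exp(1j * phases)
    else:
        tones = np.atleast_1d(np.asarray(carrier_spec, dtype=float))
        for f in tones:
            k = int(np.argmin(np.abs(freqs - f)))
            spectrum[k] = np.exp(1j * rng.uniform(0, 2 * np.pi))
    return spectrum


def generate_binaural_audio(
    carrier_spec=None,
    ild_db_by_band=None,
    itd_us: float = 0.0,
    fs: float = 16000.0,
    seed: int = 0,
    duration: float = 1.0,
    channel_noise_db: float | None = None,
):
    """Stereo audio with imposed per-band ILD and a broadband ITD.

    The right channel is the left channel with per-band amplitude gain
    10^(-ILD/20) (so positive ILD means left louder) and a time delay of
    ``itd_us`` microseconds (positive: left leads).  ``ild_db_by_band`` is a
    list of (f_lo_hz, f_hi_hz, ild_db) triples, or a scalar for broadband
    ILD.  ``channel_noise_db`` optionally adds independent per-channel noise
    at the given level (dB relative to channel RMS).

    Returns ``(stereo, meta)``: an (n, 2) float array and a metadata dict.
    ITDs whose implied phase reaches pi inside a requested ILD band are
    recorded as warnings in ``meta['warnings']``.
    """
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)

    spectrum_l = _carrier_spectrum(carrier_spec, freqs, rng)

    gain = np.ones(freqs.size)
    bands = []
    if ild_db_by_band is not None:
        if np.isscalar(ild_db_by_band):
            bands = [(0.0, fs / 2, float(ild_db_by_band))]
        else:
            bands = [(float(lo), float(hi), float(db)) for lo, hi, db in ild_db_by_band]
        for lo, hi, db in bands:
            sel = (freqs >= lo) & (freqs < hi)
            gain[sel] = 10.0 ** (-db / 20.0)

    tau = itd_us * 1e-6
    spectrum_r = spectrum_l * gain * np.exp(-2j * np.pi * freqs * tau)

    warnings: list[str] = []
    if tau != 0.0:
        f_ambig = 1.0 / (2.0 * abs(tau))
        for lo, hi, _ in bands or [(0.0, fs / 2, 0.0)]:
            if hi > f_ambig:
                warnings.append(
                    f"ITD {itd_us} us implies |phase| >= pi above {f_ambig:.0f} Hz, "
                    f"inside the band ({lo:.0f}, {hi:.0f}) Hz"
                )

    left = np.fft.irfft(spectrum_l, n=n)
    right = np.fft.irfft(spectrum_r, n=n)

    ramp_len = int(0.01 * fs)
    if ramp_len > 1:
        ramp = np.linspace(0.0, 1.0, ramp_len)
        for ch in (left, right):
            ch[:ramp_len] *= ramp
            ch[-ramp_len:] *= ramp[::-1]

    if channel_noise_db is not None:
        # one shared reference level: a lateralized noise floor would leak
        # spurious ILD into bins that carry no stimulus energy
        rms = np.sqrt(0.5 * (np.mean(left**2) + np.mean(right**2)))
        for ch in (left, right):
            ch += rng.standard_normal(n) * rms * 10.0 ** (channel_noise_db / 20.0)

    scale = max(np.max(np.abs(left)), np.max(np.abs(right)), 1e-12)
    stereo = np.column_stack([left, right]) / scale

    meta = {
        "fs": fs,
        "itd_us": itd_us,
        "ild_db_by_band": bands,
        "warnings": warnings,
    }
    return stereo, meta
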