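"""Cochlear-style spectral features.

Audio is passed through a bank of 128 overlapping bandpass (gammatone)
filters whose center frequencies are equally spaced on a logarithmic axis
between 180 and 7040 Hz (5.3 octaves).  Per-channel energy is half-wave
rectified, squared and framed, yielding an auditory spectrogram; averaging
over time gives the spectral profile that all encoding-model feature
spaces are built from.  The tonotopic axis can then be reduced to a small
number of bins with equal bandwidth in octaves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve, gammatone

FMIN_HZ = 180.0
FMAX_HZ = 7040.0
N_CHANNELS = 128

#: span of the tonotopic axis in octaves, log2(7040 / 180)
N_OCTAVES = float(np.log2(FMAX_HZ / FMIN_HZ))

_FRAME_S = 0.008  # 8 ms energy frames; immaterial after time averaging


def center_frequencies(
    n_channels: int = N_CHANNELS, fmin: float = FMIN_HZ, fmax: float = FMAX_HZ
) -> np.ndarray:
    """Log-spaced filterbank center frequencies in Hz (both endpoints included)."""
    # equals fmin * 2^(k * log2(fmax/fmin) / (n-1)), with exact endpoints
    return np.geomspace(fmin, fmax, n_channels)


def octave_bin_edges(n_bins: int, fmin: float = FMIN_HZ, fmax: float = FMAX_HZ) -> np.ndarray:
    """Edges of ``n_bins`` frequency bins of equal bandwidth in octaves, in Hz."""
    return np.geomspace(fmin, fmax, n_bins + 1)


def octave_bin_centers(n_bins: int, fmin: float = FMIN_HZ, fmax: float = FMAX_HZ) -> np.ndarray:
    """Geometric (log-domain) centers of the octave-spaced bins, in Hz."""
    edges = octave_bin_edges(n_bins, fmin, fmax)
    return np.sqrt(edges[:-1] * edges[1:])


@dataclass
class CochlearSpectrogram:
    """Nonnegative per-channel energy over time frames.

    ``values`` has shape (channels, frames); ``center_frequencies`` is
    strictly increasing and equally spaced in log2(Hz).
    """

    values: np.ndarray
    center_frequencies: np.ndarray
    frame_rate: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.center_frequencies = np.asarray(self.center_frequencies, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("spectrogram values must be 2-D (channels x frames)")
        if self.values.shape[0] != self.center_frequencies.size:
            raise ValueError("channel count must match center frequency count")
        if np.any(np.diff(self.center_frequencies) <= 0):
            raise ValueError("center frequencies must be strictly increasing")


@dataclass
class SpectralProfile:
    """Time-averaged spectral energy, raw (128 channels) or octave-binned."""

    values: np.ndarray
    frequencies: np.ndarray
    bin_edges: np.ndarray | None = field(default=None)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if self.values.shape != self.frequencies.shape:
            raise ValueError("values and frequencies must have matching length")
        if self.bin_edges is not None:
            self.bin_edges = np.asarray(self.bin_edges, dtype=float)
            if self.bin_edges.size != self.values.size + 1:
                raise ValueError("bin_edges must have length len(values) + 1")


def cochlear_filterbank(
    audio: np.ndarray,
    fs: float,
    n_channels: int = N_CHANNELS,
    fmin: float = FMIN_HZ,
    fmax: float = FMAX_HZ,
) -> CochlearSpectrogram:
    """Filter ``audio`` through the log-spaced gammatone bank and frame energies.

    Parameters
    ----------
    audio:
        Mono waveform (finite samples).
    fs:
        Sampling rate in Hz; must satisfy fs >= 2 * fmax (Nyquist).

    Returns
    -------
    CochlearSpectrogram
        (n_channels x frames) half-wave-rectified squared energy at 8 ms frames.
    """
    audio = np.asarray(audio, dtype=float)
    if audio.ndim != 1:
        raise ValueError("audio must be a 1-D mono waveform")
    if audio.size == 0:
        raise ValueError("audio is empty")
    if not np.all(np.isfinite(audio)):
        raise ValueError("audio contains non-finite samples")
    if fs < 2.0 * fmax:
        raise ValueError(
            f"sampling rate {fs} Hz violates the Nyquist bound for fmax={fmax} Hz "
            f"(need fs >= {2.0 * fmax} Hz)"
        )

    cfs = center_frequencies(n_channels, fmin, fmax)
    frame_len = max(1, int(round(_FRAME_S * fs)))
    n_frames = max(1, audio.size // frame_len)

    values = np.empty((n_channels, n_frames))
    for k, cf in enumerate(cfs):
        b, _ = gammatone(cf, "fir", fs=fs)
        y = fftconvolve(audio, b, mode="full")[: audio.size]
        energy = np.square(np.maximum(y, 0.0))  # half-wave rectify, square
        trimmed = energy[: n_frames * frame_len].reshape(n_frames, frame_len)
        values[k] = trimmed.mean(axis=1)

    return CochlearSpectrogram(values, cfs, frame_rate=fs / frame_len)


def time_average(spec: CochlearSpectrogram) -> SpectralProfile:
    """Arithmetic mean of the spectrogram over time frames."""
    if spec.values.shape[1] < 1:
        raise ValueError("spectrogram has no time frames")
    return SpectralProfile(spec.values.mean(axis=1), spec.center_frequencies)


def octave_bin_assignment(
    channel_frequencies: np.ndarray,
    n_bins: int,
    fmin: float = FMIN_HZ,
    fmax: float = FMAX_HZ,
) -> np.ndarray:
    """Bin index for each channel: half-open octave bins, last bin closed at the top.

    Every channel belongs to exactly one bin (a partition of the channels).
    """
    edges = octave_bin_edges(n_bins, fmin, fmax)
    idx = np.digitize(channel_frequencies, edges[1:-1], right=False)
    return np.clip(idx, 0, n_bins - 1)


def bin_octaves(profile: SpectralProfile | np.ndarray, n_bins: int) -> SpectralProfile:
    """Average a 128-channel profile into ``n_bins`` equal-octave-bandwidth bins.

    Bin value is the mean of member channels; a bin with no member channels
    (possible only for unusual n_bins) gets value 0.
    """
    if isinstance(profile, SpectralProfile):
        values = profile.values
        freqs = profile.frequencies
    else:
        values = np.asarray(profile, dtype=float)
        freqs = center_frequencies(values.size)
    if n_bins > values.size:
        raise ValueError(
            f"cannot bin {values.size} channels into {n_bins} bins (n_bins > channels)"
        )
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")

    assignment = octave_bin_assignment(freqs, n_bins)
    sums = np.bincount(assignment, weights=values, minlength=n_bins)
    counts = np.bincount(assignment, minlength=n_bins)
    binned = np.divide(sums, counts, out=np.zeros(n_bins), where=counts > 0)

    return SpectralProfile(
        binned, octave_bin_centers(n_bins), bin_edges=octave_bin_edges(n_bins)
    )
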