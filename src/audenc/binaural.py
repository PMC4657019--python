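"""Stimulus-side binaural cue analysis: per-frequency ILD and ITD.

ILD is the difference in time-averaged log power (dB) between the left
and right ear spectrograms (positive = left louder).  ITD is obtained by
converting the interaural phase difference per frequency bin to a time
difference, ITD = dphi / (2 pi f), with the phase difference averaged
circularly over time frames weighted by power.  Phase is only
unambiguous while |dphi| < pi, i.e. below f = 1 / (2 |ITD|); bins above
the ambiguity limit for the assumed maximum ITD are flagged invalid.

A short-time Fourier front end (32 ms Hann window, 8 ms hop) is used
here because cue extraction needs phase; the cochlear filterbank of
:mod:`audenc.features` is energy-only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.signal import ShortTimeFFT
from scipy.signal.windows import hann
from scipy.stats import ttest_1samp

#: assumed physiological maximum |ITD| (human head), microseconds
DEFAULT_MAX_ITD_US = 700.0

_WINDOW_S = 0.032
_HOP_S = 0.008


@dataclass
class CueSpectrum:
    """Per-frequency-bin ILD (dB) and ITD (us) with a phase-validity mask."""

    frequencies: np.ndarray
    ild: np.ndarray
    itd: np.ndarray
    valid_mask: np.ndarray
    power: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.ild = np.asarray(self.ild, dtype=float)
        self.itd = np.asarray(self.itd, dtype=float)
        self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
        if not (
            self.frequencies.size == self.ild.size == self.itd.size == self.valid_mask.size
        ):
            raise ValueError("cue spectrum arrays must share length")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frequency_hz": self.frequencies,
                "ild_db": self.ild,
                "itd_us": self.itd,
                "valid": self.valid_mask,
            }
        )


def stft_pair(stereo: np.ndarray, fs: float):
    """Complex spectrograms (bins x frames) of the two channels plus bin freqs."""
    stereo = np.asarray(stereo, dtype=float)
    if stereo.ndim != 2 or stereo.shape[1] != 2:
        raise ValueError("expected an (n_samples, 2) stereo array")
    win_len = int(round(_WINDOW_S * fs))
    hop = int(round(_HOP_S * fs))
    stft = ShortTimeFFT(hann(win_len, sym=False), hop=hop, fs=fs)
    Zl = stft.stft(stereo[:, 0])
    Zr = stft.stft(stereo[:, 1])
    return Zl, Zr, stft.f


def compute_ild(left_power: np.ndarray, right_power: np.ndarray) -> np.ndarray:
    """Per-bin ILD in dB from matched power spectrograms (positive = left louder)."""
    left_power = np.asarray(left_power, dtype=float)
    right_power = np.asarray(right_power, dtype=float)
    if left_power.shape != right_power.shape:
        raise ValueError("left and right spectrograms must share the same grid")
    pl = left_power.mean(axis=-1) if left_power.ndim == 2 else left_power
    pr = right_power.mean(axis=-1) if right_power.ndim == 2 else right_power
    with np.errstate(divide="ignore", invalid="ignore"):
        ild = 10.0 * np.log10(pl / pr)
    return ild


def compute_itd(
    left_spec: np.ndarray,
    right_spec: np.ndarray,
    frequencies: np.ndarray,
    max_itd_us: float = DEFAULT_MAX_ITD_US,
):
    """Per-bin ITD in microseconds from complex spectrograms.

    The interaural phase difference is the angle of the power-weighted mean
    cross-spectrum over frames (a circular mean); ITD = dphi / (2 pi f).
    Returns ``(itd_us, valid_mask)``; bins at or above the ambiguity limit
    f >= 1 / (2 max_itd) — where |implied phase| reaches pi — are invalid.
    """
    left_spec = np.asarray(left_spec)
    right_spec = np.asarray(right_spec)
    if left_spec.shape != right_spec.shape:
        raise ValueError("left and right spectrograms must share the same grid")
    frequencies = np.asarray(frequencies, dtype=float)

    cross = left_spec * np.conj(right_spec)
    if cross.ndim == 2:
        cross = cross.sum(axis=-1)
    dphi = np.angle(cross)

    with np.errstate(divide="ignore", invalid="ignore"):
        itd_us = dphi / (2.0 * np.pi * frequencies) * 1e6

    f_ambig = 1.0 / (2.0 * max_itd_us * 1e-6)
    valid = (frequencies > 0) & (frequencies < f_ambig)
    itd_us = np.where(frequencies > 0, itd_us, 0.0)
    return itd_us, valid


def analyze_binaural(
    stereo: np.ndarray, fs: float, max_itd_us: float = DEFAULT_MAX_ITD_US
) -> CueSpectrum:
    """Full cue spectrum (ILD, ITD, validity, mean power) of one stereo sound."""
    Zl, Zr, freqs = stft_pair(stereo, fs)
    pl = np.abs(Zl) ** 2
    pr = np.abs(Zr) ** 2
    ild = compute_ild(pl, pr)
    itd, valid = compute_itd(Zl, Zr, freqs, max_itd_us=max_itd_us)
    power = 0.5 * (pl.mean(axis=-1) + pr.mean(axis=-1))
    return CueSpectrum(freqs, ild, itd, valid, power=power)


def cue_informativeness(
    cues_at_minus90: list,
    cues_at_plus90: list,
    cue: str = "ild",
    alpha: float = 0.05,
    min_power_db: float | None = -40.0,
) -> pd.DataFrame:
    """Per-bin cue informativeness across a sound set, with one-tailed testing.

    For each frequency bin the cue value at +90 deg is subtracted from that
    at -90 deg per sound; positive values mean the cue distinguishes the two
    extreme azimuths (is informative).  The mean difference is normalized by
    its maximum over bins, and each bin is tested with a one-tailed
    one-sample t-test against 0, Bonferroni-corrected over tested bins.

    ``min_power_db`` excludes bins whose mean power is more than that many
    dB below the loudest bin (cues are undefined without stimulus energy);
    ``None`` tests every bin.  For ``cue='itd'`` only phase-valid bins are
    tested.

    Returns a DataFrame with columns frequency_hz, statistic (normalized
    mean difference), t_stat, p_corrected, significant, tested.
    """
    if len(cues_at_minus90) < 2 or len(cues_at_plus90) < 2:
        raise ValueError("need at least 2 sounds per azimuth for a variance estimate")
    if len(cues_at_minus90) != len(cues_at_plus90):
        raise ValueError("need paired sounds at -90 and +90 deg")
    if cue not in ("ild", "itd"):
        raise ValueError("cue must be 'ild' or 'itd'")

    freqs = cues_at_minus90[0].frequencies
    for c in list(cues_at_minus90) + list(cues_at_plus90):
        if not np.array_equal(c.frequencies, freqs):
            raise ValueError("cue spectra are not on a common frequency grid")

    get = (lambda c: c.ild) if cue == "ild" else (lambda c: c.itd)
    diffs = np.array(
        [get(m) - get(p) for m, p in zip(cues_at_minus90, cues_at_plus90)]
    )  # sounds x bins

    tested = np.all(np.isfinite(diffs), axis=0)
    if cue == "itd":
        for c in list(cues_at_minus90) + list(cues_at_plus90):
            tested &= c.valid_mask
    if min_power_db is not None:
        powers = [
            c.power for c in list(cues_at_minus90) + list(cues_at_plus90)
            if c.power is not None
        ]
        if powers:
            mean_power = np.mean(powers, axis=0)
            floor = mean_power.max() * 10.0 ** (min_power_db / 10.0)
            tested &= mean_power >= floor

    mean_diff = np.where(tested, diffs.mean(axis=0), np.nan)
    finite = mean_diff[np.isfinite(mean_diff)]
    norm = np.max(finite) if finite.size and np.max(finite) > 0 else (
        np.max(np.abs(finite)) if finite.size else 1.0
    )
    statistic = mean_diff / (norm if norm > 0 else 1.0)

    n_tested = int(tested.sum())
    t_stat = np.full(freqs.size, np.nan)
    p_corr = np.full(freqs.size, np.nan)
    if n_tested:
        res = ttest_1samp(diffs[:, tested], 0.0, alternative="greater")
        t_stat[tested] = res.statistic
        p_corr[tested] = np.minimum(res.pvalue * n_tested, 1.0)  # Bonferroni
    significant = tested & (p_corr < alpha)

    return pd.DataFrame(
        {
            "frequency_hz": freqs,
            "statistic": statistic,
            "t_stat": t_stat,
            "p_corrected": p_corr,
            "significant": significant,
            "tested": tested,
        }
    )
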