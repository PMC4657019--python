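"""The four stimulus feature spaces (sounds x features matrices W).

All four model spaces share a common budget of F = 42 parameters, chosen
relative to the 56 training sounds:

* ``frequency_only``   — 42 octave-spaced frequency bins, no location.
* ``location_only``    — 7 azimuth blocks of 6 bins; a sound activates its
  azimuth's block with the fixed taper [1/6, 1/3, 1, 1, 1/3, 1/6].
* ``independent``      — 35 frequency bins concatenated with a 7-bin
  azimuth one-hot (frequency and location coded independently).
* ``joint``            — 6 frequency bins x 7 azimuths; a sound's 6-bin
  spectral profile is written into its azimuth's block (frequency-specific
  location channels).

Column ordering for location-bearing spaces is azimuth-major (blocks
ascending from -90 deg to +90 deg), frequency ascending within a block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .features import SpectralProfile, bin_octaves, octave_bin_centers

AZIMUTHS_DEG = np.array([-90, -60, -30, 0, 30, 60, 90], dtype=float)
N_AZIMUTHS = AZIMUTHS_DEG.size

#: within-block activation taper of the location-only space
LOCATION_TAPER = np.array([1 / 6, 1 / 3, 1.0, 1.0, 1 / 3, 1 / 6])

N_FEATURES = 42
N_JOINT_FREQ_BINS = 6

MODEL_KINDS = ("frequency_only", "location_only", "independent", "joint")


@dataclass
class FeatureMatrix:
    """Sounds x features stimulus representation under one model space.

    ``label_frequency`` / ``label_azimuth`` give each column's frequency-bin
    center (Hz) and/or azimuth (deg); NaN where the column does not carry
    that attribute.
    """

    values: np.ndarray
    model_kind: str
    label_frequency: np.ndarray
    label_azimuth: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        self.label_frequency = np.asarray(self.label_frequency, dtype=float)
        self.label_azimuth = np.asarray(self.label_azimuth, dtype=float)
        if self.model_kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.model_kind!r}")
        if self.values.shape[1] != self.label_frequency.size:
            raise ValueError("feature labels must match the column count")
        if self.label_frequency.size != self.label_azimuth.size:
            raise ValueError("frequency and azimuth labels must have equal length")

    @property
    def n_sounds(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def labels_match(self, other: "FeatureMatrix") -> bool:
        """True when the two matrices share model kind and column labels."""
        return (
            self.model_kind == other.model_kind
            and self.n_features == other.n_features
            and np.array_equal(
                np.nan_to_num(self.label_frequency, nan=-1.0),
                np.nan_to_num(other.label_frequency, nan=-1.0),
            )
            and np.array_equal(
                np.nan_to_num(self.label_azimuth, nan=-999.0),
                np.nan_to_num(other.label_azimuth, nan=-999.0),
            )
        )


def azimuth_index(azimuth_deg: float) -> int:
    """Block index of an azimuth on the -90..+90 deg grid (30 deg steps)."""
    matches = np.nonzero(np.isclose(AZIMUTHS_DEG, azimuth_deg))[0]
    if matches.size == 0:
        raise ValueError(
            f"azimuth {azimuth_deg} deg is not on the grid {AZIMUTHS_DEG.tolist()}"
        )
    return int(matches[0])


def _profile_values(profile: SpectralProfile | np.ndarray) -> np.ndarray:
    values = profile.values if isinstance(profile, SpectralProfile) else np.asarray(profile)
    if values.size != 128:
        raise ValueError(f"expected a 128-channel spectral profile, got {values.size}")
    return values


def build_frequency_only(profiles: list) -> FeatureMatrix:
    """42 octave-spaced frequency bins per sound, no location information."""
    rows = [bin_octaves(_profile_values(p), N_FEATURES).values for p in profiles]
    return FeatureMatrix(
        np.vstack(rows),
        "frequency_only",
        label_frequency=octave_bin_centers(N_FEATURES),
        label_azimuth=np.full(N_FEATURES, np.nan),
    )


def build_location_only(azimuths: np.ndarray) -> FeatureMatrix:
    """7 azimuth blocks x 6 bins; the sound's block carries the fixed taper."""
    azimuths = np.atleast_1d(np.asarray(azimuths, dtype=float))
    values = np.zeros((azimuths.size, N_FEATURES))
    for i, az in enumerate(azimuths):
        a = azimuth_index(az)
        values[i, a * 6 : (a + 1) * 6] = LOCATION_TAPER
    return FeatureMatrix(
        values,
        "location_only",
        label_frequency=np.full(N_FEATURES, np.nan),
        label_azimuth=np.repeat(AZIMUTHS_DEG, 6),
    )


def build_independent(profiles: list, azimuths: np.ndarray) -> FeatureMatrix:
    """35 frequency bins concatenated with a 7-entry azimuth one-hot."""
    azimuths = np.atleast_1d(np.asarray(azimuths, dtype=float))
    if len(profiles) != azimuths.size:
        raise ValueError("profiles and azimuths must have equal length")
    values = np.zeros((azimuths.size, N_FEATURES))
    for i, (p, az) in enumerate(zip(profiles, azimuths)):
        values[i, :35] = bin_octaves(_profile_values(p), 35).values
        values[i, 35 + azimuth_index(az)] = 1.0
    return FeatureMatrix(
        values,
        "independent",
        label_frequency=np.concatenate([octave_bin_centers(35), np.full(7, np.nan)]),
        label_azimuth=np.concatenate([np.full(35, np.nan), AZIMUTHS_DEG]),
    )


def build_joint(profiles: list, azimuths: np.ndarray) -> FeatureMatrix:
    """6 frequency bins x 7 azimuths; the 6-bin profile fills the azimuth block."""
    azimuths = np.atleast_1d(np.asarray(azimuths, dtype=float))
    if len(profiles) != azimuths.size:
        raise ValueError("profiles and azimuths must have equal length")
    values = np.zeros((azimuths.size, N_FEATURES))
    for i, (p, az) in enumerate(zip(profiles, azimuths)):
        a = azimuth_index(az)
        values[i, a * 6 : (a + 1) * 6] = bin_octaves(_profile_values(p), 6).values
    return FeatureMatrix(
        values,
        "joint",
        label_frequency=np.tile(octave_bin_centers(N_JOINT_FREQ_BINS), N_AZIMUTHS),
        label_azimuth=np.repeat(AZIMUTHS_DEG, N_JOINT_FREQ_BINS),
    )


def build_model(kind: str, profiles: list, azimuths: np.ndarray) -> FeatureMatrix:
    """Dispatch to one of the four builders by model kind."""
    if kind == "frequency_only":
        return build_frequency_only(profiles)
    if kind == "location_only":
        return build_location_only(azimuths)
    if kind == "independent":
        return build_independent(profiles, azimuths)
    if kind == "joint":
        return build_joint(profiles, azimuths)
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")


def joint_to_grid(column: np.ndarray) -> np.ndarray:
    """Reshape one voxel's 42 joint weights to a 6 x 7 (frequency x azimuth) grid."""
    column = np.asarray(column, dtype=float)
    if column.size != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} joint weights, got {column.size}")
    return column.reshape(N_AZIMUTHS, N_JOINT_FREQ_BINS).T
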