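"""Topographic maps of preferred frequency and azimuth.

Each voxel's 42 joint-model weights are reorganized as a 6 (frequency)
x 7 (azimuth) matrix and 2D smoothed with a small Gaussian kernel
(size 3, SD 0.5 grid units; truncated and renormalized at the edges, so
constants are preserved).  The grid position of the maximum gives the
voxel's best frequency and best azimuth.  Downstream quantifications:

* tonotopic gradient directions — angular histogram of the spatial
  gradient of log2(best frequency) in a 2D slice, with peak detection
  (1 peak for a single gradient, 2 for a mirror-symmetric pattern);
* azimuth-preference distributions, overall and split at a
  characteristic frequency of 1.5 kHz, with periphery-vs-center tests;
* contra/ipsilateral maps via the left-side sign flip.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import convolve
from statsmodels.stats.multitest import multipletests

from .encoding import TuningMatrix, VoxelSelection
from .features import octave_bin_centers
from .model_spaces import AZIMUTHS_DEG, N_JOINT_FREQ_BINS, joint_to_grid

CF_SPLIT_HZ = 1500.0
PERIPHERY_DEG = (-90.0, 90.0)


def _gaussian_kernel_3x3(sd: float = 0.5) -> np.ndarray:
    x = np.array([-1.0, 0.0, 1.0])
    k1 = np.exp(-0.5 * (x / sd) ** 2)
    k = np.outer(k1, k1)
    return k / k.sum()


def smooth_grid(grid: np.ndarray, sd: float = 0.5) -> np.ndarray:
    """3x3 Gaussian smoothing with a renormalized truncated kernel at edges."""
    kernel = _gaussian_kernel_3x3(sd)
    num = convolve(grid, kernel, mode="constant", cval=0.0)
    den = convolve(np.ones_like(grid), kernel, mode="constant", cval=0.0)
    return num / den


def voxel_preference(column: np.ndarray, smoothing_sd: float = 0.5):
    """Best (frequency Hz, azimuth deg) of one voxel's joint weights.

    Ties after smoothing resolve to the lowest frequency bin, then the
    most central azimuth (smallest |azimuth|, left first); a tie flag is
    returned as the third element.
    """
    grid = smooth_grid(joint_to_grid(column), sd=smoothing_sd)
    best = np.max(grid)
    tied = np.argwhere(np.isclose(grid, best, rtol=0.0, atol=1e-12))
    tie_flag = tied.shape[0] > 1
    if tie_flag:
        az_order = np.argsort(np.abs(AZIMUTHS_DEG), kind="stable")
        az_rank = np.empty_like(az_order)
        az_rank[az_order] = np.arange(az_order.size)
        keys = [(f, az_rank[a]) for f, a in tied]
        f_idx, a_idx = tied[int(np.lexsort(([k[1] for k in keys], [k[0] for k in keys]))[0])]
    else:
        f_idx, a_idx = tied[0]
    freqs = octave_bin_centers(N_JOINT_FREQ_BINS)
    return float(freqs[f_idx]), float(AZIMUTHS_DEG[a_idx]), bool(tie_flag)


def preference_table(
    tuning: TuningMatrix, selection: VoxelSelection | None = None
) -> pd.DataFrame:
    """Per-voxel best-frequency/azimuth table for (selected) joint-model voxels."""
    if tuning.model_kind != "joint":
        raise ValueError("preference maps require a joint-model tuning matrix")
    voxels = (
        selection.voxel_ids if selection is not None else np.arange(tuning.n_voxels)
    )
    rows = []
    for v in voxels:
        cf, az, tie = voxel_preference(tuning.weights[:, v])
        rows.append({"voxel": int(v), "cf_hz": cf, "azimuth_deg": az, "tie_flag": tie})
    return pd.DataFrame(rows)


@dataclass
class PreferenceMap:
    """Voxel preferences placed on a volume grid."""

    table: pd.DataFrame
    shape: tuple
    coordinates: np.ndarray
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))
    side: np.ndarray | None = None

    def volume(self, column: str = "cf_hz", fill: float = np.nan) -> np.ndarray:
        vol = np.full(self.shape, fill)
        coords = self.coordinates
        for row_idx, row in self.table.reset_index(drop=True).iterrows():
            i, j, k = coords[row_idx]
            vol[int(i), int(j), int(k)] = row[column]
        return vol

    def to_nifti(self, column: str = "cf_hz"):
        import nibabel as nib

        return nib.Nifti1Image(
            self.volume(column).astype(np.float32), self.affine
        )


def tonotopy_map(
    tuning: TuningMatrix,
    selection: VoxelSelection,
    coordinates: np.ndarray,
    shape: tuple,
    affine: np.ndarray | None = None,
    side: np.ndarray | None = None,
) -> PreferenceMap:
    """Render selected voxels' preferences into a volume grid.

    ``coordinates`` holds the (i, j, k) grid index of every voxel column of
    the tuning matrix; only voxels in ``selection`` enter the map.  The
    log-frequency colour mapping is metadata left to the caller's renderer.
    """
    coordinates = np.asarray(coordinates, dtype=int)
    if coordinates.shape != (tuning.n_voxels, 3):
        raise ValueError("coordinates must be (n_voxels, 3) grid indices")
    if selection.n_selected == 0:
        raise ValueError("voxel selection is empty")
    table = preference_table(tuning, selection)
    return PreferenceMap(
        table=table,
        shape=tuple(shape),
        coordinates=coordinates[selection.voxel_ids],
        affine=affine if affine is not None else np.eye(4),
        side=None if side is None else np.asarray(side)[selection.voxel_ids],
    )


@dataclass
class GradientDistribution:
    """Gradient angles, their angular histogram, and detected peaks."""

    angles: np.ndarray
    histogram: np.ndarray
    bin_edges: np.ndarray
    peaks: np.ndarray


def _slice_gradient(values: np.ndarray):
    """Per-voxel 2D gradient with NaN-aware central/one-sided differences."""
    g0 = np.full_like(values, np.nan)
    g1 = np.full_like(values, np.nan)
    n0, n1 = values.shape

    def diff(a, b, spacing):
        return (b - a) / spacing

    for i in range(n0):
        for j in range(n1):
            if np.isnan(values[i, j]):
                continue
            lo = values[i - 1, j] if i > 0 else np.nan
            hi = values[i + 1, j] if i < n0 - 1 else np.nan
            if not np.isnan(lo) and not np.isnan(hi):
                g0[i, j] = diff(lo, hi, 2.0)
            elif not np.isnan(hi):
                g0[i, j] = diff(values[i, j], hi, 1.0)
            elif not np.isnan(lo):
                g0[i, j] = diff(lo, values[i, j], 1.0)
            lo = values[i, j - 1] if j > 0 else np.nan
            hi = values[i, j + 1] if j < n1 - 1 else np.nan
            if not np.isnan(lo) and not np.isnan(hi):
                g1[i, j] = diff(lo, hi, 2.0)
            elif not np.isnan(hi):
                g1[i, j] = diff(values[i, j], hi, 1.0)
            elif not np.isnan(lo):
                g1[i, j] = diff(lo, values[i, j], 1.0)
    return g0, g1


def gradient_directions(
    map_slice: np.ndarray, bin_width: float = 20.0
) -> GradientDistribution:
    """Distribution of the direction of increasing frequency in a 2D slice.

    ``map_slice`` holds best frequency in Hz (NaN where unmapped).  The
    spatial gradient of log2(frequency) is computed by central differences
    (one-sided at edges and next to unmapped neighbours); the angle
    convention is 0 deg along the first in-plane axis, counterclockwise
    positive, in [0, 360).  The angular histogram is circularly smoothed
    over 3 bins; peaks are strict local maxima reaching at least half the
    histogram maximum, strongest first.
    """
    map_slice = np.asarray(map_slice, dtype=float)
    if map_slice.ndim != 2 or min(map_slice.shape) < 2:
        raise ValueError("need a 2D slice with at least 2x2 mapped voxels")
    if 360.0 % bin_width:
        raise ValueError("bin_width must divide 360")

    with np.errstate(invalid="ignore"):
        log_f = np.log2(map_slice)
    g0, g1 = _slice_gradient(log_f)
    ok = (
        np.isfinite(g0) & np.isfinite(g1) & ~((g0 == 0) & (g1 == 0))
    )
    if not ok.any():
        raise ValueError("no voxel had enough mapped neighbours for a gradient")
    angles = np.degrees(np.arctan2(g1[ok], g0[ok])) % 360.0

    n_bins = int(round(360.0 / bin_width))
    hist, edges = np.histogram(angles, bins=n_bins, range=(0.0, 360.0))

    smoothed = (hist + np.roll(hist, 1) + np.roll(hist, -1)) / 3.0
    centers = (edges[:-1] + edges[1:]) / 2.0

    # circular local maxima; plateaus (ties with a neighbour) count once,
    # represented by their bin with the largest raw count
    candidate = (
        (smoothed >= np.roll(smoothed, 1))
        & (smoothed >= np.roll(smoothed, -1))
        & (smoothed >= 0.5 * smoothed.max())
        & (smoothed > 0)
    )
    peaks = []
    visited = np.zeros(n_bins, dtype=bool)
    for start in np.nonzero(candidate)[0]:
        if visited[start]:
            continue
        run = [start]
        visited[start] = True
        nxt = (start + 1) % n_bins
        while candidate[nxt] and not visited[nxt]:
            run.append(nxt)
            visited[nxt] = True
            nxt = (nxt + 1) % n_bins
        prev = (start - 1) % n_bins
        while candidate[prev] and not visited[prev]:
            run.append(prev)
            visited[prev] = True
            prev = (prev - 1) % n_bins
        best = run[int(np.argmax(hist[run]))]
        peaks.append(best)
    peaks = np.array(sorted(peaks, key=lambda b: -smoothed[b]), dtype=int)
    return GradientDistribution(angles, hist, edges, centers[peaks])


def azimuth_distribution(
    preference_tables,
    cf_split_hz: float = CF_SPLIT_HZ,
    alpha: float = 0.05,
    correction: str = "bonferroni",
):
    """Per-azimuth voxel proportions and periphery-vs-center tests.

    ``preference_tables`` is one table or a list of replicate tables (one
    per subject / simulated replicate) as returned by
    :func:`preference_table`.  Proportions are reported overall and split
    into low (< cf_split_hz) and high (> cf_split_hz) characteristic
    frequency strata (an empty stratum is omitted).  With >= 2 replicates,
    the mean peripheral proportion (+-90 deg) is compared with each central
    azimuth by one-tailed paired t-tests, corrected over comparisons.

    Returns ``(proportions, tests)``: a tidy proportions DataFrame and a
    test DataFrame (empty with a single replicate).
    """
    if isinstance(preference_tables, pd.DataFrame):
        tables = [preference_tables]
    else:
        tables = list(preference_tables)

    strata = {
        "all": lambda t: t,
        "low_cf": lambda t: t[t["cf_hz"] < cf_split_hz],
        "high_cf": lambda t: t[t["cf_hz"] > cf_split_hz],
    }
    prop_rows = []
    per_replicate = {}  # stratum -> (replicates x azimuths) proportions
    for name, pick in strata.items():
        mat = []
        for t in tables:
            sub = pick(t)
            if len(sub) == 0:
                continue
            counts = np.array(
                [np.sum(np.isclose(sub["azimuth_deg"], az)) for az in AZIMUTHS_DEG]
            )
            mat.append(counts / counts.sum())
        if not mat:
            continue  # empty stratum omitted
        mat = np.array(mat)
        per_replicate[name] = mat
        for az, p in zip(AZIMUTHS_DEG, mat.mean(axis=0)):
            prop_rows.append({"stratum": name, "azimuth_deg": az, "proportion": p})
    proportions = pd.DataFrame(prop_rows)

    test_rows = []
    if len(tables) >= 2:
        central = [az for az in AZIMUTHS_DEG if az not in PERIPHERY_DEG]
        for name, mat in per_replicate.items():
            if mat.shape[0] < 2:
                continue
            periph_idx = [i for i, az in enumerate(AZIMUTHS_DEG) if az in PERIPHERY_DEG]
            periph = mat[:, periph_idx].mean(axis=1)
            pvals, tstats = [], []
            for az in central:
                i = int(np.nonzero(AZIMUTHS_DEG == az)[0][0])
                t, p = stats.ttest_rel(periph, mat[:, i], alternative="greater")
                tstats.append(float(t))
                pvals.append(float(p))
            rej, p_adj, *_ = multipletests(pvals, alpha=alpha, method=correction)
            for az, t, p, r in zip(central, tstats, p_adj, rej):
                test_rows.append(
                    {
                        "stratum": name,
                        "center_azimuth_deg": az,
                        "t_stat": t,
                        "p_corrected": p,
                        "significant": bool(r),
                    }
                )
    tests = pd.DataFrame(test_rows)
    return proportions, tests


def laterality_maps(preferences: pd.DataFrame, side_labels) -> pd.DataFrame:
    """Contra/ipsilateral classification via the left-side azimuth sign flip.

    Azimuths of voxels in left-hemisphere structures are multiplied by -1,
    after which negative values indicate contralateral and positive values
    ipsilateral preference; 0 deg voxels are classified ``central`` and are
    excluded from contra/ipsi proportions.
    """
    side = np.asarray(side_labels)
    if side.size != len(preferences):
        raise ValueError("one side label per voxel required")
    if not np.all(np.isin(side, ["left", "right"])):
        bad = side[~np.isin(side, ["left", "right"])][0]
        raise ValueError(f"invalid or missing side label: {bad!r}")

    out = preferences.copy()
    flip = np.where(side == "left", -1.0, 1.0)
    signed = out["azimuth_deg"].to_numpy() * flip
    out["side"] = side
    out["signed_azimuth_deg"] = signed
    out["laterality"] = np.select(
        [signed < 0, signed > 0], ["contra", "ipsi"], default="central"
    )
    return out
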