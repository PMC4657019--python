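"""From voxel time series to the sounds x voxels response matrix Y.

Three stages mirror an event-related GLM pipeline:

1. ``estimate_noise_regressors`` — nuisance components: voxels that the
   task design fails to explain (split-half cross-validated R-squared at
   or below 0) form a noise pool; principal components of their residual
   series become nuisance regressors.
2. ``estimate_hrf`` — one finite-impulse-response HRF per voxel, shared
   across sounds, by deconvolution over a fixed window (default 7 TRs,
   about 20 s at TR = 2.8 s).  Estimated kernels are normalized to unit
   peak; response amplitude lives in the betas.
3. ``estimate_betas`` — per-sound response amplitudes by least squares,
   with each sound's onsets convolved with that voxel's HRF, nuisance
   columns included.

The full path series -> Y is linear in the series for a fixed HRF and
nuisance set.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .hrf import double_gamma_hrf

DEFAULT_HRF_WINDOW_TRS = 7
DEFAULT_N_NOISE_COMPONENTS = 5


@dataclass
class VoxelTimeSeries:
    """(TRs x voxels) signal with TR in seconds and an event table."""

    values: np.ndarray
    tr: float
    event_table: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        onsets = np.asarray(self.event_table["onset_tr"], dtype=int)
        if onsets.size and (onsets.min() < 0 or onsets.max() >= self.values.shape[0]):
            raise ValueError("event onsets fall outside the series")


@dataclass
class ResponseMatrix:
    """Betas (sounds x voxels) with sound and voxel identifiers."""

    betas: np.ndarray
    sound_ids: list
    voxel_ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.betas = np.atleast_2d(np.asarray(self.betas, dtype=float))
        if not np.all(np.isfinite(self.betas)):
            raise ValueError("betas must be finite")
        if self.betas.shape[0] != len(self.sound_ids):
            raise ValueError("one beta row per sound required")
        if self.voxel_ids is None:
            self.voxel_ids = np.arange(self.betas.shape[1])


def _filter_events(event_table: pd.DataFrame) -> pd.DataFrame:
    """Drop target and zero trials before estimation, if flagged."""
    table = event_table
    if "trial_type" in table.columns:
        table = table[~table["trial_type"].isin(["target", "zero"])]
    return table.reset_index(drop=True)


def _onset_matrix(event_table: pd.DataFrame, n_trs: int):
    """Per-sound onset indicator matrix (TRs x sounds) and the sound id list."""
    sound_ids = list(dict.fromkeys(event_table["sound_id"]))
    index = {s: i for i, s in enumerate(sound_ids)}
    X = np.zeros((n_trs, len(sound_ids)))
    for _, row in event_table.iterrows():
        X[int(row["onset_tr"]), index[row["sound_id"]]] += 1.0
    return X, sound_ids


def _convolve_columns(X: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causally convolve each onset column with a kernel, truncated to length."""
    n = X.shape[0]
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        out[:, j] = np.convolve(X[:, j], kernel)[:n]
    return out


def _task_design(event_table: pd.DataFrame, n_trs: int, tr: float) -> np.ndarray:
    """Combined task regressor: all onsets convolved with the canonical HRF.

    A single shared column (rather than per-sound regressors) so that the
    split-half fit is well-posed even when each sound is presented once.
    """
    onsets, _ = _onset_matrix(event_table, n_trs)
    return _convolve_columns(onsets.sum(axis=1, keepdims=True), double_gamma_hrf(tr))


def _split_half_r2(series: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Cross-validated R-squared per voxel: fit one half, score the other."""
    n = series.shape[0]
    half = n // 2
    folds = [(slice(0, half), slice(half, n)), (slice(half, n), slice(0, half))]
    r2 = np.zeros(series.shape[1])
    for train, test in folds:
        Xtr = np.column_stack([X[train], np.ones(X[train].shape[0])])
        Xte = np.column_stack([X[test], np.ones(X[test].shape[0])])
        coef, *_ = np.linalg.lstsq(Xtr, series[train], rcond=None)
        pred = Xte @ coef
        resid = series[test] - pred
        total = series[test] - series[test].mean(axis=0)
        ss_tot = np.sum(total**2, axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            fold_r2 = 1.0 - np.sum(resid**2, axis=0) / ss_tot
        r2 += np.where(np.isfinite(fold_r2), fold_r2, 0.0)
    return r2 / 2.0


def estimate_noise_regressors(
    series: VoxelTimeSeries | np.ndarray,
    event_table: pd.DataFrame | None = None,
    n_components: int = DEFAULT_N_NOISE_COMPONENTS,
    tr: float = 2.8,
) -> np.ndarray:
    """Nuisance regressors from the residuals of task-insensitive voxels.

    Voxels with split-half cross-validated task R-squared <= 0 form the
    noise pool; the top principal components of their task-residual series
    are returned as (TRs x n_components) columns.  With ``n_components=0``
    or an empty noise pool, a (TRs x 0) array is returned and downstream
    fits are unchanged.
    """
    if isinstance(series, VoxelTimeSeries):
        values, event_table, tr = series.values, series.event_table, series.tr
    else:
        values = np.atleast_2d(np.asarray(series, dtype=float))
        if event_table is None:
            raise ValueError("event_table is required with a bare array")
    if n_components == 0:
        return np.zeros((values.shape[0], 0))

    table = _filter_events(event_table)
    X = _task_design(table, values.shape[0], tr)
    if values.shape[0] <= X.shape[1] + 1:
        raise ValueError("series shorter than the task design span")

    r2 = _split_half_r2(values, X)
    noise_pool = r2 <= 0.0
    if not noise_pool.any():
        return np.zeros((values.shape[0], 0))

    # residuals against the full per-sound design, so task-locked variance
    # (including amplitude variation across sounds) cannot enter the PCA
    onsets, _ = _onset_matrix(table, values.shape[0])
    Xfull = _convolve_columns(onsets, double_gamma_hrf(tr))
    Xi = np.column_stack([Xfull, np.ones(values.shape[0])])
    coef, *_ = np.linalg.lstsq(Xi, values[:, noise_pool], rcond=None)
    resid = values[:, noise_pool] - Xi @ coef

    # a pool voxel whose residual is numerically negligible carries no
    # noise structure (fully task-explained series); drop it
    real = resid.std(axis=0) > 1e-8 * np.maximum(values[:, noise_pool].std(axis=0), 1e-30)
    resid = resid[:, real]
    if resid.shape[1] == 0:
        return np.zeros((values.shape[0], 0))
    max_rank = min(resid.shape[0], resid.shape[1])
    if n_components > max_rank:
        raise ValueError(
            f"n_components={n_components} exceeds the available rank {max_rank}"
        )
    sd = resid.std(axis=0)
    sd[sd == 0] = 1.0
    components = PCA(n_components=n_components).fit_transform(resid / sd)
    return components


def _normalize_kernels(hrfs: np.ndarray) -> np.ndarray:
    """Scale each kernel column to unit positive peak; zero kernels stay zero."""
    peaks = np.max(np.abs(hrfs), axis=0)
    peak_vals = hrfs[np.argmax(np.abs(hrfs), axis=0), np.arange(hrfs.shape[1])]
    signs = np.where(peak_vals < 0, -1.0, 1.0)
    scale = np.where(peaks > 0, peaks * signs, 1.0)
    return hrfs / scale


def _lagged(column: np.ndarray, window: int) -> np.ndarray:
    n = column.size
    return np.column_stack(
        [np.concatenate([np.zeros(l), column[: n - l]]) for l in range(window)]
    )


def estimate_hrf(
    series: VoxelTimeSeries | np.ndarray,
    event_table: pd.DataFrame | None = None,
    window: int = DEFAULT_HRF_WINDOW_TRS,
    noise_regressors: np.ndarray | None = None,
    amplitudes: "ResponseMatrix | None" = None,
) -> np.ndarray:
    """Per-voxel FIR HRF over ``window`` TRs, shared across sounds.

    The design has one column per lag (0..window-1) holding the combined
    event indicator shifted by that lag.  When current per-sound amplitude
    estimates are supplied via ``amplitudes``, each voxel's indicator is
    weighted by them before lagging (one alternating-least-squares pass on
    the bilinear amplitude x kernel model), which removes the compromise
    bias a plain unit-weight deconvolution has when response amplitudes
    differ across sounds.  Estimated kernels are normalized to unit peak
    magnitude (positive peak); an all-zero voxel keeps an all-zero kernel.
    """
    if isinstance(series, VoxelTimeSeries):
        values, event_table = series.values, series.event_table
    else:
        values = np.atleast_2d(np.asarray(series, dtype=float))
        if event_table is None:
            raise ValueError("event_table is required with a bare array")
    table = _filter_events(event_table)
    n_trs, n_voxels = values.shape
    if len(table) < window:
        raise ValueError(
            f"{len(table)} events cannot support a {window}-TR deconvolution window"
        )

    onsets, sound_ids = _onset_matrix(table, n_trs)
    extra = [np.ones((n_trs, 1))]
    if noise_regressors is not None and noise_regressors.shape[1]:
        extra.append(noise_regressors)
    N = np.column_stack(extra)

    def solve(X: np.ndarray, y: np.ndarray) -> np.ndarray:
        D = np.column_stack([X, N])
        if np.linalg.matrix_rank(D) < D.shape[1]:
            raise np.linalg.LinAlgError(
                f"deconvolution design is rank deficient "
                f"(rank {np.linalg.matrix_rank(D)} < {D.shape[1]} columns)"
            )
        coef, *_ = np.linalg.lstsq(D, y, rcond=None)
        return coef[:window]

    if amplitudes is None:
        X = _lagged(onsets.sum(axis=1), window)
        hrfs = solve(X, values)
    else:
        order = [amplitudes.sound_ids.index(s) for s in sound_ids]
        amp = amplitudes.betas[order]
        if amp.shape[1] != n_voxels:
            raise ValueError("amplitudes must cover every voxel")
        hrfs = np.empty((window, n_voxels))
        for v in range(n_voxels):
            X = _lagged(onsets @ amp[:, v], window)
            hrfs[:, v] = solve(X, values[:, v])
    return _normalize_kernels(hrfs)


def estimate_betas(
    series: VoxelTimeSeries | np.ndarray,
    event_table: pd.DataFrame | None = None,
    hrf: np.ndarray | None = None,
    noise_regressors: np.ndarray | None = None,
) -> ResponseMatrix:
    """Per-sound, per-voxel response amplitudes by least squares.

    ``hrf`` is either one kernel shared by all voxels or a (window x voxels)
    array of per-voxel kernels.  Each sound's onsets are convolved with the
    voxel's HRF; nuisance columns and an intercept are appended.
    """
    if isinstance(series, VoxelTimeSeries):
        values, event_table, tr = series.values, series.event_table, series.tr
    else:
        values = np.atleast_2d(np.asarray(series, dtype=float))
        tr = 2.8
        if event_table is None:
            raise ValueError("event_table is required with a bare array")
    table = _filter_events(event_table)
    n_trs, n_voxels = values.shape
    onsets, sound_ids = _onset_matrix(table, n_trs)
    S = len(sound_ids)

    if hrf is None:
        hrf = double_gamma_hrf(tr)
    hrf = np.asarray(hrf, dtype=float)
    per_voxel = hrf.ndim == 2
    if per_voxel and hrf.shape[1] != n_voxels:
        raise ValueError("per-voxel HRF must have one column per voxel")

    nuisance = [np.ones((n_trs, 1))]
    if noise_regressors is not None and noise_regressors.shape[1]:
        nuisance.append(noise_regressors)
    N = np.column_stack(nuisance)

    betas = np.empty((S, n_voxels))
    shared_design = None
    for v in range(n_voxels):
        kernel = hrf[:, v] if per_voxel else hrf
        if per_voxel or shared_design is None:
            Xs = _convolve_columns(onsets, kernel)
            X = np.column_stack([Xs, N])
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise np.linalg.LinAlgError(
                    "beta design is collinear (rank deficient)"
                )
            if not per_voxel:
                shared_design = X
        else:
            X = shared_design
        coef, *_ = np.linalg.lstsq(X, values[:, v], rcond=None)
        betas[:, v] = coef[:S]

    return ResponseMatrix(betas, sound_ids)


def estimate_responses(
    series: VoxelTimeSeries,
    n_noise_components: int = DEFAULT_N_NOISE_COMPONENTS,
    hrf_window: int = DEFAULT_HRF_WINDOW_TRS,
) -> ResponseMatrix:
    """Full three-stage path: noise regressors, per-voxel HRF, betas.

    The HRF stage starts from amplitudes estimated under the canonical
    kernel, so the per-voxel deconvolution accounts for amplitude
    differences across sounds.
    """
    nuisance = estimate_noise_regressors(series, n_components=n_noise_components)
    betas0 = estimate_betas(series, noise_regressors=nuisance)  # canonical kernel
    hrfs = estimate_hrf(
        series, window=hrf_window, noise_regressors=nuisance, amplitudes=betas0
    )
    return estimate_betas(series, hrf=hrfs, noise_regressors=nuisance)
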