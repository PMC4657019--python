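"""Per-voxel ridge regression (W R = Y) with ridge-trace regularization.

Each voxel j gets its own tuning vector R_j = (W'W + lambda_j I)^-1 W' Y_j.
The penalty lambda_j is picked per voxel as the smallest value on an
ascending grid at which the ridge trace has stabilized: the maximum
relative coefficient change to the next grid point falls below a
tolerance (default 5%).  The solve uses one eigendecomposition of W'W,
shared across voxels and penalties; it is numerically identical (to 1e-8)
to the explicit per-lambda inverse.

W columns and Y voxels are mean-centered before solving (the standard
ridge intercept convention); means are restored at prediction time.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model_spaces import FeatureMatrix

DEFAULT_STABILITY_TOL = 0.05
DEFAULT_N_LAMBDAS = 25
DEFAULT_LAMBDA_SPAN = (1e-3, 1e3)  # multiples of mean diag(W'W)


@dataclass
class TuningMatrix:
    """Features x voxels weights from a (ridge) fit, with per-voxel penalties."""

    weights: np.ndarray
    lambdas: np.ndarray
    model_kind: str
    label_frequency: np.ndarray
    label_azimuth: np.ndarray
    w_means: np.ndarray | None = None
    y_means: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("tuning weights must be finite")
        if np.any(self.lambdas < 0):
            raise ValueError("lambdas must be nonnegative")
        if self.weights.shape[1] != self.lambdas.size:
            raise ValueError("one lambda per voxel required")
        if self.weights.shape[0] != np.asarray(self.label_frequency).size:
            raise ValueError("feature labels must match the weight row count")

    @property
    def n_features(self) -> int:
        return self.weights.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.weights.shape[1]


@dataclass
class VoxelSelection:
    """Voxels passing the overall-response t-threshold, ranked and capped."""

    voxel_ids: np.ndarray
    t_values: np.ndarray
    mask_name: str = "all"
    cap: int = 5000

    def __post_init__(self) -> None:
        self.voxel_ids = np.asarray(self.voxel_ids, dtype=int)
        self.t_values = np.asarray(self.t_values, dtype=float)
        if self.voxel_ids.size > self.cap:
            raise ValueError("selection exceeds the requested cap")

    @property
    def n_selected(self) -> int:
        return self.voxel_ids.size


def default_lambda_grid(W: np.ndarray, n: int = DEFAULT_N_LAMBDAS) -> np.ndarray:
    """Log-spaced penalty grid scaled by the mean diagonal of centered W'W."""
    Wc = W - W.mean(axis=0, keepdims=True)
    scale = float(np.mean(np.sum(Wc * Wc, axis=0)))
    if scale <= 0:
        scale = 1.0
    lo, hi = DEFAULT_LAMBDA_SPAN
    return scale * np.logspace(np.log10(lo), np.log10(hi), n)


def ridge_path(W: np.ndarray, Y: np.ndarray, lambdas: np.ndarray) -> np.ndarray:
    """Coefficient path over the penalty grid via eigendecomposition of W'W.

    Returns an (L, F, V) array; no centering is applied here.
    """
    W = np.asarray(W, dtype=float)
    Y = np.asarray(Y, dtype=float)
    lambdas = np.asarray(lambdas, dtype=float)
    if not (np.all(np.isfinite(W)) and np.all(np.isfinite(Y))):
        raise ValueError("ridge inputs must be finite")
    if W.shape[0] != Y.shape[0]:
        raise ValueError("W and Y must be row-aligned (same sound count)")
    if lambdas.size == 0:
        raise ValueError("empty lambda grid")
    if np.any(np.diff(lambdas) < 0):
        raise ValueError("lambda grid must be sorted ascending")

    evals, Q = np.linalg.eigh(W.T @ W)
    B = Q.T @ (W.T @ Y)  # rotated cross-products, F x V
    path = np.empty((lambdas.size, W.shape[1], Y.shape[1]))
    for l, lam in enumerate(lambdas):
        path[l] = Q @ (B / (evals + lam)[:, None])
    return path


def _stable_lambda_index(path: np.ndarray, tol: float) -> np.ndarray:
    """Per voxel, index of the smallest lambda at which the trace is stable.

    Stability at grid point l: max_f |R[l+1] - R[l]| / max_f |R[l]| < tol.
    Falls back to the last grid point when no point qualifies.
    """
    L = path.shape[0]
    if L == 1:
        return np.zeros(path.shape[2], dtype=int)
    delta = np.max(np.abs(np.diff(path, axis=0)), axis=1)  # (L-1, V)
    scale = np.maximum(np.max(np.abs(path[:-1]), axis=1), 1e-30)
    rel = delta / scale
    stable = rel < tol  # (L-1, V)
    idx = np.argmax(stable, axis=0)
    never = ~stable.any(axis=0)
    idx[never] = L - 1
    return idx


def ridge_solve(
    W: FeatureMatrix | np.ndarray,
    Y: np.ndarray,
    lambda_grid: np.ndarray | None = None,
    stability_tol: float = DEFAULT_STABILITY_TOL,
    center: bool = True,
    fixed_lambdas: np.ndarray | None = None,
) -> TuningMatrix:
    """Fit W R = Y per voxel with ridge-trace penalty selection.

    Parameters
    ----------
    W:
        Training feature matrix (sounds x features).
    Y:
        Training response matrix (sounds x voxels).
    lambda_grid:
        Ascending penalties; default 25 points log-spaced over
        [1e-3, 1e3] x mean diag(W'W).
    fixed_lambdas:
        Per-voxel penalties to reuse (e.g. across permutations); skips the
        ridge-trace selection.
    """
    if isinstance(W, FeatureMatrix):
        fm, Wv = W, W.values
    else:
        Wv = np.asarray(W, dtype=float)
        fm = None
    Y = np.atleast_2d(np.asarray(Y, dtype=float))
    if Y.shape[0] == 1 and Wv.shape[0] != 1:
        Y = Y.T

    if center:
        w_means = Wv.mean(axis=0)
        y_means = Y.mean(axis=0)
        Wc = Wv - w_means
        Yc = Y - y_means
    else:
        w_means = np.zeros(Wv.shape[1])
        y_means = np.zeros(Y.shape[1])
        Wc, Yc = Wv, Y

    if fixed_lambdas is not None:
        fixed_lambdas = np.asarray(fixed_lambdas, dtype=float)
        if fixed_lambdas.size != Y.shape[1]:
            raise ValueError("fixed_lambdas must supply one penalty per voxel")
        uniq = np.unique(fixed_lambdas)
        path = ridge_path(Wc, Yc, uniq)
        weights = np.empty((Wc.shape[1], Y.shape[1]))
        for k, lam in enumerate(uniq):
            cols = fixed_lambdas == lam
            weights[:, cols] = path[k][:, cols]
        lambdas = fixed_lambdas
    else:
        if lambda_grid is None:
            lambda_grid = default_lambda_grid(Wv)
        lambda_grid = np.asarray(lambda_grid, dtype=float)
        path = ridge_path(Wc, Yc, lambda_grid)
        idx = _stable_lambda_index(path, stability_tol)
        lambdas = lambda_grid[idx]
        weights = path[idx, :, np.arange(Y.shape[1])].T

    return TuningMatrix(
        weights,
        lambdas,
        model_kind=fm.model_kind if fm is not None else "joint",
        label_frequency=(
            fm.label_frequency if fm is not None else np.full(Wc.shape[1], np.nan)
        ),
        label_azimuth=(
            fm.label_azimuth if fm is not None else np.full(Wc.shape[1], np.nan)
        ),
        w_means=w_means,
        y_means=y_means,
    )


def predict(W_test: FeatureMatrix | np.ndarray, tuning: TuningMatrix) -> np.ndarray:
    """Predicted responses Y_hat = W_test R (feature ordering is load-bearing)."""
    if isinstance(W_test, FeatureMatrix):
        if W_test.n_features != tuning.n_features:
            raise ValueError("feature count mismatch between W_test and tuning")
        same_kind = W_test.model_kind == tuning.model_kind
        same_labels = np.array_equal(
            np.nan_to_num(W_test.label_frequency, nan=-1.0),
            np.nan_to_num(np.asarray(tuning.label_frequency, dtype=float), nan=-1.0),
        ) and np.array_equal(
            np.nan_to_num(W_test.label_azimuth, nan=-999.0),
            np.nan_to_num(np.asarray(tuning.label_azimuth, dtype=float), nan=-999.0),
        )
        if not (same_kind and same_labels):
            raise ValueError(
                "feature labels of W_test do not match the fitted tuning matrix; "
                "column ordering is load-bearing"
            )
        Wv = W_test.values
    else:
        Wv = np.atleast_2d(np.asarray(W_test, dtype=float))
        if Wv.shape[1] != tuning.n_features:
            raise ValueError("feature count mismatch between W_test and tuning")
    w_means = tuning.w_means if tuning.w_means is not None else 0.0
    y_means = tuning.y_means if tuning.y_means is not None else 0.0
    return (Wv - w_means) @ tuning.weights + y_means


def overall_response_t(Y: np.ndarray) -> np.ndarray:
    """Per-voxel one-sample t statistic of the responses against zero."""
    Y = np.asarray(Y, dtype=float)
    n = Y.shape[0]
    mean = Y.mean(axis=0)
    sd = Y.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    return np.where(np.isfinite(t), t, 0.0)


def select_voxels(
    Y: np.ndarray,
    mask: np.ndarray | None = None,
    t_threshold: float = 2.9,
    cap: int = 5000,
    mask_name: str = "all",
) -> VoxelSelection:
    """Voxels inside the mask with t > threshold (strict), best ``cap`` by t.

    ``mask`` is a boolean vector over voxels (an anatomical inclusion mask);
    ``None`` includes every voxel.
    """
    Y = np.asarray(Y, dtype=float)
    V = Y.shape[1]
    if mask is None:
        mask = np.ones(V, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.size != V:
        raise ValueError("mask length must match the voxel count")
    if not mask.any():
        raise ValueError("empty voxel mask")

    t = overall_response_t(Y)
    eligible = np.nonzero(mask & (t > t_threshold))[0]
    order = eligible[np.argsort(-t[eligible], kind="stable")]
    chosen = order[:cap]
    return VoxelSelection(chosen, t[chosen], mask_name=mask_name, cap=cap)


def voxel_t_pvalue(t: float, n: int) -> float:
    """One-sided p of an overall-response t with n-1 degrees of freedom."""
    return float(stats.t.sf(t, df=n - 1))
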