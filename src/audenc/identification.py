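"""Sound-identification evaluation and its constrained permutation null.

A trained model predicts the response pattern of each held-out test
sound; the prediction is correlated with the measured patterns of *all*
test sounds, and the rank r_i of the matching sound's correlation (1 =
highest) yields the per-sound prediction accuracy

    P_i = 1 - (r_i - 1) / (S_test - 1),

the unique affine function of the rank with P(1) = 1, P(S_test) = 0 and
chance level E[P] = 0.5.  The model's accuracy is the mean P_i.

The null distribution permutes the training-sound labels under the
constraint that no sound receives a label from its own azimuth, refits
with the per-voxel penalties frozen at their unpermuted values, and
re-evaluates; p = (1 + #{null >= observed}) / (1 + n_perm).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .encoding import TuningMatrix, predict, ridge_solve
from .model_spaces import FeatureMatrix


@dataclass
class IdentificationResult:
    """Per-sound accuracies, their mean, ranks, and an optional null."""

    per_sound_accuracy: np.ndarray
    ranks: np.ndarray
    mean_accuracy: float
    null_accuracies: np.ndarray | None = None
    p_value: float | None = None

    def __post_init__(self) -> None:
        self.per_sound_accuracy = np.asarray(self.per_sound_accuracy, dtype=float)
        self.ranks = np.asarray(self.ranks, dtype=float)
        if np.any((self.per_sound_accuracy < 0) | (self.per_sound_accuracy > 1)):
            raise ValueError("per-sound accuracies must lie in [0, 1]")


def identify(
    Y_hat_test: np.ndarray, Y_test: np.ndarray, sound_ids: list | None = None
) -> IdentificationResult:
    """Rank-based identification of test sounds from predicted responses.

    For each sound i, the Pearson correlation of the predicted pattern
    Y_hat[i] with every measured pattern Y[j] is computed; ties in the
    ranking are broken by average rank.
    """
    Y_hat = np.atleast_2d(np.asarray(Y_hat_test, dtype=float))
    Y = np.atleast_2d(np.asarray(Y_test, dtype=float))
    if Y_hat.shape != Y.shape:
        raise ValueError("predicted and measured response matrices must match")
    S = Y.shape[0]
    if S < 2:
        raise ValueError("identification needs at least 2 test sounds")

    ids = sound_ids if sound_ids is not None else [str(i) for i in range(S)]
    for name, M in (("predicted", Y_hat), ("measured", Y)):
        sd = M.std(axis=1)
        bad = np.nonzero(sd == 0)[0]
        if bad.size:
            raise ValueError(
                f"{name} response of sound {ids[bad[0]]} has zero variance; "
                "correlation is undefined"
            )

    Zh = (Y_hat - Y_hat.mean(axis=1, keepdims=True)) / Y_hat.std(axis=1, keepdims=True)
    Zm = (Y - Y.mean(axis=1, keepdims=True)) / Y.std(axis=1, keepdims=True)
    corr = (Zh @ Zm.T) / Y.shape[1]  # corr[i, j] = corr(Y_hat_i, Y_j)

    ranks = np.array([rankdata(-corr[i], method="average")[i] for i in range(S)])
    accuracy = 1.0 - (ranks - 1.0) / (S - 1.0)
    return IdentificationResult(accuracy, ranks, float(accuracy.mean()))


def constrained_permutation(
    azimuths: np.ndarray, rng: np.random.Generator, max_iter: int = 10000
) -> np.ndarray:
    """A random permutation mapping every sound to a different-azimuth sound.

    Starts from a uniform random permutation and repairs conflicts with
    random constraint-preserving swaps.  Raises when the constraint is
    infeasible (some azimuth holds more than half of the sounds).
    """
    azimuths = np.asarray(azimuths)
    n = azimuths.size
    _, counts = np.unique(azimuths, return_counts=True)
    if counts.max() > n - counts.max():
        raise ValueError(
            "different-azimuth permutation is infeasible: one azimuth holds "
            f"{counts.max()} of {n} sounds"
        )

    perm = rng.permutation(n)
    for _ in range(max_iter):
        bad = np.nonzero(azimuths[perm] == azimuths)[0]
        if bad.size == 0:
            return perm
        for i in bad:
            j = int(rng.integers(n))
            if azimuths[perm[j]] != azimuths[i] and azimuths[perm[i]] != azimuths[j]:
                perm[i], perm[j] = perm[j], perm[i]
    raise RuntimeError("constrained permutation failed to converge")


def permutation_test(
    W_train: FeatureMatrix | np.ndarray,
    Y_train: np.ndarray,
    W_test: FeatureMatrix | np.ndarray,
    Y_test: np.ndarray,
    azimuths_train: np.ndarray,
    n_perm: int = 200,
    seed: int = 0,
    lambda_grid: np.ndarray | None = None,
) -> IdentificationResult:
    """Observed identification accuracy against the constrained-label null.

    Each permutation shuffles which training sound carries which response
    (rows of Y_train) under the different-azimuth constraint, refits with
    per-voxel penalties frozen at the unpermuted values, and re-evaluates.
    """
    azimuths_train = np.asarray(azimuths_train)
    if azimuths_train.size != np.atleast_2d(Y_train).shape[0]:
        raise ValueError("one azimuth label per training sound required")

    tuning = ridge_solve(W_train, Y_train, lambda_grid=lambda_grid)
    observed = identify(predict(W_test, tuning), Y_test)

    rng = np.random.default_rng(seed)
    null = np.empty(n_perm)
    for k in range(n_perm):
        perm = constrained_permutation(azimuths_train, rng)
        tuning_k = ridge_solve(
            W_train, np.asarray(Y_train)[perm], fixed_lambdas=tuning.lambdas
        )
        null[k] = identify(predict(W_test, tuning_k), Y_test).mean_accuracy

    p = (1.0 + np.sum(null >= observed.mean_accuracy)) / (1.0 + n_perm)
    return IdentificationResult(
        observed.per_sound_accuracy,
        observed.ranks,
        observed.mean_accuracy,
        null_accuracies=null,
        p_value=float(p),
    )


def _fisher_z(acc: np.ndarray, eps: float = 1e-6) -> np.ndarray:
    """Fisher transform of accuracies treated as correlations, clipped off 1."""
    return np.arctanh(np.clip(np.asarray(acc, dtype=float), -1 + eps, 1 - eps))


def compare_models(
    accuracies: dict,
    chance: float = 0.5,
    alpha: float = 0.05,
    correction: str = "bonferroni",
):
    """Group-level model comparison on Fisher-transformed accuracies.

    ``accuracies`` maps model name -> per-replicate (e.g. per-subject) mean
    accuracy vector.  Each model is tested against chance with a one-tailed
    one-sample t-test, and every model pair with a one-tailed paired t-test
    (alternative: first-listed model greater), both corrected for multiple
    comparisons.

    Returns ``(vs_chance, pairwise)`` DataFrames.
    """
    names = list(accuracies)
    lengths = {len(np.asarray(accuracies[m])) for m in names}
    if len(lengths) != 1:
        raise ValueError("all models need accuracy values for the same replicates")
    if lengths.pop() < 2:
        raise ValueError("need at least 2 replicates")

    z0 = _fisher_z(chance)
    rows = []
    for m in names:
        z = _fisher_z(accuracies[m])
        if np.std(z, ddof=1) == 0:
            d = np.mean(z) - z0
            t = 0.0 if d == 0 else np.inf * np.sign(d)
            p = 0.5 if t == 0 else (0.0 if t > 0 else 1.0)
        else:
            t, p = stats.ttest_1samp(z, z0, alternative="greater")
        rows.append({"model": m, "mean_accuracy": float(np.mean(accuracies[m])),
                     "t_stat": float(t), "p_raw": float(p)})
    vs_chance = pd.DataFrame(rows)
    rej, p_adj, *_ = multipletests(vs_chance["p_raw"], alpha=alpha, method=correction)
    vs_chance["p_corrected"] = p_adj
    vs_chance["significant"] = rej

    rows = []
    for a, b in combinations(names, 2):
        za, zb = _fisher_z(accuracies[a]), _fisher_z(accuracies[b])
        diff = za - zb
        if np.std(diff, ddof=1) == 0:
            # degenerate paired test: identical vectors are exactly at the null
            t = 0.0 if np.mean(diff) == 0 else np.inf * np.sign(np.mean(diff))
            p = 0.5 if t == 0 else (0.0 if t > 0 else 1.0)
        else:
            t, p = stats.ttest_rel(za, zb, alternative="greater")
        rows.append({"model_a": a, "model_b": b, "t_stat": float(t), "p_raw": float(p)})
    pairwise = pd.DataFrame(rows)
    if len(pairwise):
        rej, p_adj, *_ = multipletests(pairwise["p_raw"], alpha=alpha, method=correction)
        pairwise["p_corrected"] = p_adj
        pairwise["significant"] = rej
    return vs_chance, pairwise
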