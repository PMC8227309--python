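"""Normal-equation multivariate linear regression and its evaluation.

The score model is ordinary least squares fit in closed form (the
normal-equation / pseudoinverse solution).  Evaluation follows a
Monte-Carlo cross-validation protocol: for each feature count
k = 1..K, ``n_iter`` independent random 70:30 row splits are drawn, a
model on the k best-ranked features is fit on the training rows, and
accuracy is

    Acc_k = 100 - mean_iter |mean(predicted) - mean(real)|

over the test rows of each split.  With 60 rows the split is exactly
42 train / 18 test.  A per-sample mean-absolute-error is also recorded
under a distinct name; predictions are not clipped to [0, 100] unless
requested, keeping the accuracy semantics linear.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class MLRModel:
    """Fitted linear model: intercept plus one coefficient per feature."""

    feature_names: tuple[str, ...]
    coefficients: np.ndarray  # (k,)
    intercept: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.coefficients

    def predict_frame(self, fm: pd.DataFrame) -> np.ndarray:
        return self.predict(fm[list(self.feature_names)].to_numpy(dtype=float))


def fit_normal_equation(
    X: np.ndarray, y: np.ndarray, feature_names: tuple[str, ...] | None = None
) -> MLRModel:
    """Closed-form least squares with an intercept column.

    Uses the Moore-Penrose pseudoinverse, which equals the normal-
    equation solution for full-rank design matrices and remains defined
    (minimum-norm) when the design is rank deficient.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
        X = X.T
    y = np.asarray(y, dtype=float).ravel()
    n, k = X.shape
    if n != y.size:
        raise ValueError(f"X has {n} rows but y has {y.size} values")
    if n <= k + 1:
        raise ValueError(f"underdetermined fit: n={n} rows for k={k} features (+ intercept)")
    A = np.column_stack([np.ones(n), X])
    beta = np.linalg.pinv(A) @ y
    if not np.all(np.isfinite(beta)):
        raise ValueError("non-finite coefficients")
    names = tuple(feature_names) if feature_names is not None else tuple(f"x{i}" for i in range(k))
    return MLRModel(feature_names=names, coefficients=beta[1:], intercept=float(beta[0]))


def _split_sizes(n: int, train_frac: float) -> tuple[int, int]:
    n_train = int(np.floor(n * train_frac))
    return n_train, n - n_train


def _canonical_rows(fm: pd.DataFrame) -> pd.DataFrame:
    """Stable row identity order so splits do not depend on input row order."""
    return fm.sort_values(["participant_id", "repetition"], kind="mergesort").reset_index(drop=True)


@dataclass
class CVResult:
    """Per-k Monte-Carlo cross-validation record and accuracies."""

    iterations: pd.DataFrame  # columns k, iteration, mean_pred, mean_real, abs_diff, mae
    accuracies: dict[int, float]
    train_size: int
    test_size: int
    n_iter: int
    seed: int

    def best_k(self) -> int:
        return max(self.accuracies, key=lambda k: (self.accuracies[k], -k))


def evaluate_cv(
    fm: pd.DataFrame,
    ranked_features: list[str],
    K: int,
    n_iter: int = 10,
    train_frac: float = 0.7,
    seed: int = 0,
    by_participant: bool = False,
    clip: bool = False,
) -> CVResult:
    """Evaluate k-feature models, k = 1..K, by repeated random 70:30 splits.

    ``ranked_features`` is the pruned selection in ascending-p order;
    model k uses its first k names.  Each k draws its own substream of
    splits from ``seed`` so Acc_k does not depend on K.
    ``by_participant=True`` switches to the stricter grouping where all
    rows of a participant fall on the same side of the split.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > len(ranked_features):
        raise ValueError(
            f"K={K} exceeds the {len(ranked_features)} available selected features"
        )
    rows = _canonical_rows(fm)
    n = len(rows)
    n_train, n_test = _split_sizes(n, train_frac)
    if n_test < 1 or n_train < 2:
        raise ValueError(f"degenerate split sizes {n_train}/{n_test} from {n} rows")

    records = []
    accuracies: dict[int, float] = {}
    y_all = rows["score"].to_numpy(dtype=float)
    for k in range(1, K + 1):
        feats = ranked_features[:k]
        X_all = rows[feats].to_numpy(dtype=float)
        rng = np.random.default_rng([seed, 29, k])
        diffs = []
        for it in range(n_iter):
            train_idx, test_idx = _draw_split(rows, rng, n_train, by_participant)
            model = fit_normal_equation(X_all[train_idx], y_all[train_idx], tuple(feats))
            pred = model.predict(X_all[test_idx])
            if clip:
                pred = np.clip(pred, 0.0, 100.0)
            mean_pred = float(pred.mean())
            mean_real = float(y_all[test_idx].mean())
            diff = abs(mean_pred - mean_real)
            diffs.append(diff)
            records.append(
                {
                    "k": k,
                    "iteration": it,
                    "mean_pred": mean_pred,
                    "mean_real": mean_real,
                    "abs_diff": diff,
                    "mae": float(np.abs(pred - y_all[test_idx]).mean()),
                    "n_train": len(train_idx),
                    "n_test": len(test_idx),
                }
            )
        accuracies[k] = 100.0 - float(np.mean(diffs))
    return CVResult(
        iterations=pd.DataFrame(records),
        accuracies=accuracies,
        train_size=n_train,
        test_size=n_test,
        n_iter=n_iter,
        seed=seed,
    )


def _draw_split(
    rows: pd.DataFrame, rng: np.random.Generator, n_train: int, by_participant: bool
) -> tuple[np.ndarray, np.ndarray]:
    n = len(rows)
    if not by_participant:
        perm = rng.permutation(n)
        return perm[:n_train], perm[n_train:]
    participants = rows["participant_id"].to_numpy()
    order = rng.permutation(np.unique(participants))
    train_mask = np.zeros(n, dtype=bool)
    count = 0
    for pid in order:
        idx = np.flatnonzero(participants == pid)
        if count >= n_train:
            break
        train_mask[idx] = True
        count += idx.size
    return np.flatnonzero(train_mask), np.flatnonzero(~train_mask)


@dataclass
class GroupPredictionSummary:
    """Mean real vs predicted score per group over random test subsamples."""

    records: pd.DataFrame  # one row per (subsample, group)
    per_group: pd.DataFrame  # index group, columns mean_real, mean_pred
    n_subsamples: int
    test_size: int
    resampled: int = 0


def group_prediction_summary(
    fm: pd.DataFrame,
    ranked_features: list[str],
    k: int,
    n_subsamples: int = 30,
    seed: int = 0,
    train_frac: float = 0.7,
    max_resample: int = 100,
) -> GroupPredictionSummary:
    """Predict random test subsamples and aggregate scores by true group.

    Each subsample has the cross-validation test size; the model (first
    ``k`` ranked features) is refit on the complement every time.  A
    subsample missing one group is redrawn (and counted).
    """
    rows = _canonical_rows(fm)
    n = len(rows)
    _, n_test = _split_sizes(n, train_frac)
    rng = np.random.default_rng([seed, 31])
    feats = ranked_features[:k]
    X_all = rows[feats].to_numpy(dtype=float)
    y_all = rows["score"].to_numpy(dtype=float)
    groups = rows["group"].to_numpy()

    records = []
    pooled: dict[str, list[tuple[float, float]]] = {}
    resampled = 0
    for s in range(n_subsamples):
        for attempt in range(max_resample):
            test_idx = rng.choice(n, size=n_test, replace=False)
            if np.unique(groups[test_idx]).size == np.unique(groups).size:
                break
            resampled += 1
            logger.info("subsample %d redrawn: missing a group", s)
        else:
            raise RuntimeError("could not draw a subsample containing every group")
        train_mask = np.ones(n, dtype=bool)
        train_mask[test_idx] = False
        model = fit_normal_equation(X_all[train_mask], y_all[train_mask], tuple(feats))
        pred = model.predict(X_all[test_idx])
        for g in np.unique(groups[test_idx]):
            gmask = groups[test_idx] == g
            records.append(
                {
                    "subsample": s,
                    "group": g,
                    "mean_real": float(y_all[test_idx][gmask].mean()),
                    "mean_pred": float(pred[gmask].mean()),
                    "n": int(gmask.sum()),
                }
            )
            pooled.setdefault(g, []).extend(
                zip(y_all[test_idx][gmask].tolist(), pred[gmask].tolist())
            )

    per_group = pd.DataFrame(
        {
            g: {
                "mean_real": float(np.mean([a for a, _ in vals])),
                "mean_pred": float(np.mean([b for _, b in vals])),
            }
            for g, vals in pooled.items()
        }
    ).T
    out_of_range = per_group[(per_group < 0) | (per_group > 100)].dropna(how="all")
    if len(out_of_range):
        logger.warning("group means outside [0, 100]:\n%s", out_of_range)
    return GroupPredictionSummary(
        records=pd.DataFrame(records),
        per_group=per_group,
        n_subsamples=n_subsamples,
        test_size=n_test,
        resampled=resampled,
    )
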