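"""Least-squares regression, the partial F-test, and stepwise feature selection.

The target (cardiac output or systemic vascular resistance) is modelled as a
weighted sum of M selected transformed features plus a constant:

    y_hat_i = x_i' w + w_{M+1}

with the weight vector solved through the Moore-Penrose pseudoinverse of the
ones-augmented design matrix, w = X^+ y.  Model quality is the mean squared
error (1/n) * sum (y_hat_i - y_i)^2.  Candidate features enter or leave the
model according to a partial F-test on the change in the residual sum of
squares, at a 95% confidence level by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import features as ft
from .features import FeaturePool

log = logging.getLogger(__name__)

_SSE_TOL = 1e-9


def design_matrix(features_2d: np.ndarray) -> np.ndarray:
    """Augment a (n, M) feature block with a trailing column of ones."""
    features_2d = np.atleast_2d(np.asarray(features_2d, dtype=float))
    return np.hstack([features_2d, np.ones((features_2d.shape[0], 1))])


def fit_least_squares(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares weights via the Moore-Penrose pseudoinverse."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.size == 0 or X.shape[0] == 0:
        raise ValueError("empty design matrix")
    if X.shape[0] != y.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.shape[0]}")
    return np.linalg.pinv(X) @ y


def mse(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Mean squared error (1/n) * sum (y_hat_i - y_i)^2."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {y.shape} vs {y_hat.shape}")
    if y.size == 0:
        raise ValueError("mse of empty vectors is undefined")
    return float(np.mean((y_hat - y) ** 2))


def _sse(X: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray, int]:
    """Residual sum of squares, weights and rank for a design matrix fit."""
    w, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    r = y - X @ w
    return float(r @ r), w, rank


@dataclass(frozen=True)
class RegressionModel:
    """A fitted linear model on a subset of the 28 transformed features."""

    feature_indices: tuple[int, ...]
    weights: np.ndarray  # one weight per feature, in feature_indices order
    intercept: float
    training_mse: float
    alpha: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))
        if self.weights.shape != (len(self.feature_indices),):
            raise ValueError("need exactly one weight per selected feature")

    def to_yaml(self, path) -> None:
        """Serialize to a structured text file (indices, formulas, weights)."""
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "feature_indices": list(self.feature_indices),
                    "feature_formulas": [
                        ft.feature_formula(j) for j in self.feature_indices
                    ],
                    "weights": [float(w) for w in self.weights],
                    "intercept": float(self.intercept),
                    "training_mse": float(self.training_mse),
                    "alpha": self.alpha,
                },
                fh,
                sort_keys=False,
            )

    @classmethod
    def from_yaml(cls, path) -> "RegressionModel":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            tuple(d["feature_indices"]),
            np.asarray(d["weights"], dtype=float),
            d["intercept"],
            d["training_mse"],
            d.get("alpha"),
        )


def _feature_block(features, indices: Sequence[int]) -> np.ndarray:
    """Columns of a 28-feature container for the given 1-based indices."""
    if isinstance(features, pd.DataFrame):
        mat = ft.feature_matrix(features)
    else:
        mat = np.atleast_2d(np.asarray(features, dtype=float))
    if mat.shape[1] != ft.N_FEATURES:
        raise ValueError(
            f"expected a (n, {ft.N_FEATURES}) feature container, got {mat.shape}"
        )
    return mat[:, [j - 1 for j in indices]]


def fit_model(
    features, y: np.ndarray, indices: Sequence[int], alpha: float | None = None
) -> RegressionModel:
    """Fit the pseudoinverse least-squares model on the selected features."""
    indices = tuple(indices)
    y = np.asarray(y, dtype=float)
    X = design_matrix(_feature_block(features, indices)) if indices else np.ones(
        (y.shape[0], 1)
    )
    w = fit_least_squares(X, y)
    y_hat = X @ w
    return RegressionModel(
        feature_indices=indices,
        weights=w[:-1] if indices else np.zeros(0),
        intercept=float(w[-1]),
        training_mse=mse(y, y_hat),
        alpha=alpha,
    )


def predict(model: RegressionModel, features) -> np.ndarray:
    """Apply a fitted model to a 28-feature row, matrix or table."""
    if isinstance(features, dict):
        try:
            block = np.array(
                [[features[j] for j in model.feature_indices]], dtype=float
            )
        except KeyError as exc:
            raise ValueError(f"missing feature index {exc.args[0]} in input") from exc
        return float(block @ model.weights + model.intercept)
    single = np.asarray(features).ndim == 1 and not isinstance(features, pd.DataFrame)
    block = _feature_block(features, model.feature_indices) if model.feature_indices \
        else np.zeros((np.atleast_2d(features).shape[0], 0))
    out = block @ model.weights + model.intercept
    return float(out[0]) if single else out


class PartialFResult(NamedTuple):
    f_statistic: float
    p_value: float
    significant: bool


def partial_f_test(
    sse_reduced: float, sse_full: float, n: int, p_full: int, alpha: float = 0.05
) -> PartialFResult:
    """Partial F-test for a one-feature change between nested models.

    ``p_full`` counts all parameters of the larger model including the
    intercept; the statistic is ``(sse_reduced - sse_full) / (sse_full /
    (n - p_full))`` referred to an F(1, n - p_full) distribution.
    """
    if n <= p_full:
        raise ValueError(f"need n > p_full, got n={n}, p_full={p_full}")
    diff = sse_reduced - sse_full
    if diff < -_SSE_TOL * max(1.0, sse_reduced):
        raise ValueError("sse_full exceeds sse_reduced: models are not nested")
    diff = max(diff, 0.0)
    dof = n - p_full
    if sse_full <= 0:
        f_stat = 0.0 if diff == 0 else np.inf
    else:
        f_stat = diff / (sse_full / dof)
    p = float(stats.f.sf(f_stat, 1, dof))
    return PartialFResult(float(f_stat), p, p < alpha)


def _selection_sse(features, y, indices: Sequence[int]) -> tuple[float, int]:
    X = design_matrix(_feature_block(features, indices)) if indices else np.ones(
        (len(y), 1)
    )
    sse, _, rank = _sse(X, y)
    return sse, rank


def stepwise_select(
    features,
    y: np.ndarray,
    pool: FeaturePool | Iterable[int],
    alpha: float = 0.05,
    exit_alpha: float | None = None,
) -> tuple[int, ...]:
    """Stepwise (forward with backward pruning) feature selection.

    Starting from the intercept-only model, each step adds the candidate with
    the largest significant partial F (entry at ``alpha``; ties broken toward
    the lower feature index), then repeatedly removes the selected feature
    with the smallest insignificant partial F (exit at ``exit_alpha``,
    default equal to ``alpha``).  The search stops when neither an addition
    nor a removal is significant.  Candidates that would make the design
    matrix rank deficient are skipped; a feature removed in a pruning pass is
    barred from re-entering on the immediately following addition step, and a
    hard iteration guard (50 per pool feature) bounds pathological cycling.

    Returns the selected feature indices in order of entry (possibly empty).
    """
    pool_idx = sorted(pool.indices if isinstance(pool, FeaturePool) else set(pool))
    if not pool_idx:
        raise ValueError("feature pool is empty")
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 2:
        raise ValueError("need at least 2 observations")
    exit_alpha = alpha if exit_alpha is None else exit_alpha

    selected: list[int] = []
    sse_cur, _ = _selection_sse(features, y, selected)
    barred: set[int] = set()
    max_iter = len(pool_idx) * 50
    for _ in range(max_iter):
        # --- forward step ---
        best_j, best_f, best_sse = None, -np.inf, None
        p_full = len(selected) + 2  # features + candidate + intercept
        if n > p_full:
            for j in pool_idx:
                if j in selected or j in barred:
                    continue
                sse_j, rank = _selection_sse(features, y, selected + [j])
                if rank < len(selected) + 2:
                    log.warning("candidate feature %d makes the design rank deficient", j)
                    continue
                f_stat, p, sig = partial_f_test(sse_cur, sse_j, n, p_full, alpha)
                if sig and f_stat > best_f:
                    best_j, best_f, best_sse = j, f_stat, sse_j
        barred = set()
        added = best_j is not None
        if added:
            selected.append(best_j)
            sse_cur = best_sse
        # --- backward pruning ---
        removed_any = False
        while selected:
            p_full = len(selected) + 1
            if n <= p_full:
                break
            worst_j, worst_f, worst_sse = None, np.inf, None
            for j in selected:
                rest = [k for k in selected if k != j]
                sse_red, _ = _selection_sse(features, y, rest)
                f_stat, p, sig = partial_f_test(
                    sse_red, sse_cur, n, p_full, exit_alpha
                )
                if not sig and f_stat < worst_f:
                    worst_j, worst_f, worst_sse = j, f_stat, sse_red
            if worst_j is None:
                break
            selected.remove(worst_j)
            sse_cur = worst_sse
            barred.add(worst_j)
            removed_any = True
        if not added and not removed_any:
            break
    else:
        log.warning("stepwise_select hit the iteration guard; returning current set")
    return tuple(selected)
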