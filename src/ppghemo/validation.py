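"""Nested leave-one-out cross-validation with histogram-consensus model choice.

With only a few dozen subjects, a model whose features were selected on the
full data set and then scored on the same data is optimistically biased.  The
scheme here nests the selection inside the validation: in the outer loop one
subject is withheld for testing; the remaining n-1 subjects enter an inner
leave-one-out loop in which stepwise selection is run n-1 times, each time
leaving one further subject aside.  Two histograms summarize the inner runs:
HIST1 counts how often each feature index was selected, HIST2 how many
features each run selected.  The consensus model takes k = the modal model
size of HIST2 and the k most frequent features of HIST1, is refit on all
n-1 outer-training subjects, and predicts the withheld subject.  The pooled
histograms over all outer folds describe which features drive the estimate;
the held-out mean squared error estimates generalization performance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import features as ft
from .features import FeaturePool
from .regression import RegressionModel, fit_model, mse, predict, stepwise_select

log = logging.getLogger(__name__)


@dataclass
class SelectionHistograms:
    """Feature-frequency (HIST1) and model-size (HIST2) selection histograms.

    ``hist1[j]`` counts how often feature index j (1..28) was selected;
    ``hist2[k]`` counts inner runs that selected exactly k features.  The
    identity sum_k k*hist2[k] == sum_j hist1[j] always holds.
    """

    hist1: np.ndarray = field(
        default_factory=lambda: np.zeros(ft.N_FEATURES + 1, dtype=int)
    )
    hist2: np.ndarray = field(
        default_factory=lambda: np.zeros(ft.N_FEATURES + 1, dtype=int)
    )

    @property
    def n_runs(self) -> int:
        return int(self.hist2.sum())

    def record(self, selected: tuple[int, ...]) -> None:
        for j in selected:
            self.hist1[j] += 1
        self.hist2[len(selected)] += 1

    def add(self, other: "SelectionHistograms") -> None:
        self.hist1 += other.hist1
        self.hist2 += other.hist2

    def validate(self) -> None:
        sizes = np.arange(self.hist2.size)
        if int((sizes * self.hist2).sum()) != int(self.hist1.sum()):
            raise ValueError("histograms inconsistent: feature counts != size-weighted runs")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "index": np.arange(self.hist1.size),
                "hist1_feature_count": self.hist1,
                "hist2_size_count": self.hist2,
            }
        )


def inner_selection(
    features, y: np.ndarray, pool: FeaturePool, alpha: float = 0.05
) -> SelectionHistograms:
    """Leave-one-out stepwise selection over n-1 subjects; returns histograms.

    Runs :func:`stepwise_select` once per left-out subject and accumulates
    HIST1/HIST2 over the runs.
    """
    mat = ft.feature_matrix(features) if isinstance(features, pd.DataFrame) else np.asarray(
        features, dtype=float
    )
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if n < 3:
        raise ValueError("inner selection needs at least 3 subjects")
    hists = SelectionHistograms()
    for i in range(n):
        keep = np.arange(n) != i
        sel = stepwise_select(mat[keep], y[keep], pool, alpha)
        hists.record(sel)
    return hists


def consensus_model(hists: SelectionHistograms) -> tuple[int, ...]:
    """Histogram-consensus feature set: top-k of HIST1 with k the HIST2 mode.

    Ties in the HIST2 mode resolve toward the smaller model size; ties at the
    k-th HIST1 slot resolve toward the lower feature index.  If fewer than k
    features were ever selected, all ever-selected features are returned.
    """
    hists.validate()
    k = int(np.argmax(hists.hist2))  # argmax takes the first (smallest) mode
    if k == 0:
        return ()
    ever = np.nonzero(hists.hist1[1:])[0] + 1
    ranked = sorted(ever, key=lambda j: (-hists.hist1[j], j))
    return tuple(sorted(ranked[:k]))


@dataclass
class CrossValResult:
    """Everything the nested leave-one-out procedure produces."""

    subject_ids: np.ndarray
    y: np.ndarray
    predictions: np.ndarray
    fold_models: list[RegressionModel]
    pooled: SelectionHistograms
    mse_holdout: float

    @property
    def fold_indices(self) -> list[tuple[int, ...]]:
        return [m.feature_indices for m in self.fold_models]

    @property
    def mean_training_mse(self) -> float:
        return float(np.mean([m.training_mse for m in self.fold_models]))

    def folds_frame(self) -> pd.DataFrame:
        rows = []
        for sid, yv, pred, m in zip(
            self.subject_ids, self.y, self.predictions, self.fold_models
        ):
            rows.append(
                {
                    "subject_id": sid,
                    "measured": yv,
                    "predicted": pred,
                    "features": ",".join(str(j) for j in m.feature_indices),
                    "weights": ",".join(f"{w:.6g}" for w in m.weights),
                    "intercept": m.intercept,
                    "training_mse": m.training_mse,
                }
            )
        return pd.DataFrame(rows)


def nested_loocv(
    table: pd.DataFrame,
    target: str,
    pool: FeaturePool,
    alpha: float = 0.05,
) -> CrossValResult:
    """Nested leave-one-out cross-validation of the stepwise-selected model.

    ``table`` is a feature table with ``subject_id``, the 28 feature columns
    and the target column (``CO`` or ``SVR``).  For each outer fold the
    withheld subject plays no part in either feature selection or training;
    the consensus model from the inner histograms is refit on the n-1
    training subjects and scored on the withheld one.  Subjects are processed
    in ``subject_id`` order so results are independent of row order.
    """
    if target not in table.columns:
        raise ValueError(f"target column {target!r} not in table")
    df = table.sort_values("subject_id").reset_index(drop=True) if "subject_id" in \
        table.columns else table.reset_index(drop=True)
    n = len(df)
    if n < 4:
        raise ValueError(f"nested LOOCV needs at least 4 subjects, got {n}")
    mat = ft.feature_matrix(df)
    y = df[target].to_numpy(dtype=float)
    ids = (
        df["subject_id"].to_numpy()
        if "subject_id" in df.columns
        else np.arange(n)
    )

    predictions = np.empty(n)
    fold_models: list[RegressionModel] = []
    pooled = SelectionHistograms()
    for i in range(n):
        keep = np.arange(n) != i
        hists = inner_selection(mat[keep], y[keep], pool, alpha)
        sel = consensus_model(hists)
        model = fit_model(mat[keep], y[keep], sel, alpha=alpha)
        predictions[i] = predict(model, mat[i])
        fold_models.append(model)
        pooled.add(hists)
        log.info("fold %d/%d: consensus features %s", i + 1, n, sel or "(none)")
    return CrossValResult(
        subject_ids=ids,
        y=y,
        predictions=predictions,
        fold_models=fold_models,
        pooled=pooled,
        mse_holdout=mse(y, predictions),
    )
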