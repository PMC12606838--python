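"""Out-of-sample evaluation of DFPS predictors on the back-transformed scale.

Two evaluation modes mirror how the predictors are meant to be used:

* :func:`cross_validate` -- k-fold (default 5) cross-validation of a model
  specification on one estimation table: refit on k-1 folds, predict the
  held-out fold, pool all held-out pairs.
* :func:`out_of_sample_eval` -- evaluate a frozen fitted model (no refitting)
  on a table from another inequality dimension.

All metrics are computed on the proportion scale after back-transforming the
logit-scale predictions: bias = mean(predicted - observed), MAE, Pearson
correlation, and r-squared defined as the squared pooled correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import fpreg
from .predictor import inv_logit

__all__ = ["CVResult", "kfold_split", "cross_validate", "out_of_sample_eval"]


@dataclass(frozen=True)
class CVResult:
    """Pooled out-of-sample metrics on the proportion scale."""

    r_squared: float
    bias: float
    mae: float
    correlation: float
    k: int
    seed: int | None
    n: int

    def __post_init__(self) -> None:
        # triangle inequality on means: mean |e| >= |mean e|
        assert self.mae >= abs(self.bias) - 1e-12


def kfold_split(n: int, k: int = 5, seed: int = 0) -> list[np.ndarray]:
    """Partition indices 0..n-1 into k disjoint folds of near-equal size.

    Fold sizes differ by at most one; the assignment is a seeded random
    permutation, so the same seed always yields the same partition.
    """
    if n < k:
        raise ValueError(f"need at least k={k} rows, got n={n}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    return [np.sort(fold) for fold in np.array_split(perm, k)]


def _metrics(pred: np.ndarray, obs: np.ndarray, k: int, seed: int | None) -> CVResult:
    resid = pred - obs
    bias = float(resid.mean())
    mae = float(np.abs(resid).mean())
    if np.std(pred) == 0 or np.std(obs) == 0:
        corr = float("nan")
        r2 = 1.0 if np.allclose(pred, obs) else float("nan")
    else:
        corr = float(np.corrcoef(pred, obs)[0, 1])
        r2 = corr**2
    return CVResult(r2, bias, mae, corr, k, seed, len(obs))


def cross_validate(
    spec: fpreg.FPModelSpec, data: pd.DataFrame, k: int = 5, seed: int = 0
) -> CVResult:
    """k-fold cross-validation of an FP specification on an estimation table.

    Each fold's model is trained on the remaining folds and predicts the
    held-out rows on the logit scale; predictions are back-transformed and all
    held-out (predicted, observed) pairs are pooled into one set of metrics.
    """
    data = data.reset_index(drop=True)
    folds = kfold_split(len(data), k=k, seed=seed)
    X, y, clusters = fpreg.build_design(data, spec)
    obs = data[fpreg.outcome_column(spec.outcome)].to_numpy(dtype=float)
    pred = np.full(len(data), np.nan)
    for i, holdout in enumerate(folds):
        train = np.setdiff1d(np.arange(len(data)), holdout)
        try:
            fit = fpreg.fit_ols(X[train], y[train], clusters[train], spec=spec)
        except (fpreg.SingularDesignError, ValueError) as exc:
            raise type(exc)(f"fold {i}: {exc}") from exc
        pred[holdout] = inv_logit(X[holdout] @ np.asarray(fit.coefficients))
    return _metrics(pred, obs, k, seed)


def out_of_sample_eval(model: fpreg.FittedModel, data: pd.DataFrame) -> CVResult:
    """Evaluate a frozen fitted model on another table; no refitting, no folds.

    Raises if the evaluation table lacks the model's predictor columns.
    """
    spec = model.spec
    needed = [fpreg.predictor_column(spec.primary_predictor),
              fpreg.outcome_column(spec.outcome), *spec.extra_covariates]
    missing = [c for c in needed if c not in data.columns]
    if missing:
        raise KeyError(f"evaluation data lacks column(s): {missing}")
    data = data.reset_index(drop=True)
    X, _, _ = fpreg.build_design(data, spec)
    pred = inv_logit(X @ np.asarray(model.coefficients))
    obs = data[fpreg.outcome_column(spec.outcome)].to_numpy(dtype=float)
    return _metrics(np.asarray(pred), obs, k=0, seed=None)
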