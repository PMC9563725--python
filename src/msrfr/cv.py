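"""Prediction scoring and the four-fold cross-validation grid search.

Hyperparameters (lambda1..lambda4) are chosen by exhaustive grid search:
fold assignment is drawn once per cohort (so folds are stratified by
cohort and shared across all lambda combinations), each combination is
fit on three folds and scored by RMSE between predicted and held-out
mRNA values on the fourth, and the combination with the minimal mean
fold RMSE wins.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import optimizer
from .model import Hyperparameters, ModelParameters
from .optimizer import FitConfig

__all__ = ["CvGrid", "CvResult", "predict", "rmse", "nrmse", "make_folds", "cross_validate"]


def predict(params: ModelParameters, Xk: np.ndarray, k: int) -> np.ndarray:
    """Yhat_k = Xk [WXS WXk] [WYS; WYk]."""
    Xk = np.asarray(Xk, dtype=float)
    if Xk.ndim != 2 or Xk.shape[1] != params.D:
        raise ValueError(f"Xk must be (N, {params.D})")
    return Xk @ params.coefficient(k)


def rmse(Y: np.ndarray, Yhat: np.ndarray) -> float:
    """Root mean squared residual over all entries."""
    Y, Yhat = np.asarray(Y, float), np.asarray(Yhat, float)
    if Y.shape != Yhat.shape:
        raise ValueError("shape mismatch")
    return float(np.sqrt(np.mean((Y - Yhat) ** 2)))


def nrmse(Y: np.ndarray, Yhat: np.ndarray, normalization: str = "sd") -> float:
    """Per-mRNA RMSE normalized by that mRNA's spread, averaged over mRNAs.

    With ``normalization="sd"`` (default) each column's RMSE is divided
    by the column's observed (population) standard deviation, so
    predicting every column's mean scores exactly 1.  ``"range"``
    divides by the column's max-min instead.
    """
    Y, Yhat = np.asarray(Y, float), np.asarray(Yhat, float)
    if Y.shape != Yhat.shape:
        raise ValueError("shape mismatch")
    col_rmse = np.sqrt(np.mean((Y - Yhat) ** 2, axis=0))
    if normalization == "sd":
        denom = Y.std(axis=0, ddof=0)
    elif normalization == "range":
        denom = Y.max(axis=0) - Y.min(axis=0)
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    if np.any(denom <= 0):
        raise ValueError("every mRNA column must have positive spread")
    return float(np.mean(col_rmse / denom))


@dataclass(frozen=True)
class CvGrid:
    """Candidate values per penalty weight and the fold layout."""

    lambda1_values: tuple[float, ...]
    lambda2_values: tuple[float, ...]
    lambda3_values: tuple[float, ...]
    lambda4_values: tuple[float, ...]
    n_folds: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("lambda1_values", "lambda2_values", "lambda3_values", "lambda4_values"):
            vals = tuple(float(v) for v in getattr(self, name))
            if not vals:
                raise ValueError(f"{name} must be non-empty")
            object.__setattr__(self, name, vals)
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")

    def combinations(self):
        return itertools.product(
            self.lambda1_values, self.lambda2_values, self.lambda3_values, self.lambda4_values
        )


#: the published grids, by tissue experiment (for TCGA-scale cohorts)
PRESET_GRIDS = {
    "blood": CvGrid((60, 80, 100, 125, 150), (10, 15, 20, 25, 30),
                    (60, 80, 100, 125, 150), (10, 15, 20, 25, 30)),
    "kidney": CvGrid((150, 200, 250, 300, 350), (10, 15, 20, 25, 30),
                     (150, 200, 250, 300, 350), (10, 15, 20, 25, 30)),
    "lung": CvGrid((150, 200, 250, 300, 350), (10, 15, 20, 25, 30),
                   (150, 200, 250, 300, 350), (10, 15, 20, 25, 30)),
}


@dataclass
class CvResult:
    table: pd.DataFrame  # lambda1..lambda4, mean_rmse, fold_rmse_*
    best: Hyperparameters
    folds: list[list[np.ndarray]] = field(repr=False, default=None)

    @property
    def best_rmse(self) -> float:
        return float(self.table["mean_rmse"].min())

    @property
    def best_parsimonious(self) -> Hyperparameters:
        """One-standard-error rule: the most-regularized combination whose
        mean RMSE is within one standard error of the minimum.

        The cross-validated RMSE surface of this model is typically very
        flat near its minimum, so the plain argmin under-penalizes and
        keeps noise-fitting components alive; picking the largest
        penalties statistically indistinguishable from the argmin is the
        standard parsimony device for model selection.  "Most
        regularized" orders by lambda1 + lambda3 (the sparsity mass),
        then lambda2 + lambda4.
        """
        fold_cols = [c for c in self.table.columns if c.endswith("_rmse") and c != "mean_rmse"]
        i_best = self.table["mean_rmse"].idxmin()
        scores = self.table.loc[i_best, fold_cols].to_numpy(dtype=float)
        se = float(scores.std(ddof=1) / np.sqrt(len(scores)))
        eligible = self.table[self.table["mean_rmse"] <= self.table["mean_rmse"].min() + se]
        ordered = eligible.assign(
            _l13=eligible["lambda1"] + eligible["lambda3"],
            _l24=eligible["lambda2"] + eligible["lambda4"],
        ).sort_values(["_l13", "_l24", "lambda1", "lambda2"], ascending=False, kind="stable")
        b = ordered.iloc[0]
        return Hyperparameters(b["lambda1"], b["lambda2"], b["lambda3"], b["lambda4"])


def make_folds(n_samples: list[int], n_folds: int, seed: int) -> list[list[np.ndarray]]:
    """Per-cohort random partition into ``n_folds`` near-equal folds.

    Returns folds[f][k] = sample indices of cohort k held out in fold f.
    """
    rng = np.random.default_rng(seed)
    per_cohort = []
    for n in n_samples:
        if n < n_folds:
            raise ValueError(f"cohort with {n} samples cannot support {n_folds} folds")
        per_cohort.append(np.array_split(rng.permutation(n), n_folds))
    folds = [[per_cohort[k][f] for k in range(len(n_samples))] for f in range(n_folds)]
    for fold in folds:
        if any(len(ix) < 2 for ix in fold):
            raise ValueError("a fold has fewer than 2 samples in some cohort")
    return folds


def _standardize_pair(train: np.ndarray, test: np.ndarray):
    """Column-standardize with training statistics; constant columns pass through."""
    mu = train.mean(axis=0)
    sd = train.std(axis=0, ddof=1)
    sd = np.where(sd > 0, sd, 1.0)
    return (train - mu) / sd, (test - mu) / sd


def cross_validate(
    data,
    grid: CvGrid,
    config: FitConfig | None = None,
    estimate_ranks: bool = True,
) -> CvResult:
    """Grid-search lambda1..lambda4 by cross-validated held-out RMSE.

    Fold assignment is drawn once and reused for every combination.
    Training folds are re-standardized and their statistics applied to
    the held-out fold, so no held-out information enters the fit.  With
    ``estimate_ranks=False`` the rank-reduction loop is skipped inside
    CV (ranks fixed at rank_upper), which is much faster and usually
    ranks combinations identically.  Ties in mean RMSE are broken by
    the lexicographically smallest (lambda1, lambda3, lambda2, lambda4).
    """
    config = config or FitConfig()
    if hasattr(data, "X_arrays"):
        Xs, Ys = data.X_arrays(), data.Y_arrays()
    else:
        Xs, Ys = data
    K = len(Xs)
    folds = make_folds([x.shape[0] for x in Xs], grid.n_folds, grid.seed)

    # pre-split per fold: (train Xs, train Ys, test Xs, test Ys)
    splits = []
    for fold in folds:
        tr_X, tr_Y, te_X, te_Y = [], [], [], []
        for k in range(K):
            held = np.zeros(Xs[k].shape[0], dtype=bool)
            held[fold[k]] = True
            xtr, xte = _standardize_pair(Xs[k][~held], Xs[k][held])
            ytr, yte = _standardize_pair(Ys[k][~held], Ys[k][held])
            tr_X.append(xtr)
            tr_Y.append(ytr)
            te_X.append(xte)
            te_Y.append(yte)
        splits.append((tr_X, tr_Y, te_X, te_Y))

    rows = []
    for l1, l2, l3, l4 in grid.combinations():
        hp = Hyperparameters(l1, l2, l3, l4)
        fold_scores = []
        for tr_X, tr_Y, te_X, te_Y in splits:
            if estimate_ranks:
                result = optimizer.fit((tr_X, tr_Y), hp, config)
                params = result.params
            else:
                ranks = (config.rank_upper, [config.rank_upper] * K)
                params, _, _ = optimizer.fit_fixed_ranks((tr_X, tr_Y), hp, ranks, config)
            sq, n = 0.0, 0
            for k in range(K):
                resid = te_Y[k] - predict(params, te_X[k], k)
                sq += float(np.sum(resid**2))
                n += resid.size
            fold_scores.append(float(np.sqrt(sq / n)))
        rows.append(
            {
                "lambda1": l1,
                "lambda2": l2,
                "lambda3": l3,
                "lambda4": l4,
                **{f"fold{i}_rmse": s for i, s in enumerate(fold_scores)},
                "mean_rmse": float(np.mean(fold_scores)),
            }
        )

    table = pd.DataFrame(rows)
    ordered = table.sort_values(
        ["mean_rmse", "lambda1", "lambda3", "lambda2", "lambda4"], kind="stable"
    )
    b = ordered.iloc[0]
    best = Hyperparameters(b["lambda1"], b["lambda2"], b["lambda3"], b["lambda4"])
    return CvResult(table=table, best=best, folds=folds)
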