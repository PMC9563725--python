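"""Scikit-learn style front end for the multitask sparse factor regression."""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import optimizer
from .model import Hyperparameters, ModelParameters
from .optimizer import FitConfig, FitResult

__all__ = ["MSRFR"]


class MSRFR(BaseEstimator):
    """Multitask sparse reduced-rank factor regression.

    Learns, from K cohorts of matched miRNA (X) and mRNA (Y) expression
    matrices, a shared low-rank coefficient block (tissue-specific
    regulatory modules) plus one private block per cohort
    (cohort-specific modules), under an elastic-net penalty on both
    factor sides.  Block ranks are estimated automatically by shrinking
    rank-deficient blocks until every surviving block is full rank.

    Parameters
    ----------
    lambda1, lambda2 : float
        l1 and squared-Frobenius penalty weights on the miRNA-side
        loading blocks.
    lambda3, lambda4 : float
        Same pair for the mRNA-side blocks.
    rank_upper : int, default 10
        RU, the starting rank of every block (shared and per cohort).
    epsilon : float, default 1e-4
        Inner-loop stopping tolerance on |f(t+1)-f(t)| / f(t).
    max_iter : int, default 1000
        Inner-iteration cap.
    init_scale : float, default 0.1
        Standard deviation of the random Gaussian initialization.
    rank_tolerance : float, default 0.25
        Relative singular-value cutoff used by the rank check.
    warm_start : bool, default True
        Restart rank-reduced problems from the truncated previous
        solution (deterministic) instead of a fresh random draw.
    multiplier_rule : {"bound", "printed"}, default "bound"
        How prox step sizes are computed; "bound" guarantees monotone
        descent.
    random_state : int, default 0
        Seed for the initialization.

    Attributes
    ----------
    WXS_, WYS_ : ndarray
        Shared (tissue) loading blocks, (D, Rs) and (Rs, T).
    WXk_, WYk_ : list of ndarray
        Cohort-specific loading blocks.
    ranks_ : (int, list of int)
        Estimated (Rs, [R1..RK]).
    objective_trace_ : list of float
        Objective values across all inner iterations and restarts.
    converged_ : bool
        Whether the final inner run met the epsilon criterion.

    Examples
    --------
    >>> from msrfr.synthetic import SyntheticConfig, generate
    >>> data, truth = generate(SyntheticConfig(seed=0))
    >>> est = MSRFR(lambda1=4, lambda2=1, lambda3=4, lambda4=1,
    ...             rank_upper=4, random_state=0).fit(data)
    >>> est.ranks_  # doctest: +SKIP
    (2, [1, 1])
    """

    def __init__(
        self,
        lambda1: float = 1.0,
        lambda2: float = 1.0,
        lambda3: float = 1.0,
        lambda4: float = 1.0,
        rank_upper: int = 10,
        epsilon: float = 1e-4,
        max_iter: int = 1000,
        init_scale: float = 0.1,
        rank_tolerance: float = 0.25,
        warm_start: bool = True,
        multiplier_rule: str = "bound",
        random_state: int = 0,
    ):
        self.lambda1 = lambda1
        self.lambda2 = lambda2
        self.lambda3 = lambda3
        self.lambda4 = lambda4
        self.rank_upper = rank_upper
        self.epsilon = epsilon
        self.max_iter = max_iter
        self.init_scale = init_scale
        self.rank_tolerance = rank_tolerance
        self.warm_start = warm_start
        self.multiplier_rule = multiplier_rule
        self.random_state = random_state

    # -----------------------------------------------------------------
    def _hyperparameters(self) -> Hyperparameters:
        return Hyperparameters(self.lambda1, self.lambda2, self.lambda3, self.lambda4)

    def _config(self) -> FitConfig:
        return FitConfig(
            rank_upper=self.rank_upper,
            epsilon=self.epsilon,
            max_iter=self.max_iter,
            seed=self.random_state,
            init_scale=self.init_scale,
            rank_tolerance=self.rank_tolerance,
            warm_start=self.warm_start,
            multiplier_rule=self.multiplier_rule,
        )

    @staticmethod
    def _coerce(X, Y):
        if Y is None:
            return X  # MultitaskDataset or (Xs, Ys) tuple
        Xs = [np.asarray(x, dtype=float) for x in X]
        Ys = [np.asarray(y, dtype=float) for y in Y]
        if len(Xs) != len(Ys):
            raise ValueError("X and Y must list the same cohorts")
        for k, (x, y) in enumerate(zip(Xs, Ys)):
            if x.ndim != 2 or y.ndim != 2 or x.shape[0] != y.shape[0]:
                raise ValueError(f"cohort {k}: X and Y must be 2-d with equal sample counts")
        return (Xs, Ys)

    def fit(self, X, Y=None) -> "MSRFR":
        """Fit on a MultitaskDataset or on per-cohort lists of arrays."""
        data = self._coerce(X, Y)
        result: FitResult = optimizer.fit(data, self._hyperparameters(), self._config())
        self.result_ = result
        self.WXS_ = result.params.WXS
        self.WXk_ = result.params.WXk
        self.WYS_ = result.params.WYS
        self.WYk_ = result.params.WYk
        self.ranks_ = result.ranks
        self.rank_total_ = result.rank_total
        self.objective_trace_ = result.objective_trace
        self.converged_ = result.converged
        self.n_outer_restarts_ = result.n_outer_restarts
        self.n_cohorts_ = result.params.K
        if hasattr(data, "mirna_ids"):
            self.mirna_ids_ = data.mirna_ids
            self.mrna_ids_ = data.mrna_ids
            self.cohort_names_ = data.cohort_names
        return self

    @property
    def params_(self) -> ModelParameters:
        check_is_fitted(self, "result_")
        return self.result_.params

    def predict(self, X, cohort: int = 0) -> np.ndarray:
        """Predicted mRNA matrix for cohort ``cohort``: Xk [WXS WXk][WYS; WYk]."""
        check_is_fitted(self, "result_")
        X = np.asarray(getattr(X, "to_numpy", lambda: X)(), dtype=float)
        if X.shape[1] != self.params_.D:
            raise ValueError(f"X has {X.shape[1]} features, model expects {self.params_.D}")
        return X @ self.params_.coefficient(cohort)

    def score(self, X, Y=None) -> float:
        """Negative RMSE pooled over cohorts (higher is better)."""
        from .cv import rmse

        data = self._coerce(X, Y)
        if hasattr(data, "X_arrays"):
            Xs, Ys = data.X_arrays(), data.Y_arrays()
        else:
            Xs, Ys = data
        sq, n = 0.0, 0
        for k, (x, y) in enumerate(zip(Xs, Ys)):
            r = rmse(y, self.predict(x, cohort=k))
            sq += r**2 * y.size
            n += y.size
        return -float(np.sqrt(sq / n))

    def extract_modules(self, mirna_ids=None, mrna_ids=None, cohort_names=None):
        """Ranked rank-one regulatory modules of the fitted blocks."""
        from .modules import extract_modules

        check_is_fitted(self, "result_")
        return extract_modules(
            self.result_,
            mirna_ids=mirna_ids if mirna_ids is not None else getattr(self, "mirna_ids_", None),
            mrna_ids=mrna_ids if mrna_ids is not None else getattr(self, "mrna_ids_", None),
            cohort_names=cohort_names
            if cohort_names is not None
            else getattr(self, "cohort_names_", None),
        )
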