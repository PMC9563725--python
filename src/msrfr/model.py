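"""Objective, gradients and proximal machinery of the multitask factor model.

The model couples K cohorts through a shared (tissue-level) factor block
and gives each cohort a private block.  Writing ``WXSk = [WXS WXk]`` and
``WYSk = [WYS; WYk]``, cohort k's coefficient matrix is
``W^k = WXSk @ WYSk`` and the penalized objective is

    f = 1/2 sum_k ||Yk - Xk WXSk WYSk||_F^2
        + lambda1 * (||WXS||_1 + sum_k ||WXk||_1)
        + lambda2 * (||WXS||_F^2 + sum_k ||WXk||_F^2)
        + lambda3 * (||WYS||_1 + sum_k ||WYk||_1)
        + lambda4 * (||WYS||_F^2 + sum_k ||WYk||_F^2)

an elastic-net penalty on both factor sides: the l1 terms induce sparse
module vectors, the squared Frobenius terms group correlated features.
Each block is updated by a prox-linear step — a gradient step on the
smooth part followed by soft-thresholding — with the step size set from
a blockwise Lipschitz bound so that every update decreases f.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Hyperparameters",
    "ModelParameters",
    "soft_threshold",
    "objective",
    "gram_cache",
    "grad_h_shared",
    "grad_h_cohort",
    "grad_g_shared",
    "grad_g_cohort",
    "step_multipliers",
    "prox_update_block",
]

#: step multipliers never drop below this, guarding a division at cold start
MULTIPLIER_FLOOR = 1e-8


@dataclass(frozen=True)
class Hyperparameters:
    """Elastic-net weights: l1/Frobenius on the miRNA side (lambda1/lambda2)
    and on the mRNA side (lambda3/lambda4)."""

    lambda1: float
    lambda2: float
    lambda3: float
    lambda4: float

    def __post_init__(self) -> None:
        for name in ("lambda1", "lambda2", "lambda3", "lambda4"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


@dataclass
class ModelParameters:
    """The four learned blocks.

    WXS : (D, Rs) shared miRNA loadings; WXk[k] : (D, Rk) private ones.
    WYS : (Rs, T) shared mRNA loadings;  WYk[k] : (Rk, T) private ones.
    A block with zero columns/rows represents an eliminated scope.
    """

    WXS: np.ndarray
    WXk: list[np.ndarray]
    WYS: np.ndarray
    WYk: list[np.ndarray]

    def __post_init__(self) -> None:
        self.WXS = np.atleast_2d(np.asarray(self.WXS, dtype=float))
        self.WYS = np.atleast_2d(np.asarray(self.WYS, dtype=float))
        self.WXk = [np.atleast_2d(np.asarray(m, dtype=float)) for m in self.WXk]
        self.WYk = [np.atleast_2d(np.asarray(m, dtype=float)) for m in self.WYk]
        if self.WXS.shape[1] != self.WYS.shape[0]:
            raise ValueError("shared block rank mismatch between WXS and WYS")
        if len(self.WXk) != len(self.WYk):
            raise ValueError("need one (WXk, WYk) pair per cohort")
        for k, (wx, wy) in enumerate(zip(self.WXk, self.WYk)):
            if wx.shape[1] != wy.shape[0]:
                raise ValueError(f"cohort {k} block rank mismatch")

    @property
    def K(self) -> int:
        return len(self.WXk)

    @property
    def D(self) -> int:
        return self.WXS.shape[0]

    @property
    def T(self) -> int:
        return self.WYS.shape[1]

    @property
    def Rs(self) -> int:
        return self.WXS.shape[1]

    @property
    def Rk(self) -> list[int]:
        return [m.shape[1] for m in self.WXk]

    def stacked(self, k: int) -> tuple[np.ndarray, np.ndarray]:
        """(WXSk, WYSk) = ([WXS WXk], [WYS; WYk]) for cohort k."""
        return (
            np.hstack([self.WXS, self.WXk[k]]),
            np.vstack([self.WYS, self.WYk[k]]),
        )

    def coefficient(self, k: int) -> np.ndarray:
        """Cohort k's implied (D, T) coefficient matrix."""
        wx, wy = self.stacked(k)
        return wx @ wy

    def copy(self) -> "ModelParameters":
        return ModelParameters(
            self.WXS.copy(),
            [m.copy() for m in self.WXk],
            self.WYS.copy(),
            [m.copy() for m in self.WYk],
        )


def _as_arrays(data) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Accept a MultitaskDataset or a (list-of-X, list-of-Y) pair."""
    if hasattr(data, "X_arrays"):
        return data.X_arrays(), data.Y_arrays()
    Xs, Ys = data
    return [np.asarray(x, float) for x in Xs], [np.asarray(y, float) for y in Ys]


def soft_threshold(v: np.ndarray | float, tau: float) -> np.ndarray | float:
    """Elementwise shrinkage S_tau(v) = sign(v) * max(|v| - tau, 0)."""
    if tau < 0:
        raise ValueError("soft-threshold parameter must be non-negative")
    return np.sign(v) * np.maximum(np.abs(v) - tau, 0.0)


def objective(params: ModelParameters, data, hp: Hyperparameters) -> float:
    """Full penalized objective f (non-negative, finite)."""
    Xs, Ys = _as_arrays(data)
    if len(Xs) != params.K:
        raise ValueError("cohort count mismatch between data and parameters")
    loss = 0.0
    for k, (X, Y) in enumerate(zip(Xs, Ys)):
        if X.shape[1] != params.D or Y.shape[1] != params.T:
            raise ValueError(f"cohort {k}: data dimensions do not match parameters")
        R = Y - X @ params.coefficient(k)
        loss += 0.5 * float(np.sum(R * R))
    l1_x = np.abs(params.WXS).sum() + sum(np.abs(m).sum() for m in params.WXk)
    fro_x = np.sum(params.WXS**2) + sum(np.sum(m**2) for m in params.WXk)
    l1_y = np.abs(params.WYS).sum() + sum(np.abs(m).sum() for m in params.WYk)
    fro_y = np.sum(params.WYS**2) + sum(np.sum(m**2) for m in params.WYk)
    return float(
        loss
        + hp.lambda1 * l1_x
        + hp.lambda2 * fro_x
        + hp.lambda3 * l1_y
        + hp.lambda4 * fro_y
    )


# ---------------------------------------------------------------------------
# gradients of the smooth part (objective without the l1 terms)
# ---------------------------------------------------------------------------

def gram_cache(data) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Precompute (Xk^T Xk, Xk^T Yk) per cohort; every gradient needs only these."""
    Xs, Ys = _as_arrays(data)
    return [X.T @ X for X in Xs], [X.T @ Y for X, Y in zip(Xs, Ys)]


def _maybe_cache(data, cache):
    return gram_cache(data) if cache is None else cache


def _residual_factor(params, k, xtx, xty):
    """Xk^T Xk WXSk WYSk - Xk^T Yk, the (D, T) smooth-loss kernel of cohort k."""
    wx, wy = params.stacked(k)
    return xtx @ (wx @ wy) - xty


def grad_h_shared(params: ModelParameters, data, hp: Hyperparameters, cache=None) -> np.ndarray:
    """d(smooth f)/d WXS = sum_k (Xk^T Xk WXSk WYSk - Xk^T Yk) WYS^T + 2 lambda2 WXS."""
    if params.Rs == 0:
        raise ValueError("shared block is eliminated (Rs = 0)")
    xtx, xty = _maybe_cache(data, cache)
    g = 2.0 * hp.lambda2 * params.WXS
    for k in range(params.K):
        g = g + _residual_factor(params, k, xtx[k], xty[k]) @ params.WYS.T
    return g


def grad_h_cohort(k: int, params: ModelParameters, data, hp: Hyperparameters, cache=None) -> np.ndarray:
    """d(smooth f)/d WXk = (Xk^T Xk WXSk WYSk - Xk^T Yk) WYk^T + 2 lambda2 WXk."""
    if params.Rk[k] == 0:
        raise ValueError(f"cohort {k} block is eliminated (Rk = 0)")
    xtx, xty = _maybe_cache(data, cache)
    return _residual_factor(params, k, xtx[k], xty[k]) @ params.WYk[k].T + 2.0 * hp.lambda2 * params.WXk[k]


def grad_g_shared(params: ModelParameters, data, hp: Hyperparameters, cache=None) -> np.ndarray:
    """d(smooth f)/d WYS = sum_k WXS^T (Xk^T Xk WXSk WYSk - Xk^T Yk) + 2 lambda4 WYS."""
    if params.Rs == 0:
        raise ValueError("shared block is eliminated (Rs = 0)")
    xtx, xty = _maybe_cache(data, cache)
    g = 2.0 * hp.lambda4 * params.WYS
    for k in range(params.K):
        g = g + params.WXS.T @ _residual_factor(params, k, xtx[k], xty[k])
    return g


def grad_g_cohort(k: int, params: ModelParameters, data, hp: Hyperparameters, cache=None) -> np.ndarray:
    """d(smooth f)/d WYk = WXk^T (Xk^T Xk WXSk WYSk - Xk^T Yk) + 2 lambda4 WYk."""
    if params.Rk[k] == 0:
        raise ValueError(f"cohort {k} block is eliminated (Rk = 0)")
    xtx, xty = _maybe_cache(data, cache)
    return params.WXk[k].T @ _residual_factor(params, k, xtx[k], xty[k]) + 2.0 * hp.lambda4 * params.WYk[k]


# ---------------------------------------------------------------------------
# step-size multipliers
# ---------------------------------------------------------------------------

@dataclass
class StepMultipliers:
    alpha_s: float
    alpha_k: list[float]
    beta_s: float
    beta_k: list[float]

    def __iter__(self):
        return iter((self.alpha_s, self.alpha_k, self.beta_s, self.beta_k))


def _fro(m: np.ndarray) -> float:
    return float(np.linalg.norm(m)) if m.size else 0.0


def step_multipliers(
    params: ModelParameters,
    data,
    hp: Hyperparameters,
    rule: str = "bound",
    xtx_norms: list[float] | None = None,
    xtx: list[np.ndarray] | None = None,
) -> StepMultipliers:
    """Step-size multipliers for the four block families.

    With ``rule="bound"`` (default) each multiplier is a provable upper
    bound on the Lipschitz constant of the corresponding blockwise
    gradient with the other blocks held fixed, e.g. for WXS the gradient
    is linear in WXS with operator norm at most
    ``sum_k ||Xk^T Xk||_F ||WYS WYS^T||_F + 2 lambda2``.  This is what
    makes every prox-linear update a descent step.  ``rule="printed"``
    evaluates the cross-term product form in which these multipliers are
    usually quoted; it is not guaranteed to dominate the Lipschitz
    constant and is provided for comparison only.

    A multiplier that evaluates to zero (possible at a cold start with
    the matching lambda at zero) is floored at ``MULTIPLIER_FLOOR``.
    """
    if rule not in ("bound", "printed"):
        raise ValueError(f"unknown multiplier rule {rule!r}")
    if xtx is None:
        Xs, _ = _as_arrays(data)
        xtx = [X.T @ X for X in Xs]
    if xtx_norms is None:
        xtx_norms = [_fro(m) for m in xtx]

    if rule == "bound":
        alpha_s = sum(xtx_norms) * _fro(params.WYS @ params.WYS.T) + 2.0 * hp.lambda2
        alpha_k = [
            n * _fro(wy @ wy.T) + 2.0 * hp.lambda2
            for n, wy in zip(xtx_norms, params.WYk)
        ]
        beta_s = (
            sum(_fro(params.WXS.T @ m @ params.WXS) for m in xtx) + 2.0 * hp.lambda4
        )
        beta_k = [
            _fro(wx.T @ m @ wx) + 2.0 * hp.lambda4
            for m, wx in zip(xtx, params.WXk)
        ]
    else:  # printed form
        alpha_s = 2.0 * hp.lambda2
        beta_s = 2.0 * hp.lambda4
        for k, m in enumerate(xtx):
            wxsk, wysk = params.stacked(k)
            alpha_s += _fro(m @ params.WXk[k]) * _fro(wysk @ params.WYS.T)
            beta_s += _fro(params.WXS.T @ m @ wxsk @ wysk)
        alpha_k, beta_k = [], []
        for k, m in enumerate(xtx):
            wxsk, wysk = params.stacked(k)
            alpha_k.append(
                _fro(m @ params.WXS) * _fro(wysk @ params.WYk[k].T) + 2.0 * hp.lambda2
            )
            beta_k.append(_fro(params.WXk[k].T @ m @ wxsk @ wysk) + 2.0 * hp.lambda4)

    floor = MULTIPLIER_FLOOR
    return StepMultipliers(
        max(alpha_s, floor),
        [max(a, floor) for a in alpha_k],
        max(beta_s, floor),
        [max(b, floor) for b in beta_k],
    )


def prox_update_block(
    block: np.ndarray, grad: np.ndarray, multiplier: float, l1: float
) -> np.ndarray:
    """One prox-linear step: S_{l1/multiplier}(block - grad / multiplier).

    Solves argmin_w  l1*||w||_1 + multiplier/2 * ||w - (block - grad/multiplier)||^2,
    i.e. a gradient step on the smooth part followed by soft-thresholding.
    With l1 = 0 it reduces to a plain gradient step.
    """
    if multiplier <= 0:
        raise ValueError("step multiplier must be positive")
    if l1 < 0:
        raise ValueError("l1 weight must be non-negative")
    return soft_threshold(block - grad / multiplier, l1 / multiplier)
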