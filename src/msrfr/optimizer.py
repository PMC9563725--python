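"""Alternating prox-linear optimization with automatic rank estimation.

The fitting strategy has two loops.  The inner loop (`fit_fixed_ranks`)
holds the block ranks fixed and cycles prox-linear updates over the
blocks — mRNA-side blocks first (WYS, then each WYk), then miRNA-side
blocks (WXS, then each WXk) — until the relative objective change drops
below ``epsilon``.  The outer loop (`fit`) starts every rank at the
upper bound RU, and after each inner convergence checks the numerical
rank of every block: any scope whose loading pair is rank-deficient has
its rank decremented by one (down to zero, which eliminates the scope)
and the problem is re-solved, warm-started from the previous solution
with its least important component dropped.  At termination all
surviving blocks are full rank, so each column/row pair is a genuine,
linearly independent rank-one regulatory module.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .model import (
    Hyperparameters,
    ModelParameters,
    gram_cache,
    grad_g_cohort,
    grad_g_shared,
    grad_h_cohort,
    grad_h_shared,
    objective,
    prox_update_block,
    step_multipliers,
)

__all__ = [
    "FitConfig",
    "FitResult",
    "initialize",
    "fit_fixed_ranks",
    "numeric_rank",
    "fit",
]


@dataclass(frozen=True)
class FitConfig:
    """Optimization settings.

    rank_upper : RU, the starting (and maximal) rank of every block.
    epsilon : relative-objective stopping tolerance of the inner loop.
    max_iter : inner-iteration cap; hitting it sets converged=False.
    init_scale : sd of the Gaussian random initialization.
    rank_tolerance : relative singular-value cutoff for the rank check.
    warm_start : restart a rank-reduced problem from the truncated
        previous solution instead of a fresh random draw.
    n_init : random initializations tried for the first solve; the one
        reaching the lowest objective is kept.  The problem is
        non-convex, and the poorer basins (e.g. a shared module
        captured by every cohort block, paying its penalty K times)
        have visibly higher objectives, so selecting on the objective
        is both cheap and effective.
    multiplier_rule : "bound" (Lipschitz upper bound, guarantees
        descent) or "printed" (cross-term product form).
    """

    rank_upper: int = 10
    epsilon: float = 1e-4
    max_iter: int = 1000
    seed: int = 0
    init_scale: float = 0.1
    rank_tolerance: float = 0.25
    warm_start: bool = True
    n_init: int = 5
    multiplier_rule: str = "bound"

    def __post_init__(self) -> None:
        if self.rank_upper < 1:
            raise ValueError("rank_upper must be >= 1")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.n_init < 1:
            raise ValueError("n_init must be >= 1")
        if self.init_scale < 0:
            raise ValueError("init_scale must be non-negative")


@dataclass
class FitResult:
    """Outcome of the full rank-estimating fit."""

    params: ModelParameters
    ranks: tuple[int, list[int]]  # (Rs, [R1..RK])
    objective_trace: list[float]
    trace_segments: list[list[float]]  # one inner run per segment
    converged: bool
    n_outer_restarts: int

    @property
    def rank_total(self) -> int:
        rs, rk = self.ranks
        return rs + sum(rk)

    def save(self, directory: str | Path, extra_manifest: dict | None = None) -> None:
        """Parameter TSVs + trace CSV + JSON manifest."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        p = self.params
        np.savetxt(directory / "WXS.tsv", p.WXS, delimiter="\t")
        np.savetxt(directory / "WYS.tsv", p.WYS, delimiter="\t")
        for k in range(p.K):
            np.savetxt(directory / f"WX_{k}.tsv", p.WXk[k], delimiter="\t")
            np.savetxt(directory / f"WY_{k}.tsv", p.WYk[k], delimiter="\t")
        with open(directory / "trace.csv", "w") as fh:
            fh.write("segment,iteration,objective\n")
            for s, seg in enumerate(self.trace_segments):
                for i, f in enumerate(seg):
                    fh.write(f"{s},{i},{f!r}\n")
        manifest = {
            "K": p.K,
            "D": p.D,
            "T": p.T,
            "Rs": self.ranks[0],
            "Rk": self.ranks[1],
            "rank_total": self.rank_total,
            "converged": self.converged,
            "n_outer_restarts": self.n_outer_restarts,
        }
        if extra_manifest:
            manifest.update(extra_manifest)
        (directory / "fit_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n"
        )


def initialize(data, ranks: tuple[int, list[int]], config: FitConfig) -> ModelParameters:
    """Seeded iid N(0, init_scale^2) draw for every block."""
    if hasattr(data, "D"):
        D, T, K = data.D, data.T, data.K
    else:
        Xs, Ys = data
        D, T, K = Xs[0].shape[1], Ys[0].shape[1], len(Xs)
    rs, rk = ranks
    if len(rk) != K:
        raise ValueError("need one cohort rank per cohort")
    upper = min(D, T)
    for r in (rs, *rk):
        if r < 0 or r > upper:
            raise ValueError(f"rank {r} outside [0, min(D, T)] = [0, {upper}]")
    rng = np.random.default_rng(config.seed)
    s = config.init_scale
    return ModelParameters(
        WXS=s * rng.standard_normal((D, rs)),
        WXk=[s * rng.standard_normal((D, r)) for r in rk],
        WYS=s * rng.standard_normal((rs, T)),
        WYk=[s * rng.standard_normal((r, T)) for r in rk],
    )


def fit_fixed_ranks(
    data,
    hp: Hyperparameters,
    ranks: tuple[int, list[int]],
    config: FitConfig,
    init_params: ModelParameters | None = None,
) -> tuple[ModelParameters, list[float], bool]:
    """Solve the penalized problem at fixed ranks by cyclic prox-linear updates.

    Returns (params, objective trace including the initial value,
    converged flag).  The trace is non-increasing: every block update
    uses a step multiplier that dominates the blockwise Lipschitz
    constant, so each soft-thresholded gradient step is a descent step.
    """
    params = init_params.copy() if init_params is not None else initialize(data, ranks, config)
    cache = gram_cache(data)
    xtx_norms = [float(np.linalg.norm(m)) for m in cache[0]]

    f = objective(params, data, hp)
    trace = [f]
    converged = False
    for _ in range(config.max_iter):
        # mRNA-side blocks first, then miRNA-side, sequentially on the
        # current state so each step sees the freshest other blocks.
        if params.Rs > 0:
            mult = step_multipliers(
                params, data, hp, config.multiplier_rule, xtx_norms, cache[0]
            )
            g = grad_g_shared(params, data, hp, cache)
            params.WYS = prox_update_block(params.WYS, g, mult.beta_s, hp.lambda3)
        for k in range(params.K):
            if params.Rk[k] == 0:
                continue
            mult = step_multipliers(
                params, data, hp, config.multiplier_rule, xtx_norms, cache[0]
            )
            g = grad_g_cohort(k, params, data, hp, cache)
            params.WYk[k] = prox_update_block(params.WYk[k], g, mult.beta_k[k], hp.lambda3)
        if params.Rs > 0:
            mult = step_multipliers(
                params, data, hp, config.multiplier_rule, xtx_norms, cache[0]
            )
            g = grad_h_shared(params, data, hp, cache)
            params.WXS = prox_update_block(params.WXS, g, mult.alpha_s, hp.lambda1)
        for k in range(params.K):
            if params.Rk[k] == 0:
                continue
            mult = step_multipliers(
                params, data, hp, config.multiplier_rule, xtx_norms, cache[0]
            )
            g = grad_h_cohort(k, params, data, hp, cache)
            params.WXk[k] = prox_update_block(params.WXk[k], g, mult.alpha_k[k], hp.lambda1)

        f_new = objective(params, data, hp)
        trace.append(f_new)
        if not math.isfinite(f_new):
            raise RuntimeError(
                "objective became non-finite; state: "
                f"ranks={(params.Rs, params.Rk)}, iteration={len(trace) - 1}, "
                f"hyperparameters={hp}"
            )
        if abs(f_new - f) / max(f, 1e-300) < config.epsilon:
            converged = True
            break
        f = f_new
    return params, trace, converged


def numeric_rank(block: np.ndarray, rank_tolerance: float) -> int:
    """Singular values above ``rank_tolerance`` times the largest one."""
    block = np.atleast_2d(np.asarray(block, dtype=float))
    if block.size == 0 or not np.any(block):
        return 0
    sv = np.linalg.svd(block, compute_uv=False)
    return int(np.sum(sv > rank_tolerance * sv[0]))


def _truncate_block(wx: np.ndarray, wy: np.ndarray, new_rank: int):
    """Keep the ``new_rank`` components with largest importance ||wx_r||*||wy_r||."""
    imp = np.linalg.norm(wx, axis=0) * np.linalg.norm(wy, axis=1)
    keep = np.sort(np.argsort(-imp)[:new_rank])
    return wx[:, keep], wy[keep, :]


def fit(data, hp: Hyperparameters, config: FitConfig) -> FitResult:
    """Full fit: start all ranks at RU, shrink rank-deficient blocks, re-solve.

    A scope i in {shared, 1..K} is deficient when
    min(rank(WXi), rank(WYi)) < Ri; all deficient scopes are decremented
    in the same restart.  The total rank strictly decreases every
    restart, so at most RU*(K+1) restarts occur.
    """
    if hasattr(data, "K"):
        K = data.K
    else:
        K = len(data[0])
    ranks: tuple[int, list[int]] = (config.rank_upper, [config.rank_upper] * K)
    params: ModelParameters | None = None
    segments: list[list[float]] = []
    n_restarts = 0
    max_restarts = config.rank_upper * (K + 1)

    while True:
        if params is None and config.n_init > 1:
            # best-of-n_init random starts for the opening solve
            best = None
            for j in range(config.n_init):
                child = int(
                    np.random.SeedSequence([config.seed, j]).generate_state(1)[0] % (2**31)
                )
                cand = fit_fixed_ranks(data, hp, ranks, replace(config, seed=child))
                if best is None or cand[1][-1] < best[1][-1]:
                    best = cand
            params, trace, converged = best
        else:
            params, trace, converged = fit_fixed_ranks(data, hp, ranks, config, params)
        segments.append(trace)

        block_ranks = [min(numeric_rank(params.WXS, config.rank_tolerance),
                           numeric_rank(params.WYS, config.rank_tolerance))]
        block_ranks += [
            min(numeric_rank(params.WXk[k], config.rank_tolerance),
                numeric_rank(params.WYk[k], config.rank_tolerance))
            for k in range(K)
        ]
        current = [ranks[0], *ranks[1]]
        new = [r - 1 if br < r else r for r, br in zip(current, block_ranks)]
        if new == current:
            break
        n_restarts += 1
        if n_restarts > max_restarts:
            raise RuntimeError("rank-reduction loop failed to terminate")
        ranks = (new[0], new[1:])
        if config.warm_start:
            wxs, wys = _truncate_block(params.WXS, params.WYS, ranks[0])
            wxk, wyk = [], []
            for k in range(K):
                a, b = _truncate_block(params.WXk[k], params.WYk[k], ranks[1][k])
                wxk.append(a)
                wyk.append(b)
            params = ModelParameters(wxs, wxk, wys, wyk)
        else:
            params = initialize(data, ranks, replace(config, seed=config.seed + n_restarts))

    flat = [f for seg in segments for f in seg]
    return FitResult(
        params=params,
        ranks=ranks,
        objective_trace=flat,
        trace_segments=segments,
        converged=converged,
        n_outer_restarts=n_restarts,
    )
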