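"""Turn fitted loading blocks into ranked rank-one regulatory modules.

Each scope's coefficient block WX @ WY (with WX of shape (D, R), WY of
shape (R, T)) is a sum of R rank-one matrices.  Normalizing WX's columns
and WY's rows to unit norm and collecting their norms into diagonal
matrices DX and DY gives W = W~X DX DY W~Y; the product DX[r] * DY[r] is
the importance weight of module r.  A feature belongs to a module when
the magnitude of its unit-norm weight exceeds 2 / sqrt(#features on
that side).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ModuleDecomposition",
    "RegulatoryModule",
    "decompose",
    "select_features",
    "selection_threshold",
    "extract_modules",
    "modules_to_frame",
    "save_modules",
]

TISSUE_SCOPE = "tissue"


@dataclass
class ModuleDecomposition:
    """Unit-norm factorization W ~= WX_tilde @ diag(dx) @ diag(dy) @ WY_tilde."""

    scope: str
    WX_tilde: np.ndarray  # (D, R), unit-norm columns
    WY_tilde: np.ndarray  # (R, T), unit-norm rows
    dx: np.ndarray  # (R,), non-negative
    dy: np.ndarray  # (R,), non-negative

    @property
    def importance(self) -> np.ndarray:
        return self.dx * self.dy

    def reconstruct(self) -> np.ndarray:
        return (self.WX_tilde * (self.dx * self.dy)) @ self.WY_tilde


@dataclass
class RegulatoryModule:
    """One rank-one miRNA->mRNA regulatory module."""

    scope: str  # TISSUE_SCOPE or a cohort label
    rank_index: int  # 1 = most important within its scope
    importance: float
    mirna_weights: np.ndarray  # unit norm, length D
    mrna_weights: np.ndarray  # unit norm, length T
    mirna_ids: list[str] = field(repr=False, default=None)
    mrna_ids: list[str] = field(repr=False, default=None)
    selected_mirnas: list[str] = None
    selected_mrnas: list[str] = None


def decompose(WX: np.ndarray, WY: np.ndarray, scope: str = TISSUE_SCOPE) -> ModuleDecomposition:
    """Normalize one scope's block pair into sorted unit-norm modules.

    Modules are sorted by decreasing importance dx*dy.  The sign of each
    pair is fixed so the largest-magnitude miRNA weight is positive (the
    factorization is sign-ambiguous; flipping both vectors changes
    nothing).  Components with a zero-norm vector on either side carry
    no signal and are dropped with a warning.
    """
    WX = np.atleast_2d(np.asarray(WX, dtype=float))
    WY = np.atleast_2d(np.asarray(WY, dtype=float))
    if WX.shape[1] != WY.shape[0]:
        raise ValueError("WX and WY rank mismatch")
    dx = np.linalg.norm(WX, axis=0)
    dy = np.linalg.norm(WY, axis=1)
    keep = (dx > 0) & (dy > 0)
    if not keep.all():
        warnings.warn(
            f"scope {scope}: dropped {int((~keep).sum())} zero-norm module(s)",
            UserWarning,
            stacklevel=2,
        )
    WX, WY, dx, dy = WX[:, keep], WY[keep, :], dx[keep], dy[keep]
    WXn = WX / dx if WX.size else WX
    WYn = WY / dy[:, None] if WY.size else WY
    # deterministic sign: largest |entry| of each miRNA vector positive
    for r in range(WXn.shape[1]):
        i = int(np.argmax(np.abs(WXn[:, r])))
        if WXn[i, r] < 0:
            WXn[:, r] = -WXn[:, r]
            WYn[r, :] = -WYn[r, :]
    order = np.argsort(-(dx * dy), kind="stable")
    return ModuleDecomposition(scope, WXn[:, order], WYn[order, :], dx[order], dy[order])


def selection_threshold(n_features: int) -> float:
    """2 / sqrt(total number of features on that side)."""
    return 2.0 / np.sqrt(n_features)


def select_features(weights: np.ndarray, feature_ids: list[str] | None = None) -> list:
    """Features whose |unit-norm weight| strictly exceeds 2/sqrt(n)."""
    weights = np.asarray(weights, dtype=float)
    idx = np.flatnonzero(np.abs(weights) > selection_threshold(weights.size))
    if feature_ids is None:
        return idx.tolist()
    return [feature_ids[i] for i in idx]


def extract_modules(
    fit_result,
    mirna_ids: list[str] | None = None,
    mrna_ids: list[str] | None = None,
    cohort_names: list[str] | None = None,
) -> list[RegulatoryModule]:
    """All regulatory modules of a fit, per scope, ranked by importance.

    ``fit_result`` may be a FitResult or a bare ModelParameters.  The
    number of modules per scope equals the scope's final rank.
    """
    params = getattr(fit_result, "params", fit_result)
    D, T = params.D, params.T
    mirna_ids = list(mirna_ids) if mirna_ids is not None else [f"mir_{i}" for i in range(D)]
    mrna_ids = list(mrna_ids) if mrna_ids is not None else [f"gene_{j}" for j in range(T)]
    if cohort_names is None:
        cohort_names = [f"cohort_{k}" for k in range(params.K)]

    scopes = [(TISSUE_SCOPE, params.WXS, params.WYS)]
    scopes += [
        (cohort_names[k], params.WXk[k], params.WYk[k]) for k in range(params.K)
    ]
    out: list[RegulatoryModule] = []
    for scope, WX, WY in scopes:
        dec = decompose(WX, WY, scope)
        for r in range(dec.WX_tilde.shape[1]):
            mir_w = dec.WX_tilde[:, r]
            mrna_w = dec.WY_tilde[r, :]
            out.append(
                RegulatoryModule(
                    scope=scope,
                    rank_index=r + 1,
                    importance=float(dec.importance[r]),
                    mirna_weights=mir_w,
                    mrna_weights=mrna_w,
                    mirna_ids=mirna_ids,
                    mrna_ids=mrna_ids,
                    selected_mirnas=select_features(mir_w, mirna_ids),
                    selected_mrnas=select_features(mrna_w, mrna_ids),
                )
            )
    return out


def modules_to_frame(modules: list[RegulatoryModule]) -> pd.DataFrame:
    """Long-format table: one row per (module, side, feature)."""
    rows = []
    for m in modules:
        for side, ids, w, sel in (
            ("miRNA", m.mirna_ids, m.mirna_weights, set(m.selected_mirnas)),
            ("mRNA", m.mrna_ids, m.mrna_weights, set(m.selected_mrnas)),
        ):
            for fid, weight in zip(ids, w):
                rows.append(
                    {
                        "scope": m.scope,
                        "rank_index": m.rank_index,
                        "side": side,
                        "feature": fid,
                        "weight": float(weight),
                        "selected": fid in sel,
                    }
                )
    return pd.DataFrame(rows)


def save_modules(modules: list[RegulatoryModule], directory: str | Path) -> None:
    """One weights TSV per scope plus a JSON summary."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    frame = modules_to_frame(modules)
    for scope, sub in frame.groupby("scope", sort=False):
        sub.to_csv(directory / f"modules_{scope}.tsv", sep="\t", index=False)
    summary = [
        {
            "scope": m.scope,
            "rank_index": m.rank_index,
            "importance": m.importance,
            "n_selected_mirnas": len(m.selected_mirnas),
            "n_selected_mrnas": len(m.selected_mrnas),
            "selected_mirnas": m.selected_mirnas,
            "selected_mrnas": m.selected_mrnas,
        }
        for m in modules
    ]
    (directory / "modules_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
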