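"""Kennard-Stone calibration/prediction partitioning and outlier screening."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .plsmodel import fit_pls, predict_pls

__all__ = ["SplitResult", "kennard_stone", "screen_outliers"]


@dataclass(frozen=True)
class SplitResult:
    """Disjoint calibration/prediction row indices plus the pick order."""

    calibration: np.ndarray
    prediction: np.ndarray
    selection_order: np.ndarray

    def __post_init__(self) -> None:
        cal = np.asarray(self.calibration, dtype=int)
        pred = np.asarray(self.prediction, dtype=int)
        order = np.asarray(self.selection_order, dtype=int)
        if np.intersect1d(cal, pred).size:
            raise ValueError("calibration and prediction sets overlap")
        if order.size != cal.size or not np.array_equal(np.sort(order), np.sort(cal)):
            raise ValueError("selection order must enumerate the calibration set")
        object.__setattr__(self, "calibration", np.sort(cal))
        object.__setattr__(self, "prediction", np.sort(pred))
        object.__setattr__(self, "selection_order", order)


def kennard_stone(X: np.ndarray, n_cal: int) -> SplitResult:
    """Max-min Euclidean-distance sample selection.

    The first two picks are the pair at maximum distance; every following
    pick maximizes its minimum distance to the already-selected set.
    Deterministic: exact ties resolve to the lowest row index (np.argmax
    convention).  Distances are computed on whatever matrix is passed in,
    so supply pre-treated spectra to make the split see the modeling
    geometry.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = X.shape[0]
    if not 2 <= n_cal <= n:
        raise ValueError(f"n_cal must be in [2, {n}], got {n_cal}")
    D = cdist(X, X)
    # farthest pair; argmax on the flattened matrix -> lowest-index tie-break
    i, j = np.unravel_index(int(np.argmax(D)), D.shape)
    order = [min(i, j), max(i, j)]
    selected = np.zeros(n, dtype=bool)
    selected[order] = True
    mindist = np.minimum(D[order[0]], D[order[1]])
    while len(order) < n_cal:
        mindist[selected] = -np.inf
        nxt = int(np.argmax(mindist))
        order.append(nxt)
        selected[nxt] = True
        mindist = np.minimum(mindist, D[nxt])
    cal = np.array(order)
    pred = np.where(~selected)[0]
    return SplitResult(calibration=cal, prediction=pred, selection_order=cal.copy())


def screen_outliers(
    X: np.ndarray,
    y: np.ndarray,
    nlv: int = 5,
    leverage_k: float = 3.0,
    resid_k: float = 2.5,
    max_frac: float = 0.1,
    max_iter: int = 2,
):
    """Leverage/residual outlier screen on a preliminary full-spectrum PLS.

    A sample is flagged when its score-space leverage exceeds
    ``leverage_k * (nlv + 1) / n`` or its absolute studentized y-residual
    exceeds ``resid_k``.  At most ``max_iter`` passes are made and never
    more than ``max_frac`` of the samples are removed (worst offenders
    first).  Returns ``(flagged_indices, diagnostics)`` where diagnostics
    maps sample index -> (leverage, studentized residual).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if nlv < 1:
        raise ValueError("nlv must be >= 1")
    if nlv >= n:
        raise ValueError("nlv must be below the sample count")
    if not 0 <= max_frac <= 0.25:
        raise ValueError("max_frac must be in [0, 0.25]")
    max_remove = int(np.floor(max_frac * n))
    flagged: list[int] = []
    diagnostics: dict[int, tuple[float, float]] = {}
    keep = np.arange(n)
    for _ in range(max_iter):
        if keep.size <= nlv + 1 or len(flagged) >= max_remove:
            break
        nlv_eff = min(nlv, keep.size - 2, X.shape[1])
        model = fit_pls(X[keep], y[keep], nlv_eff)
        T = model.scores
        m = keep.size
        H = T @ np.linalg.solve(T.T @ T, T.T)
        lev = 1.0 / m + np.diag(H)
        resid = y[keep] - predict_pls(model, X[keep])
        dof = max(m - nlv_eff - 1, 1)
        s = np.sqrt(np.sum(resid**2) / dof)
        with np.errstate(divide="ignore", invalid="ignore"):
            stud = np.where(s > 0, resid / (s * np.sqrt(np.clip(1 - lev, 1e-12, None))), 0.0)
        lev_cut = leverage_k * (nlv_eff + 1) / m
        bad = (lev > lev_cut) | (np.abs(stud) > resid_k)
        for local, idx in enumerate(keep):
            diagnostics[int(idx)] = (float(lev[local]), float(stud[local]))
        if not bad.any():
            break
        # worst first, respecting the removal budget
        severity = np.maximum(lev / lev_cut, np.abs(stud) / resid_k)
        cand = keep[bad][np.argsort(-severity[bad], kind="stable")]
        room = max_remove - len(flagged)
        newly = [int(i) for i in cand[:room]]
        if not newly:
            break
        flagged.extend(newly)
        keep = np.setdiff1d(keep, np.array(newly, dtype=int))
    return np.array(sorted(flagged), dtype=int), diagnostics
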