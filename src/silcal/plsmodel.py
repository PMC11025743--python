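"""Single-response PLS regression (NIPALS), cross-validation, nlv choice.

The response is always mean-centered internally, and X is column-centered
inside the model even when the pre-treatment pipeline did not mean-center
-- the NIPALS convention -- so reported pipeline labels stay honest about
what was applied to the spectra themselves.

Cross-validation follows the 10%-segment convention: the rows are randomly
partitioned (seeded) into ``ceil(n / ceil(0.1 n))`` disjoint segments, each
row held out exactly once, and any pre-treatment fit state plus the
centering constants are re-estimated inside every training fold.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["PLSModel", "CVResult", "fit_pls", "predict_pls", "cross_validate", "choose_nlv", "make_segments"]

_RANK_TOL = 1e-10


@dataclass
class PLSModel:
    """Fitted latent-variable regression.

    ``regression_vector`` lives on the pre-treated (and possibly
    variable-subset) scale; ``x_means``/``y_mean`` are the centering
    constants so that  yhat = y_mean + (X - x_means) @ regression_vector.
    """

    nlv: int
    weights: np.ndarray  # (p, nlv)
    loadings: np.ndarray  # (p, nlv)
    scores: np.ndarray  # (n, nlv)
    y_loadings: np.ndarray  # (nlv,)
    regression_vector: np.ndarray  # (p,)
    x_means: np.ndarray
    y_mean: float
    selected_vars: np.ndarray | None = None  # indices into the full variable axis

    def predict(self, Xnew: np.ndarray) -> np.ndarray:
        return predict_pls(self, Xnew)


def fit_pls(X: np.ndarray, y: np.ndarray, nlv: int, selected_vars=None) -> PLSModel:
    """Fit single-response PLS by NIPALS with per-component deflation.

    ``selected_vars`` (optional) restricts the model to those column
    indices; the stored regression vector is then dimensioned to the subset
    and predictions expect either the subset matrix or the full matrix.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    if selected_vars is not None:
        selected_vars = np.asarray(selected_vars, dtype=int)
        X = X[:, selected_vars]
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y disagree in sample count")
    if nlv < 1:
        raise ValueError("nlv must be >= 1")
    if nlv > min(n - 1, p):
        raise ValueError(f"nlv={nlv} exceeds min(n-1, n_vars)={min(n - 1, p)}")
    if np.std(y) == 0:
        raise ValueError("response has zero variance")

    x_means = X.mean(axis=0)
    y_mean = float(y.mean())
    Xd = X - x_means
    yc = y - y_mean
    scale = float(np.abs(Xd).max()) or 1.0

    W = np.zeros((p, nlv))
    P = np.zeros((p, nlv))
    T = np.zeros((n, nlv))
    q = np.zeros(nlv)
    k_eff = 0
    for k in range(nlv):
        w = Xd.T @ yc
        nw = np.linalg.norm(w)
        if nw <= _RANK_TOL * scale * max(np.linalg.norm(yc), 1.0):
            # no covariance left.  If X itself is deflated to zero the
            # requested complexity exceeds the rank; otherwise y is simply
            # orthogonal to the remaining X space and the later components
            # add nothing (a null model at k = 0).
            if np.linalg.norm(Xd) <= _RANK_TOL * scale * math.sqrt(n * p):
                raise ValueError(
                    f"requested nlv={nlv} exceeds the effective rank ({k} components)"
                )
            break
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        if tt <= (_RANK_TOL * scale) ** 2 * n:
            raise ValueError(
                f"requested nlv={nlv} exceeds the effective rank ({k} components)"
            )
        pk = Xd.T @ t / tt
        qk = float(yc @ t / tt)
        Xd = Xd - np.outer(t, pk)
        W[:, k], P[:, k], T[:, k], q[k] = w, pk, t, qk
        k_eff = k + 1

    # B = W (P'W)^{-1} q  -- the regression vector on centered data
    if k_eff == 0:
        B = np.zeros(p)
    else:
        Wk, Pk, qk_ = W[:, :k_eff], P[:, :k_eff], q[:k_eff]
        B = Wk @ np.linalg.solve(Pk.T @ Wk, qk_)
    return PLSModel(
        nlv=nlv, weights=W, loadings=P, scores=T, y_loadings=q,
        regression_vector=B, x_means=x_means, y_mean=y_mean,
        selected_vars=selected_vars,
    )


def predict_pls(model: PLSModel, Xnew: np.ndarray) -> np.ndarray:
    """yhat = y_mean + (Xnew - x_means) @ regression_vector."""
    Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
    p = model.regression_vector.size
    if Xnew.shape[1] != p:
        if model.selected_vars is not None and Xnew.shape[1] > p:
            Xnew = Xnew[:, model.selected_vars]
        else:
            raise ValueError(
                f"expected {p} variables, got {Xnew.shape[1]}"
            )
    return model.y_mean + (Xnew - model.x_means) @ model.regression_vector


@dataclass
class CVResult:
    """Per-nlv cross-validation errors and the partition that produced them."""

    rmsecv: np.ndarray  # (nlv_max,), index k -> nlv = k + 1
    r_cv: np.ndarray
    segments: list
    seed: int
    predictions: np.ndarray | None = None  # (nlv_max, n) out-of-fold

    def __post_init__(self) -> None:
        if np.any(self.rmsecv < 0):
            raise ValueError("RMSECV must be non-negative")


def make_segments(n: int, seed: int) -> list:
    """Seeded random partition into ~10% segments, each row out once."""
    seg_size = math.ceil(0.1 * n)
    n_seg = math.ceil(n / seg_size)
    order = np.random.default_rng(seed).permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(order, n_seg)]


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    nlv_max: int,
    seed: int = 0,
    *,
    pipeline=None,
    selected_vars=None,
    segments=None,
) -> CVResult:
    """Random-segment cross-validation of the pre-treat + PLS chain.

    ``pipeline`` (a PretreatmentPipeline, or None for raw spectra) is cloned
    and refitted inside every training fold; ``selected_vars`` restricts the
    model to those (post-pre-treatment) columns.  Passing ``segments``
    reuses a fixed partition, which is how the variable-selection search
    removes partition noise from subset comparisons.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n = X.shape[0]
    if n < 10:
        raise ValueError("cross-validation needs at least 10 samples")
    if segments is None:
        segments = make_segments(n, seed)
    smallest_train = n - max(len(s) for s in segments)
    if nlv_max >= smallest_train:
        raise ValueError(
            f"nlv_max={nlv_max} must be below the smallest training-fold size "
            f"({smallest_train})"
        )
    preds = np.full((nlv_max, n), np.nan)
    for seg in segments:
        mask = np.ones(n, dtype=bool)
        mask[seg] = False
        Xtr, Xte = X[mask], X[seg]
        ytr = y[mask]
        if pipeline is not None:
            pl = pipeline.clone()
            Xtr = pl.fit_transform(Xtr)
            Xte = pl.transform(Xte)
        nlv_hi = nlv_max
        for nlv in range(1, nlv_max + 1):
            try:
                model = fit_pls(Xtr, ytr, nlv, selected_vars=selected_vars)
            except ValueError:
                nlv_hi = nlv - 1
                break
            preds[nlv - 1, seg] = predict_pls(model, Xte)
        for nlv in range(nlv_hi + 1, nlv_max + 1):
            preds[nlv - 1, seg] = preds[nlv_hi - 1, seg]
    if np.isnan(preds).any():
        raise ValueError("cross-validation failed to produce predictions")
    resid = preds - y[None, :]
    rmsecv = np.sqrt(np.mean(resid**2, axis=1))
    r_cv = np.array(
        [
            np.corrcoef(y, preds[k])[0, 1] if np.std(preds[k]) > 0 else 0.0
            for k in range(nlv_max)
        ]
    )
    return CVResult(rmsecv=rmsecv, r_cv=r_cv, segments=segments, seed=seed, predictions=preds)


def choose_nlv(cv: CVResult, cap: int = 10) -> int:
    """Global RMSECV minimum subject to nlv <= cap; ties go to fewer LVs."""
    if cv.rmsecv.size == 0:
        raise ValueError("empty CV result")
    upto = cv.rmsecv[: min(cap, cv.rmsecv.size)]
    return int(np.argmin(upto)) + 1
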