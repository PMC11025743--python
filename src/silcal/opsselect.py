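"""Ordered predictor selection (OPS) for PLS wavelength selection.

Variables are ranked by an informative vector built from a PLS model with
``hops`` components -- the absolute regression vector, the absolute
column-response correlation, or (default) their elementwise product -- and
nested subsets of the ranking are scored by seeded 10%-segment
cross-validation.  Three search strategies are provided:

* ``ops_auto``   -- one pass over subset sizes window, window+increment, ...
* ``ops_feed``   -- iterate ops_auto on its own selection until the RMSECV
                    improvement falls below 2% or 10 loops have run;
* ``ops_intervals`` -- split the wavelength axis into contiguous intervals
                    (10% of the axis, at least 50 variables), run OPS per
                    interval with a per-interval hops, and pool the
                    selections.

The full spectrum is always among the evaluated candidates, so a selection
can never cross-validate worse than no selection on the same partition.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import numpy as np

from .plsmodel import choose_nlv, cross_validate, fit_pls, make_segments

__all__ = [
    "OPSConfig",
    "SelectionResult",
    "rank_variables",
    "ops_auto",
    "ops_feed",
    "ops_intervals",
    "interval_sizes",
]


@dataclass(frozen=True)
class OPSConfig:
    """Hyperparameters of the OPS searches (defaults = the standard recipe)."""

    window: int = 10
    increment: int = 5
    percent_tested: float = 1.0
    cv_fraction: float = 0.10
    feed_min_delta: float = 0.02  # relative RMSECV change ending the feed loop
    feed_max_loops: int = 10
    interval_fraction: float = 0.10
    interval_min_vars: int = 50
    hops: int | None = None  # None -> choose by cross-validation, capped at 10
    vector_kind: str = "prod"  # "reg" | "corr" | "prod"
    nlv_cap: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.window < 1 or self.increment < 1:
            raise ValueError("window and increment must be >= 1")
        if not 0 < self.cv_fraction < 1:
            raise ValueError("cv_fraction must be in (0, 1)")
        if self.interval_min_vars < self.window:
            raise ValueError("interval_min_vars must be >= window")
        if self.vector_kind not in ("reg", "corr", "prod"):
            raise ValueError(f"unknown vector_kind {self.vector_kind!r}")


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one OPS search."""

    selected_vars: np.ndarray  # original-axis order (ascending indices)
    rmsecv_path: np.ndarray  # RMSECV per evaluated candidate (auto) or loop (feed)
    chosen_nlv: int
    strategy: str
    rmsecv: float  # RMSECV of the returned selection
    rmsecv_full: float  # RMSECV of the full spectrum on the same partition
    r_cv: float

    def __post_init__(self) -> None:
        sel = np.asarray(self.selected_vars, dtype=int)
        if sel.size == 0:
            raise ValueError("selection must be non-empty")
        if np.asarray(self.rmsecv_path).size == 0:
            raise ValueError("rmsecv_path must be non-empty")
        object.__setattr__(self, "selected_vars", np.sort(sel))


def rank_variables(X: np.ndarray, y: np.ndarray, hops: int, vector_kind: str = "prod") -> np.ndarray:
    """Variables sorted by descending informativity; ties by ascending index."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    p = X.shape[1]
    need_reg = vector_kind in ("reg", "prod")
    need_corr = vector_kind in ("corr", "prod")
    info = np.ones(p)
    if need_reg:
        model = fit_pls(X, y, hops)
        info = info * np.abs(model.regression_vector)
    if need_corr:
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        sx = Xc.std(axis=0)
        sy = yc.std()
        const = sx == 0
        if const.any():
            warnings.warn(
                f"{const.sum()} constant column(s) ranked last for correlation-based OPS",
                stacklevel=2,
            )
        with np.errstate(divide="ignore", invalid="ignore"):
            corr = np.where(const, 0.0, np.abs(Xc.T @ yc) / (X.shape[0] * np.where(const, 1.0, sx) * sy))
        info = info * corr
    # collapse numerical ties (12 significant digits) so equally informative
    # variables keep their wavelength order
    scale = info.max()
    if scale > 0:
        info = np.round(info / scale, 12)
    return np.lexsort((np.arange(p), -info))


def _choose_hops(X, y, cfg: OPSConfig, segments) -> int:
    cap = min(cfg.nlv_cap, X.shape[0] - max(len(s) for s in segments) - 1, X.shape[1])
    cv = cross_validate(X, y, nlv_max=max(cap, 1), seed=cfg.seed, segments=segments)
    return choose_nlv(cv, cap=cfg.nlv_cap)


def _subset_sizes(n_vars: int, cfg: OPSConfig) -> list[int]:
    top = int(round(cfg.percent_tested * n_vars))
    sizes = list(range(cfg.window, top + 1, cfg.increment))
    if not sizes:
        sizes = [min(cfg.window, n_vars)]
    if sizes[-1] != n_vars:
        sizes.append(n_vars)  # full spectrum always evaluated
    return sizes


def ops_auto(
    X: np.ndarray,
    y: np.ndarray,
    cfg: OPSConfig = OPSConfig(),
    *,
    var_pool: np.ndarray | None = None,
    segments=None,
    strategy_label: str = "auto",
) -> SelectionResult:
    """Single-pass OPS: score nested subsets of the ranked variable order.

    ``var_pool`` restricts the search to those original-axis indices (used
    by the feed loop and the interval strategy); the returned indices are
    always on the original axis.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    pool = np.arange(X.shape[1]) if var_pool is None else np.asarray(var_pool, dtype=int)
    if pool.size < cfg.window:
        raise ValueError(
            f"window={cfg.window} exceeds the available {pool.size} variables"
        )
    if segments is None:
        segments = make_segments(X.shape[0], cfg.seed)
    Xp = X[:, pool]
    hops = cfg.hops if cfg.hops is not None else _choose_hops(Xp, y, cfg, segments)
    hops = min(hops, Xp.shape[1], X.shape[0] - 2)
    order = pool[rank_variables(Xp, y, hops, cfg.vector_kind)]

    best = None  # (rmsecv, size, selection, nlv)
    path = []
    for size in _subset_sizes(pool.size, cfg):
        sel = np.sort(order[:size])
        cv = cross_validate(
            X, y, nlv_max=_nlv_max_for(size, X.shape[0], segments, cfg),
            seed=cfg.seed, selected_vars=sel, segments=segments,
        )
        nlv = choose_nlv(cv, cap=cfg.nlv_cap)
        rm = float(cv.rmsecv[nlv - 1])
        path.append(rm)
        if best is None or rm < best[0] - 1e-15:
            best = (rm, size, sel, nlv, float(cv.r_cv[nlv - 1]))
    rmsecv_full = path[-1]
    rm, size, sel, nlv, rcv = best
    return SelectionResult(
        selected_vars=sel, rmsecv_path=np.array(path), chosen_nlv=nlv,
        strategy=strategy_label, rmsecv=rm, rmsecv_full=rmsecv_full, r_cv=rcv,
    )


def _nlv_max_for(size: int, n: int, segments, cfg: OPSConfig) -> int:
    smallest_train = n - max(len(s) for s in segments)
    return max(1, min(cfg.nlv_cap, size, smallest_train - 1))


def ops_feed(
    X: np.ndarray,
    y: np.ndarray,
    cfg: OPSConfig = OPSConfig(),
    *,
    var_pool: np.ndarray | None = None,
    segments=None,
) -> SelectionResult:
    """Feedback OPS: iterate ops_auto on its own selection to convergence.

    Stops when the relative RMSECV change between consecutive loops falls
    below ``cfg.feed_min_delta`` (2% by default) or after
    ``cfg.feed_max_loops`` (10) iterations; the last accepted selection is
    returned together with the RMSECV path across loops.
    """
    if segments is None:
        segments = make_segments(np.atleast_2d(X).shape[0], cfg.seed)
    pool = None if var_pool is None else np.asarray(var_pool, dtype=int)
    loop_path = []
    result = None
    for _ in range(cfg.feed_max_loops):
        if pool is not None and pool.size < cfg.window:
            break
        res = ops_auto(X, y, cfg, var_pool=pool, segments=segments, strategy_label="feed")
        prev = loop_path[-1] if loop_path else None
        loop_path.append(res.rmsecv)
        result = res
        pool = res.selected_vars
        if prev is not None and abs(prev - res.rmsecv) < cfg.feed_min_delta * prev:
            break
    return replace(result, rmsecv_path=np.array(loop_path), strategy="feed")


def interval_sizes(n_vars: int, fraction: float = 0.10, min_vars: int = 50) -> list[int]:
    """Contiguous interval sizes: max(min_vars, ceil(fraction*n)) each,
    last interval absorbing the remainder.  256 vars -> [50, 50, 50, 50, 56].
    """
    m = max(min_vars, math.ceil(fraction * n_vars))
    if n_vars < m:
        raise ValueError(
            f"only {n_vars} variables: fewer than one interval of {m}; use ops_auto"
        )
    n_int = n_vars // m
    sizes = [m] * n_int
    sizes[-1] += n_vars - m * n_int
    return sizes


def ops_intervals(
    X: np.ndarray,
    y: np.ndarray,
    cfg: OPSConfig = OPSConfig(),
    *,
    use_feed: bool = False,
    segments=None,
) -> SelectionResult:
    """Interval OPS: per-interval search with its own hops, pooled selection.

    The wavelength axis is cut into contiguous intervals; each interval
    gets its own cross-validated hops and an OPS search (feed loop optional,
    same convergence criteria); the union of interval selections is then
    re-scored by cross-validated PLS.  Falls back to the full spectrum when
    the union scores worse on the same partition.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float).ravel()
    n_vars = X.shape[1]
    sizes = interval_sizes(n_vars, cfg.interval_fraction, cfg.interval_min_vars)
    if segments is None:
        segments = make_segments(X.shape[0], cfg.seed)
    icfg = replace(cfg, hops=None)  # per-interval hops, recomputed each time
    union: list[np.ndarray] = []
    start = 0
    for size in sizes:
        pool = np.arange(start, start + size)
        start += size
        search = ops_feed if use_feed else ops_auto
        res = search(X, y, icfg, var_pool=pool, segments=segments)
        # keep a proper sub-selection only; a full-interval "selection" just
        # means OPS found nothing to discard there
        union.append(res.selected_vars)
    sel = np.unique(np.concatenate(union))
    cv_sel = cross_validate(
        X, y, nlv_max=_nlv_max_for(sel.size, X.shape[0], segments, cfg),
        seed=cfg.seed, selected_vars=sel, segments=segments,
    )
    nlv_sel = choose_nlv(cv_sel, cap=cfg.nlv_cap)
    rm_sel = float(cv_sel.rmsecv[nlv_sel - 1])
    cv_full = cross_validate(
        X, y, nlv_max=_nlv_max_for(n_vars, X.shape[0], segments, cfg),
        seed=cfg.seed, segments=segments,
    )
    nlv_full = choose_nlv(cv_full, cap=cfg.nlv_cap)
    rm_full = float(cv_full.rmsecv[nlv_full - 1])
    if rm_sel <= rm_full:
        return SelectionResult(
            selected_vars=sel, rmsecv_path=np.array([rm_sel]), chosen_nlv=nlv_sel,
            strategy="intervals", rmsecv=rm_sel, rmsecv_full=rm_full,
            r_cv=float(cv_sel.r_cv[nlv_sel - 1]),
        )
    return SelectionResult(
        selected_vars=np.arange(n_vars), rmsecv_path=np.array([rm_sel, rm_full]),
        chosen_nlv=nlv_full, strategy="intervals", rmsecv=rm_full,
        rmsecv_full=rm_full, r_cv=float(cv_full.r_cv[nlv_full - 1]),
    )
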