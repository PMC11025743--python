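"""In situ ruminal degradation kinetics.

Two models are fitted to nylon-bag time series (typically hours
0, 3, 6, 12, 24, 48, 72, 96) by bounded nonlinear least squares:

* first-order asymptotic (Ørskov-McDonald), for DM/OM/CP degraded
  fractions:              Y(t) = a + b (1 - e^(-kd t))
  with a = readily soluble fraction (%), b = potentially degradable
  fraction (%), kd = fractional degradation rate of b (per h);

* Γ(2) survivor (Van Milgen), for the non-degraded NDF residue:
      R(t) = b (1 + λ t) e^(-λ t) + I
  with I = undegradable fraction (%) and λ the joint fractional rate of
  latency and degradation (per h); the degradation rate is derived from
  the Γ(2) distribution as kd = 0.59635 λ.

Degradation and residue are complementary: degradation (%) = 100 - residue.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "DegradationCurve",
    "FirstOrderParams",
    "Gamma2Params",
    "GAMMA2_KD_FACTOR",
    "first_order_degraded",
    "gamma2_residue",
    "fit_first_order",
    "fit_gamma2",
    "residue_to_degradation",
    "complement",
    "predict_curve",
    "KineticsError",
    "UnidentifiableError",
]

GAMMA2_KD_FACTOR = 0.59635  # kd = 0.59635 * lambda, Γ(2) property

_FLAT_SD = 0.5  # % -- below this the rate is unidentifiable
_MAX_ITER = 500
_FTOL = 1e-12


class KineticsError(RuntimeError):
    """Raised when a degradation-curve fit cannot be completed."""


class UnidentifiableError(KineticsError):
    """Raised when the data carry no information about the rate (flat curve)."""


@dataclass(frozen=True)
class DegradationCurve:
    """One in situ time series: either degraded fraction or residue (%)."""

    times: np.ndarray  # h, strictly increasing, >= 0
    values: np.ndarray  # %, within [-5, 105] (measurement-noise tolerance)
    kind: str  # "degraded" | "residue"

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if self.kind not in ("degraded", "residue"):
            raise ValueError(f"kind must be 'degraded' or 'residue', got {self.kind!r}")
        if t.ndim != 1 or v.shape != t.shape:
            raise ValueError("times and values must be 1-D and aligned")
        if np.any(t < 0) or np.any(np.diff(t) <= 0):
            raise ValueError("times must be non-negative and strictly increasing")
        if np.any(v < -5) or np.any(v > 105):
            raise ValueError("values outside [-5, 105] %")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class FirstOrderParams:
    """Fitted Ørskov-McDonald parameters with diagnostics."""

    a: float
    b: float
    kd: float
    rss: float = 0.0
    iterations: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.a < 0 or self.b < 0 or self.a + self.b > 100 + 1e-9 or self.kd <= 0:
            raise ValueError("need a >= 0, b >= 0, a + b <= 100, kd > 0")


@dataclass(frozen=True)
class Gamma2Params:
    """Fitted Γ(2) parameters; kd is always 0.59635 * lambda."""

    b: float
    lam: float
    i_frac: float
    rss: float = 0.0
    iterations: int = 0
    converged: bool = True

    def __post_init__(self) -> None:
        if self.b < 0 or self.i_frac < 0 or self.b + self.i_frac > 100 + 1e-9 or self.lam <= 0:
            raise ValueError("need b >= 0, I >= 0, b + I <= 100, lambda > 0")

    @property
    def kd(self) -> float:
        return GAMMA2_KD_FACTOR * self.lam


def first_order_degraded(t, a, b, kd, form: str = "standard"):
    """Ørskov-McDonald curve.  form="standard": a + b(1 - e^(-kd t)) (the
    increasing degraded fraction); form="exponential": a + b e^(-kd t)
    (a decaying residue-style curve)."""
    t = np.asarray(t, dtype=float)
    if form == "standard":
        return a + b * (1.0 - np.exp(-kd * t))
    if form == "exponential":
        return a + b * np.exp(-kd * t)
    raise ValueError(f"unknown form {form!r}")


def gamma2_residue(t, b, lam, i_frac):
    """Γ(2) survivor residue: b (1 + λt) e^(-λt) + I."""
    t = np.asarray(t, dtype=float)
    return b * (1.0 + lam * t) * np.exp(-lam * t) + i_frac


def _multistart_fit(resid_fn, starts, bounds):
    best = None
    for x0 in starts:
        x0 = np.clip(x0, bounds[0], bounds[1])
        try:
            sol = least_squares(
                resid_fn, x0, bounds=bounds, method="trf",
                ftol=_FTOL, xtol=1e-12, gtol=1e-12, max_nfev=_MAX_ITER,
            )
        except Exception:  # singular jacobian etc. from one start is fine
            continue
        rss = float(np.sum(sol.fun**2))
        if best is None or rss < best[0]:
            best = (rss, sol)
    if best is None:
        raise KineticsError("nonlinear fit failed to converge from every start")
    return best


def fit_first_order(curve: DegradationCurve, form: str = "standard") -> FirstOrderParams:
    """Fit the first-order asymptotic model to a degraded-fraction curve.

    Bounded least squares (a, b in [0, 100], kd in (0, 1]) from five
    deterministic starts spanning the rate bounds; the best residual sum of
    squares wins.  A flat curve (sample SD below 0.5%) is rejected as
    rate-unidentifiable.
    """
    if curve.kind != "degraded":
        raise ValueError("fit_first_order expects a degraded-fraction curve")
    t, y = curve.times, curve.values
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    if np.std(y, ddof=1) < _FLAT_SD:
        raise UnidentifiableError("flat curve: degradation rate is unidentifiable")

    a0 = float(np.clip(y[0], 0, 100))
    span = float(np.clip(abs(y[-1] - y[0]), 1.0, 100))
    starts = [(a0, span, kd0) for kd0 in (0.005, 0.02, 0.05, 0.15, 0.5)]
    bounds = (np.array([0.0, 0.0, 1e-6]), np.array([100.0, 100.0, 1.0]))

    def resid(p):
        return first_order_degraded(t, *p, form=form) - y

    rss, sol = _multistart_fit(resid, starts, bounds)
    a, b, kd = sol.x
    return FirstOrderParams(
        a=float(a), b=float(b), kd=float(kd), rss=rss,
        iterations=int(sol.nfev), converged=bool(sol.success),
    )


def fit_gamma2(curve: DegradationCurve) -> Gamma2Params:
    """Fit the Γ(2) survivor model to a residue curve.

    Bounded least squares (b, I in [0, 100], λ in (0, 1]) with the same
    five-start policy; kd is derived as 0.59635 λ, never fitted.
    """
    if curve.kind != "residue":
        raise ValueError("fit_gamma2 expects a residue curve")
    t, r = curve.times, curve.values
    if t.size < 4:
        raise ValueError("need at least 4 time points")
    if np.std(r, ddof=1) < _FLAT_SD:
        raise UnidentifiableError("flat curve: degradation rate is unidentifiable")

    i0 = float(np.clip(r.min(), 0, 100))
    b0 = float(np.clip(r[0] - i0, 1.0, 100))
    starts = [(b0, lam0, i0) for lam0 in (0.005, 0.02, 0.05, 0.15, 0.5)]
    bounds = (np.array([0.0, 1e-6, 0.0]), np.array([100.0, 1.0, 100.0]))

    def resid(p):
        return gamma2_residue(t, *p) - r

    rss, sol = _multistart_fit(resid, starts, bounds)
    b, lam, i_frac = sol.x
    return Gamma2Params(
        b=float(b), lam=float(lam), i_frac=float(i_frac), rss=rss,
        iterations=int(sol.nfev), converged=bool(sol.success),
    )


def complement(curve: DegradationCurve) -> DegradationCurve:
    """Flip between residue and degraded scales: values -> 100 - values."""
    other = "degraded" if curve.kind == "residue" else "residue"
    return DegradationCurve(times=curve.times, values=100.0 - curve.values, kind=other)


def residue_to_degradation(curve: DegradationCurve) -> DegradationCurve:
    """Degradation (%) = 100 - residue; requires a residue-kind curve."""
    if curve.kind != "residue":
        raise ValueError("curve is already on the degraded scale")
    return complement(curve)


def predict_curve(params, times) -> np.ndarray:
    """Closed-form model evaluation at the given times (h)."""
    t = np.asarray(times, dtype=float)
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    if isinstance(params, FirstOrderParams):
        return first_order_degraded(t, params.a, params.b, params.kd)
    if isinstance(params, Gamma2Params):
        return gamma2_residue(t, params.b, params.lam, params.i_frac)
    raise TypeError(f"unsupported parameter type {type(params).__name__}")
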