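"""Model-evaluation statistics for calibration studies.

RMSE and Pearson correlation per phase (calibration / cross-validation /
prediction), Lin's concordance correlation coefficient, the MSEP
decomposition into squared bias (SB), magnitude of random fluctuation
(MaF) and model random fluctuation (MoF), and the joint test of the
observed-on-predicted regression having intercept 0 and slope 1.

All variances, covariances and SDs here use the population (n) denominator;
Pearson's r is denominator-invariant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "MSEPDecomposition",
    "EquivalenceTestResult",
    "error_metrics",
    "ccc",
    "msep_decompose",
    "equivalence_test",
    "build_report",
]

_DEGENERATE_TOL = 1e-10


def _check_pair(obs, pred, min_n=2):
    obs = np.asarray(obs, dtype=float).ravel()
    pred = np.asarray(pred, dtype=float).ravel()
    if obs.size != pred.size:
        raise ValueError("observed and predicted lengths differ")
    if obs.size < min_n:
        raise ValueError(f"need at least {min_n} observations")
    if not (np.all(np.isfinite(obs)) and np.all(np.isfinite(pred))):
        raise ValueError("non-finite values in observed/predicted")
    return obs, pred


def error_metrics(obs, pred) -> tuple[float, float]:
    """(RMSE, Pearson r).  r is NaN-flagged when either vector is constant."""
    obs, pred = _check_pair(obs, pred)
    rmse = float(np.sqrt(np.mean((obs - pred) ** 2)))
    if np.std(obs) == 0 or np.std(pred) == 0:
        return rmse, float("nan")
    return rmse, float(np.corrcoef(obs, pred)[0, 1])


def ccc(obs, pred) -> float:
    """Lin's concordance correlation coefficient (population moments).

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (xbar - ybar)^2).  Returns NaN when
    both vectors are constant (agreement undefined).
    """
    obs, pred = _check_pair(obs, pred)
    sx2 = float(np.var(pred))
    sy2 = float(np.var(obs))
    mdiff = float(pred.mean() - obs.mean())
    denom = sx2 + sy2 + mdiff**2
    if denom == 0:
        return float("nan")
    sxy = float(np.mean((pred - pred.mean()) * (obs - obs.mean())))
    return 2.0 * sxy / denom


@dataclass(frozen=True)
class MSEPDecomposition:
    """MSEP = SB + MaF + MoF, all in squared property units."""

    msep: float
    sb: float
    maf: float
    mof: float
    n: int
    s_x: float  # population SD of predicted
    s_y: float  # population SD of observed
    r: float

    def __post_init__(self) -> None:
        for name in ("msep", "sb", "maf", "mof"):
            if getattr(self, name) < -1e-12:
                raise ValueError(f"{name} must be non-negative")
        if abs(self.msep - (self.sb + self.maf + self.mof)) > 1e-8 * max(self.msep, 1.0):
            raise ValueError("decomposition does not add up")


def msep_decompose(obs, pred) -> MSEPDecomposition:
    """Decompose the mean squared error of prediction.

    SB  = (mean(pred) - mean(obs))^2          -- central-tendency bias
    MaF = (s_x - s_y)^2                       -- dispersion mismatch
    MoF = 2 s_x s_y (1 - r)                   -- residual model error
    with population SDs; MSEP = mean((pred - obs)^2) = SB + MaF + MoF.
    """
    obs, pred = _check_pair(obs, pred)
    n = obs.size
    msep = float(np.mean((pred - obs) ** 2))
    sb = float((pred.mean() - obs.mean()) ** 2)
    s_x = float(np.std(pred))
    s_y = float(np.std(obs))
    maf = (s_x - s_y) ** 2
    if s_x == 0 or s_y == 0:
        r = 0.0  # correlation undefined; the covariance (hence MoF term) is 0
        mof = msep - sb - maf
    else:
        r = float(np.corrcoef(obs, pred)[0, 1])
        mof = 2.0 * s_x * s_y * (1.0 - r)
    return MSEPDecomposition(msep=msep, sb=sb, maf=max(maf, 0.0), mof=max(mof, 0.0),
                             n=n, s_x=s_x, s_y=s_y, r=r)


@dataclass(frozen=True)
class EquivalenceTestResult:
    """Joint test of intercept 0 / slope 1 for observed = f(predicted)."""

    beta0: float
    beta1: float
    se0: float
    se1: float
    p_joint: float
    alpha: float
    reject: bool
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.se0 < 0 or self.se1 < 0:
            raise ValueError("standard errors must be non-negative")
        if not 0 <= self.p_joint <= 1:
            raise ValueError("p-value outside [0, 1]")


def equivalence_test(obs, pred, alpha: float = 0.05) -> EquivalenceTestResult:
    """OLS of observed on predicted with the joint F-test of (β0, β1) = (0, 1).

    The F statistic has (2, n-2) degrees of freedom.  Degenerate perfect
    fits are handled per contract: zero residual variance with exactly
    (0, 1) is reported as equivalent ("degenerate" flag, p = 1); zero
    residual variance along any other line rejects with p = 0.
    """
    obs, pred = _check_pair(obs, pred, min_n=3)
    if np.std(pred) == 0:
        raise ValueError("predicted values are constant; regression undefined")
    design = sm.add_constant(pred)
    fit = sm.OLS(obs, design).fit()
    beta0, beta1 = (float(v) for v in fit.params)
    scale = max(float(np.mean(obs**2)), 1.0)
    if fit.ssr <= _DEGENERATE_TOL * scale * obs.size:
        exact_identity = abs(beta0) < 1e-8 and abs(beta1 - 1) < 1e-8
        return EquivalenceTestResult(
            beta0=beta0, beta1=beta1, se0=0.0, se1=0.0,
            p_joint=1.0 if exact_identity else 0.0, alpha=alpha,
            reject=not exact_identity, degenerate=True,
        )
    se0, se1 = (float(v) for v in fit.bse)
    ftest = fit.f_test((np.eye(2), np.array([0.0, 1.0])))
    p = float(ftest.pvalue)
    return EquivalenceTestResult(
        beta0=beta0, beta1=beta1, se0=se0, se1=se1,
        p_joint=p, alpha=alpha, reject=p < alpha,
    )


REPORT_COLUMNS = [
    "property", "nvars", "nlv", "RMSE_C", "R_C", "RMSE_CV", "R_CV",
    "RMSE_P", "R_P", "R2_P", "CCC", "MSEP", "SB", "MaF", "MoF",
    "beta0", "beta1", "p_joint", "suitable",
]


def evaluate_property(
    name: str,
    *,
    nvars: int,
    nlv: int,
    obs_cal=None,
    pred_cal=None,
    rmsecv: float = float("nan"),
    r_cv: float = float("nan"),
    obs_pred=None,
    pred_pred=None,
    alpha: float = 0.05,
    suitable: bool = True,
) -> dict:
    """One report row; prediction-phase statistics only when a prediction
    set exists (degradability-style runs are evaluated by CV alone)."""
    row = {
        "property": name, "nvars": int(nvars), "nlv": int(nlv),
        "RMSE_CV": float(rmsecv), "R_CV": float(r_cv), "suitable": bool(suitable),
    }
    if obs_cal is not None:
        rmse_c, r_c = error_metrics(obs_cal, pred_cal)
        row["RMSE_C"], row["R_C"] = rmse_c, r_c
    if obs_pred is not None:
        rmse_p, r_p = error_metrics(obs_pred, pred_pred)
        dec = msep_decompose(obs_pred, pred_pred)
        eq = equivalence_test(obs_pred, pred_pred, alpha=alpha)
        row.update(
            RMSE_P=rmse_p, R_P=r_p, R2_P=r_p**2, CCC=ccc(obs_pred, pred_pred),
            MSEP=dec.msep, SB=dec.sb, MaF=dec.maf, MoF=dec.mof,
            beta0=eq.beta0, beta1=eq.beta1, p_joint=eq.p_joint,
        )
    return row


def build_report(rows: list[dict], mode: str = "split") -> pd.DataFrame:
    """Assemble per-property rows into the standard report table.

    ``mode="cv_only"`` drops the prediction-phase columns entirely (the
    layout used when the dataset is too small to split and the model is
    evaluated by cross-validation alone).
    """
    if not rows:
        raise ValueError("no report rows")
    df = pd.DataFrame(rows)
    cols = [c for c in REPORT_COLUMNS if c in df.columns]
    df = df.reindex(columns=cols)
    if mode == "cv_only":
        drop = [c for c in ("RMSE_P", "R_P", "R2_P", "MSEP", "SB", "MaF", "MoF",
                            "beta0", "beta1", "p_joint", "CCC") if c in df.columns]
        df = df.drop(columns=drop)
    return df.reset_index(drop=True)
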