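"""Spectral pre-treatments, their composition, and the RMSECV-driven search.

Ten named transforms are supported; the column-wise ones (mean centering,
autoscaling) and MSC learn statistics from the calibration rows only and
reuse them on prediction rows, the per-spectrum ones (SNV, normalize,
baseline, detrend, smoothing, derivatives) are stateless.

Token spelling follows the abbreviations common in forage NIR reports:
MC, Auto, Smoth, 1Der, 2Der, MSC, Norm, Base, SNV, Detrend; pipelines are
spelled as "+"-joined tokens, e.g. "2Der + Norm".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import savgol_filter

__all__ = [
    "PretreatmentPipeline",
    "pipeline_from_tokens",
    "search_pipelines",
    "STEP_TOKENS",
]

STEP_TOKENS = {
    "mean_center": "MC",
    "autoscale": "Auto",
    "smoothing": "Smoth",
    "deriv1": "1Der",
    "deriv2": "2Der",
    "msc": "MSC",
    "normalize": "Norm",
    "baseline": "Base",
    "snv": "SNV",
    "detrend": "Detrend",
}
TOKEN_STEPS = {v: k for k, v in STEP_TOKENS.items()}

_COLUMNWISE = {"mean_center", "autoscale"}
_SCATTER = {"msc", "snv"}
_DERIVS = {"deriv1", "deriv2"}


def _sg(X: np.ndarray, window: int, polyorder: int, deriv: int, delta: float) -> np.ndarray:
    if window > X.shape[1]:
        raise ValueError(
            f"Savitzky-Golay window {window} exceeds channel count {X.shape[1]}"
        )
    # mode="interp": edge values come from the polynomial fitted to the last
    # full window -- no padding, no fabricated boundary data
    return savgol_filter(
        X, window_length=window, polyorder=polyorder, deriv=deriv,
        delta=delta, axis=1, mode="interp",
    )


@dataclass
class PretreatmentPipeline:
    """Ordered list of named spectral transforms with learned fit state.

    ``steps`` is a list of (name, params) pairs; length 1-4.  Call
    :meth:`fit_transform` on calibration spectra, then :meth:`transform` on
    prediction spectra; the latter reuses the stored statistics and never
    re-estimates anything from the new rows.
    """

    steps: list
    wavelengths: np.ndarray | None = None
    fit_state: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        norm_steps = []
        for s in self.steps:
            name, params = (s, {}) if isinstance(s, str) else (s[0], dict(s[1]))
            if name not in STEP_TOKENS:
                raise ValueError(f"unknown pre-treatment {name!r}")
            norm_steps.append((name, params))
        if not 1 <= len(norm_steps) <= 4:
            raise ValueError("pipeline length must be between 1 and 4")
        self.steps = norm_steps

    @property
    def tokens(self) -> str:
        return " + ".join(STEP_TOKENS[name] for name, _ in self.steps)

    @property
    def fitted(self) -> bool:
        return bool(self.fit_state.get("_fitted", False))

    def clone(self) -> "PretreatmentPipeline":
        return PretreatmentPipeline(
            steps=[(n, dict(p)) for n, p in self.steps], wavelengths=self.wavelengths
        )

    # -- per-step application -------------------------------------------------

    def _delta(self) -> float:
        if self.wavelengths is None:
            return 1.0
        return float(np.mean(np.diff(self.wavelengths)))

    def _axis(self, n_channels: int) -> np.ndarray:
        if self.wavelengths is None:
            return np.arange(n_channels, dtype=float)
        return np.asarray(self.wavelengths, dtype=float)

    def _apply_step(self, idx: int, name: str, params: dict, X: np.ndarray, fit: bool) -> np.ndarray:
        st = self.fit_state
        key = f"{idx}:{name}"
        if name == "mean_center":
            if fit:
                st[key] = X.mean(axis=0)
            return X - st[key]
        if name == "autoscale":
            if fit:
                mu = X.mean(axis=0)
                sd = X.std(axis=0, ddof=1) if X.shape[0] > 1 else np.ones(X.shape[1])
                sd = np.where(sd > 0, sd, 1.0)
                st[key] = (mu, sd)
            mu, sd = st[key]
            return (X - mu) / sd
        if name == "smoothing":
            return _sg(X, params.get("window", 11), params.get("polyorder", 2), 0, 1.0)
        if name == "deriv1":
            return _sg(X, params.get("window", 11), params.get("polyorder", 2), 1, self._delta())
        if name == "deriv2":
            return _sg(X, params.get("window", 11), params.get("polyorder", 2), 2, self._delta())
        if name == "msc":
            if fit:
                st[key] = X.mean(axis=0)
            ref = st[key]
            return _msc(X, ref)
        if name == "normalize":
            ordp = params.get("norm", "l2")
            if ordp == "l2":
                nrm = np.linalg.norm(X, axis=1)
            elif ordp == "l1":
                nrm = np.abs(X).sum(axis=1)
            elif ordp == "max":
                nrm = np.abs(X).max(axis=1)
            else:
                raise ValueError(f"unknown norm {ordp!r}")
            if np.any(nrm == 0):
                raise ValueError("cannot normalize an all-zero spectrum")
            return X / nrm[:, None]
        if name == "baseline":
            degree = params.get("degree", 0)
            if degree == 0:
                return X - X.min(axis=1, keepdims=True)
            ax = self._axis(X.shape[1])
            out = np.empty_like(X)
            for i, row in enumerate(X):
                coef = np.polyfit(ax, row, degree)
                out[i] = row - np.polyval(coef, ax)
            return out
        if name == "snv":
            mu = X.mean(axis=1, keepdims=True)
            sd = X.std(axis=1, ddof=1, keepdims=True)
            bad = np.where(sd.ravel() == 0)[0]
            if bad.size:
                raise ValueError(
                    f"SNV undefined for constant spectrum at row index {bad[0]}"
                )
            return (X - mu) / sd
        if name == "detrend":
            ax = self._axis(X.shape[1])
            A = np.column_stack([np.ones_like(ax), ax])
            coef, *_ = np.linalg.lstsq(A, X.T, rcond=None)
            return X - (A @ coef).T
        raise AssertionError(name)

    # -- public API -----------------------------------------------------------

    def fit_transform(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[0] == 0:
            raise ValueError("cannot fit a pipeline on an empty matrix")
        self.fit_state = {}
        for i, (name, params) in enumerate(self.steps):
            X = self._apply_step(i, name, params, X, fit=True)
        self.fit_state["_fitted"] = True
        self.fit_state["_n_channels"] = X.shape[1]
        return X

    def transform(self, Xnew: np.ndarray) -> np.ndarray:
        if not self.fitted:
            raise RuntimeError("pipeline must be fitted before transforming new samples")
        Xnew = np.atleast_2d(np.asarray(Xnew, dtype=float))
        for i, (name, params) in enumerate(self.steps):
            Xnew = self._apply_step(i, name, params, Xnew, fit=False)
        if Xnew.shape[1] != self.fit_state["_n_channels"]:
            raise ValueError("channel axis of new samples does not match the fit")
        return Xnew


def _msc(X: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Multiplicative scatter correction against a reference spectrum."""
    out = np.empty_like(X)
    A = np.column_stack([np.ones_like(ref), ref])
    for i, row in enumerate(X):
        (alpha, beta), *_ = np.linalg.lstsq(A, row, rcond=None)
        if abs(beta) < 1e-12:
            raise ValueError(f"MSC slope is zero for row index {i}")
        out[i] = (row - alpha) / beta
    return out


def pipeline_from_tokens(tokens: str, wavelengths=None, **step_params) -> PretreatmentPipeline:
    """Build a pipeline from a "+"-joined token string, e.g. "2Der + Norm"."""
    names = []
    for tok in tokens.split("+"):
        tok = tok.strip()
        if tok not in TOKEN_STEPS:
            raise ValueError(f"unknown pre-treatment token {tok!r}")
        names.append(TOKEN_STEPS[tok])
    steps = [(n, step_params.get(n, {})) for n in names]
    return PretreatmentPipeline(steps=steps, wavelengths=wavelengths)


def admissible(names: tuple[str, ...]) -> bool:
    """Combination grammar keeping the pipeline search chemically sensible.

    No repeats; at most one of {MSC, SNV}; scatter correction precedes
    derivatives; column-wise steps (MC, Auto) only terminal; detrend leads,
    or directly follows SNV or a derivative (covering the winning
    combinations seen in practice, e.g. "SNV + Detrend", "2Der + Detrend",
    "Detrend + MC").
    """
    if len(set(names)) != len(names):
        return False
    if sum(n in _SCATTER for n in names) > 1:
        return False
    for i, n in enumerate(names):
        if n in _COLUMNWISE and i != len(names) - 1:
            return False
        if n in _SCATTER and any(m in _DERIVS for m in names[:i]):
            return False
        if n == "detrend" and i > 0 and names[i - 1] not in ({"snv"} | _DERIVS):
            return False
    return True


def enumerate_pipelines(
    step_names=None, max_len: int = 4, wavelengths=None
) -> list[PretreatmentPipeline]:
    """All grammar-admissible ordered combinations up to ``max_len`` steps."""
    if step_names is None:
        step_names = list(STEP_TOKENS)
    if not step_names:
        raise ValueError("empty pre-treatment grammar")
    pipes = []
    for k in range(1, max_len + 1):
        for combo in itertools.permutations(step_names, k):
            if admissible(combo):
                pipes.append(PretreatmentPipeline(steps=list(combo), wavelengths=wavelengths))
    return pipes


def search_pipelines(
    X: np.ndarray,
    y: np.ndarray,
    *,
    wavelengths=None,
    step_names=None,
    max_len: int = 4,
    nlv_max: int = 10,
    seed: int = 0,
    include_identity: bool = True,
):
    """Exhaustive pre-treatment search scored by PLS cross-validation.

    Every admissible pipeline (plus the identity = raw spectra when
    ``include_identity``) is scored by the RMSECV at its RMSECV-optimal
    latent-variable count, on one fixed seeded 10%-segment CV partition.
    Returns ``(best_pipeline_or_None, table)`` where the table ranks all
    candidates; ``None`` means raw spectra won.  Ties break toward the
    shorter pipeline, then lexicographic token order.
    """
    import pandas as pd

    from .plsmodel import choose_nlv, cross_validate, make_segments

    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if X.shape[0] < 10:
        raise ValueError("pipeline search needs at least 10 samples")
    segments = make_segments(X.shape[0], seed)
    candidates: list[tuple[str, PretreatmentPipeline | None]] = []
    if include_identity:
        candidates.append(("(raw)", None))
    for p in enumerate_pipelines(step_names, max_len, wavelengths):
        candidates.append((p.tokens, p))

    rows = []
    for tokens, pipe in candidates:
        try:
            cv = cross_validate(
                X, y, nlv_max=nlv_max, seed=seed, pipeline=pipe, segments=segments
            )
        except (ValueError, np.linalg.LinAlgError):
            continue
        nlv = choose_nlv(cv)
        rows.append(
            {
                "pipeline": tokens,
                "n_steps": 0 if pipe is None else len(pipe.steps),
                "nlv": nlv,
                "rmsecv": cv.rmsecv[nlv - 1],
                "_pipe": pipe,
            }
        )
    if not rows:
        raise ValueError("no pipeline could be evaluated")
    table = pd.DataFrame(rows)
    # ties in RMSECV (to 1e-12) break toward fewer steps, then token order
    table["_key"] = table["rmsecv"].round(12)
    table = table.sort_values(["_key", "n_steps", "pipeline"], kind="stable").drop(columns="_key")
    best = table.iloc[0]["_pipe"]
    table = table.drop(columns="_pipe").reset_index(drop=True)
    return best, table
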