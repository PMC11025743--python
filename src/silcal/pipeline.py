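"""End-to-end calibration workflow, one property at a time.

Stage order is fixed: outlier screen -> pre-treatment search (on the
post-screen data) -> Kennard-Stone split (or CV-only mode for small
datasets) -> OPS variable selection -> final PLS at the chosen latent
count -> evaluation report.  Each property gets its own independent
dataset; a failure in one property never stops the others.  A property
whose best cross-validated correlation falls below the suitability
threshold is reported "unsuitable" instead of emitting a model.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .modeleval import build_report, evaluate_property
from .opsselect import OPSConfig, ops_auto, ops_feed, ops_intervals
from .plsmodel import choose_nlv, cross_validate, fit_pls, make_segments, predict_pls
from .preprocess import search_pipelines
from .sampling import kennard_stone, screen_outliers
from .spectra_io import ReferenceTable, SpectraSet

__all__ = ["RunConfig", "PropertyResult", "run_calibration"]


@dataclass(frozen=True)
class RunConfig:
    """All knobs of a calibration run."""

    properties: tuple[str, ...] = ()  # empty -> every reference column
    mode: str = "split"  # "split" | "cv_only"
    cal_frac: float = 0.7
    max_pipeline_len: int = 2
    pretreatment_steps: tuple[str, ...] | None = None
    ops: OPSConfig = field(default_factory=OPSConfig)
    strategies: tuple[str, ...] = ("auto",)  # subset of {"auto","feed","iops"}
    nlv_cap: int = 10
    alpha: float = 0.05
    suitability_r_cv: float = 0.5
    outlier_kwargs: dict = field(default_factory=dict)
    seed: int = 0
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("split", "cv_only"):
            raise ValueError("mode must be 'split' or 'cv_only'")
        if not 0 < self.cal_frac < 1:
            raise ValueError("cal_frac must be in (0, 1)")
        bad = set(self.strategies) - {"auto", "feed", "iops"}
        if bad:
            raise ValueError(f"unknown strategies: {sorted(bad)}")


@dataclass
class PropertyResult:
    """Per-stage artifacts for one property."""

    name: str
    outlier_flags: np.ndarray | None = None
    pipeline_tokens: str | None = None
    split: dict | None = None
    selection: dict | None = None
    model: object | None = None
    suitable: bool = True
    error: str | None = None


_SEARCHES = {"auto": ops_auto, "feed": ops_feed, "iops": ops_intervals}


def run_calibration(
    spectra: SpectraSet, refs: ReferenceTable, config: RunConfig
) -> tuple[pd.DataFrame, dict[str, PropertyResult]]:
    """Run the full workflow for every requested property.

    Returns the evaluation report (one row per property) and the per-stage
    artifacts.  With ``config.outdir`` set, the report, flags, splits and
    selections are persisted as CSV/JSON.
    """
    min_n = 15 if config.mode == "split" else 10
    if spectra.n_samples < min_n:
        raise ValueError(f"need at least {min_n} samples for mode={config.mode!r}")
    props = config.properties or refs.property_names
    rows, artifacts = [], {}
    for prop in props:
        res = PropertyResult(name=prop)
        artifacts[prop] = res
        try:
            rows.append(_run_one(spectra, refs, prop, config, res))
        except Exception as exc:  # a stage error aborts this property only
            res.error = f"{type(exc).__name__}: {exc}"
            rows.append({"property": prop, "nvars": 0, "nlv": 0,
                         "RMSE_CV": float("nan"), "R_CV": float("nan"),
                         "suitable": False})
    report = build_report(rows, mode="cv_only" if config.mode == "cv_only" else "split")
    if config.outdir is not None:
        _persist(report, artifacts, config)
    return report, artifacts


def _run_one(spectra, refs, prop, config, res: PropertyResult) -> dict:
    y_all = refs.values_for(prop)
    have = np.where(np.isfinite(y_all))[0]
    X = spectra.absorbance[have]
    y = y_all[have]
    wl = spectra.wavelengths

    # 1. outlier screen on the raw spectra (preliminary full-spectrum PLS)
    flags, _ = screen_outliers(X, y, **config.outlier_kwargs)
    res.outlier_flags = have[flags] if flags.size else np.array([], dtype=int)
    keep = np.setdiff1d(np.arange(X.shape[0]), flags)
    X, y = X[keep], y[keep]

    # 2. pre-treatment search on the post-screen data
    best_pipe, _table = search_pipelines(
        X, y, wavelengths=wl, step_names=config.pretreatment_steps,
        max_len=config.max_pipeline_len, nlv_max=config.nlv_cap, seed=config.seed,
    )
    res.pipeline_tokens = "(raw)" if best_pipe is None else best_pipe.tokens

    # 3. split (distances on the pre-treated spectra) or CV-only
    if config.mode == "split":
        if best_pipe is not None:
            geom = best_pipe.clone()
            Xg = geom.fit_transform(X)
        else:
            Xg = X
        n_cal = max(2, int(round(config.cal_frac * X.shape[0])))
        split = kennard_stone(Xg, n_cal)
        cal, pred = split.calibration, split.prediction
        res.split = {"calibration": cal.tolist(), "prediction": pred.tolist()}
    else:
        cal, pred = np.arange(X.shape[0]), np.array([], dtype=int)

    Xcal, ycal = X[cal], y[cal]
    if best_pipe is not None:
        pipe = best_pipe.clone()
        Xcal_t = pipe.fit_transform(Xcal)
    else:
        pipe = None
        Xcal_t = Xcal

    # 4. OPS selection on the pre-treated calibration matrix
    segments = make_segments(Xcal.shape[0], config.seed)
    cfg = config.ops if config.ops.seed == config.seed else \
        OPSConfig(**{**asdict(config.ops), "seed": config.seed})
    best_sel = None
    for strat in config.strategies:
        search = _SEARCHES[strat]
        try:
            sel = search(Xcal_t, ycal, cfg, segments=segments)
        except ValueError:
            continue
        if best_sel is None or sel.rmsecv < best_sel.rmsecv:
            best_sel = sel
    if best_sel is None:
        raise ValueError("no variable-selection strategy could run")
    res.selection = {
        "strategy": best_sel.strategy,
        "selected_vars": best_sel.selected_vars.tolist(),
        "rmsecv": best_sel.rmsecv,
    }

    # 5. suitability gate
    res.suitable = bool(best_sel.r_cv >= config.suitability_r_cv)
    if not res.suitable:
        return {"property": prop, "nvars": int(best_sel.selected_vars.size),
                "nlv": int(best_sel.chosen_nlv), "RMSE_CV": best_sel.rmsecv,
                "R_CV": best_sel.r_cv, "suitable": False}

    # 6. final PLS + evaluation
    model = fit_pls(Xcal_t, ycal, best_sel.chosen_nlv, selected_vars=best_sel.selected_vars)
    res.model = model
    pred_cal = predict_pls(model, Xcal_t)
    kwargs = dict(
        nvars=best_sel.selected_vars.size, nlv=best_sel.chosen_nlv,
        obs_cal=ycal, pred_cal=pred_cal,
        rmsecv=best_sel.rmsecv, r_cv=best_sel.r_cv, alpha=config.alpha,
    )
    if pred.size:
        Xp_t = pipe.transform(X[pred]) if pipe is not None else X[pred]
        kwargs.update(obs_pred=y[pred], pred_pred=predict_pls(model, Xp_t))
    return evaluate_property(prop, **kwargs)


def _persist(report: pd.DataFrame, artifacts: dict, config: RunConfig) -> None:
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report.to_csv(out / "report.csv", index=False)
    meta = {}
    for prop, res in artifacts.items():
        meta[prop] = {
            "outliers": None if res.outlier_flags is None else res.outlier_flags.tolist(),
            "pipeline": res.pipeline_tokens,
            "split": res.split,
            "selection": res.selection,
            "suitable": res.suitable,
            "error": res.error,
        }
    (out / "artifacts.json").write_text(json.dumps(meta, indent=2))
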