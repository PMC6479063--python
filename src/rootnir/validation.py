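"""Repeated hold-out validation: seeded splits, leakage-free evaluation,
chemometric accuracy metrics, aggregation and wavelength-selection frequency.

The workflow mirrors operational NIR calibration: the sample set is split
many times (default 100) into a calibration and a validation portion,
calibration and validation spectra are pre-processed *independently*, the
model (full-spectrum PLSR, or CARS-selected PLSR) is trained on calibration
only, and its predictions of the untouched validation samples are scored by

    BIAS  = mean(pred - obs)
    RMSEP = sqrt(mean((pred - obs)^2))
    SEP   = sqrt(sum((e - BIAS)^2) / (n - 1))      (bias-corrected)
    R2p   = squared Pearson correlation(pred, obs)
    RPD   = sd(obs, n-1) / SEP

so that RMSEP^2 = SEP^2 (n-1)/n + BIAS^2 and RPD * SEP = sd(obs) hold as
identities.  RPD above ~1.5-2 is usable for screening, 2-2.5 acceptable,
2.5-3 good, above 3 excellent for quantitative prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cars import CarsConfig, run_cars
from .pls import cross_validate_nlv, fit_pls, predict
from .preprocess import PreprocessSpec, apply_preprocess
from .spectra import SpectraMatrix

_SEED_MOD = 2**31 - 1


def _repeat_seed(master_seed: int, repeat: int) -> int:
    """Per-repeat seed by fixed affine offset from the master seed."""
    return (master_seed * 100_003 + 7_919 * repeat + 1) % _SEED_MOD


@dataclass
class SplitPlan:
    repeat: int
    seed: int
    cal_idx: np.ndarray
    val_idx: np.ndarray

    def __post_init__(self):
        cal, val = set(self.cal_idx.tolist()), set(self.val_idx.tolist())
        if cal & val:
            raise ValueError("calibration and validation indices overlap")


@dataclass
class MetricsReport:
    """One split's accuracy figures (validation unless suffixed _cal)."""

    nlv: int
    rmse_cal: float
    rmsep: float
    sep: float
    bias: float
    r2p: float
    rpd: float
    n_val: int
    flags: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {"nLV": self.nlv, "RMSE": self.rmse_cal, "RMSEP": self.rmsep,
                "SEP": self.sep, "BIAS": self.bias, "R2p": self.r2p,
                "RPD": self.rpd, "n_val": self.n_val}


def make_splits(n: int = 74, n_cal: int = 44, n_val: int = 30,
                repeats: int = 100, master_seed: int = 0) -> list:
    """Seeded calibration/validation split plans, reusable across model runs.

    The same plans must be fed to every model variant being compared so that
    full-spectrum and variable-selection results are evaluated on identical
    draws.
    """
    if n_cal + n_val != n:
        raise ValueError(f"n_cal + n_val = {n_cal + n_val} does not equal n = {n}")
    plans = []
    for r in range(repeats):
        seed = _repeat_seed(master_seed, r)
        perm = np.random.default_rng(seed).permutation(n)
        plans.append(SplitPlan(repeat=r, seed=seed,
                               cal_idx=np.sort(perm[:n_cal]),
                               val_idx=np.sort(perm[n_cal:])))
    return plans


def compute_metrics(observed: np.ndarray, predicted: np.ndarray,
                    nlv: int = 0, rmse_cal: float = np.nan) -> MetricsReport:
    """Validation metrics for one observed/predicted pair of vectors."""
    obs = np.asarray(observed, dtype=float).ravel()
    pred = np.asarray(predicted, dtype=float).ravel()
    if obs.size != pred.size:
        raise ValueError("observed and predicted lengths differ")
    if obs.size < 3:
        raise ValueError("need at least 3 validation samples")
    n = obs.size
    e = pred - obs
    bias = float(e.mean())
    rmsep = float(np.sqrt(np.mean(e**2)))
    sep = float(np.sqrt(np.sum((e - bias) ** 2) / (n - 1)))
    flags = []
    sd_obs = float(np.std(obs, ddof=1))
    if sd_obs == 0:
        flags.append("zero-variance observations: RPD undefined")
        rpd = np.nan
        r2p = np.nan
    elif sep == 0:
        flags.append("zero SEP (error-free or constant-offset prediction)")
        rpd = np.inf
        r2p = 1.0 if np.std(pred, ddof=1) > 0 else np.nan
    else:
        rpd = sd_obs / sep
        if np.std(pred, ddof=1) == 0:
            flags.append("constant predictions: R2p undefined")
            r2p = np.nan
        else:
            r2p = float(np.corrcoef(obs, pred)[0, 1] ** 2)
    return MetricsReport(nlv=nlv, rmse_cal=rmse_cal, rmsep=rmsep, sep=sep,
                         bias=bias, r2p=r2p, rpd=rpd, n_val=n, flags=flags)


def evaluate_split(spectra: SpectraMatrix, reference: pd.DataFrame,
                   split: SplitPlan, preprocess_spec: PreprocessSpec,
                   model: str = "full", cars_config: CarsConfig | None = None,
                   max_nlv: int = 15, folds: int = 10,
                   r2_variant: str = "pearson"):
    """Evaluate one split end to end without calibration/validation leakage.

    Calibration and validation sets are pre-processed independently (each
    with its own statistics), the model is fit on calibration only, and the
    validation spectra are only ever touched at prediction time.

    Returns ``(MetricsReport, selected_band_indices)``; the selected indices
    are all bands for ``model="full"`` and the CARS best subset for
    ``model="cars"``.
    """
    y = reference.set_index("sample_id").loc[spectra.ids, "lignin_pct"].to_numpy(float)
    cal = spectra.subset(split.cal_idx)
    val = spectra.subset(split.val_idx)
    y_cal, y_val = y[split.cal_idx], y[split.val_idx]

    try:
        cal_p = apply_preprocess(cal, preprocess_spec)
    except Exception as exc:
        raise RuntimeError(f"pre-processing failed on the calibration set: {exc}") from exc
    try:
        val_p = apply_preprocess(val, preprocess_spec)
    except Exception as exc:
        raise RuntimeError(f"pre-processing failed on the validation set: {exc}") from exc

    if model == "cars":
        cfg = cars_config or CarsConfig(seed=split.seed)
        if cfg.seed is None:
            cfg = CarsConfig(**{**cfg.__dict__, "seed": split.seed})
        trace = run_cars(cal_p.values, y_cal, cfg)
        bands = trace.best_subset
    elif model == "full":
        bands = np.arange(spectra.n_bands)
    else:
        raise ValueError(f"unknown model spec {model!r} (use 'full' or 'cars')")

    Xc, Xv = cal_p.values[:, bands], val_p.values[:, bands]
    cap = max(1, min(max_nlv, Xc.shape[0] - 2, bands.size))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        prof = cross_validate_nlv(Xc, y_cal, cap, folds=folds, seed=split.seed)
        fitted = fit_pls(Xc, y_cal, prof.chosen_nlv, band_indices=bands)
    rmse_cal = float(np.sqrt(np.mean((predict(fitted, Xc) - y_cal) ** 2)))
    pred = predict(fitted, Xv)
    report = compute_metrics(y_val, pred, nlv=fitted.n_components, rmse_cal=rmse_cal)
    if r2_variant == "ssr":
        sst = float(np.sum((y_val - y_val.mean()) ** 2))
        report.r2p = 1.0 - float(np.sum((pred - y_val) ** 2)) / sst if sst else np.nan
    return report, bands


def run_block(spectra: SpectraMatrix, reference: pd.DataFrame, splits,
              preprocess_spec: PreprocessSpec, model: str = "full",
              cars_config: CarsConfig | None = None, max_nlv: int = 15,
              folds: int = 10):
    """Evaluate every split plan; returns (reports, selected_subsets)."""
    reports, subsets = [], []
    for plan in splits:
        cfg = cars_config
        if model == "cars":
            base = cars_config or CarsConfig()
            cfg = CarsConfig(**{**base.__dict__, "seed": plan.seed})
        rep, bands = evaluate_split(spectra, reference, plan, preprocess_spec,
                                    model=model, cars_config=cfg,
                                    max_nlv=max_nlv, folds=folds)
        reports.append(rep)
        subsets.append(bands)
    return reports, subsets


def reports_frame(reports) -> pd.DataFrame:
    """Per-repeat metrics table (one row per split, columns as in reports)."""
    return pd.DataFrame([r.as_dict() for r in reports])


def aggregate_reports(reports) -> pd.DataFrame:
    """Mean and n-1 SD of each metric over repeats (fractional mean nLV ok)."""
    if len(reports) < 2:
        raise ValueError("need >= 2 reports to aggregate")
    df = reports_frame(reports).drop(columns="n_val")
    agg = pd.DataFrame({"mean": df.mean(), "sd": df.std(ddof=1)})
    agg["formatted"] = [f"{m:.2f} ± {s:.2f}" for m, s in zip(agg["mean"], agg["sd"])]
    agg.attrs["n_repeats"] = len(reports)
    return agg


def selection_frequency(best_subsets, n_bands: int) -> np.ndarray:
    """Per-band selection percentage over repeats (0-100)."""
    if not len(best_subsets):
        raise ValueError("no subsets given")
    counts = np.zeros(n_bands)
    for s in best_subsets:
        counts[np.asarray(s, dtype=int)] += 1
    return 100.0 * counts / len(best_subsets)


SURVEY_COLUMNS = ("species", "lignin_mg", "val_cal_ratio", "RPD", "R2p",
                  "RMSEP", "SEP")


def summarize_survey(records: pd.DataFrame) -> pd.DataFrame:
    """Quantile summary (min, Q25, median, Q75, max, n) per survey column.

    Missing cells are ignored column-wise; quantiles use linear interpolation
    of order statistics.  Columns with no data are omitted with a note.
    """
    rows = {}
    for col in records.columns:
        vals = pd.to_numeric(records[col], errors="coerce").dropna()
        if vals.empty:
            warnings.warn(f"survey column {col!r} has no data; omitted")
            continue
        rows[col] = {
            "min": vals.min(),
            "Q25": vals.quantile(0.25),
            "median": vals.quantile(0.5),
            "Q75": vals.quantile(0.75),
            "max": vals.max(),
            "n": int(vals.size),
        }
    if not rows:
        raise ValueError("no survey column contains data")
    return pd.DataFrame(rows).T[["min", "Q25", "median", "Q75", "max", "n"]]
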