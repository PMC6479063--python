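"""Competitive adaptive reweighted sampling (CARS) wavelength selection.

CARS wraps PLS regression in an iterative elimination loop.  At sampling run
i of N it (1) draws a Monte-Carlo subset of the calibration samples, (2) fits
a PLS model on the currently retained bands, (3) forcibly keeps only the top
ceil(r_i * p) bands by absolute regression coefficient, where the retention
fraction r_i follows an exponentially decreasing function (EDF) from 1 down
to 2/p, and (4) resamples within the survivors with probability proportional
to |coefficient| (adaptive reweighted sampling, ARS), so weakly weighted
bands drop out stochastically.  Each run's retained set is scored by
cross-validated RMSECV on the full calibration set; the subset of the
best-scoring run wins.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pls import cross_validate_nlv, fit_pls


@dataclass
class CarsConfig:
    """Knobs of the CARS loop.

    n_runs : number of sampling runs N (the EDF spans run 1..N).
    mc_ratio : fraction of calibration samples drawn (without replacement)
        for each run's coefficient fit.
    folds : inner CV folds for both the coefficient-fit nLV and the run score.
    max_nlv : ceiling on latent variables everywhere inside the loop.
    exact_size_ars : use weighted sampling *without* replacement of exactly
        the EDF-prescribed size instead of the classic draw-with-replacement
        (whose unique set may come out smaller).
    """

    n_runs: int = 50
    mc_ratio: float = 0.8
    folds: int = 10
    max_nlv: int = 15
    seed: int | None = None
    exact_size_ars: bool = False

    def __post_init__(self):
        if self.n_runs < 2:
            raise ValueError("n_runs must be >= 2")
        if not 0 < self.mc_ratio <= 1:
            raise ValueError("mc_ratio must be in (0, 1]")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass
class CarsRun:
    retained: np.ndarray       # band indices retained after this run's ARS
    ratio: float               # EDF retention fraction r_i
    rmsecv: float
    nlv: int


@dataclass
class CarsTrace:
    runs: list
    best_run: int = field(init=False)
    best_subset: np.ndarray = field(init=False)

    def __post_init__(self):
        self.best_run = _best_run_index(self.runs)
        self.best_subset = self.runs[self.best_run].retained

    def to_frame(self) -> pd.DataFrame:
        """Per-run summary (run, n_retained, ratio, RMSECV, nLV)."""
        return pd.DataFrame({
            "run": np.arange(1, len(self.runs) + 1),
            "n_retained": [r.retained.size for r in self.runs],
            "ratio": [r.ratio for r in self.runs],
            "rmsecv": [r.rmsecv for r in self.runs],
            "nlv": [r.nlv for r in self.runs],
        })


def edf_ratio(i: int, n_runs: int, p: int) -> float:
    """Exponentially decreasing retention fraction r_i = a * exp(-k * i).

    The constants a = (p/2)^(1/(N-1)) and k = ln(p/2)/(N-1) pin the endpoints:
    all p bands survive run 1 (r_1 = 1) and exactly 2 survive run N
    (r_N = 2/p).
    """
    if n_runs < 2:
        raise ValueError("n_runs must be >= 2")
    if p < 3:
        raise ValueError("need at least 3 bands")
    if not 1 <= i <= n_runs:
        raise ValueError(f"run index {i} outside 1..{n_runs}")
    a = (p / 2.0) ** (1.0 / (n_runs - 1))
    k = math.log(p / 2.0) / (n_runs - 1)
    return a * math.exp(-k * i)


def ars_sample(weights: np.ndarray, n_draw: int,
               rng: np.random.Generator, exact_size: bool = False) -> np.ndarray:
    """Adaptive reweighted sampling of band indices.

    Classic form: ``n_draw`` draws *with* replacement, probability
    proportional to weight, returning the unique indices drawn (so the result
    can be smaller than ``n_draw``).  ``exact_size`` switches to weighted
    sampling without replacement of exactly ``min(n_draw, n_positive)``.
    Zero-weight bands are never returned.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("weights must be nonnegative")
    total = w.sum()
    if total <= 0:
        raise ValueError("all ARS weights are zero")
    prob = w / total
    if exact_size:
        n_pos = int(np.sum(w > 0))
        size = min(n_draw, n_pos)
        drawn = rng.choice(w.size, size=size, replace=False, p=prob)
        return np.sort(drawn)
    drawn = rng.choice(w.size, size=n_draw, replace=True, p=prob)
    return np.unique(drawn)


def _best_run_index(runs) -> int:
    """Minimal RMSECV; ties -> fewer bands, then earlier run."""
    keys = [(r.rmsecv, r.retained.size, i) for i, r in enumerate(runs)]
    return min(keys)[2]


def select_best(trace: CarsTrace) -> np.ndarray:
    """Band subset of the best run (min RMSECV; ties -> smaller, earlier)."""
    if not trace.runs:
        raise ValueError("empty CARS trace")
    return trace.runs[_best_run_index(trace.runs)].retained


def run_cars(X: np.ndarray, y: np.ndarray, cfg: CarsConfig) -> CarsTrace:
    """Run the full CARS loop on a calibration set.

    Returns a :class:`CarsTrace` whose ``best_subset`` holds the wavelengths
    of the lowest-RMSECV run.  Deterministic under a fixed ``cfg.seed``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if p < 3:
        raise ValueError("CARS needs at least 3 bands")
    rng = np.random.default_rng(cfg.seed)
    n_mc = max(2, int(math.ceil(cfg.mc_ratio * n)))
    retained = np.arange(p)
    runs: list = []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # small-subset rank warnings inside the loop
        for i in range(1, cfg.n_runs + 1):
            mc_rows = rng.choice(n, size=min(n_mc, n), replace=False)
            Xi, yi = X[np.ix_(mc_rows, retained)], y[mc_rows]
            cap = min(cfg.max_nlv, Xi.shape[0] - 2, retained.size)
            cap = max(cap, 1)
            prof = cross_validate_nlv(Xi, yi, cap, folds=min(cfg.folds, Xi.shape[0]),
                                      seed=int(rng.integers(2**31 - 1)))
            model = fit_pls(Xi, yi, prof.chosen_nlv)
            b = np.abs(model.coef)

            keep = int(math.ceil(edf_ratio(i, cfg.n_runs, p) * p))
            keep = min(keep, retained.size)
            if keep < 2:
                warnings.warn("EDF retained set clamped at 2 bands")
                keep = 2
            top = np.argsort(b)[::-1][:keep]  # forced removal: top |b|

            weights = np.zeros(retained.size)
            weights[top] = b[top]
            if weights.sum() <= 0:
                # coefficients vanished (mean-only model): keep the forced set
                local = np.sort(top)
            else:
                # classic ARS draws as many times as there are bands in the
                # full grid, so only weakly weighted survivors drop out and
                # the EDF, not the draw count, governs the decay
                n_draw = keep if cfg.exact_size_ars else p
                local = ars_sample(weights, n_draw, rng, cfg.exact_size_ars)
            if local.size < 2:
                extra = top[~np.isin(top, local)][: 2 - local.size]
                local = np.sort(np.concatenate([local, extra]))
            new_retained = retained[np.sort(local)]

            sub = X[:, new_retained]
            cap2 = max(1, min(cfg.max_nlv, n - 2, new_retained.size))
            score = cross_validate_nlv(sub, y, cap2, folds=min(cfg.folds, n),
                                       seed=int(rng.integers(2**31 - 1)))
            runs.append(CarsRun(
                retained=new_retained,
                ratio=edf_ratio(i, cfg.n_runs, p),
                rmsecv=float(score.rmsecv_by_nlv[score.chosen_nlv - 1]),
                nlv=score.chosen_nlv,
            ))
            retained = new_retained
    return CarsTrace(runs=runs)


def cluster_bands(indices: np.ndarray, wavelengths: np.ndarray,
                  max_gap_nm: float = 10.0) -> list:
    """Group selected band indices into adjacent wavelength clusters.

    Purely a reporting aid: consecutive selected wavelengths closer than
    ``max_gap_nm`` are merged, and each cluster is summarized by its member
    indices and central wavelength.
    """
    idx = np.sort(np.asarray(indices, dtype=int))
    if idx.size == 0:
        return []
    clusters, current = [], [idx[0]]
    for j in idx[1:]:
        if wavelengths[j] - wavelengths[current[-1]] <= max_gap_nm:
            current.append(j)
        else:
            clusters.append(current)
            current = [j]
    clusters.append(current)
    return [{"indices": np.array(c),
             "center_nm": float(np.mean(wavelengths[c]))} for c in clusters]
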