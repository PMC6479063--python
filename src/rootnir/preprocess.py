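"""Spectral pre-processing: SNV, MSC, two penalized baseline correctors and
Savitzky-Golay derivatives, plus a raw passthrough.

All transforms act per spectrum (or, for MSC, relative to the mean spectrum of
the set being processed), so calibration and validation sets can — and in the
repeated-validation workflow must — be processed independently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.signal import savgol_filter
from scipy.sparse.linalg import spsolve

from .spectra import SpectraMatrix

METHODS = ("raw", "b.als", "b.irls", "msc", "snv", "d1", "d2")


@dataclass
class PreprocessSpec:
    """Named transform plus its hyper-parameters (serializable)."""

    method: str = "snv"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"unknown pre-processing method {self.method!r}; "
                             f"choose one of {METHODS}")


# ---------------------------------------------------------------------------
# scatter corrections
# ---------------------------------------------------------------------------

def snv(spectra: SpectraMatrix) -> SpectraMatrix:
    """Standard normal variate: per-spectrum centering and unit-SD scaling.

    Each row becomes (x - mean(x)) / sd(x) with the n-1 SD, removing additive
    offsets and multiplicative scatter sample by sample.
    """
    X = spectra.values
    mu = X.mean(axis=1, keepdims=True)
    sd = X.std(axis=1, ddof=1, keepdims=True)
    flat = np.where(sd[:, 0] == 0)[0]
    if flat.size:
        raise ValueError(
            f"constant spectrum (SNV undefined) for sample {spectra.ids[flat[0]]!r}"
        )
    out = spectra.copy()
    out.values = (X - mu) / sd
    return out


def msc(spectra: SpectraMatrix, reference: np.ndarray | None = None) -> SpectraMatrix:
    """Multiplicative scatter correction against a reference spectrum.

    Each spectrum is regressed on the reference (x ~ a + b*ref, OLS) and
    corrected to (x - a)/b.  When ``reference`` is omitted it defaults to the
    mean spectrum of the set being processed — which is why MSC results for
    independently processed calibration and validation sets diverge whenever
    their means differ.
    """
    X = spectra.values
    if reference is None:
        if spectra.n_samples < 2:
            raise ValueError("MSC needs >= 2 spectra to form a mean reference")
        reference = X.mean(axis=0)
    ref = np.asarray(reference, dtype=float)
    if ref.shape != (spectra.n_bands,):
        raise ValueError("MSC reference length does not match the band count")
    ref_c = ref - ref.mean()
    denom = ref_c @ ref_c
    if denom == 0:
        raise ValueError("MSC reference spectrum is constant")
    b = (X - X.mean(axis=1, keepdims=True)) @ ref_c / denom
    tiny = np.abs(b) < 1e-12
    if np.any(tiny):
        i = int(np.where(tiny)[0][0])
        raise ValueError(f"MSC slope ~ 0 for sample {spectra.ids[i]!r}")
    a = X.mean(axis=1) - b * ref.mean()
    out = spectra.copy()
    out.values = (X - a[:, None]) / b[:, None]
    return out


# ---------------------------------------------------------------------------
# baseline correctors (second-difference penalized smoothers)
# ---------------------------------------------------------------------------

def _smoother_matrix(n: int, lam: float, w: np.ndarray) -> sparse.csc_matrix:
    D = sparse.diags([1.0, -2.0, 1.0], [0, 1, 2], shape=(n - 2, n))
    return sparse.diags(w) + lam * (D.T @ D)


def baseline_als(spectrum: np.ndarray, lam: float = 1e6, p: float = 0.05,
                 max_iter: int = 10) -> np.ndarray:
    """Asymmetric-least-squares baseline removal (returns corrected spectrum).

    The baseline z minimizes  sum_i w_i (y_i - z_i)^2 + lam * sum (d2 z)^2
    with asymmetric weights w_i = p where y > z (peaks barely pull the
    baseline up) and 1-p where y < z, iterated until the weights stabilize.

    Parameters
    ----------
    lam : float
        Second-difference smoothness penalty; larger = stiffer baseline.
    p : float
        Asymmetry in (0, 1); small p lets peaks float above the baseline.
    max_iter : int
        Reweighting iterations; non-convergence warns and returns the last
        estimate.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    if not 0 < p < 1:
        raise ValueError("asymmetry p must be in (0, 1)")
    y = np.asarray(spectrum, dtype=float)
    n = y.size
    w = np.ones(n)
    z = y
    for _ in range(max_iter):
        z = spsolve(_smoother_matrix(n, lam, w).tocsc(), w * y)
        w_new = np.where(y > z, p, 1.0 - p)
        if np.array_equal(w_new, w):
            break
        w = w_new
    else:
        warnings.warn("ALS baseline did not converge; returning last estimate")
    return y - z


def baseline_irls(spectrum: np.ndarray, lam: float = 1e6, max_iter: int = 20,
                  tol: float = 1e-6) -> np.ndarray:
    """Iteratively reweighted ("restricted") penalized baseline removal.

    Like :func:`baseline_als` but with continuous robust weights: points above
    the current baseline are down-weighted by a Cauchy factor
    1 / (1 + (r / 3s)^2), s being the scale of the below-baseline residuals,
    so peak regions are progressively excluded ("restricted") from the fit.
    """
    if lam <= 0:
        raise ValueError("lam must be positive")
    y = np.asarray(spectrum, dtype=float)
    n = y.size
    w = np.ones(n)
    z = y
    for _ in range(max_iter):
        z_new = spsolve(_smoother_matrix(n, lam, w).tocsc(), w * y)
        r = y - z_new
        neg = r[r < 0]
        s = float(np.std(neg)) if neg.size else float(np.std(r))
        if s == 0:  # exact fit (flat spectrum): baseline is the data
            z = z_new
            break
        w = np.where(r > 0, 1.0 / (1.0 + (r / (3.0 * s)) ** 2), 1.0)
        if np.max(np.abs(z_new - z)) < tol * max(1.0, np.max(np.abs(y))):
            z = z_new
            break
        z = z_new
    else:
        warnings.warn("IRLS baseline did not converge; returning last estimate")
    return y - z


def _baseline_matrix(spectra: SpectraMatrix, func, **params) -> SpectraMatrix:
    out = spectra.copy()
    out.values = np.vstack([func(row, **params) for row in spectra.values])
    return out


# ---------------------------------------------------------------------------
# derivatives
# ---------------------------------------------------------------------------

def derivative(spectra: SpectraMatrix, order: int, window: int = 11,
               polyorder: int = 2) -> SpectraMatrix:
    """Savitzky-Golay derivative along the band axis (length-preserving).

    Edges are handled by polynomial extension (the filter's interpolating
    mode), so the matrix keeps its shape.  The grid step used to scale the
    derivative is the mean wavelength spacing; for grids uniform in
    wavenumber this is an approximation that is immaterial for regression,
    where the derivative acts as a linear filter.
    """
    if order not in (1, 2):
        raise ValueError("derivative order must be 1 or 2")
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if window > spectra.n_bands:
        raise ValueError(f"window {window} exceeds band count {spectra.n_bands}")
    if not window > polyorder:
        raise ValueError("window must exceed polyorder")
    if polyorder < order:
        raise ValueError("polyorder must be >= derivative order")
    delta = float(np.mean(np.diff(spectra.wavelengths)))
    out = spectra.copy()
    out.values = savgol_filter(spectra.values, window, polyorder, deriv=order,
                               delta=delta, axis=1, mode="interp")
    return out


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def apply_preprocess(spectra: SpectraMatrix, spec: PreprocessSpec) -> SpectraMatrix:
    """Apply one named transform; ``raw`` is the identity.

    The spec is recorded in the output's metadata.  The function never mixes
    information across calls: processing a calibration set and a validation
    set separately keeps them statistically independent (MSC's default mean
    reference is the mean of whichever set is passed in).
    """
    p = spec.params
    if spec.method == "raw":
        out = spectra.copy()
    elif spec.method == "snv":
        out = snv(spectra)
    elif spec.method == "msc":
        out = msc(spectra, reference=p.get("reference"))
    elif spec.method == "b.als":
        out = _baseline_matrix(spectra, baseline_als,
                               lam=p.get("lam", 1e6), p=p.get("p", 0.05),
                               max_iter=p.get("max_iter", 10))
    elif spec.method == "b.irls":
        out = _baseline_matrix(spectra, baseline_irls,
                               lam=p.get("lam", 1e6),
                               max_iter=p.get("max_iter", 20))
    elif spec.method in ("d1", "d2"):
        out = derivative(spectra, order=1 if spec.method == "d1" else 2,
                         window=p.get("window", 11),
                         polyorder=p.get("polyorder", 2))
    else:  # unreachable given PreprocessSpec validation
        raise ValueError(f"unknown method {spec.method!r}")
    out.meta["preprocess"] = {"method": spec.method, "params": dict(p)}
    return out
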