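"""PLS1 regression (NIPALS) with cross-validated latent-variable selection.

Partial least squares regression projects a wide, collinear predictor matrix
(absorbance at hundreds of bands) onto a few latent variables that maximize
covariance with the response, then regresses the response on those scores.
Spectra are mean-centered only (no variance scaling — the chemometric
convention for absorbance data).  The number of latent variables (nLV) is
chosen by K-fold cross-validation as the global RMSECV minimizer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np


@dataclass
class PLSModel:
    """Fitted PLS1 model.

    Attributes
    ----------
    x_mean, y_mean : centering statistics.
    x_weights : (p, A) NIPALS weight vectors (unit norm).
    x_loadings : (p, A) loadings.
    y_loadings : (A,) regression of y on each score.
    coef : (p,) regression coefficients at ``n_components`` (original scale).
    intercept : scalar such that yhat = X @ coef + intercept.
    n_components : latent variables actually fitted (may be fewer than
        requested if the residual matrix ran out of rank).
    band_indices : which columns of the full grid the model uses (None =
        all columns of the training matrix).
    """

    x_mean: np.ndarray
    y_mean: float
    x_weights: np.ndarray
    x_loadings: np.ndarray
    y_loadings: np.ndarray
    coef: np.ndarray
    intercept: float
    n_components: int
    band_indices: np.ndarray | None = None
    _rotations: np.ndarray = field(default=None, repr=False)

    def coef_path(self) -> np.ndarray:
        """(p, A) coefficient vectors for every truncation 1..n_components."""
        return np.cumsum(self._rotations * self.y_loadings, axis=1)

    def to_dict(self) -> dict:
        return {
            "x_mean": self.x_mean.tolist(),
            "y_mean": float(self.y_mean),
            "coef": self.coef.tolist(),
            "intercept": float(self.intercept),
            "n_components": int(self.n_components),
            "band_indices": None if self.band_indices is None
            else np.asarray(self.band_indices).tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PLSModel":
        coef = np.asarray(d["coef"], dtype=float)
        return cls(
            x_mean=np.asarray(d["x_mean"], dtype=float),
            y_mean=float(d["y_mean"]),
            x_weights=np.empty((coef.size, 0)),
            x_loadings=np.empty((coef.size, 0)),
            y_loadings=np.empty(0),
            coef=coef,
            intercept=float(d["intercept"]),
            n_components=int(d["n_components"]),
            band_indices=None if d.get("band_indices") is None
            else np.asarray(d["band_indices"], dtype=int),
            _rotations=np.empty((coef.size, 0)),
        )


@dataclass
class CVProfile:
    """Cross-validation error profile over candidate latent-variable counts."""

    rmsecv_by_nlv: np.ndarray  # index a-1 -> RMSECV with a latent variables
    chosen_nlv: int
    folds: int
    seed: int | None


def fit_pls(X: np.ndarray, y: np.ndarray, nlv: int,
            band_indices: np.ndarray | None = None) -> PLSModel:
    """Fit mean-centered PLS1 by the NIPALS recursion.

    Deterministic: no randomness enters the fit.  If the deflated predictor
    matrix loses rank before ``nlv`` components, the fit stops early with a
    warning and ``n_components`` reflects the effective count.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if y.size != n:
        raise ValueError("X and y have inconsistent sample counts")
    if nlv < 1:
        raise ValueError("nlv must be >= 1")
    cap = min(n - 1, p)
    if nlv > cap:
        raise ValueError(f"nlv={nlv} exceeds min(n_samples-1, n_bands)={cap}")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    Xc = X - x_mean
    yc = y - y_mean
    scale = max(float(np.abs(Xc).max()), 1.0)

    W = np.zeros((p, nlv))
    P = np.zeros((p, nlv))
    q = np.zeros(nlv)
    a_eff = 0
    for a in range(nlv):
        w = Xc.T @ yc
        wn = np.linalg.norm(w)
        if wn <= 1e-13 * scale:
            warnings.warn(
                f"predictor residual exhausted after {a_eff} components "
                f"(requested {nlv}); fitting reduced model"
            )
            break
        w /= wn
        t = Xc @ w
        tt = float(t @ t)
        if tt <= 1e-26 * scale**2:
            warnings.warn(
                f"degenerate score at component {a + 1}; "
                f"fitting {a_eff}-component model"
            )
            break
        pvec = Xc.T @ t / tt
        qa = float(yc @ t / tt)
        Xc = Xc - np.outer(t, pvec)
        yc = yc - qa * t
        W[:, a], P[:, a], q[a] = w, pvec, qa
        a_eff += 1

    if a_eff == 0:
        # y uncorrelated with X: the model is just the mean
        W = np.zeros((p, 1))
        P = np.zeros((p, 1))
        q = np.zeros(1)
        R = np.zeros((p, 1))
        a_eff = 1
    else:
        W, P, q = W[:, :a_eff], P[:, :a_eff], q[:a_eff]
        # rotations R = W (P'W)^-1 map centered X to scores: T = Xc R
        R = np.linalg.solve((P.T @ W).T, W.T).T
    coef = R @ q
    model = PLSModel(
        x_mean=x_mean, y_mean=y_mean, x_weights=W, x_loadings=P, y_loadings=q,
        coef=coef, intercept=float(y_mean - x_mean @ coef),
        n_components=a_eff, band_indices=band_indices, _rotations=R,
    )
    return model


def predict(model: PLSModel, X: np.ndarray, nlv: int | None = None,
            via_scores: bool = False) -> np.ndarray:
    """Predict responses for new spectra.

    ``nlv`` truncates the model to its first components; ``via_scores``
    computes predictions through latent scores instead of the folded
    coefficient vector (the two agree to numerical precision).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.x_mean.size:
        raise ValueError(
            f"X has {X.shape[1]} bands but the model expects {model.x_mean.size}"
        )
    Xc = X - model.x_mean
    if via_scores:
        a = model.n_components if nlv is None else min(nlv, model.n_components)
        T = Xc @ model._rotations[:, :a]
        return model.y_mean + T @ model.y_loadings[:a]
    if nlv is None or nlv >= model.n_components:
        coef = model.coef
    else:
        coef = model.coef_path()[:, nlv - 1]
    return model.y_mean + Xc @ coef


def _fold_indices(n: int, folds: int, rng: np.random.Generator) -> list:
    """Seeded shuffle split into folds as equal as possible."""
    perm = rng.permutation(n)
    return [np.sort(part) for part in np.array_split(perm, folds)]


def cross_validate_nlv(X: np.ndarray, y: np.ndarray, max_nlv: int,
                       folds: int = 10, seed: int | None = None) -> CVProfile:
    """K-fold RMSECV profile over 1..max_nlv latent variables.

    One NIPALS fit per fold at the largest candidate supplies predictions for
    every smaller truncation (NIPALS components are nested).  The chosen nLV
    is the global RMSECV minimizer; ties break to the smaller model.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if folds > n:
        raise ValueError(f"{folds} folds exceed {n} samples")
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    # cap candidates so the largest held-out fold still leaves enough training rank
    min_train = n - max(_sizes(n, folds))
    cap = min(max_nlv, min_train - 1, p)
    if cap < 1:
        raise ValueError("not enough samples per fold for even one latent variable")

    sse = np.zeros(cap)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # rank exhaustion per fold is handled below
        for test_idx in _fold_indices(n, folds, rng):
            mask = np.ones(n, dtype=bool)
            mask[test_idx] = False
            model = fit_pls(X[mask], y[mask], cap)
            preds = (model.y_mean
                     + (X[test_idx] - model.x_mean) @ model.coef_path())
            if model.n_components < cap:  # pad: extra components add nothing
                pad = np.repeat(preds[:, -1:], cap - model.n_components, axis=1)
                preds = np.hstack([preds, pad])
            sse += np.sum((preds - y[test_idx, None]) ** 2, axis=0)
    rmsecv = np.sqrt(sse / n)
    chosen = int(np.argmin(rmsecv)) + 1  # argmin takes the first = smallest nLV
    return CVProfile(rmsecv_by_nlv=rmsecv, chosen_nlv=chosen, folds=folds, seed=seed)


def _sizes(n: int, folds: int) -> list:
    base, extra = divmod(n, folds)
    return [base + (1 if i < extra else 0) for i in range(folds)]
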