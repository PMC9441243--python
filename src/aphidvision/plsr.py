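"""Receptor-blind wavelength-importance analysis via PLS regression.

Trap catch is regressed on raw reflectance with partial least squares (PLS1,
NIPALS algorithm, mean-centering only — reflectance columns share units, so no
autoscaling).  Because neighbouring wavelengths are strongly collinear, PLSR
extracts a few latent components instead of fitting 80 unstable OLS
coefficients.  The coefficient spectrum, normalized by its maximum, is then
scanned for local maxima (excitatory wavelengths) and plateaus of negative
coefficients (inhibitory wavelengths) — a receptor-free mirror of the
opponent-mechanism analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ComputationError, InputError
from .spectra import ExperimentData

_EPS = 1e-14


def _nipals_pls1(Xc: np.ndarray, yc: np.ndarray, n_components: int
                 ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """NIPALS decomposition of centered data.

    Returns (W, P, q, T): weights, X-loadings, y-loadings and scores, each with
    one column (entry) per extracted component.  X is deflated per component.
    """
    X = Xc.copy()
    yr = yc.copy()
    W, P, Q, T = [], [], [], []
    for _ in range(n_components):
        w = X.T @ yr
        wn = np.linalg.norm(w)
        if wn < _EPS:
            break
        w = w / wn
        t = X @ w
        tt = float(t @ t)
        if tt < _EPS:
            break
        p = (X.T @ t) / tt
        q = float(yr @ t) / tt
        X = X - np.outer(t, p)
        yr = yr - q * t
        W.append(w)
        P.append(p)
        Q.append(q)
        T.append(t)
    if not W:
        raise ComputationError("PLSR extracted no components (X'y vanishes)")
    return (np.column_stack(W), np.column_stack(P), np.array(Q),
            np.column_stack(T))


def _coefficients_path(W: np.ndarray, P: np.ndarray, q: np.ndarray
                       ) -> list[np.ndarray]:
    """Regression coefficients on the centered scale for 1..k components."""
    out = []
    for k in range(1, W.shape[1] + 1):
        Wk, Pk, qk = W[:, :k], P[:, :k], q[:k]
        R = Wk @ np.linalg.solve(Pk.T @ Wk, np.eye(k))
        out.append(R @ qk)
    return out


@dataclass
class PLSRModel:
    """Fitted PLS1 model of counts on reflectance."""

    n_components: int
    x_wavelengths: np.ndarray
    coefficients: np.ndarray
    normalized_coefficients: np.ndarray
    r2: float
    r2_path: np.ndarray  # training r² for 1..n_components
    rmsep: np.ndarray | None  # LOO RMSEP for 0..n_components, if computed
    x_mean: np.ndarray
    y_mean: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, float))
        return self.y_mean + (X - self.x_mean) @ self.coefficients


def fit_plsr(X: np.ndarray, y: np.ndarray, n_components: int = 3,
             wavelengths: np.ndarray | None = None,
             cv: str | None = "loo") -> PLSRModel:
    """Mean-centered NIPALS PLS1 of response y on spectra X (traps × wavelengths).

    ``cv="loo"`` additionally computes the leave-one-out RMSEP for 0..k
    components; ``cv=None`` skips it.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.ndim != 1 or X.shape[0] != y.size:
        raise InputError("X must be (n_traps, n_wavelengths) and y of length n_traps")
    if not np.all(np.isfinite(X)):
        raise InputError("X contains missing or non-finite values")
    if n_components >= min(X.shape):
        raise InputError("n_components must be smaller than min(n_traps, n_wavelengths)")
    if np.ptp(y) < _EPS:
        raise ComputationError("response has zero variance")
    wavelengths = (np.asarray(wavelengths, float) if wavelengths is not None
                   else np.arange(X.shape[1], dtype=float))
    if wavelengths.size != X.shape[1]:
        raise InputError("wavelength grid length must match the number of X columns")

    x_mean = X.mean(axis=0)
    y_mean = float(y.mean())
    W, P, q, _ = _nipals_pls1(X - x_mean, y - y_mean, n_components)
    path = _coefficients_path(W, P, q)
    sst = float(np.sum((y - y_mean) ** 2))
    r2_path = np.array([
        1.0 - float(np.sum((y - (y_mean + (X - x_mean) @ beta)) ** 2)) / sst
        for beta in path
    ])
    coef = path[-1]
    rmsep = rmsep_curve(X, y, max_components=len(path),
                        wavelengths=wavelengths) if cv == "loo" else None
    c_max = float(coef.max())
    normalized = coef / c_max if abs(c_max) > _EPS else np.full_like(coef, np.nan)
    return PLSRModel(n_components=len(path), x_wavelengths=wavelengths,
                     coefficients=coef, normalized_coefficients=normalized,
                     r2=float(r2_path[-1]), r2_path=r2_path, rmsep=rmsep,
                     x_mean=x_mean, y_mean=y_mean)


def rmsep_curve(X: np.ndarray, y: np.ndarray, max_components: int = 10,
                wavelengths: np.ndarray | None = None) -> np.ndarray:
    """Leave-one-out RMSEP for 0..max_components PLS components.

    The 0-component entry is the error of the leave-one-out mean predictor.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = y.size
    if max_components >= n - 1:
        raise InputError("max_components must be below n_traps - 1")
    sq_err = np.zeros(max_components + 1)
    for i in range(n):
        mask = np.arange(n) != i
        Xi, yi = X[mask], y[mask]
        xm, ym = Xi.mean(axis=0), float(yi.mean())
        sq_err[0] += (y[i] - ym) ** 2
        try:
            W, P, q, _ = _nipals_pls1(Xi - xm, yi - ym, max_components)
        except ComputationError:
            sq_err[1:] += (y[i] - ym) ** 2
            continue
        path = _coefficients_path(W, P, q)
        for k in range(1, max_components + 1):
            beta = path[min(k, len(path)) - 1]
            pred = ym + (X[i] - xm) @ beta
            sq_err[k] += (y[i] - pred) ** 2
    return np.sqrt(sq_err / n)


@dataclass
class PeakReport:
    """Structure of a normalized coefficient spectrum."""

    maxima: list[float]  # wavelengths of strict local maxima
    global_max: float  # wavelength of the largest coefficient
    negative_interval: tuple[float, float] | None  # longest run of coef < 0
    small_threshold: float = 0.3


def normalize_and_find_peaks(model: PLSRModel,
                             small_threshold: float = 0.3) -> PeakReport:
    """Locate local maxima and the negative plateau of the coefficient spectrum.

    Maxima must be strict against both neighbours; runs of exactly equal values
    that stand above both sides report their central wavelength.  The negative
    plateau is the longest contiguous interval with normalized coefficient < 0.
    """
    c = model.coefficients
    if np.all(np.abs(c) < _EPS):
        raise ComputationError("all PLSR coefficients are zero")
    z = model.normalized_coefficients
    wl = model.x_wavelengths

    maxima: list[float] = []
    i = 0
    n = z.size
    while i < n:
        j = i
        while j + 1 < n and z[j + 1] == z[i]:
            j += 1
        left_ok = i == 0 or z[i - 1] < z[i]
        right_ok = j == n - 1 or z[j + 1] < z[i]
        interior = i > 0 and j < n - 1  # edges are not local maxima
        if left_ok and right_ok and interior:
            maxima.append(float(wl[(i + j) // 2]))
        i = j + 1

    negative_interval = None
    best_len = 0
    i = 0
    while i < n:
        if z[i] < 0:
            j = i
            while j + 1 < n and z[j + 1] < 0:
                j += 1
            if j - i + 1 > best_len:
                best_len = j - i + 1
                negative_interval = (float(wl[i]), float(wl[j]))
            i = j + 1
        else:
            i += 1
    return PeakReport(maxima=maxima, global_max=float(wl[int(np.argmax(z))]),
                      negative_interval=negative_interval,
                      small_threshold=small_threshold)


def fit_plsr_experiment(experiment: ExperimentData, n_components: int = 3,
                        taxon: str | None = None, wavelength_max: float = 700.0,
                        wavelength_min: float = 0.0, relative_response: bool = False,
                        cv: str | None = "loo") -> PLSRModel:
    """PLSR of trap counts on trap reflectance restricted to the visible+UV grid.

    The response is the raw total count per trap by default;
    ``relative_response=True`` uses the reference-normalized catch instead.
    """
    grid, X = experiment.spectra_matrix()
    cols = (grid >= wavelength_min) & (grid <= wavelength_max)
    if relative_response:
        from .opponent import relative_catch

        y = relative_catch(experiment, taxon).y
    else:
        y = experiment.counts_total(taxon)
    return fit_plsr(X[:, cols], y, n_components, wavelengths=grid[cols], cv=cv)
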