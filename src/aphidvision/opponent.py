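"""Evidence for a colour-opponent mechanism (COM) from trap catches.

The two-step procedure:

(i)  On the yellow-to-black trap series — colours that excite essentially
     only the green receptor — the relative catch y is regressed on the green
     photon catch G with a Gompertz dose-response y = a·exp(b·exp(c·G)).

(ii) That green-only model is then applied to *all* traps.  If behaviour were
     driven by the green receptor alone, the residuals e*_t = y_t − ŷ_G would
     carry no further spectral information.  A negative correlation of e*_t
     with the photon catch of a short-wavelength receptor instead indicates an
     inhibitory (opponent) input; tracing that correlation over candidate
     receptor peaks (the correlogram) localizes the inhibitory receptor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats

from .errors import ComputationError, FitError, InputError
from .receptors import LAMBDA_GRID, PhotonCatchSet, photon_catch_matrix
from .spectra import ExperimentData


@dataclass
class RelativeCatch:
    """Per-trap catch relative to the mean catch of the two reference traps."""

    trap_ids: list[str]
    y: np.ndarray
    n_ref: float
    taxon: str | None = None

    def __getitem__(self, trap_id: str) -> float:
        return float(self.y[self.trap_ids.index(trap_id)])

    def subset(self, trap_ids: list[str]) -> np.ndarray:
        index = {t: i for i, t in enumerate(self.trap_ids)}
        return self.y[[index[t] for t in trap_ids]]


def relative_catch(experiment: ExperimentData,
                   taxon: str | None = None) -> RelativeCatch:
    """y_t = n_t / mean(n_ref1, n_ref2), summed over taxa unless filtered."""
    counts = experiment.counts_total(taxon)
    ids = experiment.trap_ids
    ref_counts = [counts[ids.index(r)] for r in experiment.reference_ids]
    n_ref = float(np.mean(ref_counts))
    if n_ref <= 0:
        raise ComputationError("mean reference catch is zero; relative catch undefined")
    return RelativeCatch(ids, counts / n_ref, n_ref, taxon)


def gompertz(G: np.ndarray, a: float, b: float, c: float) -> np.ndarray:
    """Double-exponential sigmoid y = a·exp(b·exp(c·G)) (b, c < 0 when well-posed)."""
    return a * np.exp(b * np.exp(c * np.asarray(G, float)))


@dataclass
class GompertzFit:
    """Nonlinear least-squares fit of the green-receptor dose-response."""

    a: float
    b: float
    c: float
    a_se: float
    b_se: float
    c_se: float
    residual_se: float
    df: int
    G: np.ndarray
    fitted: np.ndarray

    @property
    def params(self) -> tuple[float, float, float]:
        return self.a, self.b, self.c

    def predict(self, G: np.ndarray) -> np.ndarray:
        return gompertz(G, self.a, self.b, self.c)


_C0_GRID = (-0.2, -0.5, -1.0, -2.0)


def fit_gompertz(G: np.ndarray, y: np.ndarray) -> GompertzFit:
    """Fit y = a·exp(b·exp(c·G)) by multi-start nonlinear least squares.

    Starts: a0 = max(y); c0 over a fixed grid; b0 solved from the observed y
    at the smallest G.  The best converged start by residual sum of squares
    wins.  Flat or otherwise unidentifiable data raise :class:`FitError`.
    """
    G = np.asarray(G, dtype=float)
    y = np.asarray(y, dtype=float)
    if G.size != y.size:
        raise InputError("G and y must have equal length")
    if G.size < 6:
        raise InputError("need at least 6 traps to fit the Gompertz curve")
    if np.ptp(y) < 1e-12:
        raise FitError("response is constant; Gompertz parameters are unidentifiable")

    a0 = float(np.max(y))
    i_min = int(np.argmin(G))
    frac0 = float(np.clip(y[i_min] / a0, 1e-6, 1.0 - 1e-6))

    def resid(theta: np.ndarray) -> np.ndarray:
        return gompertz(G, *theta) - y

    best = None
    diagnostics = []
    for c0 in _C0_GRID:
        b0 = np.log(frac0) / np.exp(c0 * G[i_min])
        sol = optimize.least_squares(resid, x0=[a0, b0, c0],
                                     xtol=1e-10, ftol=1e-12, gtol=1e-12,
                                     max_nfev=20000)
        diagnostics.append((c0, sol.status, float(np.sum(sol.fun ** 2))))
        if sol.status <= 0:
            continue
        ssr = float(np.sum(sol.fun ** 2))
        if best is None or ssr < best[0]:
            best = (ssr, sol)
    if best is None:
        raise FitError(f"Gompertz fit did not converge from any start: {diagnostics}")

    ssr, sol = best
    n = G.size
    df = n - 3
    s2 = ssr / df if df > 0 else np.nan
    J = sol.jac
    JTJ = J.T @ J
    if np.linalg.cond(JTJ) > 1e12:
        raise FitError("Gompertz fit is degenerate (near-singular Jacobian); "
                       "the data do not span the sigmoid's rise")
    cov = np.linalg.inv(JTJ) * s2
    se = np.sqrt(np.diag(cov))
    a, b, c = sol.x
    return GompertzFit(a=float(a), b=float(b), c=float(c),
                       a_se=float(se[0]), b_se=float(se[1]), c_se=float(se[2]),
                       residual_se=float(np.sqrt(s2)), df=df,
                       G=G, fitted=gompertz(G, a, b, c))


def com_residuals(fit: GompertzFit, G_all: np.ndarray,
                  y_all: np.ndarray) -> np.ndarray:
    """e*_t = y_t − ŷ_G for every trap (not just the training series)."""
    return np.asarray(y_all, float) - fit.predict(np.asarray(G_all, float))


@dataclass
class ComCorrelogram:
    """Pearson correlation of residuals with each candidate receptor's catch."""

    lambda_grid: np.ndarray
    r: np.ndarray
    p: np.ndarray

    @property
    def lambda_min_r(self) -> float:
        """Peak wavelength of the most negative correlation."""
        return float(self.lambda_grid[int(np.argmin(self.r))])

    @property
    def lambda_max_r(self) -> float:
        return float(self.lambda_grid[int(np.argmax(self.r))])

    def significant(self, alpha: float = 0.05) -> np.ndarray:
        return self.p < alpha


def correlogram(residuals: np.ndarray, pcs: PhotonCatchSet) -> ComCorrelogram:
    """Correlate residuals with the photon catch of every candidate receptor."""
    e = np.asarray(residuals, dtype=float)
    if e.size != len(pcs.trap_ids):
        raise InputError("residuals do not match the photon-catch matrix traps")
    if e.size < 10:
        raise InputError("need at least 10 traps for a correlogram")
    if np.ptp(e) < 1e-14:
        raise ComputationError("residuals have zero variance")
    r = np.empty(len(pcs.lambda_grid))
    p = np.empty_like(r)
    for j in range(len(pcs.lambda_grid)):
        col = pcs.P[:, j]
        if np.ptp(col) < 1e-14:
            raise ComputationError(
                f"photon catch at {pcs.lambda_grid[j]:g} nm has zero variance")
        res = stats.pearsonr(e, col)
        r[j], p[j] = res.statistic, res.pvalue
    return ComCorrelogram(pcs.lambda_grid.copy(), r, p)


@dataclass
class LinearResidualModel:
    """OLS of COM residuals on the photon catch of one (blue) receptor."""

    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    adj_r2: float
    residual_se: float
    p_slope: float
    n: int


def linear_residual_model(residuals: np.ndarray,
                          P_blue: np.ndarray) -> LinearResidualModel:
    """Fit e* = intercept + slope·P and report the summary statistics."""
    e = np.asarray(residuals, float)
    P = np.asarray(P_blue, float)
    model = sm.OLS(e, sm.add_constant(P)).fit()
    return LinearResidualModel(
        slope=float(model.params[1]), intercept=float(model.params[0]),
        slope_se=float(model.bse[1]), intercept_se=float(model.bse[0]),
        adj_r2=float(model.rsquared_adj),
        residual_se=float(np.sqrt(model.mse_resid)),
        p_slope=float(model.pvalues[1]), n=int(model.nobs))


def flag_suspicious_training_traps(experiment: ExperimentData,
                                   series: str = "yellow-black",
                                   threshold: float = 0.08) -> list[str]:
    """Traps labelled as the green-only training series whose mean reflectance
    below 480 nm exceeds ``threshold`` — they would excite a blue/UV receptor
    and should not be in the series."""
    flagged = []
    for t in experiment.traps:
        if t.series != series:
            continue
        wl = t.spectrum.wavelength_nm
        mean_short = float(t.spectrum.value[wl < 480.0].mean())
        if mean_short > threshold:
            flagged.append(t.trap_id)
    return flagged


@dataclass
class ComAnalysis:
    """Bundled output of the two-step COM evidence procedure."""

    trap_ids: list[str]
    relative: RelativeCatch
    pcs: PhotonCatchSet
    training_ids: list[str]
    fit: GompertzFit
    residuals: np.ndarray
    correlogram: ComCorrelogram


def com_analysis(experiment: ExperimentData, green_peak: float = 530.0,
                 series: str = "yellow-black", taxon: str | None = None,
                 lambda_grid: np.ndarray = LAMBDA_GRID,
                 include_reference: bool = False) -> ComAnalysis:
    """Run steps (i) and (ii) on an experiment.

    Reference traps define the response scale and are excluded from the
    analysis set by default.
    """
    rel = relative_catch(experiment, taxon)
    pcs_full = photon_catch_matrix(experiment, lambda_grid)
    keep = [t.trap_id for t in experiment.traps
            if include_reference or not t.is_reference]
    index = {t: i for i, t in enumerate(experiment.trap_ids)}
    rows = [index[t] for t in keep]
    pcs = PhotonCatchSet(keep, pcs_full.lambda_grid, pcs_full.P[rows])
    y = rel.subset(keep)
    G = pcs.column(green_peak)

    training_ids = [t for t in keep if experiment.trap(t).series == series]
    if not training_ids:
        raise InputError(f"no traps labelled with series '{series}'")
    tr_rows = [keep.index(t) for t in training_ids]
    fit = fit_gompertz(G[tr_rows], y[tr_rows])
    resid = com_residuals(fit, G, y)
    corr = correlogram(resid, pcs)
    return ComAnalysis(keep, rel, pcs, training_ids, fit, resid, corr)
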