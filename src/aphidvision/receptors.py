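"""Photoreceptor sensitivity templates and photon catches.

A receptor with peak wavelength λmax is modelled as a symmetric Gaussian in
wavelength whose full width at half maximum is a fixed fraction of the peak
(Δλ/λmax = 0.18, no beta band).  The photon catch P of a stimulus is the
integral of stimulus reflectance × receptor sensitivity × illuminant,
normalized by the same integral for the background the stimulus appears
against:

    P_R(t) = ∫ I_t(λ) S_R(λ) D(λ) dλ  /  ∫ I_b(λ) S_R(λ) D(λ) dλ

so P is dimensionless, equals 1 for the background itself, and is invariant
to any common rescaling of the illuminant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .errors import ComputationError, InputError
from .spectra import ExperimentData, Spectrum, shared_grid

#: default half-max bandwidth to peak-wavelength ratio.
FWHM_RATIO = 0.18

#: default candidate peak-wavelength grid: 320-610 nm in 10 nm steps.
LAMBDA_GRID = np.arange(320.0, 611.0, 10.0)

ShapeFn = Callable[[np.ndarray, float, float], np.ndarray]


def gaussian_shape(wl: np.ndarray, lambda_max: float, fwhm: float) -> np.ndarray:
    """Gaussian sensitivity with unit peak and the given FWHM, in wavelength."""
    return np.exp(-4.0 * np.log(2.0) * ((wl - lambda_max) / fwhm) ** 2)


@dataclass(frozen=True)
class ReceptorTemplate:
    """Sensitivity curve S(λ) with unit peak at ``lambda_max``."""

    lambda_max: float
    fwhm_ratio: float
    sensitivity: Spectrum
    shape: ShapeFn

    @property
    def fwhm(self) -> float:
        return self.fwhm_ratio * self.lambda_max

    def at(self, grid: np.ndarray) -> np.ndarray:
        """Evaluate the analytic template on an arbitrary grid."""
        return self.shape(np.asarray(grid, float), self.lambda_max, self.fwhm)


def make_template(lambda_max: float, grid: np.ndarray | None = None,
                  fwhm_ratio: float = FWHM_RATIO,
                  shape: ShapeFn = gaussian_shape) -> ReceptorTemplate:
    """Build a receptor template sampled on ``grid`` (default 320-950 at 5 nm).

    ``shape`` is pluggable so a nomogram or log-domain template can replace the
    Gaussian without touching the photon-catch machinery.
    """
    if not 300.0 <= lambda_max <= 700.0:
        raise InputError(f"lambda_max {lambda_max:g} nm outside the supported 300-700 nm range")
    if grid is None:
        grid = np.arange(320.0, 951.0, 5.0)
    grid = np.asarray(grid, dtype=float)
    fwhm = fwhm_ratio * lambda_max
    sens = Spectrum(grid, shape(grid, lambda_max, fwhm))
    return ReceptorTemplate(float(lambda_max), float(fwhm_ratio), sens, shape)


def _trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    w = np.empty_like(grid)
    w[1:-1] = (grid[2:] - grid[:-2]) / 2.0
    w[0] = (grid[1] - grid[0]) / 2.0
    w[-1] = (grid[-1] - grid[-2]) / 2.0
    return w


def photon_catch(trap: Spectrum, template: ReceptorTemplate,
                 illuminant: Spectrum, background: Spectrum,
                 integration_step: float = 1.0) -> float:
    """Background-normalized photon catch of one stimulus in one receptor.

    All spectra are resampled internally onto a shared fine grid covering the
    overlap of their supports; integration is trapezoidal on that grid.  The
    measured spectra are piecewise linear, so refining the grid below their
    native 5 nm step only sharpens the quadrature of the smooth sensitivity
    curve; 1 nm keeps the error comfortably below 1e-4 relative.
    """
    grid = shared_grid([trap, illuminant, background], step=integration_step)
    w = _trapezoid_weights(grid) * template.at(grid) * illuminant.interp(grid)
    denom = float(background.interp(grid) @ w)
    if denom <= 0.0:
        raise ComputationError(
            f"background photon catch is non-positive for lambda_max={template.lambda_max:g} nm"
        )
    return float(trap.interp(grid) @ w) / denom


@dataclass
class PhotonCatchSet:
    """Photon catches for every trap × every candidate receptor peak."""

    trap_ids: list[str]
    lambda_grid: np.ndarray
    P: np.ndarray  # shape (n_traps, n_receptors)

    def __post_init__(self) -> None:
        if self.P.shape != (len(self.trap_ids), len(self.lambda_grid)):
            raise InputError("photon-catch matrix shape does not match its labels")

    def column(self, lambda_max: float) -> np.ndarray:
        """Catches of all traps for the receptor peaking at ``lambda_max``."""
        idx = np.nonzero(np.isclose(self.lambda_grid, lambda_max))[0]
        if idx.size == 0:
            raise InputError(f"lambda_max {lambda_max:g} nm not on the receptor grid")
        return self.P[:, idx[0]]

    def get(self, trap_id: str, lambda_max: float) -> float:
        return float(self.column(lambda_max)[self.trap_ids.index(trap_id)])

    def to_frame(self):
        import pandas as pd

        rows = [
            {"trap_id": tid, "lambda_max": lm, "P": self.P[i, j]}
            for i, tid in enumerate(self.trap_ids)
            for j, lm in enumerate(self.lambda_grid)
        ]
        return pd.DataFrame(rows)


def photon_catch_matrix(experiment: ExperimentData,
                        lambda_grid: Sequence[float] | np.ndarray = LAMBDA_GRID,
                        fwhm_ratio: float = FWHM_RATIO,
                        shape: ShapeFn = gaussian_shape,
                        integration_step: float = 1.0) -> PhotonCatchSet:
    """Photon catches for every trap against every candidate receptor.

    Vectorized: one shared grid, one weighted integral per (trap, receptor).
    Integration uses a fine internal grid (see :func:`photon_catch`).
    """
    lambda_grid = np.asarray(lambda_grid, dtype=float)
    specs = [t.spectrum for t in experiment.traps] + [experiment.illuminant,
                                                      experiment.background]
    grid = shared_grid(specs, step=integration_step)
    D = experiment.illuminant.interp(grid)
    w = _trapezoid_weights(grid) * D
    # receptors × wavelengths sensitivity matrix
    S = np.vstack([
        shape(grid, lm, fwhm_ratio * lm) for lm in lambda_grid
    ])
    kernel = S * w  # (n_receptors, n_wl)
    T = np.vstack([t.spectrum.interp(grid) for t in experiment.traps])
    denom = kernel @ experiment.background.interp(grid)  # (n_receptors,)
    if np.any(denom <= 0.0):
        bad = lambda_grid[np.argmin(denom)]
        raise ComputationError(f"background photon catch non-positive at {bad:g} nm")
    P = (T @ kernel.T) / denom
    return PhotonCatchSet(experiment.trap_ids, lambda_grid, P)
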