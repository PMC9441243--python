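"""Spectral containers and I/O.

Reflectance and irradiance spectra are the carrier objects of the whole
pipeline: trap paints, bare-soil backgrounds, the D65 daylight illuminant and
wheat-leaf reflectance all travel as :class:`Spectrum`.  Reflectance is
dimensionless (relative to a white standard, e.g. BaSO4 or Spectralon);
illuminants carry relative (photon or energy) irradiance.

The standard working grid is 5 nm band centres; trap measurements cover
320-950 nm, leaf measurements 300-700 nm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .errors import ComputationError, InputError, RangeError, SpectrumFormatError

#: maximum admissible reflectance; real measurements against a white standard
#: occasionally exceed 1 slightly, but values beyond this signal a broken file.
REFLECTANCE_CAP = 1.5

#: default grid step in nm for all standardized calculations.
GRID_STEP_NM = 5.0


@dataclass(frozen=True)
class Spectrum:
    """A sampled spectrum: strictly ascending wavelengths with one value each.

    Parameters
    ----------
    wavelength_nm
        Strictly ascending wavelengths (band centres) in nanometres.
    value
        Non-negative reflectance (dimensionless) or relative irradiance.
    """

    wavelength_nm: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength_nm, dtype=float)
        val = np.asarray(self.value, dtype=float)
        if wl.ndim != 1 or val.ndim != 1 or wl.size != val.size:
            raise SpectrumFormatError("wavelength and value arrays must be 1-d and equal length")
        if wl.size < 2:
            raise SpectrumFormatError("a spectrum needs at least two samples")
        if not np.all(np.diff(wl) > 0):
            raise SpectrumFormatError("wavelengths must be strictly ascending")
        if not np.all(np.isfinite(val)):
            raise SpectrumFormatError("spectrum contains non-finite values")
        if np.any(val < 0):
            raise SpectrumFormatError("spectrum contains negative values")
        wl.setflags(write=False)
        val.setflags(write=False)
        object.__setattr__(self, "wavelength_nm", wl)
        object.__setattr__(self, "value", val)

    def __len__(self) -> int:
        return self.wavelength_nm.size

    @property
    def support(self) -> tuple[float, float]:
        return float(self.wavelength_nm[0]), float(self.wavelength_nm[-1])

    def interp(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation of the values onto ``grid`` (must lie in support)."""
        grid = np.asarray(grid, dtype=float)
        lo, hi = self.support
        if grid.min() < lo - 1e-9 or grid.max() > hi + 1e-9:
            raise RangeError(
                f"requested grid [{grid.min():g}, {grid.max():g}] outside support [{lo:g}, {hi:g}]"
            )
        return np.interp(grid, self.wavelength_nm, self.value)

    def validate_reflectance(self, label: str = "spectrum") -> "Spectrum":
        """Reject implausible reflectance values (> REFLECTANCE_CAP) loudly."""
        if np.any(self.value > REFLECTANCE_CAP):
            bad = float(self.value.max())
            raise SpectrumFormatError(
                f"{label}: reflectance {bad:.3f} exceeds the plausibility cap {REFLECTANCE_CAP}"
            )
        return self


def make_grid(start: float, stop: float, step: float = GRID_STEP_NM) -> np.ndarray:
    """Uniform wavelength grid including both endpoints."""
    n = int(round((stop - start) / step))
    return start + step * np.arange(n + 1)


def shared_grid(spectra: Iterable[Spectrum], step: float = GRID_STEP_NM) -> np.ndarray:
    """The common 5 nm grid covering the overlap of all supports.

    Grid nodes are aligned to multiples of ``step`` so that spectra measured on
    the standard grids coincide node-for-node.
    """
    spectra = list(spectra)
    lo = max(s.support[0] for s in spectra)
    hi = min(s.support[1] for s in spectra)
    start = math.ceil(lo / step - 1e-9) * step
    stop = math.floor(hi / step + 1e-9) * step
    if stop <= start:
        raise ComputationError("spectra have no overlapping wavelength support")
    return make_grid(start, stop, step)


def resample(spectrum: Spectrum, grid_start: float, grid_stop: float,
             step: float = GRID_STEP_NM) -> Spectrum:
    """Linearly interpolate onto a uniform grid within the spectrum's support."""
    grid = make_grid(grid_start, grid_stop, step)
    return Spectrum(grid, spectrum.interp(grid))


def smooth_moving_average(spectrum: Spectrum, window_nm: float = 2.4) -> Spectrum:
    """Centred moving average over all samples within ±window_nm/2.

    Edge samples use the truncated window.  A window narrower than the grid
    step leaves the spectrum unchanged (each window holds a single sample).
    """
    if window_nm <= 0:
        raise InputError("window_nm must be positive")
    wl = spectrum.wavelength_nm
    val = spectrum.value
    half = window_nm / 2.0
    lo = np.searchsorted(wl, wl - half, side="left")
    hi = np.searchsorted(wl, wl + half, side="right")
    csum = np.concatenate([[0.0], np.cumsum(val)])
    out = (csum[hi] - csum[lo]) / (hi - lo)
    return Spectrum(wl.copy(), out)


def read_spectra_table(path: str | Path) -> dict[str, Spectrum]:
    """Read a wide CSV (wavelength_nm column + one column per spectrum).

    Column labels are preserved verbatim as keys.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SpectrumFormatError(f"{path}: need a wavelength column plus at least one spectrum")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.to_numpy().any():
        col = bad.any(axis=0).idxmax()
        row = int(bad[col].idxmax())
        raise SpectrumFormatError(
            f"{path}: non-numeric value {df.loc[row, col]!r} in column '{col}' at row {row}")
    df = numeric
    wl = df.iloc[:, 0].to_numpy(dtype=float)
    if not np.all(np.diff(wl) > 0):
        raise SpectrumFormatError(f"{path}: wavelength column is not strictly ascending")
    out: dict[str, Spectrum] = {}
    for col in df.columns[1:]:
        series = df[col]
        if series.isna().any():
            row = int(series.isna().idxmax())
            raise SpectrumFormatError(
                f"{path}: missing value in column '{col}' at row {row} "
                f"(wavelength {wl[row]:g} nm)"
            )
        spec = Spectrum(wl, series.to_numpy(dtype=float))
        out[str(col)] = spec.validate_reflectance(label=f"{path}:{col}")
    return out


def write_spectra_table(path: str | Path, spectra: Mapping[str, Spectrum]) -> None:
    """Write spectra sharing one grid to a wide CSV (inverse of the reader)."""
    items = list(spectra.items())
    wl = items[0][1].wavelength_nm
    for name, s in items[1:]:
        if not np.array_equal(s.wavelength_nm, wl):
            raise InputError(f"spectrum '{name}' is not on the shared grid")
    df = pd.DataFrame({"wavelength_nm": wl})
    for name, s in items:
        df[name] = s.value
    df.to_csv(path, index=False)


def read_two_column(path: str | Path) -> Spectrum:
    """Read a two-column (wavelength, value) CSV, e.g. background or illuminant."""
    df = pd.read_csv(path)
    if df.shape[1] != 2:
        raise SpectrumFormatError(f"{path}: expected exactly two columns")
    return Spectrum(df.iloc[:, 0].to_numpy(float), df.iloc[:, 1].to_numpy(float))


def write_two_column(path: str | Path, spectrum: Spectrum,
                     value_name: str = "value") -> None:
    pd.DataFrame({"wavelength_nm": spectrum.wavelength_nm,
                  value_name: spectrum.value}).to_csv(path, index=False)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Read a long counts CSV with columns trap_id, taxon, count."""
    df = pd.read_csv(path)
    required = {"trap_id", "taxon", "count"}
    if not required.issubset(df.columns):
        raise SpectrumFormatError(f"{path}: counts table needs columns {sorted(required)}")
    if (df["count"] < 0).any():
        raise SpectrumFormatError(f"{path}: negative counts")
    return df


def load_d65(units: str = "photon", step: float = GRID_STEP_NM) -> Spectrum:
    """The CIE standard daylight illuminant D65 on 300-830 nm.

    Parameters
    ----------
    units
        ``"photon"`` (default) converts the tabulated relative spectral power
        to relative photon irradiance by multiplying with wavelength —
        receptors count absorbed quanta, not energy.  ``"energy"`` returns the
        power spectrum as tabulated.
    step
        Output grid step in nm (values are interpolated from the packaged
        10 nm tabulation).

    The result is renormalized so that the value at 560 nm equals 1.
    """
    if units not in ("photon", "energy"):
        raise InputError("units must be 'photon' or 'energy'")
    ref = resources.files("aphidvision.data").joinpath("cie_d65_10nm.csv")
    with resources.as_file(ref) as p:
        raw = read_two_column(p)
    grid = make_grid(300.0, 830.0, step)
    val = raw.interp(grid)
    if units == "photon":
        val = val * grid
    anchor = float(np.interp(560.0, grid, val))
    return Spectrum(grid, val / anchor)


@dataclass
class TrapRecord:
    """One water trap: its colour, series membership and taxon-wise catch."""

    trap_id: str
    series: str
    spectrum: Spectrum
    counts: dict[str, float]
    is_reference: bool = False

    def total_count(self) -> float:
        return float(sum(self.counts.values()))


@dataclass
class ExperimentData:
    """A complete trap experiment: traps, background, illuminant, references."""

    traps: list[TrapRecord]
    background: Spectrum
    illuminant: Spectrum
    reference_ids: tuple[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ids = {t.trap_id for t in self.traps}
        for rid in self.reference_ids:
            if rid not in ids:
                raise InputError(f"reference trap '{rid}' not among the traps")
        grid = self.traps[0].spectrum.wavelength_nm
        for t in self.traps:
            if not np.array_equal(t.spectrum.wavelength_nm, grid):
                raise InputError(f"trap '{t.trap_id}' is not on the shared grid")
            if any(v < 0 for v in t.counts.values()):
                raise InputError(f"trap '{t.trap_id}' has negative counts")
        for t in self.traps:
            t.is_reference = t.trap_id in self.reference_ids

    @property
    def trap_ids(self) -> list[str]:
        return [t.trap_id for t in self.traps]

    @property
    def taxa(self) -> list[str]:
        seen: list[str] = []
        for t in self.traps:
            for k in t.counts:
                if k not in seen:
                    seen.append(k)
        return seen

    def trap(self, trap_id: str) -> TrapRecord:
        for t in self.traps:
            if t.trap_id == trap_id:
                return t
        raise KeyError(trap_id)

    def counts_total(self, taxon: str | None = None) -> np.ndarray:
        """Per-trap counts in trap order, summed over taxa unless filtered."""
        if taxon is None:
            return np.array([t.total_count() for t in self.traps])
        return np.array([t.counts.get(taxon, 0.0) for t in self.traps])

    def spectra_matrix(self) -> tuple[np.ndarray, np.ndarray]:
        """(wavelength grid, traps × wavelengths reflectance matrix)."""
        grid = self.traps[0].spectrum.wavelength_nm
        X = np.vstack([t.spectrum.value for t in self.traps])
        return grid, X
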