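"""Synthetic trap experiments and leaf sets with known ground truth.

The generator emulates the structure of the field studies the pipeline is
built for: ~70 paint-mixture trap colours spanning hue, saturation and
brightness series (including a yellow-to-black series and high-UV variants),
Poisson trap catches produced by a known green/blue opponent choice model
against a bare-soil background, and wheat-leaf reflectance whose chlorophyll
absorption deepens with mineral-nitrogen supply.

Because the truth is known, every downstream stage (Gompertz evidence step,
correlogram, split regression, blue-peak optimization, PLSR, leaf ANOVA) can
be checked for round-trip recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .errors import GenerationError, InputError
from .leaves import LeafSample
from .receptors import make_template, photon_catch
from .spectra import ExperimentData, Spectrum, TrapRecord, load_d65, make_grid

TRAP_GRID = make_grid(320.0, 950.0, 5.0)

#: taxon composition of the synthetic catch (shares follow the dominance of
#: the cabbage aphid and the green peach aphid in spring trap catches).
DEFAULT_TAXON_SHARES: dict[str, float] = {
    "Brevicoryne brassicae": 0.404,
    "Myzus persicae": 0.239,
    "other": 0.357,
}

PAINT_NAMES = ("yellow", "blue", "white", "black", "green", "red", "uv_additive")


@dataclass(frozen=True)
class PaintBase:
    """A base masonry paint: a name and its reflectance spectrum."""

    name: str
    reflectance: Spectrum


@dataclass
class GroundTruth:
    """Parameters of the generative opponent choice model.

    ``n_ref_mean`` is the expected count in a reference trap; coloured traps
    get expected count n_ref_mean × (b + a·max(0, ln(G/B))).  Optional
    per-taxon overrides let slope/intercept differ between taxa.
    """

    a_true: float = 2.499
    b_true: float = 0.025
    lambda_max_G: float = 530.0
    lambda_max_B: float = 470.0
    n_ref_mean: float = 500.0
    noise: str = "none"
    taxon_shares: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TAXON_SHARES))
    taxon_effects: dict[str, tuple[float, float]] | None = None
    overdispersion: float | None = None  # NB dispersion k; None = pure Poisson

    def __post_init__(self) -> None:
        if self.a_true < 0 or self.b_true < 0:
            raise InputError("a_true and b_true must be non-negative")
        for lm in (self.lambda_max_G, self.lambda_max_B):
            if not 320.0 <= lm <= 610.0:
                raise InputError("receptor peaks must lie in 320-610 nm")
        if self.n_ref_mean <= 0:
            raise InputError("n_ref_mean must be positive")
        if self.noise not in ("none", "poisson"):
            raise InputError("noise must be 'none' or 'poisson'")
        total = sum(self.taxon_shares.values())
        if abs(total - 1.0) > 1e-9:
            raise InputError("taxon shares must sum to 1")

    def params_for(self, taxon: str) -> tuple[float, float]:
        if self.taxon_effects and taxon in self.taxon_effects:
            return self.taxon_effects[taxon]
        return self.a_true, self.b_true


def _gauss(wl: np.ndarray, mu: float, sigma: float) -> np.ndarray:
    return np.exp(-0.5 * ((wl - mu) / sigma) ** 2)


def _base_curves(wl: np.ndarray) -> dict[str, np.ndarray]:
    return {
        "yellow": 0.03 + 0.85 * expit((wl - 510.0) / 9.0),
        "black": np.full_like(wl, 0.04),
        "white": 0.72 + 0.16 * expit((wl - 380.0) / 25.0),
        "blue": 0.05 + 0.45 * _gauss(wl, 470.0, 40.0),
        "green": 0.05 + 0.40 * _gauss(wl, 550.0, 40.0),
        "red": 0.04 + 0.70 * expit((wl - 610.0) / 12.0),
        "uv_additive": 0.06 + 0.55 * _gauss(wl, 350.0, 35.0),
    }


def make_paint_bases(seed: int) -> dict[str, PaintBase]:
    """The seven base paints on the 320-950 nm / 5 nm grid.

    A seeded low-frequency ripple (< ±2.5%) individualizes the curves per seed
    while preserving the qualitative invariants of each base.
    """
    wl = TRAP_GRID
    rng = np.random.default_rng(seed)
    bases: dict[str, PaintBase] = {}
    for name, curve in _base_curves(wl).items():
        ripple = np.zeros_like(wl)
        for _ in range(3):
            amp = rng.uniform(0.0, 0.008)
            period = rng.uniform(120.0, 400.0)
            phase = rng.uniform(0.0, 2.0 * np.pi)
            ripple += amp * np.sin(2.0 * np.pi * wl / period + phase)
        value = np.clip(curve * (1.0 + ripple), 0.0, 1.0)
        bases[name] = PaintBase(name, Spectrum(wl, value))
    return bases


def mix_paints(weights: Mapping[str, float],
               bases: Mapping[str, PaintBase]) -> Spectrum:
    """Mix base paints by a weighted geometric mean of their reflectances.

    This is a cheap surrogate for subtractive pigment mixing: the mixture is
    always between the constituents at every wavelength and dark pigments
    dominate, as they do physically.  Base reflectances are floored at 1e-4
    before taking logs.
    """
    items = list(weights.items())
    if not items:
        raise InputError("weights must not be empty")
    total = sum(w for _, w in items)
    if any(w < 0 for _, w in items):
        raise InputError("mixing weights must be non-negative")
    if abs(total - 1.0) > 1e-9:
        raise InputError(f"mixing weights sum to {total:.12g}, expected 1")
    unknown = [n for n, _ in items if n not in bases]
    if unknown:
        raise InputError(f"unknown base paint(s): {unknown}")
    wl = bases[items[0][0]].reflectance.wavelength_nm
    log_mix = np.zeros_like(wl, dtype=float)
    for name, w in items:
        log_mix += w * np.log(np.maximum(bases[name].reflectance.value, 1e-4))
    return Spectrum(wl, np.exp(log_mix))


def soil_background(start: float = 300.0, stop: float = 950.0) -> Spectrum:
    """Bare-soil reflectance: rising linearly from 0.05 at 320 nm to 0.25 at 950 nm."""
    grid = make_grid(start, stop, 5.0)
    value = 0.05 + (grid - 320.0) * (0.25 - 0.05) / (950.0 - 320.0)
    return Spectrum(grid, np.clip(value, 0.0, 1.0))


@dataclass(frozen=True)
class PlanEntry:
    """One planned trap colour: label, series membership and paint recipe."""

    name: str
    series: str
    weights: dict[str, float]
    is_reference: bool = False


def _two_base_series(series: str, primary: str, secondary: str,
                     fractions: np.ndarray) -> list[PlanEntry]:
    return [
        PlanEntry(f"{series}-{i + 1:02d}", series,
                  {primary: float(f), secondary: float(1.0 - f)})
        for i, f in enumerate(fractions)
    ]


def default_series_plan(n_colours: int = 70) -> list[PlanEntry]:
    """The primary colour plan: mixtures of yellow, blue, white and black paint.

    Always contains one pure-yellow reference colour and a 10-colour
    yellow-to-black series; the remaining budget is distributed over
    saturation/brightness series of the same four paints so both the G>B and
    the G<B regimes are covered.  Keeping the primary experiment to these four
    paints matters for the receptor-blind wavelength analysis: a green or red
    pigment would plant its own reflectance peak into the stimulus covariance
    and mask the behavioural action spectrum.  Hue-richer colours live in
    :func:`extended_series_plan` and are meant for validation experiments.
    """
    if n_colours < 13:
        raise InputError("default plan needs at least 13 colours; pass a custom series_plan")
    plan: list[PlanEntry] = [
        PlanEntry("ref-yellow", "reference", {"yellow": 1.0}, is_reference=True)
    ]
    yb_fracs = np.geomspace(1.0, 0.02, 10)
    plan += _two_base_series("yellow-black", "yellow", "black", yb_fracs)

    remaining = n_colours - len(plan)
    series_spec = [
        ("blue-white", "blue", "white", 8),
        ("yellow-blue", "yellow", "blue", 8),
        ("blue-black", "blue", "black", 8),
        ("yellow-white", "yellow", "white", 8),
        ("grey", "white", "black", 7),
    ]
    return _fill_plan(plan, series_spec, remaining)


def extended_series_plan(n_colours: int = 70) -> list[PlanEntry]:
    """A hue-richer plan adding green, red and UV-reflective colours.

    Suitable as a second, independent experiment for cross-validating a model
    fitted on the primary plan.  Not the default for the receptor-blind PLSR
    analysis (see :func:`default_series_plan`).
    """
    if n_colours < 13:
        raise InputError("extended plan needs at least 13 colours; pass a custom series_plan")
    plan: list[PlanEntry] = [
        PlanEntry("ref-yellow", "reference", {"yellow": 1.0}, is_reference=True)
    ]
    yb_fracs = np.geomspace(1.0, 0.02, 10)
    plan += _two_base_series("yellow-black", "yellow", "black", yb_fracs)

    remaining = n_colours - len(plan)
    series_spec = [
        ("blue-white", "blue", "white", 8),
        ("yellow-blue", "yellow", "blue", 8),
        ("blue-black", "blue", "black", 8),
        ("yellow-white", "yellow", "white", 8),
        ("grey", "white", "black", 7),
        ("green-black", "green", "black", 5),
        ("green-white", "green", "white", 5),
        ("uv-yellow", "uv_additive", "yellow", 5),
        ("uv-green", "uv_additive", "green", 3),
        ("red-white", "red", "white", 2),
    ]
    return _fill_plan(plan, series_spec, remaining)


def _fill_plan(plan: list[PlanEntry], series_spec: list[tuple],
               remaining: int) -> list[PlanEntry]:
    """Distribute the remaining colour budget over the series proportionally."""
    total_nominal = sum(k for *_, k in series_spec)
    sizes = [max(1, int(round(k * remaining / total_nominal))) for *_, k in series_spec]
    # trim/pad to hit the budget exactly, never dropping a series entirely
    i = 0
    while sum(sizes) > remaining:
        j = int(np.argmax(sizes))
        if sizes[j] > 1:
            sizes[j] -= 1
        i += 1
        if i > 1000:  # pragma: no cover
            break
    while sum(sizes) < remaining:
        sizes[int(np.argmin(sizes))] += 1
    for (series, prim, sec, _), k in zip(series_spec, sizes):
        if series == "uv-yellow" or series == "uv-green":
            fracs = np.linspace(0.15, 0.6, k)
        else:
            fracs = np.linspace(1.0, 0.1, k)
        plan += _two_base_series(series, prim, sec, fracs)
    return plan


def generate_trap_experiment(truth: GroundTruth, n_traps: int = 140,
                             series_plan: Sequence[PlanEntry] | None = None,
                             seed: int = 0) -> ExperimentData:
    """Generate a full trap experiment from a known opponent model.

    Each planned colour is painted on two replicate traps (suffixes ``a``/``b``,
    mirroring duplicate traps in the field).  Expected counts are
    n_ref_mean × (b + a·max(0, ln(G/B))) with G, B the photon catches of the
    truth's green and blue receptors against the generated soil background;
    the two pure-yellow reference traps have expected count n_ref_mean exactly
    (they define the unit of relative catch).  Counts are Poisson (or the
    exact expectation when ``truth.noise == "none"``).
    """
    if n_traps < 10:
        raise InputError("n_traps must be at least 10")
    if series_plan is None:
        if n_traps < 26:
            raise InputError("default plan needs n_traps >= 26; pass a custom series_plan")
        series_plan = default_series_plan(n_colours=n_traps // 2)
    replicates = ("a", "b") if n_traps >= 2 * len(series_plan) else ("a",)

    bases = make_paint_bases(seed)
    background = soil_background()
    illuminant = load_d65()
    tmpl_G = make_template(truth.lambda_max_G)
    tmpl_B = make_template(truth.lambda_max_B)
    rng = np.random.default_rng(seed)

    taxa = list(truth.taxon_shares)
    traps: list[TrapRecord] = []
    reference_ids: list[str] = []
    for entry in series_plan:
        spectrum = mix_paints(entry.weights, bases)
        G = photon_catch(spectrum, tmpl_G, illuminant, background)
        B = photon_catch(spectrum, tmpl_B, illuminant, background)
        if not (np.isfinite(G) and np.isfinite(B)) or G <= 0 or B <= 0:
            raise GenerationError(f"non-finite photon catch for colour '{entry.name}'")
        x = float(np.log(G / B))
        for rep in replicates:
            trap_id = f"{entry.name}-{rep}"
            counts: dict[str, float] = {}
            for taxon in taxa:
                a_g, b_g = truth.params_for(taxon)
                y = 1.0 if entry.is_reference else b_g + a_g * max(0.0, x)
                mean = truth.taxon_shares[taxon] * truth.n_ref_mean * y
                if not np.isfinite(mean):
                    raise GenerationError(f"non-finite expected count for trap '{trap_id}'")
                counts[taxon] = _draw_count(mean, truth, rng)
            traps.append(TrapRecord(trap_id, entry.series, spectrum, counts,
                                    is_reference=entry.is_reference))
            if entry.is_reference:
                reference_ids.append(trap_id)
    if len(reference_ids) != 2:
        raise GenerationError("the plan must contain exactly one reference colour "
                              "painted on two replicate traps")
    return ExperimentData(traps=traps, background=background, illuminant=illuminant,
                          reference_ids=(reference_ids[0], reference_ids[1]),
                          meta={"truth": truth, "seed": seed})


def _draw_count(mean: float, truth: GroundTruth, rng: np.random.Generator) -> float:
    if truth.noise == "none":
        return mean
    if truth.overdispersion is not None:
        k = truth.overdispersion
        return float(rng.negative_binomial(k, k / (k + mean))) if mean > 0 else 0.0
    return float(rng.poisson(mean))


# ---------------------------------------------------------------------------
# wheat-leaf generator

#: the incomplete 3 organic × 4 mineral-N factorial collapsed to 10 treatments
DEFAULT_TREATMENTS: list[tuple[str, int]] = [
    ("none", 0), ("none", 60), ("none", 110), ("none", 160),
    ("farmyard manure", 0), ("farmyard manure", 110), ("farmyard manure", 160),
    ("crop residues", 0), ("crop residues", 110), ("crop residues", 160),
]

_ORGANIC_DEPTH_BONUS = {"none": 0.0, "farmyard manure": 0.08, "crop residues": 0.05}

LEAF_GRID = make_grid(300.0, 700.0, 1.0)


def leaf_reflectance(depth: float, amp_mult: float = 1.0,
                     grid: np.ndarray = LEAF_GRID) -> Spectrum:
    """A two-parameter wheat-leaf reflectance curve on 300-700 nm.

    ``depth`` is the chlorophyll-absorption depth: larger depth suppresses the
    green reflectance peak at 550 nm (dark green, well-fertilized leaves);
    shallow absorption yields the yellowish-green of nitrogen-starved leaves.
    A red-edge shoulder rises towards 700 nm.
    """
    green_amp = 0.30 * np.exp(-1.1 * depth) * amp_mult
    value = (0.04
             + green_amp * _gauss(grid, 550.0, 38.0)
             + 0.30 * expit((grid - 710.0) / 12.0))
    return Spectrum(grid, np.clip(value, 0.0, 1.0))


def chlorophyll_depth(mineral_n: float, organic_level: str) -> float:
    """Monotone map from fertilization to chlorophyll-absorption depth."""
    return 0.25 + 0.75 * (mineral_n / 160.0) + _ORGANIC_DEPTH_BONUS[organic_level]


def generate_leaf_set(seed: int = 0, reps: int = 3, leaves_per_plot: int = 6,
                      noise_sd: float = 1.0,
                      treatments: Sequence[tuple[str, int]] | None = None
                      ) -> list[LeafSample]:
    """Generate the leaf-sampling campaign: 10 treatments × 3 plots × 6 leaves.

    ``noise_sd`` scales both the between-plot and the within-plot variation;
    0 makes all spectra within a treatment identical.
    """
    treatments = list(treatments) if treatments is not None else DEFAULT_TREATMENTS
    rng = np.random.default_rng(seed)
    leaves: list[LeafSample] = []
    plot_no = 0
    for organic, n_level in treatments:
        for rep in range(reps):
            plot_no += 1
            plot_id = f"P{plot_no:02d}"
            depth = chlorophyll_depth(n_level, organic)
            depth_plot = depth * (1.0 + noise_sd * 0.03 * rng.standard_normal())
            for leaf in range(leaves_per_plot):
                mult = 1.0 + noise_sd * 0.05 * rng.standard_normal()
                spectrum = leaf_reflectance(max(depth_plot, 0.01), max(mult, 0.2))
                leaves.append(LeafSample(
                    plot_id=plot_id, organic_level=organic, mineral_n=n_level,
                    leaf_id=f"{plot_id}-L{leaf + 1}", spectrum=spectrum,
                    chlorophyll_depth=max(depth_plot, 0.01)))
    return leaves
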