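"""Applying the colour-choice model to wheat-leaf spectra.

Leaf reflectance from a long-term fertilization trial (3 organic levels ×
4 mineral-N levels collapsed to 10 treatments, 3 field replicates, 6 leaves
per plot) is preprocessed to the standard 5 nm grid, converted to predicted
relative attractivity with a fitted split-regression model, aggregated to plot
means (no pseudo-replication of leaves) and tested across mineral-N levels
with one-way ANOVA and Tukey's HSD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .errors import InputError, RangeError
from .spectra import Spectrum, resample, smooth_moving_average

ORGANIC_LEVELS = ("none", "farmyard manure", "crop residues")
MINERAL_N_LEVELS = (0, 60, 110, 160)


@dataclass
class LeafSample:
    """One measured leaf: plot identity, fertilization treatment and spectrum."""

    plot_id: str
    organic_level: str
    mineral_n: int
    leaf_id: str
    spectrum: Spectrum
    y_hat: float | None = None
    chlorophyll_depth: float | None = None  # only set for synthetic leaves


def preprocess_leaf(raw: Spectrum, window_nm: float = 2.4,
                    grid_start: float = 300.0, grid_stop: float = 700.0,
                    step: float = 5.0) -> Spectrum:
    """Smooth with a 2.4 nm moving average, then resample to 300-700 nm at 5 nm."""
    lo, hi = raw.support
    if lo > grid_start or hi < grid_stop:
        raise RangeError(
            f"leaf spectrum covers {lo:g}-{hi:g} nm; need {grid_start:g}-{grid_stop:g} nm")
    return resample(smooth_moving_average(raw, window_nm), grid_start, grid_stop, step)


def predict_leaf_set(model, leaves: list[LeafSample], background: Spectrum,
                     illuminant: Spectrum,
                     preprocess: bool = True) -> list[LeafSample]:
    """Predicted attractivity for every leaf (returns new samples, inputs untouched).

    The background defaults to whatever is passed in — the model was calibrated
    against bare soil, and the same soil spectrum is the sensible default.
    """
    from .choice import predict_attractivity

    out = []
    for leaf in leaves:
        spec = preprocess_leaf(leaf.spectrum) if preprocess else leaf.spectrum
        y_hat = predict_attractivity(model, spec, background, illuminant)
        out.append(replace(leaf, spectrum=spec, y_hat=y_hat))
    return out


def plot_means(leaves: list[LeafSample]) -> pd.DataFrame:
    """Mean predicted attractivity per plot (the unit of replication)."""
    rows = [{"plot_id": l.plot_id, "organic_level": l.organic_level,
             "mineral_n": l.mineral_n, "y_hat": l.y_hat} for l in leaves]
    df = pd.DataFrame(rows)
    if df["y_hat"].isna().any():
        raise InputError("leaves must be predicted before aggregation")
    return (df.groupby(["plot_id", "organic_level", "mineral_n"], as_index=False)
              ["y_hat"].mean())


@dataclass
class TreatmentTest:
    """One-way ANOVA over mineral-N levels with Tukey HSD groupings."""

    anova_F: float
    anova_p: float
    tukey: pd.DataFrame  # pairwise comparisons
    letters: dict[int, str]  # compact letter display per N level
    summary: pd.DataFrame  # per-level mean and sd of plot means
    alpha: float


def treatment_test(leaves: list[LeafSample], alpha: float = 0.05,
                   factors: str = "mineral") -> TreatmentTest:
    """Test the fertilization effect on predicted attractivity.

    Analysis runs on plot means.  ``factors="mineral"`` (default) is a one-way
    ANOVA over mineral-N levels pooling organic treatments; ``"mineral+organic"``
    fits the additive two-way model (the Tukey contrast stays on mineral N).
    """
    df = plot_means(leaves)
    levels = sorted(df["mineral_n"].unique())
    if len(levels) < 2:
        raise InputError("need at least two mineral-N levels")
    counts = df.groupby("mineral_n")["plot_id"].count()
    if (counts < 2).any():
        raise InputError("every mineral-N level needs at least two plots")

    if factors == "mineral":
        fit = smf.ols("y_hat ~ C(mineral_n)", data=df).fit()
    elif factors == "mineral+organic":
        fit = smf.ols("y_hat ~ C(mineral_n) + C(organic_level)", data=df).fit()
    else:
        raise InputError("factors must be 'mineral' or 'mineral+organic'")
    table = sm.stats.anova_lm(fit, typ=2)
    F = float(table.loc["C(mineral_n)", "F"])
    p = float(table.loc["C(mineral_n)", "PR(>F)"])

    hsd = pairwise_tukeyhsd(df["y_hat"].to_numpy(), df["mineral_n"].to_numpy(),
                            alpha=alpha)
    tukey = pd.DataFrame(hsd.summary().data[1:], columns=hsd.summary().data[0])
    letters = compact_letter_display(levels, tukey)
    summary = (df.groupby("mineral_n")["y_hat"].agg(["mean", "std", "count"])
                 .reset_index())
    return TreatmentTest(F, p, tukey, letters, summary, alpha)


def compact_letter_display(levels: list[int],
                           tukey: pd.DataFrame) -> dict[int, str]:
    """Assign letters so that levels sharing a letter are not significantly
    different (maximal non-significant cliques, lettered by ascending level)."""
    different = {
        (row["group1"], row["group2"]) for _, row in tukey.iterrows() if row["reject"]
    }

    def compatible(group: tuple) -> bool:
        return all((a, b) not in different and (b, a) not in different
                   for a, b in itertools.combinations(group, 2))

    cliques: list[tuple] = []
    for size in range(len(levels), 0, -1):
        for combo in itertools.combinations(levels, size):
            if compatible(combo) and not any(set(combo) <= set(c) for c in cliques):
                cliques.append(combo)
    cliques.sort(key=lambda c: min(levels.index(v) for v in c))
    letters: dict[int, str] = {lv: "" for lv in levels}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for lv in clique:
            letters[lv] += letter
    return letters
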