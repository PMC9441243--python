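"""The piecewise opponent colour-choice model.

Relative catch y is modelled against the log ratio of green to blue photon
catch with a breakpoint fixed where the two catches are equal:

    y = b + a·log(G/B)   for G > B
    y = b                for G ≤ B

The left branch is flat because short-wavelength-dominated stimuli elicit the
baseline response only.  The blue receptor position is found by refitting the
model over a candidate peak grid and keeping the best coefficient of
determination; model completeness is checked by correlating the residuals with
every candidate receptor's photon catch.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import ComputationError, FitError, InputError
from .opponent import ComCorrelogram, correlogram, relative_catch
from .receptors import LAMBDA_GRID, PhotonCatchSet, make_template, photon_catch, \
    photon_catch_matrix
from .spectra import ExperimentData, Spectrum

_LOG_BASES = {"e": math.e, "10": 10.0}


def log_ratio(G: float | np.ndarray, B: float | np.ndarray,
              log_base: str = "e") -> float | np.ndarray:
    """log(G/B); natural log by default (the slope is base-dependent)."""
    if log_base not in _LOG_BASES:
        raise InputError("log_base must be 'e' or '10'")
    G = np.asarray(G, dtype=float)
    B = np.asarray(B, dtype=float)
    if np.any(G <= 0) or np.any(B <= 0):
        raise InputError("photon catches must be positive to take the log ratio")
    out = np.log(G / B) / math.log(_LOG_BASES[log_base])
    return float(out) if out.ndim == 0 else out


@dataclass
class SplitRegressionModel:
    """Fitted piecewise colour-choice model with a split at log(G/B) = 0."""

    a: float
    b: float
    a_se: float
    b_se: float
    lambda_max_G: float
    lambda_max_B: float
    r2: float
    n: int
    log_base: str = "e"
    trap_ids: list[str] | None = None
    residuals: np.ndarray | None = None
    left_slope: float | None = None  # only set by the diagnostic free-left fit
    left_slope_se: float | None = None
    #: relative standard error of the reference-trap normalization; the OLS
    #: a_se/b_se condition on the observed reference catch, but both fitted
    #: parameters scale with 1/n_ref, so this shared multiplicative
    #: uncertainty must be added for honest parameter uncertainty.
    scale_rel_se: float = 0.0

    @property
    def a_se_total(self) -> float:
        return float(np.hypot(self.a_se, self.a * self.scale_rel_se))

    @property
    def b_se_total(self) -> float:
        return float(np.hypot(self.b_se, self.b * self.scale_rel_se))

    def predict_from_ratio(self, x: np.ndarray | float) -> np.ndarray | float:
        x = np.asarray(x, dtype=float)
        out = self.b + self.a * np.maximum(0.0, x)
        return float(out) if out.ndim == 0 else out


def fit_split_regression(x: np.ndarray, y: np.ndarray,
                         lambda_max_G: float = 530.0,
                         lambda_max_B: float = 470.0,
                         log_base: str = "e",
                         trap_ids: list[str] | None = None,
                         free_left_slope: bool = False) -> SplitRegressionModel:
    """Least squares on the design {1, max(0, x)}.

    The split point is fixed at x = 0 by construction, so no breakpoint search
    is needed.  ``free_left_slope`` adds min(0, x) as a diagnostic regressor.

    Standard errors are heteroskedasticity-robust (HC3): catch counts have
    variance proportional to their mean, so the high-catch traps that anchor
    the slope are noisier than the classical OLS formula assumes.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise InputError("x and y must have equal length")
    n_pos = int(np.sum(x > 0))
    n_neg = int(np.sum(x <= 0))
    if n_pos < 3 or n_neg < 3:
        raise FitError(
            f"need >= 3 traps on each side of the split (got {n_pos} with G>B, "
            f"{n_neg} with G<=B)")
    cols = [np.maximum(0.0, x)]
    if free_left_slope:
        cols.append(np.minimum(0.0, x))
    X = sm.add_constant(np.column_stack(cols))
    fit = sm.OLS(y, X).fit(cov_type="HC3")
    sst = float(np.sum((y - y.mean()) ** 2))
    ssr = float(np.sum(fit.resid ** 2))
    r2 = 1.0 - ssr / sst if sst > 0 else 0.0
    model = SplitRegressionModel(
        a=float(fit.params[1]), b=float(fit.params[0]),
        a_se=float(fit.bse[1]), b_se=float(fit.bse[0]),
        lambda_max_G=lambda_max_G, lambda_max_B=lambda_max_B,
        r2=float(np.clip(r2, 0.0, 1.0)), n=int(x.size), log_base=log_base,
        trap_ids=trap_ids, residuals=np.asarray(fit.resid))
    if free_left_slope:
        model.left_slope = float(fit.params[2])
        model.left_slope_se = float(fit.bse[2])
    return model


def model_inputs(experiment: ExperimentData, green_peak: float = 530.0,
                 blue_peak: float = 470.0, taxon: str | None = None,
                 log_base: str = "e", include_reference: bool = False
                 ) -> tuple[list[str], np.ndarray, np.ndarray]:
    """(trap ids, log ratio x, relative catch y) for the fit-eligible traps."""
    rel = relative_catch(experiment, taxon)
    peaks = [blue_peak] if np.isclose(blue_peak, green_peak) else [blue_peak, green_peak]
    pcs = photon_catch_matrix(experiment, np.asarray(peaks, float))
    keep = [t.trap_id for t in experiment.traps
            if include_reference or not t.is_reference]
    index = {t: i for i, t in enumerate(experiment.trap_ids)}
    rows = np.array([index[t] for t in keep])
    G = pcs.column(green_peak)[rows]
    B = pcs.column(blue_peak)[rows]
    x = log_ratio(G, B, log_base)
    return keep, np.asarray(x), rel.subset(keep)


def fit_choice_model(experiment: ExperimentData, green_peak: float = 530.0,
                     blue_peak: float = 470.0, taxon: str | None = None,
                     log_base: str = "e",
                     include_reference: bool = False) -> SplitRegressionModel:
    """Fit the split regression to an experiment at fixed receptor peaks."""
    ids, x, y = model_inputs(experiment, green_peak, blue_peak, taxon,
                             log_base, include_reference)
    model = fit_split_regression(x, y, green_peak, blue_peak, log_base, ids)
    model.scale_rel_se = _reference_scale_rel_se(experiment, taxon)
    return model


def _reference_scale_rel_se(experiment: ExperimentData,
                            taxon: str | None) -> float:
    """Shared multiplicative uncertainty from the reference normalization: the
    mean of two count-noise references has relative s.e. 1/sqrt(r1 + r2)."""
    counts = experiment.counts_total(taxon)
    all_ids = experiment.trap_ids
    ref_total = float(sum(counts[all_ids.index(r)]
                          for r in experiment.reference_ids))
    return 1.0 / math.sqrt(ref_total) if ref_total > 0 else 0.0


@dataclass
class BluePeakScan:
    """Result of optimizing the blue receptor position over a candidate grid."""

    lambda_max_B: float
    model: SplitRegressionModel
    table: pd.DataFrame  # lambda_max, r2, a, b per successful candidate
    skipped: list[float] = field(default_factory=list)
    ties: list[float] = field(default_factory=list)
    degenerate: bool = False


def optimize_blue_peak(experiment: ExperimentData, green_peak: float = 530.0,
                       candidates: np.ndarray = LAMBDA_GRID,
                       taxon: str | None = None, log_base: str = "e",
                       include_reference: bool = False) -> BluePeakScan:
    """Refit the split regression for every candidate blue peak; keep the best r².

    Ties are broken toward the smaller wavelength and reported.  Candidates
    whose fit fails (e.g. all traps on one side of the split) are skipped with
    a warning.
    """
    rel = relative_catch(experiment, taxon)
    pcs = photon_catch_matrix(experiment, np.asarray(candidates, float))
    keep = [t.trap_id for t in experiment.traps
            if include_reference or not t.is_reference]
    index = {t: i for i, t in enumerate(experiment.trap_ids)}
    rows = np.array([index[t] for t in keep])
    y = rel.subset(keep)
    G = pcs.column(green_peak)[rows]

    results: list[tuple[float, SplitRegressionModel]] = []
    skipped: list[float] = []
    for lm in pcs.lambda_grid:
        B = pcs.column(lm)[rows]
        try:
            x = log_ratio(G, B, log_base)
            model = fit_split_regression(x, y, green_peak, float(lm), log_base, keep)
        except (FitError, InputError) as exc:
            warnings.warn(f"blue-peak candidate {lm:g} nm skipped: {exc}")
            skipped.append(float(lm))
            continue
        model.scale_rel_se = _reference_scale_rel_se(experiment, taxon)
        results.append((float(lm), model))
    if not results:
        raise FitError("no blue-peak candidate produced a valid fit")

    table = pd.DataFrame({
        "lambda_max": [lm for lm, _ in results],
        "r2": [m.r2 for _, m in results],
        "a": [m.a for _, m in results],
        "b": [m.b for _, m in results],
    })
    best_r2 = table["r2"].max()
    tied = table.loc[np.isclose(table["r2"], best_r2, atol=1e-12), "lambda_max"]
    best_lm = float(tied.min())
    best_model = dict(results)[best_lm]
    return BluePeakScan(
        lambda_max_B=best_lm, model=best_model, table=table, skipped=skipped,
        ties=sorted(float(v) for v in tied) if len(tied) > 1 else [],
        degenerate=bool(best_r2 <= 0.0))


def predict_attractivity(model: SplitRegressionModel, spectrum: Spectrum,
                         background: Spectrum, illuminant: Spectrum) -> float:
    """Predicted relative catch of an arbitrary stimulus spectrum."""
    tG = make_template(model.lambda_max_G)
    tB = make_template(model.lambda_max_B)
    G = photon_catch(spectrum, tG, illuminant, background)
    B = photon_catch(spectrum, tB, illuminant, background)
    return float(model.predict_from_ratio(log_ratio(G, B, model.log_base)))


@dataclass
class ValidationResult:
    """Observed-vs-predicted regression for a transferred model."""

    slope: float
    intercept: float
    r2: float
    n: int


def cross_validate(model: SplitRegressionModel, experiment2: ExperimentData,
                   taxon: str | None = None,
                   include_reference: bool = False) -> ValidationResult:
    """Apply a fitted model to a second experiment and regress observed on predicted."""
    ids, x, y_obs = model_inputs(experiment2, model.lambda_max_G,
                                 model.lambda_max_B, taxon, model.log_base,
                                 include_reference)
    y_pred = model.predict_from_ratio(x)
    fit = sm.OLS(y_obs, sm.add_constant(y_pred)).fit()
    return ValidationResult(slope=float(fit.params[1]),
                            intercept=float(fit.params[0]),
                            r2=float(fit.rsquared), n=int(fit.nobs))


@dataclass
class CompletenessReport:
    """Residual correlogram of a fitted model plus the summed-input check."""

    correlogram: ComCorrelogram
    summed_r: float
    summed_p: float
    incomplete: bool
    alpha: float

    @property
    def max_r(self) -> float:
        return float(self.correlogram.r.max())

    @property
    def max_r_lambda(self) -> float:
        return self.correlogram.lambda_max_r

    @property
    def min_r(self) -> float:
        return float(self.correlogram.r.min())


def completeness_check(model: SplitRegressionModel, experiment: ExperimentData,
                       lambda_grid: np.ndarray = LAMBDA_GRID,
                       summed_peaks: tuple[float, float, float] = (350.0, 470.0, 530.0),
                       taxon: str | None = None, include_reference: bool = False,
                       alpha: float = 0.05,
                       residuals: np.ndarray | None = None) -> CompletenessReport:
    """Test whether model residuals still carry spectral information.

    Residuals u_t = y_t − ŷ_M are correlated with the photon catch of every
    candidate receptor and with the summed input of the UV, blue and green
    receptors.  Any per-wavelength significance (no multiplicity correction)
    flags the model incomplete.
    """
    ids, x, y = model_inputs(experiment, model.lambda_max_G, model.lambda_max_B,
                             taxon, model.log_base, include_reference)
    u = np.asarray(residuals, float) if residuals is not None \
        else y - model.predict_from_ratio(x)
    full_grid = np.unique(np.concatenate([np.asarray(lambda_grid, float),
                                          np.asarray(summed_peaks, float)]))
    pcs_all = photon_catch_matrix(experiment, full_grid)
    index = {t: i for i, t in enumerate(experiment.trap_ids)}
    rows = [index[t] for t in ids]
    pcs = PhotonCatchSet(ids, pcs_all.lambda_grid, pcs_all.P[rows])
    grid_cols = [j for j, lm in enumerate(pcs.lambda_grid)
                 if np.any(np.isclose(lm, lambda_grid))]
    corr = correlogram(u, PhotonCatchSet(ids, pcs.lambda_grid[grid_cols],
                                         pcs.P[:, grid_cols]))
    summed = sum(pcs.column(lm) for lm in summed_peaks)
    res = stats.pearsonr(u, summed)
    incomplete = bool(np.any(corr.p < alpha) or res.pvalue < alpha)
    return CompletenessReport(corr, float(res.statistic), float(res.pvalue),
                              incomplete, alpha)


@dataclass
class GroupComparison:
    """ANCOVA of the split regression across taxon groups."""

    groups: list[str]
    per_group: pd.DataFrame  # group, a, b, n
    slope_F: float
    slope_p: float
    intercept_F: float
    intercept_p: float


def compare_groups(experiment: ExperimentData,
                   grouping: dict[str, str] | None = None,
                   green_peak: float = 530.0, blue_peak: float = 470.0,
                   log_base: str = "e",
                   include_reference: bool = False) -> GroupComparison:
    """Covariance analysis: common slope and common intercept F-tests.

    ``grouping`` maps taxon label → group label; unmapped taxa join "other".
    Groups whose own reference catch is zero or that have too few traps on
    either side of the split are excluded with a warning.
    """
    if grouping is None:
        grouping = {"Myzus persicae": "M. persicae",
                    "Brevicoryne brassicae": "B. brassicae"}
    group_taxa: dict[str, list[str]] = {}
    for taxon in experiment.taxa:
        group_taxa.setdefault(grouping.get(taxon, "other"), []).append(taxon)

    ids, x, _ = model_inputs(experiment, green_peak, blue_peak, None,
                             log_base, include_reference)
    xpos = np.maximum(0.0, x)
    frames = []
    per_group_rows = []
    for group, taxa in sorted(group_taxa.items()):
        try:
            y = _group_relative(experiment, taxa, ids)
            m = fit_split_regression(x, y, green_peak, blue_peak, log_base)
        except (ComputationError, FitError) as exc:
            warnings.warn(f"group '{group}' excluded from ANCOVA: {exc}")
            continue
        per_group_rows.append({"group": group, "a": m.a, "b": m.b, "n": m.n})
        frames.append(pd.DataFrame({"y": y, "xpos": xpos, "group": group}))
    if len(frames) < 2:
        raise FitError("need at least two fit-eligible groups for the ANCOVA")
    data = pd.concat(frames, ignore_index=True)

    full = smf.ols("y ~ C(group) + C(group):xpos", data=data).fit()
    common_slope = smf.ols("y ~ C(group) + xpos", data=data).fit()
    slope_test = sm.stats.anova_lm(common_slope, full)
    common_intercept = smf.ols("y ~ xpos", data=data).fit()
    intercept_test = sm.stats.anova_lm(common_intercept, common_slope)
    return GroupComparison(
        groups=[r["group"] for r in per_group_rows],
        per_group=pd.DataFrame(per_group_rows),
        slope_F=float(slope_test["F"].iloc[1]),
        slope_p=float(slope_test["Pr(>F)"].iloc[1]),
        intercept_F=float(intercept_test["F"].iloc[1]),
        intercept_p=float(intercept_test["Pr(>F)"].iloc[1]))


def _group_relative(experiment: ExperimentData, taxa: list[str],
                    ids: list[str]) -> np.ndarray:
    """Relative catch for a taxon group: summed counts over the group's taxa,
    normalized by the group's own mean reference catch."""
    counts = np.sum([experiment.counts_total(t) for t in taxa], axis=0)
    all_ids = experiment.trap_ids
    ref = float(np.mean([counts[all_ids.index(r)] for r in experiment.reference_ids]))
    if ref <= 0:
        raise ComputationError(f"group {taxa} has zero reference catch")
    y = counts / ref
    index = {t: i for i, t in enumerate(all_ids)}
    return y[[index[t] for t in ids]]
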