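# Methods

This note records the scientific model implemented by `aphidvision`, the
design of the synthetic-data generator used to exercise it, and the numerical
and statistical choices that matter for interpreting its output.

## 1. Receptor model and photon catch

Each photoreceptor class is a Gaussian sensitivity curve

    S(λ) = exp(−4 ln 2 · ((λ − λmax) / (0.18 λmax))²),

i.e. peak sensitivity 1 at λmax and a full width at half maximum fixed at
0.18·λmax. No secondary (beta) absorption peak is modelled. Candidate
receptors live on a 10 nm grid from 320 to 610 nm; the shape function is
pluggable so a rhodopsin nomogram could replace the Gaussian without touching
anything else.

The photon catch of stimulus reflectance R against background reflectance
R_b under illuminant I is

    P = ∫ R(λ) S(λ) I(λ) dλ / ∫ R_b(λ) S(λ) I(λ) dλ.

The background normalization makes P dimensionless, equal to 1 for the
background itself, linear in any rescaling of the stimulus and invariant to
rescaling the illuminant. The illuminant is CIE D65, converted to photon
units (multiplied by λ) because photoreceptors count photons, not energy,
and normalized to 1 at 560 nm. Integration is trapezoidal on a shared 1 nm
grid: the measured spectra are piecewise linear (5 nm data), so the fine grid
only sharpens the quadrature of the smooth Gaussian factor; agreement with a
0.1 nm brute-force integral is ~5·10⁻⁵ relative.

## 2. The opponent choice model

With G and B the photon catches of the green (530 nm) and blue (470 nm)
receptors, relative catch y (trap catch divided by the mean catch of two
identical yellow reference traps) follows the split regression

    y = b + a·ln(G/B)  for G > B,    y = b  otherwise,

with the breakpoint fixed at G = B — the design matrix is simply
{1, max(0, ln G/B)}, so no breakpoint search is needed. The blue receptor
position is identified by refitting over the whole candidate grid and keeping
the best r² (ties break toward shorter wavelengths; candidates that put
fewer than 3 traps on either side of the split are skipped with a warning).

**Standard errors.** Two count-noise effects make naive OLS standard errors
anti-conservative, and both are handled analytically:

- Counts are Poisson-like, so Var(y_t) grows with the expected catch; the
  slope is anchored by the high-catch yellow traps. The regression therefore
  reports heteroskedasticity-robust (HC3) standard errors.
- Every y_t shares the same noisy denominator (the mean reference catch), so
  the fitted a and b carry a common multiplicative error with relative s.e.
  1/√(r₁+r₂) for reference counts r₁, r₂. The model exposes `a_se_total`
  and `b_se_total`, which add this component in quadrature.

With both corrections, simulation z-scores for a and b have standard
deviation ≈ 1.0 and the 2-s.e. intervals cover the generating values at
their nominal rate.

**Group comparison caveat.** `compare_groups` runs a textbook ANCOVA
(common-slope and common-intercept F-tests) on per-group relative catches.
Each group is normalized by its own reference catch, so the shared
multiplicative error above perturbs each group's effective slope by a few
percent; with ~140 traps per group the pooled F-test can detect this
normalization artifact. Treat small p-values near the null with caution and
read the per-group parameter table alongside the test.

## 3. Two-step opponency evidence

Step one fits a Gompertz dose-response y = a·exp(b·exp(c·G)) to the
yellow-to-black series only — colours mixed from yellow and black paint,
with negligible blue/UV reflectance, that stimulate essentially only the
green receptor. The fit is multi-start nonlinear least squares (a₀ = max y,
c₀ over a fixed grid, b₀ solved from the darkest trap); degenerate fits
(flat data, near-singular Jacobian) raise instead of returning garbage.

Step two applies the green-only model to every trap and correlates the
residuals e* = y − ŷ_G with the photon catch of each candidate receptor.
Under a green-only hypothesis these correlations vanish; a deep negative
well at short wavelengths indicates an inhibitory input. On default
synthetic data the minimum lands at 450 nm with r ≈ −0.84. Note the
correlogram minimum need not coincide exactly with the best-fitting blue
receptor position (470 nm): the correlogram convolves the inhibitory action
spectrum with the strong correlations between neighbouring receptors and
with the stimulus set's blue-band placement.

## 4. Receptor-blind PLSR

As a check that does not presuppose any receptor model, raw counts are
regressed on raw reflectance (320–700 nm, 5 nm grid) by PLS1 using the
NIPALS algorithm with mean-centering only (the columns share units, so no
autoscaling). Coefficients for k components are B_k = W_k(P_kᵀW_k)⁻¹q_k;
leave-one-out RMSEP supports choosing k (default 3). The implementation is
verified in tests against an independent SVD-based PLS1 and against
scikit-learn to ~1e-14.

The normalized coefficient spectrum is scanned for strict interior local
maxima and for the longest run of negative coefficients. On the default
synthetic experiment the maximum falls at 530 nm and the negative band spans
the blue/UV region — the opponent structure recovered without receptors.

**Why the stimulus set matters.** The location of a PLSR coefficient peak is
a property of the stimulus covariance as much as of the behaviour.
Experiments during development showed that adding colours with their own
pigment features near or above 530 nm (a green paint peaking at 550 nm, red
edges, slow yellow edges) drags the coefficient maximum to 545–585 nm even
though the generating behaviour is unchanged: the regression localizes on
whatever spectral feature carries the response variance. The primary
synthetic plan therefore uses only yellow, blue, white and black paints —
the classic trap-colour set — whose steep yellow edge near 510 nm leaves the
green-receptor flank as the only response-carrying feature. Hue-richer
colours (green, red, UV-reflective) are provided in `extended_series_plan`
and are intended for validating a fitted model, not for the receptor-blind
analysis.

## 5. Synthetic-data generator

The generator exists to make every analysis runnable with known ground
truth; it is deliberately simple and its realism limits are stated here.

- **Colours.** 70 colours × 2 replicate traps = 140 traps: one pure-yellow
  reference colour (2 traps), a 10-colour yellow-to-black series (the
  Gompertz training set, 20 traps, giving 17 residual degrees of freedom),
  and saturation/brightness series (yellow-white, yellow-blue, blue-black,
  blue-white, grey) filling the budget. Paints mix by a weighted geometric
  mean of base reflectances — a cheap surrogate for subtractive pigment
  mixing in which dark pigments dominate, as they do physically. A seeded
  low-frequency ripple (< ±2.5%) individualizes base paints per seed.
- **Background and illuminant.** Bare soil is a linear ramp from 0.05 at
  320 nm to 0.25 at 950 nm; the illuminant is the packaged D65.
- **Counts.** Expected count is n_ref_mean·(b + a·max(0, ln G/B)) per
  coloured trap and exactly n_ref_mean per reference trap — the references
  define the unit of relative catch and are excluded from fits by default.
  Counts are split across taxa by fixed shares and drawn Poisson (or
  negative binomial if overdispersion is requested); per-taxon (a, b)
  overrides support group-comparison studies.
- **Leaves.** A wheat-leaf spectrum is a flat baseline plus a green
  reflectance peak at 550 nm whose amplitude decays exponentially with
  chlorophyll absorption depth, plus a red-edge shoulder. Depth increases
  monotonically with mineral N (0→160 kg/ha) and organic fertilization.
  The campaign is 10 treatments × 3 plots × 6 leaves; analysis runs on plot
  means to avoid pseudo-replication.
- **Limits.** Paint spectra are smooth two-parameter families, not measured
  paints; counts are independent across traps (no spatial or temporal
  structure, no trap-position effects); leaf spectra have no water or
  structural absorption features. None of these affect the identifiability
  properties the generator is designed to exercise.

## 6. Leaf application

Raw leaf spectra are smoothed with a 2.4 nm moving average, resampled to the
300–700 nm / 5 nm grid, converted to predicted relative attractivity with
the fitted split regression (soil background, D65), averaged per plot, and
tested across mineral-N levels by one-way ANOVA plus Tukey's HSD with a
compact letter display. Predicted attractivity decreases strictly with
chlorophyll depth — well-fertilized, darker-green leaves are less attractive
to spring migrants, the agronomically relevant conclusion.

## 7. Problem sizes and runtime

All default analyses are small: 140 traps × 77 wavelengths, 30 candidate
receptors, 180 leaves. Everything runs in seconds on one CPU; the full
50-seed acceptance battery takes well under a minute.
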