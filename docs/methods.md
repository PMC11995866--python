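# Methods

This package implements the quantitative analysis chain used to characterize
a light-driven anion-pumping rhodopsin and its mutants: global kinetic
fitting of flash-photolysis transient-absorption matrices under a sequential
photocycle model, constrained one- and two-site binding-isotherm fitting of
anion-titration spectra, and an initial-slope transport-activity statistic
with expression normalization, many-to-one significance testing and
cross-anion correlation.  Because raw spectra for such studies are typically
not deposited, every stage ships with a seeded synthetic-data generator that
emulates the measurement, so correctness is established by parameter
recovery: plant known values, fit, compare.

## Photocycle model

After flash excitation the pigment relaxes through a chain of
spectroscopically distinct intermediates.  We model the chain as irreversible
first-order steps,

    X1 -> X2 -> ... -> Xn -> ground,    dc_j/dt = c_{j-1}/tau_{j-1} - c_j/tau_j,

with the first intermediate at unit concentration at t = 0 (photoexcitation
treated as instantaneous: the earliest observation, 0.01 ms, does not resolve
the formation of the first state).  The concentrations have the closed-form
Bateman solution; coefficients are assembled from the rate differences, and
(near-)coincident rates (relative spacing below 1e-9) switch to a matrix
exponential of the bidiagonal rate matrix, which is exact for repeated roots.
Concentrations are clipped of sub-1e-12 negative round-off.

For the wild-type pump the observable chain is K -> L -> O -> ground; any
distinction between N and O states is collapsed into the single O species
(the data cannot separate them at this time resolution).

**Measurement model.**  The difference absorbance is

    dA(lambda, t) = sum_j SADS_j(lambda) c_j(t) = sum_i DADS_i(lambda) e^{-t/tau_i},

where SADS are species-associated difference spectra and DADS the
decay-associated amplitudes of the exponential basis.  The two
representations are connected by the triangular Bateman coefficient matrix
(`dads = sads @ M`); the map is exactly invertible whenever the taus are
distinct.

**Global fitting (variable projection).**  `fit_global` optimizes the shared
time constants in log space (positivity by construction) with
`scipy.optimize.least_squares`; at every candidate tau vector the
per-wavelength amplitudes — which enter linearly — are solved exactly by
least squares, so the nonlinear search runs over only `n_exp` parameters.
Initialization is a multi-start log grid: `n_exp` log-spaced centers across
the observed time range, shifted by eight offsets spanning +/-0.9 decades;
the best residual sum of squares wins and ties go to the lexicographically
smallest tau vector.  Fitting is unweighted least squares on the provided
(log-spaced) samples; taus are reported sorted ascending.  Non-convergence
returns the best candidate flagged `converged=False` rather than raising;
fitted taus closer than a ratio of 1.05 set a `degenerate` flag and a
warning, since the model order is then too high for the data.  Standard
errors for the taus come from the Gauss-Newton covariance of the projected
residual, scaled by the residual variance with the amplitude count included
in the degrees of freedom — an approximation adequate for well-separated
taus.  Both full-matrix and selected-trace fitting (e.g. the 470/570/600 nm
traces classically used for this pigment) are supported; full-matrix is the
default and is what the recovery numbers quote.

**Intermediate assignment.**  Fitted SADS are labeled by band position: a
positive maximum at 440-500 nm is L-like (blue-shifted), at 590-640 nm
O-like (red-shifted); the fastest unlabeled species with a positive band
beyond 520 nm is K-like.  A species with no positive lobe above the floor is
`bleach-only`.  The floor combines 0.1% of the global SADS amplitude with
five robust sigmas estimated from the spectrum's first differences (dense
grids only; with a handful of selected wavelengths the differences reflect
band structure, not noise).  Labels are never duplicated — a second
candidate for a taken label keeps a numbered fallback.

**O-intermediate accumulation.**  The score is the largest positive SADS
value in 590-640 nm (any species) divided by the deepest bleach in
520-590 nm.  The threshold defaults to 0.10: in the shipped scenarios the
wild type and H167Q score about 0.5 while the O-free H167A/H167I scenarios
score below 0.05, so the decision is robust to the planted noise level.
Zero bleach depth makes the score undefined; the detector then returns
"not accumulating" with a warning rather than a division error.

## Binding isotherms

Anion binding shifts the visible band (blue for chloride, red for sulfate in
the wild type), giving two-lobed difference spectra against the salt-free
reference.  The titration curve is fitted with the hyperbolic
(Hill-exponent-1) isotherms

    one-site:  dA(x) = x / (Kd + x)
    two-site:  dA(x) = Vmax1 x / (Kd1 + x) + (1 - Vmax1) x / (Kd2 + x)

with the saturating amplitude fixed at 1 (the convention under which the
reported constants were obtained).  An optional Hill exponent exists but
defaults to 1 and is excluded from model selection.  Fits run in linear
concentration space and include the c = 0 point; Kd is log-parameterized for
positivity; the two-site fit uses the identifiability convention Kd1 <= Kd2
and a multi-start over spread initial Kd pairs.

**Curve extraction and normalization.**  The tracked wavelength is the
dominant lobe of the highest-concentration difference spectrum.  Three
details matter at realistic noise:

1. *Selection decoupling.*  The lobe is located on the span between the
   highest and lowest nonzero concentration columns.  Selecting on the raw
   difference against the reference would prefer wavelengths where the
   reference column's noise inflates the lobe — and that same reference
   noise is a common additive offset on every curve point, which biases the
   fitted Kd low (we measured about -45% before decoupling).
2. *Finite bandwidth.*  Reads use a 10 nm boxcar around the tracked
   wavelength, emulating the slit bandwidth of a scanning
   spectrophotometer; a single-pixel read leaves the curve dominated by one
   noise draw per concentration.
3. *Both lobes.*  When the difference spectrum has a positive and a negative
   lobe, the curve is their difference, doubling the signal; this is the
   absorbance change "at the peak wavelengths" of the difference spectrum.

Because the constrained fits fix the plateau at 1, the extracted curve is
divided by the plateau of a provisional unconstrained fit (free Vmax) rather
than by the largest observed point, so the normalization is consistent even
for sub-saturating titrations.  The provisional model defaults to one-site;
for curves known or suspected to be biphasic, `provisional="two_site"` (or
`"auto"`, which picks by AICc) avoids the biased plateau a one-site
provisional fit produces on strongly two-site data.

The two-site log-Kds are bounded to within two decades of the sampled
concentration range: a site with Kd far outside the measured window is
amplitude-degenerate, and unbounded fits occasionally ran to Kd ~ 1e5 mM on
noisy curves.  A fitted Kd pair closer than 5% is flagged
`reduces-to-one-site`.

**Model selection** fits both isotherms and compares small-sample-corrected
AICc; the two-site model must win by more than 2 to be preferred (parsimony
on ties), and is refused outright below five positive concentrations.  AICc
was chosen over an F-test because the constrained models are not nested in
the usual sense (the amplitude constraint, not a zeroed parameter, separates
them).

**Diagnostics.**  `classify_shift` compares the wavelengths of the positive
and negative lobes of the highest-concentration difference column; the
no-shift floor is a robust noise sigma (from first differences — spectral
bands are smooth, so differencing isolates noise) scaled by the expected
extreme of n Gaussian draws plus one sigma of margin.  `find_isosbestic`
reports the in-window wavelength minimizing the maximum |dA| across columns,
only if that maximum stays below 5% of the global |dA| maximum — a pinned
crossing is the signature of a clean two-state titration, and its absence
flags a multi-state series.

## Transport activity

The activity statistic is the slope of the extracellular pH change over the
first 10 s of illumination (alkalization positive, matching the secondary
proton counterflux that accompanies inward anion transport).  A linear
baseline drift is estimated by ordinary least squares on the
pre-illumination segment (at least 30 s required) and subtracted from the
light-window OLS slope; the uncorrected mode is available but drift
correction is the default, since slow acidification drifts otherwise bias
the short window.  Windows reaching past light-off are truncated with a
warning.

Panels of replicate slopes are normalized per replicate by the mutant's
relative expression level (WT = 1), aggregated as mean +/- SD with n
recorded, and expressed relative to WT.  Each mutant is compared with WT by
a permutation maxT many-to-one procedure: Welch t statistics per mutant, a
family-wise null built by permuting the pooled observations and recording
the maximum |t| over the family, and adjusted p-values from that null.  This
is the distribution-free analogue of Dunnett's test, preferred here because
replicate counts of 3-5 make multivariate-t quantiles fragile.  The null
simulation in the test suite puts the family-wise type-I error at ~0.05-0.06
against the 0.07 acceptance bound.  Cross-anion agreement is summarized by
the Pearson correlation of per-mutant normalized chloride and sulfate
activities with an OLS regression line; exclusions are possible but nothing
is excluded by default.

## Synthetic data

All generators draw from `numpy.random.default_rng(seed)`; identical
scenario and seed reproduce a dataset bit for bit.

* **Spectra** are Gaussian bands in wavelength space.  Real retinylidene
  bands are nearer Gaussian in energy with vibronic structure; wavelength
  Gaussians reproduce positions, widths and shifts, which is all the
  analyses consume.  Titration spectra mix an unbound and a bound band with
  the isotherm fraction; transient matrices are SADS (positive intermediate
  band minus ground-state bleach band) times Bateman concentrations.
* **Noise** is homoscedastic Gaussian per matrix cell; no shot noise,
  photoselection or instrument response convolution.  Transient scenarios
  support `noise_relative`, scaling sigma to the clean matrix maximum
  (1% in the shipped scenarios).
* **pH traces** are a linear drift plus a linear light-on ramp, with a
  single-exponential relaxation back to the drift line after light-off (the
  relaxation shape does not touch the 0-10 s statistic).
* **Panels** draw replicate slopes as true * (1 + cv * N(0,1)); the planted
  activities are raw slopes, so they scale with expression and the
  normalization stage is actually exercised.  `gen_correlated_panel` draws
  per-mutant (Cl, SO4) activity pairs with a bivariate-normal correlated
  component (rho = 0.94 by default) for correlation-recovery experiments.

**Scenario catalog.**  Binding constants and time constants in the shipped
scenarios are the reported values for the wild type and the Arg71/His167
mutants (one-site Kd: WT-Cl 0.59 mM, WT-SO4 3.6 mM, R71A-Cl 4.5 mM,
H167A-SO4 6.5 mM; two-site pairs 0.094/2.2 mM and 1.2/82 mM; taus
0.050/2.2/12 ms for the wild type and 0.20/16/65 ms for H167Q).  Band
positions are approximate by necessity — the source spectra are published
as figures — and are package choices: ground bleach near 558 nm, L band at
450-470 nm, O band at 620 nm, and K modeled as a narrow (sigma 10 nm)
shoulder at ~575 nm, red of the bleach but clear of the 590-640 nm O
window so that O-free scenarios score near zero.  The two-site amplitude
split Vmax1 = 0.6 is arbitrary (no split is reported) and the H167A/H167I
taus are plausible placeholders (none are reported).  In the O-free
scenarios the third species is bleach-only — zero positive-band amplitude
with partial bleach — rather than an all-zero spectrum, which would make
the third exponential unidentifiable; physically this is ground-state
recovery without a red-absorbing state.  Titrations use 16 log-spaced
concentrations over 0.01-1000 mM plus the 0 mM reference at noise sigma
0.02 (two-site: 20 points over 0.001-1000 mM at sigma 0.01); transients use
the 420-710 nm / 10 nm grid with 60 log-spaced times over 0.01 ms-4 s.

**What passing recovery does not show.**  The generators share their
forward models with the fitters (up to noise), so recovery certifies the
estimation machinery — identifiability, bias, convergence — under the
stated noise, not robustness to model misfit: baseline wander, wavelength
calibration error, branched or reversible photocycles, heteroscedastic or
correlated noise, and pH-electrode nonlinearity are all outside the
emulation.

## Numerical choices

* Bateman/expm degeneracy switch at relative rate spacing 1e-9; the
  continuity of the solution across the switch is tested against the
  repeated-root limit t k e^{-kt}.
* Variable-projection amplitudes via `numpy.linalg.lstsq`; tau search via
  Levenberg-Marquardt in log-tau.
* One-site fits fall back to a 10^4-point log-grid search if the local
  optimizer fails (flagged, never silent); the grid is also the test oracle.
* AICc uses k = n_params + 1 (noise variance counts).
* Seeds: derived per-replicate seeds stay below 2^31.

## Problem sizes

Recovery experiments use 20 seeded replicates per scenario; the transient
matrices are 30 wavelengths x 60 times; the permutation test uses 1000-5000
permutations (vectorized); the null-calibration simulation uses 500
replicates.  The full test suite runs in well under a minute on one CPU.

## Known limitations

* The sequential chain is strictly irreversible and unbranched; back
  reactions and parallel cycles are out of scope.
* SADS standard errors are not propagated from the tau uncertainty.
* The isosbestic check reports a single wavelength, not a confidence
  interval.
* Dunnett-style control is permutation-based; with n = 3 replicates the
  permutation null is coarse and adjusted p-values are conservative.
* The two-site model fixes the total amplitude at 1; partially saturating
  titrations rely on the provisional-fit plateau, which inherits that
  model's bias if the true binding has more than two classes.
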