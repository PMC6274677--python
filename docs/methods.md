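# Methods

## Signal model and scales

A frozen protein solution contains two proton populations.  Rigid
protons (protein backbone/side chains and ice) dephase on the ~10 µs
scale with a solid-like decay, modelled as a Gaussian
`F·exp(−t²/2τ_f²)`; mobile (rotating) water protons are motionally
narrowed and decay slowly, modelled as a single exponential
`S·exp(−t/τ_s)` with τ_s in the hundreds of µs.  The spectrometer
records nothing during the dead time (6–8 µs after the 90° pulse), so
both amplitudes at t = 0 are obtained by evaluating the *fitted model*
at t = 0 — never by polynomial extension of the visible decay.  These
two shapes are the standard wide-line forms; the fast shape is
selectable (`FidModelConfig.fast_shape`) because real solid lineshapes
sit between Gaussian and exponential.

The slow amplitude is proportional to n·B₀/T (Curie law), so
amplitudes are corrected by T/T_ref before use; dividing by the
total-water reference — by default the same sample measured above 0 °C,
where all water is mobile — gives the mobile fraction n, independent of
the arbitrary spectrometer unit.  How the reference was obtained
(above-melting trace vs. an externally supplied value, e.g. gravimetric
water content) is recorded in the melting diagram's metadata, because
the published procedure does not fix it.

Temperatures are held internally in kelvin; files declare °C or K
explicitly.  The dimensionless energy axis is T_fn = T/273.15.  The
Waugh–Fedin constant c in E₀ = c·R·T is calibrated from the latent
heat of ice, c = 6.01 kJ/mol / (R·273.15 K) = 2.6455 with
R = 8.317 J/(mol·K); downstream arithmetic uses the full-precision
value while reports round to 2.65.  R is kept at 8.317 (not CODATA
8.314) so worked numbers match the published tables; all constants are
a single overridable configuration object.

## Fitting the melting diagram

The model is piecewise: n = 0 below the onset; a step of one grid bin
to the plateau level A; A on [T_fno, T_fne]; and a power-series rise
above.  Estimation proceeds in four stages.

**Noise.**  σ_n comes from stated per-point errors when present,
otherwise from a robust MAD estimate of consecutive differences
(1.4826·MAD/√2), which the step and the smooth rise barely perturb.

**Onset.**  The threshold (default 3σ_n above zero, floored at 1e−6)
selects the first crossing interval; the reported onset is the linear
interpolation to the half-rise level of that interval.  A pure
threshold crossing localizes a sharp step at its lower bracketing point
with a bias of (threshold/A)·Δt; the half-rise convention is bias-free
for steps and coincides with the threshold crossing on densely sampled
smooth curves.

**Plateau.**  Stage one is run-based slope thresholding: the longest
contiguous run of points after the onset whose finite-difference slope
magnitude stays within slope_tol (default three times the propagated
noise slope 3·√2·σ_n/Δt).  If no run spans min_span (default 0.02 in
T_fn, ~5.5 K) the plateau is degenerate — T_fno = T_fne = onset, the
no-plateau IDP limit, a valid result rather than an error.  Stage two
refines T_fne, because on realistic grids the start of the
heterogeneous rise has slopes far below any noise-derived threshold
(for a weak quadratic rise the first post-plateau slope can be ~20× 
smaller than slope_tol), so the run systematically over-extends: the
continuity-constrained segmented model — plateau mean plus a
nonnegative linear+quadratic rise anchored at the candidate boundary —
is profiled over grid candidates inside the run, and the boundary is
then optimized continuously between neighboring grid points by
minimizing the same residual sum of squares.  Ties break toward the
longest plateau, which keeps flat noiseless curves at the full window.

**Rise.**  With T_fne fixed, A is the unweighted average of the
plateau points (an inverse-variance-weighted option exists but the
noise is homoscedastic, and the published procedure is the plain
average; a joint shared-intercept estimator is available as
`plateau_stat="joint"` and is statistically equivalent here).  The
rise is fitted by linear least squares in u = T_fn − T_fne with basis
{u, u²}: the anchors T_fn1, T_fn2 of the power-series notation are not
identifiable separately from A (a linear term's intercept folds into
the plateau level), so both are set to T_fne, which makes continuity
n(T_fne) = A exact by construction and is reported back in the
power-series convention.  The quadratic order suffices in practice; a
cubic is admitted only if it improves the BIC by a configured margin
(default 6), and an under-determined rise falls back to linear with a
warning.  Parameter standard errors come from the fit covariance with
σ² = RSS/dof; the plateau boundaries carry a localization uncertainty
of half the grid spacing.  Points between −1 and 0 °C are flagged
unreliable and excluded from all fitting (partial bulk melting).

## Differential melting diagram

The analytic DMD is the derivative of the fitted model: the onset
delta is rendered as a finite bar one grid bin wide with area exactly
A; the plateau contributes zero; above T_fne the curve is
B + 2C·(T_fn − T_fn2) (+3D·u² when a cubic was admitted).  Integrals
of analytic curves are taken in closed form, so the conservation
identity ∫ over [onset, 1] = n(1) − 0 holds to machine precision; the
model-free numeric DMD (centered finite differences, the oracle the
analytic curve is tested against) is integrated by the trapezoidal
rule.  Centered differences are exact for quadratics on uniform grids
and converge at second order otherwise — both facts are asserted in
the test suite.  The published method's self-check is implemented the
same way: n_he read from the highest reliable point must agree with
the DMD area over [T_fne, ≈1] within combined uncertainties.

## Order parameters and counts

HeR = (1 − T_fne)/(1 − T_fno) with the conventions HeR = 1 for a
degenerate plateau and HeR = 0 when the plateau reaches the bulk
melting point; its uncertainty is first-order propagated from the
boundary errors.  HeRn = n_he/(n_he + n_ho) is unit-invariant
(fractions or counts).  HeM = (B + 2C)/(1 − T_fne) is not bounded by 1
(tangent-like) and returns 0 at the homogeneous limit T_fne = 1 by
convention.  n_he is always reported as a *lower bound* (flagged in
the output), because the last reliable reading sits below T_fn = 1.

Fractions convert to waters per protein molecule by
fraction × (water molarity)/(protein molarity), protein molarity =
concentration/molecular weight.  The solvent water molarity defaults
to 55.35 mol/L (pure water near 0 °C); a water mass fraction in the
sample spec scales it, crudely correcting for protein volume.  The
conversion assumptions are echoed in the report's provenance block
rather than silently applied, since published counts for small
proteins are sensitive to exactly this choice.

## Synthetic ground truth

The generator realizes the analysis' own forward model — zero below
the onset, a one-bin step, a flat plateau, a quadratic rise — plus
homoscedastic Gaussian noise on n (an amplitude-level noise option
exists at the FID stage for signal-chain realism).  Defaults encode
the study conditions: 35 temperatures from −70 to −1 °C (the reliable
window below bulk melting), noise s.d. 0.002 on n, and three presets
with the published characteristic parameters — `ubiquitin_like`
(plateau 0.832–0.961, level 0.019, quadratic rise reaching +0.009 at
T_fn = 0.995), `erd10_like` (0.835–0.889, 0.0157, +0.098 at 0.995),
and `bulk_water_like` (a single step at T_fn ≈ 1).  The rise
coefficients are C = Δn_he/(0.995 − T_fne)² with B = 0: the published
fits found the quadratic member sufficient, and the heterogeneous
fractions pin the curve's endpoint.  The `erd10_like` onset is placed
0.0004 below its plateau start, mirroring the globular preset's
spacing, because the published text onset for the disordered protein
(−42 °C) lies *above* its own plateau start (−45.1 °C), which the
geometry of the model cannot represent.

The FID generator emits two-component traces with Curie-scaled
amplitudes, dead-time truncation (window 8–1500 µs, 160 samples), a
constant rigid-proton amplitude, and an above-melting reference trace
at +10 °C for normalization.  Everything is deterministic under an
explicit seed; no global random state is used anywhere.

What the generator does **not** emulate: spectrometer artifacts
(ringing, phase error, field drift), temperature-dependent relaxation
of the rigid component, heteroscedastic or correlated noise, warming
hysteresis, and partial bulk melting just below 0 °C.  Passing
recovery tests therefore demonstrate the estimators' correctness and
statistical behavior under the assumed signal model, not robustness to
every instrumental pathology of real data.

## Numerical choices and degenerate inputs

Duplicate temperatures are rejected at diagram assembly; small
negative fractions (≥ −0.02, noise) are clamped to zero with a
warning; fractions above 1.05 are rejected.  The FID fit is
initialized by variable projection (a log-spaced grid over decay-pair
candidates with amplitudes from nonnegative least squares) and
polished by bounded least squares; the mobile-water decay is
constrained to τ_s ≥ max(3·t₀, 25 µs) — motional narrowing makes
shorter "slow" decays unphysical, and the bound prevents the
exponential from chasing the solid signal when a trace contains no
mobile water at all.  Fit non-convergence raises an error carrying
residual diagnostics; a failed trace in a series is excluded with a
warning, and the series fails if fewer than five usable points remain.
All tolerances (onset threshold, slope_tol, min_span, high-T cut,
BIC margin) are configurable, logged at INFO level by the CLI, and
recorded in the output JSON.

## Known limitations

* The plateau-level precision is bounded by the number of plateau grid
  points: for a short plateau (the IDP-like preset has ~7 points at
  the default grid) the median relative error of A at noise s.d. 0.002
  is ≈3%, and a Cramér–Rao-style argument (oracle given the true
  boundary and rise shape) shows no estimator can do better than ≈2%
  under those conditions.  Denser sampling across the plateau, not a
  different estimator, is the way to improve it.
* Onset and plateau-start are only localizable to the grid spacing
  (the data contain no information inside a sampling interval), so
  "exact" noiseless recovery applies to A, B, C and T_fne but only
  grid-resolution recovery to the onset and T_fno.
* HeM inherits the fitted B and C and is therefore the most
  fit-sensitive of the order parameters; with a short rise segment its
  scatter is large, and published HeM values cannot be checked without
  the underlying coefficients.
* Only the slow-warming equilibrium branch is modelled; cooling
  hysteresis is out of scope, as are frequency-domain (spectral-width)
  analyses, T1/T2 relaxometry, and DSC-based specific-heat modelling
  of the plateau region.
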