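# Methods

## The measurement and the fitted quantity

An EIS sweep applies a small sinusoidal voltage across an interdigitated
electrode immersed in the culture and records the current; the complex
impedance at each frequency is Z = V/I, with |Z| = |V|/|I| and
∠Z = ∠V − ∠I. Sweeps span 10 Hz–1 MHz (61 log-spaced points by default,
about 12 per decade — enough to resolve all four model terms; the count is
configurable). Readings are converted from polar to rectangular form and
**only the reactance X = Im(Z) is modelled**. The real part of synthetic
sweeps is filled with a constant series resistance (100 Ω) purely so that
Nyquist plots are drawable; it never enters a fit.

Sign conventions: capacitive reactance is negative; Nyquist plots show
(R, −X) so capacitive data land in the first quadrant; phase angles are
degrees in files and interfaces, wrapped to (−180, 180].

## The fractional reactance model

```
Z_fit(s) = a0 + b0·s^p1 + c0·s^-0.5 + d0·s^p2 ,   s = j·2πf
```

evaluated on the principal branch (jω)^p = ω^p·e^{jpπ/2}, so a lone s^p
term holds a constant phase of p·90° and contributes reactance
coeff·ω^p·sin(pπ/2). Limiting cases recover the ideal elements: p = −1 is
a capacitor 1/(k1·s), p = +1 an inductor k2·s, p = −0.5 the Warburg
diffusion element A_W·ω^−0.5·(1−j) with its −45° phase (the 45° line on a
Nyquist plot). The culture data this model targets do not follow a Randles
circuit; the fractional polynomial is the empirically adequate form.

Two readings deserve flagging:

- **Term assignment.** The model form used here takes b0 with the free
  negative exponent p1, c0 with the Warburg exponent fixed at −0.5, and d0
  with the free positive exponent p2. Source renderings of the composite
  equation lose fraction bars and radicals, and an alternative assignment of
  the middle terms exists; the form above is the one consistent with the
  Warburg derivation that precedes it and with p1, p2 being the only free
  exponents. This is documented rather than silently assumed.
- **a0 in the reactance.** Although a frequency-independent term would
  normally be a resistance, a0 here is treated as a constant *reactive*
  offset and participates directly in the reactance fit — this is the only
  reading under which −a0 can be reported with error bars from a
  reactance-only fit, as the methodology requires.
- **Units of b0.** b0 multiplies s^−1.5; it behaves capacitively but its SI
  unit is not Farad. Coefficients are stored as raw magnitudes with
  pseudo-units Ω·(rad/s)^−p.

## Estimation

The loss is the unweighted sum of squared reactance residuals (weighting by
1/|X| or 1/|Z| is available as configuration; unweighted is the default and
the minimal reading of "least squares difference"). Two stages:

- **Fixed exponents** (p1, p2) = (−1.5, +1): the model is linear in
  (a0, b0, c0, d0) and the estimate is the exact solution of the linear
  least-squares problem on the design matrix
  [1, ω^−1.5·sin(−3π/4), ω^−0.5·sin(−π/4), ω], solved by SVD after column
  equilibration (the columns span ~10 decades in norm; equilibration keeps
  the solve at machine precision — noiseless recovery is ~1e−12 relative).
- **Free exponents**: p1 ∈ [−3, −0.01], p2 ∈ [0.01, 2] are estimated by
  variable projection — a bounded trust-region search over (p1, p2) alone,
  with the four coefficients profiled out by the linear solve at every
  candidate pair. The search runs from a deterministic list of five exponent
  starts ((−1.5, 1) plus four pairs spanning the box), keeping the best
  residual; the evaluation budget across starts is capped at 50,000. The
  procedure is deterministic: identical input gives bit-identical results.
  On noiseless data generated from the fixed-exponent model it returns
  p1 = −1.5 and p2 = 1 to ~1e−8.

d0 is never pinned to a nonzero constant (doing so destabilises the
optimisation); a `fix_d0_zero` option drops the inductive term entirely,
which is adequate for sweeps insensitive to wiring inductance.

Standard errors come from the Gauss–Newton covariance σ²(JᵀWJ)⁻¹ with the
analytic Jacobian (including the ∂/∂p columns for free fits) and
σ² = SSR/(n−k). They are model-based (homoscedastic assumption); under the
generator's relative noise they understate the scatter of the ill-identified
coefficients — see limitations.

**Replicates.** Each reactor is fitted independently; parameters are then
averaged across the (three) replicate reactors per sampling hour, with
spread reported as the sample standard deviation (ddof = 1, defined as 0
for a single reactor). The dispersion statistic across replicates is not
uniquely determined by the methodology being emulated; sample SD is the
choice here.

## Growth analysis

CFU arithmetic: log₁₀(CFU/mL) = log₁₀(count / (dilution × plated volume)),
with 0.1 mL default plated volume (affects only the additive constant).
A zero count maps to the half-detection-limit sentinel
log₁₀(0.5/(dilution·volume)) rather than −∞.

The exponential window is either configured manually (default 0–6 h, the
first sampling periods of a fast-growing culture) or selected automatically
as the longest contiguous run of per-step log-CFU slopes ≥ 50% of the
maximum observed slope.

The correlation step regresses replicate-mean −b0 (y) on log₁₀ CFU/mL (x)
by OLS inside the window, matching fit hours to CFU hours by nearest
neighbour within 0.5 h. A constant-CFU window is a degenerate regressor and
raises an error rather than returning an undefined R².

Pb-presence classification: the threshold is the midpoint of the two class
means of log₁₀|b0|; a query strictly on the exposed side classifies as
`pb_present`, with ties going to `pb_absent`. The rule is monotone under a
common rescaling of all magnitudes.

Residual-Pb(II) series are carried as observational context; no kinetic
model is fitted to them.

## Synthetic experiments

The generator emulates the study design: 2 conditions (`with_pb`,
`without_pb`) × 3 replicate reactors × 10 hourly samples (t = 0…9 h) × a
61-point sweep, everything a pure function of (config, seed).

- **Growth.** `rise_plateau` (K. pneumoniae-like) integrates
  dL/dt = r·(1 − L/K) in closed form: fast early growth at rate
  r = 0.55 log-units/h from L₀ = 6, saturating toward K = 9.5 — early slope
  equals r, growth continues slowly late in the run. `rise_decline`
  (P. bifermentans-like) follows the same curve to a 9 h peak, then declines
  linearly at 0.15 log-units/h (substrate depletion). Growth is simulated
  directly in log-CFU space, the scale all comparisons use.
- **Pb(II) depletion.** C(t+Δ) = max(floor, C(t) − uptake·log_cfu(t)·Δ)
  from 80 mg/L (the nominal dose: 0.8 mL of 10,000 mg/L stock into 100 mL),
  uptake 0.9 mg/L per hour per log-CFU, floor 5 mg/L; non-increasing by
  construction. Unexposed reactors carry 0 mg/L.
- **Linkage.** Affine maps from log-CFU to the negated coefficients, with
  multiplicative offsets in the Pb condition. Preset magnitudes are anchored
  to the canonical example scales (a0 ≈ 5 Ω, b0 ≈ −2·10⁴, c0 ≈ −500,
  d0 ≈ 2·10⁻⁵ H in the exposed condition) with a ×100 |b0| and ×20 |c0|
  separation between conditions — the orders-of-magnitude separation that
  motivates log-scale plotting and threshold classification. The −b0 map is
  strictly decreasing in log-CFU (slope −30 unexposed, −3000 exposed).
  These magnitudes are plausible-scale choices, not measured values; only
  their orders of magnitude and signs carry meaning.
- **Noise.** X_obs = X + ε_abs + ε_rel·|X|, independent Gaussians from a
  seeded stream; the default σ_rel = 0.01 corresponds to a per-point
  signal-to-noise ratio of 100. Identical seeds give byte-identical
  datasets.
- **Chemistry helpers.** Stock concentration from salt mass ×
  ion mass fraction / volume (Pb fraction in Pb(NO₃)₂ = 207.2/331.2 from
  atomic masses Pb 207.2, N 14.007, O 15.999); nominal reactor dose
  v_add·c_stock/v_reactor, added volume not counted in the denominator.

What the generator does **not** emulate: electrode double-layer physics,
biofouling drift, Gram-type-specific charge effects, suspended-precipitate
scattering, non-Gaussian instrument noise, or any coupling between the real
and imaginary channels. Passing tests therefore demonstrate that the
estimation and correlation machinery is correct and well-conditioned under
the stated noise model — not that the affine linkage itself holds for real
cultures.

## Problem sizes and numerical choices

The test suite and the reproduction script run the default experiment sizes
(60 sweeps of 61 points; fits are microsecond-scale linear solves, the
free-exponent search a few hundred model evaluations). Monte-Carlo checks
use 200–500 replicates. Tolerances: noiseless coefficient recovery is
asserted at 1e−6 relative (achieved ~1e−12); the fixed-exponent fit agrees
with an independent normal-equations solve to 1e−8 relative; exponent
recovery on noiseless data to ±0.01.

## Known limitations

- The free-exponent fit at realistic noise has limited precision: at SNR
  100 on the default grid, the information-theoretic (GLS) standard error
  of p1 is ≈ 0.05, so noisy exponent estimates scatter at the few-percent
  level; exponent self-consistency under noise is therefore checked against
  the estimator's analytic standard error, not a fixed absolute tolerance.
- |b0| in the unexposed condition sits near the reactance noise floor, so
  its *relative* recovery error is large (~50% at SNR 100) even though the
  exposed-condition |b0| — the quantity the growth correlation and the
  classifier rely on — is recovered to ~2%. This asymmetry is intrinsic to
  the orders-of-magnitude |b0| separation between conditions.
- Reported standard errors assume homoscedastic residuals; under relative
  noise they are indicative, not exact.
- Only the reactance is fitted; the real part of the impedance is ignored
  throughout, and no Kramers–Kronig consistency check is performed.
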