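# eisgrowth

Inline, non-invasive monitoring of anaerobic bacterial growth — and of
dissolved lead — from electrochemical impedance spectroscopy (EIS) sweeps.

Batch bioreactors used for Pb(II) biorecovery are hard to observe: plating
CFU counts takes a day, and sampling breaks anaerobiosis. The impedance of
the culture medium, measured over a 10 Hz–1 MHz sweep with an interdigitated
electrode, changes as cells proliferate and as Pb(II) ions are removed from
solution. `eisgrowth` turns those sweeps into biology: it fits a fractional
equivalent-circuit model to the measured reactance, tracks the fitted circuit
parameters over culture time, correlates the dominant parameter with
log₁₀(CFU/mL), and classifies whether a reactor contains Pb(II).

## The model

After converting each polar impedance reading to rectangular form, the
reactance X (imaginary part of Z) of a sweep is fitted with a short
fractional polynomial in the Laplace variable s = jω:

```
Z_fit(s) = a0 + b0·s^p1 + c0·s^-0.5 + d0·s^p2
```

- `a0` — constant reactive offset (Ω),
- `b0·s^p1` — a fractional-power **supercapacitor**; on real culture data the
  free exponent settles at `p1 = −1.5`,
- `c0·s^-0.5` — a **Warburg** diffusion element (constant −45° phase),
- `d0·s^p2` — wiring **inductance**, with `p2 = +1` (d0 in Henry).

On the principal branch, `Im(coeff·(jω)^p) = coeff·ω^p·sin(pπ/2)`, so with
the canonical exponents the fitted reactance is

```
X(ω) = a0 − (b0/√2)·ω^−1.5 − (c0/√2)·ω^−0.5 + d0·ω .
```

With the exponents fixed, the model is linear in (a0, b0, c0, d0) and the
fit is exact linear least squares; with free exponents (p1 < 0, p2 > 0) a
deterministic multi-start variable-projection search estimates them too.
During the exponential growth phase, −b0 decreases approximately linearly
with log₁₀(CFU/mL), and |b0| is orders of magnitude larger in reactors that
contain Pb(II) — the two observations that make the supercapacitance both a
growth proxy and a Pb-presence indicator.

## Worked example

Fit a noisy synthetic sweep generated from known parameters
(a0 = 5 Ω, b0 = −2·10⁴, c0 = −500, d0 = 2·10⁻⁵ H):

```python
import numpy as np
from eisgrowth import (CircuitParams, FrequencyGrid, ReactanceModel,
                       canonical_model_reactance)

grid = FrequencyGrid.default()                      # 61 points, 10 Hz–1 MHz
truth = CircuitParams(a0=5.0, b0=-2.0e4, c0=-500.0, d0=2.0e-5)
x = canonical_model_reactance(truth, grid)
rng = np.random.default_rng(0)
x_obs = x + 0.01 * np.abs(x) * rng.standard_normal(x.size)   # 1% noise

res = ReactanceModel(x_obs, grid).fit()
print(res.summary())
```

```
Fractional reactance model fit
==============================================
n frequencies                 61
stage                 fixed-exponent
weighting                   none
SSR (Ω²)                     3.50454
iterations used                1
converged                   True
----------------------------------------------
param         estimate       std err
a0             5.08356        0.0513
b0            -20392.4           263
c0            -495.218          3.18
d0         1.99032e-05      2.66e-08
p1                -1.5             0
p2                   1             0
----------------------------------------------
negated report (−a0, −b0, −c0, −d0): -5.08356, 20392.4, 495.218, -1.99032e-05
```

All four coefficients are recovered within ~2% of truth at 1% measurement
noise; the `negated_report` line gives the sign convention used when
plotting parameter trajectories. Running the free-exponent stage on the
noiseless sweep returns `p1 = -1.50, p2 = 1.00`, the canonical exponents.

The full pipeline — synthetic experiment (3 reactors × 2 Pb conditions ×
10 hourly sweeps), per-sweep fits, replicate averaging, growth correlation —
runs from the shell:

```sh
eisgrowth run-all --seed 7 --out pipeline_out
cat pipeline_out/correlation/report.md
```

The report gives the OLS slope of −b0 against log₁₀(CFU/mL) inside the
exponential window (0–6 h); a negative slope with R² near 1 reproduces the
behaviour that makes −b0 a usable growth proxy.

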