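# Methods

This note records the models, the numerical choices, and the reasoning
behind the places where the design was genuinely open. Nothing here
states an empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Tight slow-binding progress curves

### Model and assumptions

The one-step scheme E + I ⇌ EI (rate constants `kon_app`, `koff`) under
a constant supply of competing substrate gives the complex concentration
as a Riccati equation whose closed form is

    x(t) = x1·(1 − e^(−kt)) / (1 − (x1/x2)·e^(−kt)),   k = kon_app·(x2 − x1),

with `x1 < x2` the roots of `x² − (Et + It + Ki′)·x + Et·It = 0` and
`Ki′ = koff/kon_app` the apparent inhibition constant (apparent because
substrate competes for the active site; no attempt is made to convert to
a substrate-free Ki, since the substrate Km is not part of the model).
Integrating product formation `dP/dt ∝ (Et − x)/Et` yields exactly the
logarithmic progress-curve expression used by the fitter, with

    vs = v0·(Et − x1)/Et,   γ = x1/x2 = Et·(1 − vs/v0)²/It.

The second equality for γ is an algebraic identity (`x1·x2 = Et·It`), and
is what licenses recomputing γ from `(Et, It, v0, vs)` inside the model
function instead of floating it: the fit stays 4-parameter
(`v0, f = vs/v0, k, A0`) and always self-consistent. The γ ≥ 1 region is
unreachable at an optimum (it corresponds to inconsistent velocities);
during optimization γ is clamped at 1 − 1e−9 so the model stays
evaluable while the optimizer moves away.

Assumptions: free-substrate kinetics (substrate consumption ≤ 10% over
the window, enforced by a simulator warning), a single binding step (no
EI ⇌ EI* isomerization), and constant enzyme activity over the run.

### Fitting

* Reparameterization `vs = f·v0`, `f ∈ [0, 1]` enforces `0 ≤ vs ≤ v0`
  by construction; `k ∈ [1e−6, 1] s⁻¹`; unweighted least squares
  (Levenberg–Marquardt via lmfit).
* Start values: `v0` from the slope of the first 10% of points, `vs`
  from the last 20%, `A0` from the first point, `k` from a log-linear
  fit of the decay of the local slope toward `vs` (fallback `2/t_end`).
  Up to 5 restarts with `k` jittered by up to 1.5 decades on
  non-convergence; the best χ² wins.
* A trace with `vs/v0 ≥ 0.999` is degenerate-linear: the fit is returned
  converged but flagged `k_identifiable = False` and excluded from the
  Henderson regression with a warning.
* Inhibitor-free curves never enter the tight-binding fitter (γ is
  undefined at It = 0); they go to the linear `fit_uninhibited`, which
  restricts itself to the linear range (signal below 20% of the
  theoretical plateau `ε·l·S0`, minimum 10 points) when the assay design
  is supplied.

### Henderson regression

`It/(1 − vs/v0)` against `v0/vs`, ordinary least squares **with a free
intercept**. Exact theory gives intercept = Et; forcing the line through
the origin provably biases the slope upward on exact data (asserted as a
property test), so the free intercept is kept and the intercept-vs-Et
comparison is surfaced as a diagnostic. Per-curve fitted `v0` is used
for the x-values (the inhibitor-free control slope is reported
separately in the pipeline output).

## ITC independent-sites isotherm

Displacement-cell dilution uses the standard effective concentrations
`Mt = M0(1 − ΔV/2V0)/(1 + ΔV/2V0)`, `Xt = Xs(ΔV/V0)/(1 + ΔV/2V0)`; the
occupancy quadratic is solved in the numerically stable smaller-root
form, and the per-injection heat includes the average-displacement
correction `(dVi/V0)(Qi + Q(i−1))/2`, applied symmetrically in the
simulator and the fitter (a flag disables it for sensitivity checks).

`Kd` is fitted in log10 space (positivity plus scale-invariance); unless
start values are supplied, a six-point multi-start over Kd decades
(10⁻¹⁰…10⁻⁵ M) guards against the flat directions of the isotherm at
extreme c. `ΔH` starts from the first-injection heat per mole injected,
`n` from 1. After the fit, `c = n·M0/Kd` is computed and a conditioning
warning fires outside 1 < c < 1000. A no-binding flag compares the total
observed heat with a noise scale estimated from first differences of the
heats (the isotherm is smooth, so differences are noise-dominated when
nothing binds).

Choices where the protocol leaves freedom: active cell volume
V0 = 950 µL (instrument-class typical; every fixture carries it
explicitly), ΔH = −50 kJ/mol in fixtures (only the exothermic sign is
constrained by observation), exothermic-negative sign convention, first
injection kept by default (`drop_first` available; on clean data it
moves n by < 2%, asserted in tests).

At the 50 °C fixture (c ≈ 3400) the titration is essentially a step
function: n and ΔH remain well determined (≤ 1%), while Kd is
structurally weak — noiseless fits still land on it, but the uncertainty
printed by any fitter in this regime should not be trusted, which is
exactly what the conditioning warning communicates.

## DSF melts

Model: Boltzmann sigmoid between linear native and unfolded baselines;
`Tm` is the half-transition point by construction, matching the
"half-point of the transition" operational definition; transition width
`a` in °C. Curves are truncated at the global fluorescence maximum
before fitting because hydrophobicity-reporting dyes quench beyond it;
on simulated quenched data the untruncated fit is biased by > 0.5 °C
while the truncated fit is unbiased (asserted in tests).

Numerical choices: no-transition guard (amplitude < 3× a noise scale
estimated from second differences) returns a flagged result instead of a
meaningless Tm; the Tm start value is the half-amplitude crossing of a
heavily smoothed curve (window ≈ n/20 points), which is robust on the
dense 0.05 °C instrument grid where a narrow-window derivative is
noise-dominated; bounds keep Tm inside the observed range and `a > 0`.
The derivative cross-check (`tm_by_derivative`) smooths with a
configurable window (default 5 points, appropriate for decimated grids;
~50 points is appropriate at 0.05 °C spacing) and agrees with the
sigmoid Tm within one grid step on symmetric transitions; with a sloping
unfolded baseline it acquires a small documented offset bounded by a/2.

## Synthetic data: what it emulates, what it does not

The generator reproduces the *designs* of the three assays: 2 nM
protease / 0.5 mM chromogenic substrate / 0–8 nM inhibitor progress
series at 25 °C (1800 s window) and 50 °C (900 s); 19 × 5 µL injections
of 100 µM titrant into 5 µM protein; 25→99 °C ramps at 0.05 °C/s
sampled every second. Fixture truths are the reported constants
(Ki′ = 330 / 20 pM, n = 0.68 / 0.89 with KD = 96 / 1.3 nM,
Tm = 67.8 / 85.2 °C).

Values the protocols do not pin down were chosen once, as follows:

* **kon/koff split.** Only the ratio Ki′ = koff/kon is observable from
  the fitted constants. The package uses kon_app = 1×10⁶ M⁻¹s⁻¹ (25 °C)
  and 1×10⁷ M⁻¹s⁻¹ (50 °C) so that the observed rate `k = kon(x2 − x1)`
  satisfies `k·t_end ≳ 3–4` across the inhibitor grid — i.e. binding
  equilibrates within the assay windows, as it must for a measurable
  `vs`. (An order of magnitude slower would leave the 25 °C curves
  visibly unequilibrated at 1800 s.) The values are within the range
  typical of propeptide–protease association.
* **Uninhibited rate.** kcat = 25 s⁻¹ with Km = 0.5 mM gives
  v0 ≈ 2.2×10⁻⁴ AU/s at 2 nM enzyme (ε₄₁₀ = 8800 M⁻¹cm⁻¹, 1 cm path),
  i.e. ~0.4 AU accumulated at 25 °C — a realistic spectrophotometer
  trace — while keeping substrate consumption just under the 10%
  free-substrate guard.
* **Noise.** 1% multiplicative on absorbance, 0.2 µJ additive on heats
  (0.5 µJ in the noisy-recovery checks), 2% multiplicative on
  fluorescence. These are instrument-plausible defaults, not measured
  values.
* **DSF baselines/quench.** Native 1000 + 2·T, unfolded 9000 − 15·T
  (arbitrary units), width 1.5 °C, exponential quench (τ = 6 °C) beyond
  Tm + 3a.

What passing recovery tests shows: the fitting machinery is unbiased and
precise *under the stated model with these noise magnitudes*. What it
does not show: robustness to baseline drift, substrate depletion beyond
10% (the simulator can generate it; the fitter deliberately implements
the free-substrate model), enzyme inactivation, ITC baseline/integration
artifacts (inputs here are already-integrated heats), or multi-domain
DSF transitions. Real-data error bars will be larger.

## Problem sizes in the verification runs

Recovery statistics use 10 seeds per temperature for Ki′ (4 inhibited
curves each, 450–900 points per curve), 20 replicates per DSF fixture,
and single noiseless fits for ITC — sizes at which the medians are
stable to well within the asserted tolerances (the Ki′ medians move by
only a few percent across independent seed streams).

## Known limitations

* The Henderson slope at the 50 °C fixture leans on curves with
  `vs/v0` down to ~0.003, where the steady-state slope is close to the
  noise floor; individual-seed Ki′ estimates scatter by tens of percent
  (median stays within the asserted band). This mirrors the practical
  difficulty of measuring picomolar constants by this method.
* Fit covariances are the local Gauss–Newton approximations reported by
  the optimizer; in the high-c ITC regime they understate the true Kd
  uncertainty, which is why the conditioning warning exists.
* The CLI `ki` verb consumes the per-curve fit table; it trusts the
  table's converged flags and does not re-validate the underlying
  traces.
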