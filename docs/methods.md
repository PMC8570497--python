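# Methods

## The circuit model

The synaptic cleft is treated as a single equipotential compartment at
potential `v_cl` relative to the grounded interstitial space. It is bounded
by the presynaptic cleft-facing membrane (capacitance `c_pre`, plus
voltage-gated conductances), the postsynaptic cleft-facing membrane
(`c_syn`), and a lumped leak conductance to ground `g_cl`. The rest of the
postsynaptic cell is `c_post`/`g_post` with resting potential `v_rest`.
For a calyx-type synapse the pre- and postsynaptic cleft-facing
capacitances are close to equal; the package calls this common value the
cleft capacitance `c_cl` (internally it uses `c_syn`) and defines the cleft
time constant `tau_cl = c_cl / g_cl`.

Currents entering the cleft are

    i_enter = c_pre * dv_pre/dt + sum_ion g_ion * (v_pre - v_cl - v_ion)

and dissipate through two parallel routes: the membranes' capacitance and
`g_cl`. Two limits bracket the behaviour:

* **capacitive dissipation** (`g_cl` small):
  `v_cl = (c_pre + c_syn)^-1 * ∫ i_enter dt`; the recorded voltage-clamp
  prespike is `i_rec = -c_syn/(c_pre+c_syn) * i_enter` — about half of
  `i_enter`, resembling the inverted first derivative of the AP;
* **resistive dissipation** (`g_cl` large): `v_cl = i_enter / g_cl`;
  `i_rec = -(c_syn c_pre / g_cl) * d2v_pre/dt2 = -g_cl tau_cl^2 * d2v_pre/dt2`
  for a symmetric cleft — the inverted second derivative.

The closed forms assume the postsynaptic side is voltage clamped, so
`g_syn` and the non-cleft-facing compartment drop out of them. The
calcium-current component obeys the same algebra: `-i_rec = i_ca`
(capacitive) or `-i_rec = tau_cl * di_ca/dt` (resistive). In current clamp
the prespike is the first-order RC response of the postsynaptic membrane to
`-i_rec` (gain `1/g_post`, time constant `c_post/g_post`).

Sign conventions: inward membrane currents are negative everywhere; `v_cl`
is 0 at rest; `i_rec` is what a postsynaptic voltage-clamp amplifier
records, so the prespike of a rising AP starts with a negative peak.

## The ODE model with channel feedback

When voltage-gated channels populate the cleft-facing membrane their rates
are evaluated at `v_pre - v_cl`, so gating feeds back on the cleft
potential. The simulator integrates

    c_post * dv_post/dt = c_cl * dv_cl/dt - g_post (v_post - v_rest)
    2 c_cl * dv_cl/dt   = c_cl (dv_pre/dt + dv_post/dt) - g_cl v_cl
                          + sum g_max p_open (v_pre - v_cl - v_channel)

together with the master equations of every channel scheme. The two
voltage equations are linear in the derivatives and reference each other;
they are solved by exact algebraic elimination at every evaluation, not by
fixed-point iteration. `v_pre` (an input waveform, never generated — the AP
invades the terminal passively) and any injected cleft current are supplied
to the adaptive integrator by cubic-spline interpolation.

Channel schemes (states, with transition-rate stoichiometry folded in):

* sodium `na5`: C1 =(2a/b)= C2 =(a/2b)= C3 =(g/d)= O =(theta/epsilon)= I;
* potassium `k6_ht`, `k6_lt`: C1..C5 with 4a/b … a/4b, then C5 =(g/d)= O,
  where g and d are voltage-independent;
* calcium `ca2`: C =(a/b)= O with the open probability squared (two
  independent gates).

Every rate is `a * exp(b * v)` with `a` in 1/ms and `b` in 1/mV; the
built-in constants (all 16 transitions) ship as package defaults and can be
overridden from a config mapping. Exponent arguments are clamped to ±50 —
far outside the physiological range — for numerical safety. Default
reversal potentials are +50 (Na), −90 (K), +40 mV (Ca), with the
postsynaptic cell resting at −70 mV.

Numerics: occupancies are integrated as raw states and renormalized only
for reporting, which keeps the conservation test (|Σp − 1| < 1e-6 along
any trajectory) a genuine accuracy check. The default integrator is the
embedded Runge–Kutta 4/5 with `rtol 1e-6`, `atol 1e-9`; tightening changes
nothing visible. The homogeneous model (all four channels) is stiff — the
sodium deactivation rate near rest approaches 1e7/s — so `method="LSODA"`
is offered and verified to reproduce the RK45 trajectories to tolerance.
`g_cl = inf` is accepted as the zero-cleft-resistance limit (`v_cl` pinned
at 0), and `c_post = c_cl/2` is rejected as a singular coupling.

## Cleft geometry

For a radially-symmetric (disc) synapse of radius `r` and height `h` with a
homogeneously distributed capacitive current density, the radial field
grows linearly from the center and the potential profile is parabolic:

    v(x) = (r^2 - x^2) * R_ex * C_m / (4h) * dv_pre/dt      (disc)
    v(x) = (r^2 - x^2) * R_ex * C_m / (2h) * dv_pre/dt      (sheet)

The disc prespike is `i_post = r^4 * pi * R_ex * C_m^2/(8h) * d2v/dt2` —
fourth-power radius scaling, which is why intracellular prespikes are seen
only at giant synapses — and is exactly the lumped `g_cl tau_cl^2 d2v/dt2`
with `g_cl = 8*pi*h/R_ex` and `c_cl = C_m*pi*r^2`. The disc conductance is
radius-invariant (the escape area `2*pi*r*h` grows exactly as fast as the
path length), so a measured `g_cl` plus a cleft height gives the
extracellular resistivity directly: `R_ex = 8*pi*h/g_cl` (1 µS and 30 nm
give ≈75 Ω cm).

The sheet (finger) prespike has no printed closed form here; it is
computed from first principles by quadrature of the capacitive current
density `C_m * dv_cl/dt` over the finger width times the total finger
length, and cross-checked in the tests against the resulting closed form
`(8/3) r_f^2 / r_c^2` relative to the equal-area disc. For 4 µm fingers and
a 1000 µm² contact area the center potential falls to ~2.5% and the
prespike to ~3.4% of the disc values — fenestration as an adaptation that
suppresses cleft potentials.

Geometry functions are SI throughout with explicit converters for Ω cm,
µF/cm² and µm, because silently mixing the field's unit systems is the
dominant implementation risk for these formulas.

## Estimation pipeline

1. **P/5 isolation.** The passive (capacitive) prespike component is
   estimated from five sweeps driven at one-fifth stimulus amplitude;
   `Δi_post = mean(active) − 5*mean(passive)`, segmented into stimulus
   epochs of which the first 20 are skipped (EPSC contamination at train
   onset) and the next 25 averaged.
2. **tau_cl, two ways.** Peak-ratio: for a roughly Gaussian calcium current
   of width `tau_Ca` (half the peak-to-peak delay of the biphasic
   `Δi_post`), the positive peak of `Δi_post` is the fraction
   `tau_cl/tau_Ca * e^-0.5` of the cleft-facing calcium-current amplitude.
   Slope: OLS of `Δi_post` on `-di_ca/dt` at the integer-sample lag
   maximizing Pearson's r (parabolic sub-sample refinement of the reported
   lag); the slope is `tau_cl`. A `cleft_fraction` (default 1.0, with 2/3
   as the literature-motivated alternative) scales the estimate when part
   of the calcium current arises outside the cleft.
3. **Regime discrimination.** Per AP of a train, the first negative and
   positive prespike peaks are regressed on the first two extrema of the
   AP's first and second derivative; resistive dissipation predicts the
   second-derivative fit to win (higher |r|, intercept through the origin,
   slope `-g_cl tau_cl^2`). Paired two-sided t-tests (n−1 df) compare the
   two models across trains.
4. **Derived parameters.** `g_cl = |slope|/tau_cl^2`, `c_cl = g_cl*tau_cl`,
   `R_ex = 8*pi*h/g_cl` for an assumed height (default 30 nm).

Numerical choices: derivatives of sampled records use local-quadratic
(Savitzky–Golay) fits with a 5-sample default window — at 50 kHz this
attenuates first/second derivatives by <1% for components up to 50 samples
per period while suppressing per-sample noise (a 7-sample window costs
1.4–1.8% and measurably biases the slope estimator); smooth model-internal
signals use plain central differences. Extrema are refined by a
least-squares parabola over five samples, which keeps the noise-induced
amplitude bias of peak picking below ~5% at SNR 10. Peak detection uses a
prominence threshold of five robust noise SDs (median absolute deviation
of first differences); traces with no qualifying peaks raise an explicit
"no prespike detected" error rather than returning numbers.

## Synthetic recordings

The generator emulates the study conditions: trains of 45 identical AP
waveforms at 100 Hz (independently decaying/broadening trains for the
regime-discrimination analyses), a Gaussian inward calcium current during
each repolarization (default −1.9 nA peak, `tau_Ca` 0.217 ms, i.e. 0.51 ms
FWHM), one active sweep plus five passive sweeps at exactly 1/5 amplitude
about rest (eliciting no calcium current), i.i.d. Gaussian current noise,
and an optional difference-of-exponentials EPSC (0.2 ms rise, 1 ms decay)
starting a configurable delay after each calcium peak, on active sweeps
only. Simulation uses 5 µs sampling, synthetic "recordings" 20 µs, so that
cleft time constants of order 10 µs are resolvable. Fixed seeds give
bit-identical output.

Because the AP-waveform template used in the original voltage-clamp
experiments is not published, the AP surrogate is the product of two
logistic ramps on a common scaled time axis (rise/decay time-constant ratio
`asymmetry`, default 0.4), normalized to a requested amplitude and FWHM.
It is smooth, twice differentiable, and rescales purely in time when only
the FWHM changes. Its default amplitude (120 mV from a −80 mV rest) is a
configurable guess — the source experiments state only the FWHM — and the
cleft-feedback results are reported with a 100–140 mV sensitivity band for
exactly this reason. What the generator does **not** emulate: series-
resistance filtering, stochastic channel gating, vesicle release and
receptor kinetics, drifting baselines, or non-Gaussian noise. Passing
round-trip tests therefore demonstrates correctness of the estimators
under the model's own assumptions, not robustness to every artifact of
real recordings.

## Cleft-feedback experiment

`calcium_cleft_experiment` pairs two calcium-only ODE runs — zero cleft
resistance versus a finite `g_cl` (default 0.67 µS, `c_cl` 10 pF) — with
the calcium density calibrated so the zero-resistance run peaks at −2 nA.
The calibration is exact in one probe run: with `v_cl` pinned at zero there
is no feedback and the current is linear in `g_max`. Reported quantities:
`v_cl` extrema, the relative reduction of the calcium peak, and the shift
of the calcium-current peak time and 10%-of-peak onset time. With the
surrogate AP the calibrated densities (≈0.04 and ≈0.07 nS/µm² for 1.0 and
0.2 ms FWHM) differ from values published for a real AP template, which is
expected — the logistic surrogate activates the two-gate calcium scheme
more effectively — and is precisely why the density is calibrated rather
than fixed; the paired, relative measures are insensitive to it.

Problem sizes: simulations span 8 FWHM past the AP peak at 5 µs sampling
(≈2200 samples for the slow AP); the parameter-recovery benchmark uses 20
recordings of 45-stimulus trains at 20 µs; the regime-discrimination check
uses 100 seeded batches of 13 eight-AP trains per regime.

## Known limitations

* The lumped `v_cl` ignores the spatial profile during simulation; the
  geometry module quantifies the profile but the two are not coupled (no
  finite-element model — morphologically complex synapses are out of
  scope).
* The closed-form prespike predictions hold under postsynaptic voltage
  clamp; the current-clamp prespike is derived from `i_rec` afterwards
  rather than co-integrated.
* The peak-ratio estimator assumes a Gaussian calcium current; skewed
  currents bias `tau_Ca` and hence `tau_cl`, which is why the slope
  estimator is the primary one.
* `R_ex` inherits the assumed cleft height linearly; it is reported "given
  h".
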