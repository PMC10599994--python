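# Methods

This note records the model, the numerical choices, and the synthetic-data
conditions behind `springwing`, at the level of detail a user needs to
judge what the tests do and do not demonstrate.

## Reduced stretch-activation kernel

Delayed stretch activation is represented by its velocity impulse
response, g(t) = (1/g0)(−e^(−r3 t) + e^(−r4 t)), normalized to unit area
by the *analytic* constant g0 = 1/r4 − 1/r3.  The time-to-peak
t0 = ln(r3/r4)/(r3 − r4) is the kernel's single timescale once the rate
ratio κ = r4/r3 is held fixed; for *Manduca sexta* flight muscle κ = 0.62
and t0 = 1.258/r3.  The confluent case r3 = r4 is handled by the analytic
limit t·e^(−rt) (t0 = 1/r, g0 = 1/r²) rather than rejected, because
parameter sweeps can approach κ = 1 arbitrarily closely; the switch
happens below a relative rate difference of 1e−9.

The discrete (FIR) form samples g at t = 0, dt, 2dt, … (left endpoint,
matching a causal discrete convolution whose unit impulse reproduces the
coefficients exactly) and truncates at the first sample *past the peak*
where g < 1% of its maximum — the below-1% region near t = 0 is not a
valid truncation point.  The truncated tail carries mass ≈ 0.5% for the
*M. sexta* rates at dt = 1e−4 s.  Consequences: the filter's gain at the
25 Hz operating frequency matches the kernel's analytic Fourier transform
to ≲ 0.1% and its phase to ≲ 0.4% of a cycle, but the *complex* response
error away from the operating band is bounded by (and can approach) the
tail mass, which is several percent of |G| at 50 Hz where |G| is small.
The tests assert the 1% gain/phase fidelity at the drive frequency and
the tail-mass bound across the band.

## Muscle trace analysis

The stretch–hold–release–hold protocol holds tetanus for 150 ms,
stretches by 4.5% strain at the in-vivo rate ε̇0 = 2π·f·ε0 (7.07 s⁻¹ at
f = 25 Hz, a 6.4 ms ramp), holds 150 ms, releases at the same rate and
holds again.  Strain and stress are shortening-positive, so the stretch
is a negative strain ramp.

The post-stretch force is fitted with the seven-parameter sum of
exponentials K2 e^(−r2 t) + K3(1 − e^(−r3 t)) + K4 e^(−r4 t) + c.  Sums
of exponentials are notoriously ill-conditioned in a joint fit, so the
fit uses **variable projection**: only the three rates are optimized
(bounded log-rates, trust-region least squares, multi-start from
r2 = 10/ramp-duration, r3 = 1.258/t̂0 with t̂0 the observed
trough-to-peak delay, r4 = 0.62·r3), with the amplitudes solved linearly
at each step.  Because the model is invariant under relabelling its
exponentials, the fitted triple is canonicalized afterwards: the rise
term is the negative-coefficient exponential (K3 ≥ 0), the fastest of
the remaining two is the viscoelastic decay r2, the slowest is r4.

A caveat the tests make explicit: at 2% multiplicative noise the global
least-squares optimum can wander along the (r3, r4, K3, K4) ridge — the
individual rates of the seven-parameter model are then only weakly
identified (the optimum sometimes merges r3 and r4 into a confluent pair
even when started at the truth).  What the data do pin down are the
time-to-peak implied by the fitted pair (median error ≈ 4% at 2% noise)
and the two-rate *reduced* fit of the post-trough rise-and-fall (median
r3 error ≈ 9%, median t0 error ≈ 1%).  Recovery tests therefore assert
those identifiable quantities.

The DSA magnitude is the rise from the **first local minimum** of the
post-stretch hold (the viscoelastic trough; a global minimum is wrong
because the slow decay can undershoot it at the end of the hold) to the
subsequent peak; the delay is measured from stretch completion.  The
finite-pulse ("IIR") correction deconvolves the rectangular strain-rate
pulse from the response in the frequency domain (Tikhonov-regularized at
the sinc zeros of the pulse spectrum, relative weight 1e−9) and reports
the ratio of impulse-response peak to pulse-response peak; it tends to 1
as the pulse narrows and is verified against a direct time-domain
convolution oracle to 1e−3.

Work-loop power under imposed sinusoidal strain is computed by direct
convolution over steady cycles.  For the pure two-exponential kernel the
mean power at fixed strain amplitude rises monotonically to a saturation
value ½ε²Fa·r3r4 (it is positive only above the crossover frequency
√(r3 r4)/2π), so there is no interior "peak-power frequency"; what moves
with t0 is the half-saturation frequency and the per-cycle work peak,
both ∝ 1/t0, and the timescale test is phrased on those.

## Synthetic trace generator

`synthesize_trace` is the study-conditions generator: tetanic plateau at
the response asymptote K3 + c, a linear viscoelastic rise over the
stretch ramp, the exact seven-parameter response over the post-stretch
hold (referenced to the first grid sample after the ramp so that
noiseless fits recover parameters to machine precision), and a partial
mirrored viscoelastic drop on release (scale 0.4; no shortening
deactivation, which this muscle does not show).  Reference amplitudes
reproduce the measured means: tetanus 203 kN/m² and a trough-to-peak DSA
rise of 32.1 kN/m² at rates (36.39, 22.80) s⁻¹.  Noise is multiplicative
Gaussian on stress (default study condition 2%) plus optional
low-pass-filtered additive sensor noise, seeded and bit-reproducible.
The generator does *not* emulate trial-to-trial kinetic variability,
fatigue, temperature drift, or ergometer compliance — recovery results
say nothing about those.

## Spring–wing plant and placeholder parameters

The plant stores linear thorax stiffness k (N/m) plus transmission T
(rad/m) and always converts to rotational stiffness k/T² internally; the
natural period Tn = 2π√(I/(k/T²)) is a property of the rotational system
and is independent of Γ, c_lin and forcing.  The added-mass expression
v = 2ρπv̂Lw²/AR² is implemented verbatim from its source derivation even
though, as written, it does not carry mass dimensions; a warning is
raised at use and any directly measured inertia should take precedence.
`c_lin` is an opt-in linear viscous term (default 0) for emulating
bearing/friction losses of physical realizations.

The shipped **hawkmoth parameter set is a placeholder**, loudly flagged
as such, constructed once from documented anchors rather than from
measured tables: muscle length L = 11.7 mm; transmission
T = φ0/X0 = 2.042 rad / 0.527 mm = 3878.5 rad/m (117° peak-to-peak
against 4.5% strain); natural period Tn = t0/0.54 = 63.0 ms (the
documented hawkmoth location t0/Tn = 0.54 at t0 = 34 ms); and the
remaining inertia/stiffness scale (I = 4.149e−8 kg m², k = 6216 N/m)
fixed so the fully asynchronous axis shows its documented structure — a
quiescent braking regime at small t0/Tn and an emergent-frequency curve
crossing the 25 Hz drive near t0/Tn = 0.2.  Γ = 1.446e−8 N m s² is then
calibrated so a 2,720 mN synchronous drive at 25 Hz yields exactly 117°.
At a smaller inertia scale the same anchors produce a closed loop that is
linearly unstable at *every* t0/Tn (a high-frequency feedback mode), so
the scale is not a free styling choice; it is the one remaining
qualitative anchor.  The roboflapper placeholder takes its inertia from
the published wing geometry (10 × 3.6 × 0.5 cm acrylic plate rotating
about one end plus flat-plate added mass in water, I ≈ 4.1e−4 kg m²) and
back-computes the torsion-spring stiffness from the published
Tn = 0.416 s.  Both files carry `provenance: placeholder` and should be
overwritten with measured values for quantitative work.

## Closed-loop engine

Fixed-step integration at dt = 1e−4 s over 5 s from φ(0) = 0.1 rad (the
non-zero start seeds self-excited oscillation).  Each step emulates a
discrete controller: the current wing velocity is pushed into the FIR
history, the muscle-pair force is evaluated and held over the step
(zero-order hold), and the plant is advanced by classical RK4 (an
explicit-Euler mode exists for fidelity experiments).  Because the raw
antagonistic forces are exact negatives, the tension-only clipped pair
sums to the signed single-expression force; the engine exploits this
identity, and the actuation tests verify it against the explicit
clipped-pair computation.  Runs are bit-reproducible; non-finite states
raise with the failing step index.  Halving dt changes the steady
amplitude by < 0.5%.

Metrics: emergent frequency is the FFT argmax (zero bin excluded) of the
last 2.5 s of position — 0.4 Hz bins, optional quadratic-interpolation
refinement; cycle power integrates force over muscle displacement
(Σ F·Δφ/T with the force held per step, which balances the dissipation
Γ⟨|φ̇|³⟩ to ≲ 0.01%) across the last five wingbeats of a steady window;
amplitude variation is the s.d. of successive peak-to-peak wingbeat
angles (peak prominence 1% of the running amplitude).  Steady state
means < 1% relative amplitude drift across the trailing ≤ 50 wingbeats;
in interference regimes, where the amplitude fluctuates persistently and
no strict steady state exists, the sweep computes power over the last
detected cycles anyway (`require_steady=False`) — this mirrors the
five-periods-after-transient procedure and keeps the power map defined
on the bridge approaches.  Traces below 1° peak-to-peak are quiescent.

## Sweep, tuning, classification

Gains are tuned once and frozen across the grid: Fs by bisection at
K_r = 1 to the 117° target (1% tolerance; recovers ≈ 2.72 N on the
shipped plant), μ by a 17-point logarithmic bracket scan plus bisection
at K_r = 0 with the kernel at the hawkmoth timescale (t0/Tn = 0.54);
monotonicity of amplitude in μ is checked on the scan, not assumed.  The
default grid is 21 × 21 over K_r ∈ [0, 1] and t0/Tn ∈ [0.01, 1] (odd
counts include the exact endpoints and K_r = 0.5); per-cell kernels come
from rates_from_t0 at κ = 0.62.  A full default sweep takes roughly a
minute on one CPU core (the FIR loop is numba-compiled).

Regime labels: synchronous-entrained if |f − fs| ≤ one spectral bin and
the cell is above the quiescence floor; interference if the amplitude
variation exceeds 5% of the mean peak-to-peak angle; asynchronous-
dominant otherwise when oscillating; quiescent else.  The interference
threshold and quiescence floor are documented knobs — the reference
descriptions of these regimes are qualitative.  The bifurcation scan
bisects the steady amplitude against a 1° threshold on the K_r = 0 axis;
the bridge origin root-finds f_emergent(t0/Tn) = fs with
spectrally-refined frequency estimates on the monotone-decreasing
oscillating branch.  On the shipped placeholder plant the onset sits
near t0/Tn ≈ 0.04 and the bridge origin near 0.2; the hawkmoth marker
(K_r = 0.88, t0/Tn = 0.54) is configuration, not a recomputed quantity,
since the quasi-static estimate (0.86) and the simulation placement
(0.88) are both retained as documented constants.

## Ancestral-state reconstruction

Flight-muscle type evolves as a continuous-time Markov chain (Mk) on a
rooted, time-calibrated tree: equal-rates (ER, 1 parameter) or
all-rates-different (ARD, k(k−1) parameters).  Two-state transition
probabilities use the closed form π + (I − π)e^(−st); ≥ 3 states fall
back to the matrix exponential.  Likelihoods use Felsenstein pruning
with per-node rescaling; ambiguous tips (wingless/unknown, or tips
absent from the trait table — reported with a warning) contribute 1 for
every allowed state, the default coding, with an explicit third state
available.  The root prior is flat by default (stationary optional).
Rates are fitted as bounded log-rates by L-BFGS-B from a one-expected-
change-per-tree start; boundary or effectively-zero-rate solutions are
flagged; AIC = 2k − 2lnL is reported.  Marginal node posteriors combine
below-node pruning partials with above-node partials (re-rooting
formulation) and are exact — they match brute-force enumeration over all
internal-state assignments to 1e−10 on every tree small enough to
enumerate, which is the test oracle throughout (no external package
stands in for the implementation).

The iterative node-constraining probability clamps each successive node
of an ancestor-to-descendant chain to the focal state (clamping =
restricting that node's allowed state set, which makes the product of
step conditionals equal the joint posterior probability of the whole
chain by the chain rule — verified against enumeration).  The published
node-level probabilities (86%/87%/100%) depend on the published
600-odd-tip calibrated phylogeny and its trait table, which are external
inputs; with them supplied, `asr` / `asr-path` compute the corresponding
quantities, and without them the chain-rule and calibration properties
stand in.  The trait simulator draws a birth–death tree (dendropy),
optionally rescaled to a target depth, evolves states by sampling each
branch's transition matrix, and keeps the full internal truth for
scoring; recovery tests use 200-tip trees, 50 seeds, and a reconstruction-
calibration check (nodes with posterior ≈ p are correct ≈ p of the time).

## Problem sizes in the shipped tests

The default test run uses: 100-seed Monte-Carlo for kernel-fit recovery,
50 seeds for seven-parameter fit recovery and for Mk rate recovery
(200-tip trees), a full 21 × 21 sweep of 5 s closed-loop simulations for
the map-topology checks, and enumeration oracles on 2–5-tip trees.  The
whole suite runs in about three minutes on one CPU core.

## Known limitations

* The hawkmoth and roboflapper parameter files are anchored placeholders,
  not measured tables; absolute powers and gains shift with the true
  values, though the documented qualitative structure (entrained tongue,
  bifurcation, bridge near t0/Tn ≈ 0.2) is reproduced by construction of
  the anchors and verified by simulation.
* The aerodynamic model is quasi-steady quadratic drag with constant
  coefficients: no leading-edge-vortex dynamics, wake capture, wing
  pitching, or body translation.
* The muscle model is the reduced linear convolution kernel under tonic
  activation: no calcium dynamics, twitch kinetics, temperature scaling,
  or large-strain nonlinearity; the seven-parameter fit is descriptive,
  not mechanistic.
* Mk reconstruction assumes homogeneous rates across the tree; hidden-
  rate (heterogeneous) models and Bayesian stochastic mapping are out of
  scope.
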