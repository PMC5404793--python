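# Methods

This note documents the models, measurement definitions, numerical choices
and known limitations of `spikeinit`, in the package's own words. Nothing
here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units

Internal unit system: mV, ms, pA, pF, nS, GΩ (mutually consistent:
nS·mV = pA, pF·mV/ms = pA, pF/nS = ms). Constructors and configuration
files accept the units in which such models are conventionally published
(µm, Ω·cm, Ω·cm², µF/cm², pS/µm², MΩ) and convert on load
(`spikeinit.units`).

## Channel models

Two kinetic families share one representation — tabulated `x_inf(V)` and
`tau(V)` per gate on a uniform voltage grid (−120…80 mV, 0.01 mV), with
integer exponents:

* **Boltzmann gates with fixed time constants** (`GateSpec`):
  `x_inf = 1/(1 + exp(−(V − V½)/k))`, first-order relaxation with
  voltage-independent τ. Inactivation is the same code path with negative
  slope factor. The two-compartment model uses exactly the simplified set:
  Na activation V½ = −25 mV, k = 6 mV, τ = 100 µs; Na inactivation
  V½ = −35 mV, k = −6 mV, τ = 0.5 ms; K activation V½ = −15 mV, k = 4 mV,
  τ = 2 ms; all single gates (m·h and n).
* **Rate-function kinetics**: arbitrary α/β(V), used for the canonical
  squid-axon Hodgkin–Huxley reference (6.3 °C set on an absolute voltage
  scale, rest ≈ −65 mV; m³h, n⁴; Cm = 1 µF/cm², gNa = 120, gK = 36,
  gL = 0.3 mS/cm², ENa = 50, EK = −77, EL = −54.387 mV). The same loader
  slot (`Kinetics.from_tables` / `from_file`) accepts user-supplied rate
  tables, e.g. for published cortical Nav/Kv schemes.

**Cable fallback Na activation is m³, not m¹.** The cable model's axonal Na
density (8000 pS/µm²) is ~24,000× its leak density (Rm = 30 kΩ·cm²). A
single Boltzmann gate at V½ = −25 mV leaves an open fraction of ~5·10⁻⁴ at
−70 mV, so the subthreshold Na current would exceed the total leak at every
potential and the cable would have no resting state. The fallback therefore
uses three identical activation gates with per-gate V½ = −40 mV, k = 6 mV,
τ = 100 µs (resting open fraction ~3·10⁻⁷; activation still steep near
threshold), with the inactivation and K gates unchanged from the simplified
set. The two-compartment model keeps its printed single-gate kinetics
exactly — its conductance-to-leak ratio (100:1) is small enough to rest.

**Reversal potentials** are not part of the printed parameter sets; the
package uses standard cortical values ENa = +60 mV, EK = −90 mV, exposed in
every config. Downstream quantities (onset rapidness, influx partition)
shift by some tens of percent across reasonable choices, which is why the
corresponding checks carry wide tolerances.

## Compartmental model

Geometry: isopotential cylindrical soma (default 20 µm × 30 µm; its internal
axial resistance is neglected because the soma acts as a current sink that
effectively clamps the proximal axon) joined to a uniform cylindrical axon
(50 µm × 1 µm, 50 segments; 10 segments for channel-clustering experiments,
mirroring the bookkeeping in which clustering multiplies densities by the
segment count), optional dendrite (3000 µm × 5 µm, 60 segments). Membrane
areas are lateral cylinder areas **without end caps**, the common simulator
convention, so density↔total conversions like 800 nS / 2000 µm² =
400 pS/µm² are reproducible. Passive set: Cm = 0.75 µF/cm², Ri = 150 Ω·cm,
Rm = 30,000 Ω·cm² (τm = 22.5 ms), EL = −70 mV. Channel densities: axonal Na
8000, somatic Na 800 (0 in "no somatic Na" variants), dendritic Na
20 pS/µm². K densities are not part of the printed set; the package default
(axon 1500, soma 320, dendrite 0 pS/µm²) is in the range used by cortical
cable models and gives robust repolarization with the slow simplified K
gate. Axial link resistances are center-to-center:
R = (4·Ri/π)(L₁/(2d₁²) + L₂/(2d₂²)); the soma–axon junction uses the
half-resistance of the first axonal segment.

The compartments form a path graph (dendrite → soma → axon), so the implicit
update is tridiagonal.

## Integration

Operator splitting per step Δt: gates relax **exactly**
(x ← x∞ + (x − x∞)e^(−Δt/τ), coefficients interpolated from the kinetics
tables at the start-of-step voltage), then the voltages advance by an
implicit θ-scheme with conductances frozen over the step — θ = ½
(Crank–Nicolson) for current clamp, solved by the Thomas algorithm; θ = 1
(backward Euler) for voltage-clamp runs, because the clamp conductance 1/Rs
(10⁴–10⁶ nS) makes the somatic equation stiff and Crank–Nicolson would ring
at command steps. Default Δt = 1 µs, recording stride 10 µs (tests and
sweeps use 2–5 µs steps; convergence is checked by halving Δt: spike peak
time shifts < 5 µs and peak dV/dt < 1 %). The discrete scheme satisfies the
summed charge balance exactly (axial terms cancel pairwise); reconstructing
C·dV/dt from recorded traces by centered differences reproduces the balance
to ≲0.3 % of the peak Na current at Δt = 0.5 µs. Resting states are found
by a root solve of the full algebraic current balance with gates at steady
state (residual < 10⁻³ pA), never by settling.

The two-compartment model has its own algebraically explicit 2×2
Crank–Nicolson core with closed-form Boltzmann gate updates; the cable
integrator applied to the equivalent two-node graph reproduces its traces
to < 0.1 mV and serves as a cross-check in the tests, not as the
implementation. **Axonal leak:** the printed single leak conductance
(12 nS, giving the soma its ~20 ms time constant) is applied to each
compartment; scaling it by the capacitance ratio (0.24 nS) leaves the
subthreshold axonal Na current unopposed and the model then has no resting
fixed point at all (verified by nullcline scan). Both choices remain
configurable.

## Protocols

* **Stimuli**: current steps and ramps at any compartment. Rheobase is
  found by bisection (default tolerance 1 pA, 30 ms steps); reproduction
  runs use 1.5× rheobase, a choice made once for all models since the
  original stimuli are unstated.
* **Voltage clamp**: the soma is driven through a series resistance
  (default Rs = 0.1 MΩ, an "ideal" configuration); recorded current is
  (Vcmd − Vs)/Rs, positive into the cell. P/n leak subtraction uses n = 4
  hyperpolarizing subpulses of amplitude −(Vcmd − Vhold)/4 delivered from
  holding (hyperpolarizing so they activate no Na; standard practice where
  the original protocol is not detailed); baselines are measured over the
  5 ms before any prepulse. Subpulses are independent deterministic runs
  from the same holding state, so one subpulse simulation is replicated n
  times. Holding defaults to the model's resting potential; IV scans use
  0.5 mV command resolution.
* **Prepulse inactivation**: a conditioning voltage step before each
  command. Note that in the coupled model a long depolarizing prepulse also
  activates axonal K, which repolarizes the (unclamped) AIS and lets h
  partially recover; the prepulse nevertheless abolishes the IV
  discontinuity, which is the property of interest.
* **Threshold**: V at the first upward crossing of dV/dt = 5 mV/ms before
  the spike peak, linearly interpolated between samples.

## Spike-shape measures

dV/dt is computed by centered differences, optionally after Savitzky–Golay
(local cubic) smoothing — unnecessary for noise-free simulation, recommended
for noisy recordings (with 0.1 mV Gaussian noise at 10 µs sampling, a
51-sample window and a 3 mV slope window recover known rates to better than
10 %; defaults stay at no smoothing / 0.5 mV). The upstroke runs from the
last non-positive dV/dt sample to the voltage peak.

The **phase-slope function** s(V) = d(dV/dt)/dV is a moving least-squares
slope over a ±0.5 mV voltage window along the upstroke; where the
trajectory outruns the sampling (fewer than 3 samples per window) a
neighbor difference substitutes. **Onset rapidness** is the maximum of s
over the *first component* of the phase plot: components are delimited by
strict local maxima of s (prominence > 1 % of the maximum guards float
plateaus; ties resolve to the earlier maximum; maxima with negative s do
not count), and biphasic plots (somatic regeneration) return the earlier,
lower-voltage maximum, with the component boundary at the minimum of s
between the two maxima. Piecewise-linear phase plots whose slope jumps by
> 1.3× without an intervening dip — the degenerate shape of the synthetic
biphasic fixture — are segmented at the jump, provided the rise resolves
within a few samples/estimator windows of voltage; the plateau value clear
of the smeared transition is reported. If s is monotone the supremum is
returned with a flag. **Fixed-dV/dt phase slope** is the local
least-squares slope at the first upward crossing of the queried dV/dt —
the conventional measure, which mis-reads biphasic plots when the queried
value falls on the wrong branch (demonstrated exactly on the biphasic
fixture).

**Tangent prediction.** If the somatic current at initiation is the
resistive axonal current, somatic phase slope = (dVa/dt)/(Va − Vthr); its
maximum is the steepest tangent from (Vthr, 0) to the axonal phase plot.
The sampled ratio diverges as Va → Vthr and vanishes at the voltage peak,
so the tangency is taken as the largest *interior* local maximum along the
trajectory (final sample if the ratio is constant, as for an exponential
trajectory starting at threshold). On the default cable model the
prediction agrees with measured somatic rapidness to a few percent.

**IV discontinuity**: smallest command at which the peak corrected current
jumps by more than 1 nA (at the default 0.5 mV step; both configurable and
reported) between consecutive commands; midpoint of the bracketing pair.
Because the detection threshold is absolute, scans should cover the
threshold region (the paper-style "1 mV below to ~5 mV above"); far above
threshold a steep but graded curve can exceed 1 nA per step.

**Current balance**: Na and K summed over the AIS membrane
(depolarizing-positive, i.e. reported as contributions to C·dV/dt so the
balance sums to zero), axial current measured at the soma–axon junction
(positive = axon → soma; its contribution to the AIS is the negative).
**Na influx** is the time integral of |I_Na| over a window covering one
spike, in pC.

## Extracellular fields

Line-source approximation in a homogeneous resistive medium
(σ = 0.3 S/m): each compartment is a uniform line current with the
closed-form potential φ = I/(4πσL)·[asinh(h₁/r) − asinh(h₀/r)]; the soma is
a thick line source along the cell axis and the radial distance is floored
at the segment radius (evaluation at the membrane surface, which also
removes the on-axis singularity). The source current of a compartment is
ionic + capacitive; by current conservation it equals axial-in + electrode
current, which is how it is computed (no numerical differentiation), so the
monopole balance Σ segment currents = injected current holds to roundoff.
Fields are E = −∇φ by central differences on the grid; default grids frame
the cell with 100 µm margins.

## Synthetic fixtures

The generators produce the traces the estimators are validated on:
exponential upstrokes V = V₀ + A·e^(t/τ) (phase slope exactly 1/τ),
piecewise-exponential biphasic upstrokes continuous in V and dV/dt (phase
slope plateaus r₁ then r₂), and analytic series-RC clamp responses (for
P/n linearity). Defaults (V₀ = −70 mV, A = 0.5 mV, 10 µs sampling, rates
5–40 /ms) sit in the physiological range of the spikes being emulated.
Noise is additive i.i.d. Gaussian on voltage samples with a mandatory seed;
all parameters are recorded in the trace metadata. These fixtures emulate
phase-plane *structure* only — they carry no channel noise, electrode
artifacts, or repolarization — so estimator tests on them validate the
measurement chain, not the biophysics.

## Experiments

`run_experiment` sweeps one structural parameter (Ri ∈ {1, 30, 150,
250} Ω·cm; gNa × {0.5, 1, 2}; soma areas ~10²–10⁴ µm²; clustering positions
on a 10-segment axon; a granule-cell-like preset with 0.3 µm axon and
~300 µm² soma) and characterizes each condition with the same battery
(rheobase, current-clamp threshold, both rapidness measures, tangent
prediction, initiation site, IV discontinuity and peak clamp current).
Everything is deterministic; reports are columnar text with a JSON sidecar
(package version, config hash, solver settings). Tests and the acceptance
script run sweeps at 2–5 µs steps and analysis sampling of 1–10 µs — sizes
chosen so the full suite completes in minutes while staying inside the
convergence envelope above.

## Known limitations

* The simplified fallback kinetics reproduce every *structural* signature
  of critical resistive coupling in the cable model (axonal initiation,
  biphasic somatic / monophasic axonal phase plots, voltage-clamp
  discontinuity co-located with current-clamp threshold, |axial| > |K| on
  the upstroke, additive threshold shift under conductance scaling,
  excitability increasing with Ri and with AIS distance), but not the
  *quantitative* figures obtained with the original published channel
  schemes (e.g. somatic onset rapidness ≈ 52.5 /ms; ours is ≈ 41 /ms).
  Exact reproduction requires loading those rate tables via
  `Kinetics.from_file`.
* With the slow single-gate K (τ = 2 ms) the junction current never
  reverses during repolarization, so the late-phase dipole inversion and
  the negative near-soma extracellular spike seen with fast axonal Kv do
  not occur; the initiation-time dipole (negative near the AIS, positive
  near the soma) is robust.
* The soma-size dependence of the fixed-dV/dt artifact is muted under the
  fallback kinetics (both phase plots become linear below 20 mV/ms); the
  artifact mechanism is demonstrated exactly on the controlled biphasic
  fixture instead.
* For the canonical squid Hodgkin–Huxley reference, the phase slope
  evaluated strictly at dV/dt = 20 mV/ms is ≈ 3.2 /ms — robust to
  stimulus, sampling and integrator — while the maximum ("linear-part")
  phase slope is ≈ 5.6–6.2 /ms; the conventional quoted sharpness of this
  model corresponds to the latter.
* Single electrode with a pure series resistance (no capacitance
  neutralization or bridge balance); isotropic, frequency-independent
  extracellular medium; no stochastic gating, temperature dependence,
  myelination, or reconstructed morphologies.
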