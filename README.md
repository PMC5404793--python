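# spikeinit

Biophysical modelling and analysis of **sharp action-potential onset** in the
soma–AIS system.

Somatic spikes of most vertebrate neurons rise with a distinct "kink":
dV/dt jumps almost discontinuously at onset, even though sodium channels
activate smoothly (Boltzmann slope k ≈ 6 mV). `spikeinit` implements the
modelling apparatus needed to study why: spikes initiate in the axon initial
segment (AIS), which is resistively coupled to a much larger soma. The soma
acts as a current sink — at initiation the Na current entering the AIS is
balanced not by local K/leak currents but by the axial current
I = (Va − Vs)/Ra flowing to the soma, so the soma and AIS form an electrical
dipole, and when the product of axial resistance and Na conductance exceeds a
critical value, axonal Na channels open as a *discontinuous* function of
somatic voltage (critical resistive coupling).

The package is a library for computational neuroscientists who want to
simulate, measure and stress-test this regime:

- **`spikeinit.cable`** — implicit (Crank–Nicolson) compartmental simulator
  for a cylindrical soma + 50 µm axon (optional dendrite), with
  per-compartment channel placement, channel-clustering operations and full
  per-current bookkeeping. Includes the canonical isopotential squid
  Hodgkin–Huxley membrane as the smooth-onset reference.
- **`spikeinit.twocomp`** — the minimal two-compartment soma–AIS model
  (Cs = 250 pF, Ca = 5 pF, Ra = 4.5 MΩ, single-gate Boltzmann channels with
  fixed time constants), integrated by an independent 2-unknown core.
- **`spikeinit.protocols`** — current steps and ramps, somatic voltage clamp
  through a series resistance with P/n leak subtraction and inactivating
  prepulses, spike-threshold detection (dV/dt criterion), rheobase search.
- **`spikeinit.analysis`** — phase plots (dV/dt vs V), onset rapidness as
  the maximum phase slope of the first phase-plot component, fixed-dV/dt
  phase slope, the tangent-based theoretical prediction of somatic
  rapidness from the axonal phase plot, IV-discontinuity detection, and the
  current-balance decomposition at the initiation site.
- **`spikeinit.lsa`** — extracellular potentials and field maps by the
  line-source approximation (σ = 0.3 S/m), showing the soma–AIS dipole.
- **`spikeinit.fixtures`** — synthetic traces with analytically known
  phase-plane structure (exponential and biphasic upstrokes, passive RC
  clamp responses) used to validate every estimator without a simulation.
- **`spikeinit.experiments`** — config-driven sweeps (intracellular
  resistivity, soma size, Na density, channel clustering, small-neuron
  preset, field movies) with deterministic tabular reports.

## Worked example

```python
import spikeinit as sp

# --- two-compartment soma-AIS model -----------------------------------
params = sp.TwoCompartmentParams()
rheobase = sp.find_rheobase(params, dt=1e-3)
stim = sp.StimulusProtocol.step(1.5 * rheobase, onset=1.0)
res = sp.simulate_two_compartment(params, stim, duration=30.0,
                                  dt=1e-3, record_stride=1)
win = sp.spike_window(res.t, res.v_soma)
pp = sp.phase_plot(res.t, res.v_soma, window=win)
rapidness, info = sp.onset_rapidness(pp, return_details=True)
q_ais = sp.na_influx_charge(res, ("axon", 0), window=win)
q_soma = sp.na_influx_charge(res, "soma", window=win)
print(f"rheobase:                {rheobase:.0f} pA")
print(f"somatic phase plot:      {info['n_components']} components")
print(f"onset rapidness:         {rapidness:.1f} /ms")
print(f"Na influx AIS vs soma:   {q_ais:.1f} vs {q_soma:.1f} pC "
      f"({100 * (q_ais / q_soma - 1):+.0f}%)")

# --- somatic voltage clamp ---------------------------------------------
clamp = sp.ClampProtocol.scan(-62.0, -50.0, 0.5)
cr = sp.run_voltage_clamp(params, clamp, dt=5e-3)
iv = sp.IVCurve.from_clamp(cr).annotate_discontinuity()
print(f"IV discontinuity:        {iv.discontinuity_voltage:.2f} mV "
      f"(jump {iv.jump_na:.1f} nA)")
```

prints

```
rheobase:                227 pA
somatic phase plot:      2 components
onset rapidness:         21.3 /ms
Na influx AIS vs soma:   23.7 vs 17.4 pC (+37%)
IV discontinuity:        -56.75 mV (jump 15.0 nA)
```

The somatic spike is *biphasic*: the first, sharp component is the axial
current delivered by the AIS spike (onset rapidness ≈ 21 /ms, versus ≈ 6 /ms
for the smooth isopotential Hodgkin–Huxley reference), the second is the
somatic Na regeneration. Despite an order-of-magnitude difference in channel
*density*, total Na influx in AIS and soma is comparable (≈ 40 % larger in
the AIS), and the peak current seen in somatic voltage clamp jumps by many
nA across a 0.5 mV command increment — the all-or-none signature of critical
resistive coupling. See `docs/methods.md` for the model equations,
measurement definitions and known limitations.

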