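# Methods

This note documents the models implemented in `nsinet`, the parameters
that matter, the calibration that fixed the free ones, the numerical
conventions, and what the shipped tests do and do not demonstrate.

## Neuron models

**AdEx.** All spiking neurons follow the adaptive exponential
integrate-and-fire equations (capacitance `C`, leak `g_L`, rest `E_L`,
sharpness `Delta_T`, adaptation conductance `a`, spike-triggered
increment `b`, adaptation time constant `tau_w`). The defaults are the
regular-bursting parameter set from the AdEx literature (C = 200 pF,
g_L = 10 nS, E_L = −58 mV, Δ_T = 2 mV, a = 2 nS, b = 100 pA), with two
deliberate choices:

* **Spike detection at 0 mV, never at V_th.** V_th only parameterises
  the exponential upstroke. This permits V_reset (−46 mV) above V_th
  (−51 mV): after each reset the upstroke re-ignites, producing
  multi-spike bursts whose length is limited by the adaptation current.
  The gap |V_th − V_reset| therefore controls burst vigour, which is the
  lever behind frequency manipulation.
* **Reset semantics.** A step first integrates both equations with
  explicit Euler; if the updated V_m exceeds 0 mV the step is treated as
  the spike event: V_m is set to the effective reset and w jumps by
  exactly b (the Euler increment of w for that step is discarded). The
  exponential argument is clamped at 20 to avoid overflow inside the
  single step in which the upstroke diverges; this has no effect on
  dynamics because any such step crosses the 0 mV cutoff anyway.

**NSI.** The non-spiking interneuron is a leaky integrator in
displacement coordinates, u = V_m − V_rest, with τ_m·du/dt = −u + R·I.
V_rest = −60 mV. R = 15/148 GΩ so that the maximum input current
(148 pA) displaces the membrane by exactly the 15 mV biological
fluctuation range; τ_m = 20 ms (unpublished; chosen equal to the AdEx
membrane time constant C/g_L). A guard threshold (−30 mV) asserts the
sub-threshold contract: the NSI must never approach spiking for the
graded coupling to be meaningful.

## Coupling rules and sign conventions

The displacement d = |V_rest − V_m| (reference captured at run start,
i.e. −60 mV) drives three rules:

* current injection I = ±w·d, positive for excitatory tests and
  negative for inhibitory ones;
* manipulation offset |V_cm| = d/3, clamped at 5 mV (the range known to
  keep the oscillator stable);
* feedback weight w = scaling·(desired − current spikes in the last
  5 ms window), excitatory below the set point (scaling 2) and
  inhibitory above it (scaling 50), with an optional, default-off cap.

The offset *direction* depends on the characteristic. Excitatory tests
start the targeted characteristic displaced 5 mV away from the default
(V_th at −56 mV, V_reset at −41 mV) and the offset moves it back toward
the default as drive grows, shrinking |V_th − V_reset| and raising the
burst frequency; inhibitory tests start at the defaults and push away.
The untargeted characteristic always keeps the network default (−51 /
−46 mV). Magnitudes are computed from |V_rest − V_m| and signed by the
test polarity: this is the only reading that makes the excitatory
threshold sweep −56 → −51 mV, the current column positive, and both
polarities sweep the same frequency range.

An offset targeted at V_m is added to the membrane potential after
integration, once per recording step (1 ms), config-exposed. Applying it
every 0.1 ms integration step would multiply its effect tenfold (5 mV
per 0.1 ms ≈ a 10 nA-equivalent drive) and swamp the dynamics entirely;
the 1 ms convention matches the description of adding the offset "at
that time step" on the recording grid. Even so, V_m manipulation is the
least stable channel, as expected.

## Network and study conditions

16 neurons: two five-neuron AdEx half-centers coupled by mutual
all-to-all inhibition (no within-population connections), a five-neuron
motor population (MNP) receiving an excitatory projection from one
half-center and an inhibitory one from the other, and the single NSI.
The MNP only ever receives current injections, never voltage
manipulation.

Study conditions (not calibration targets): 6 s trials; input levels
updated every 1 s; stepping schedules run 0 → 148 pA in 29.6 pA
increments for excitatory tests and 148 → 0 pA for inhibitory ones;
Gaussian current noise with σ = 25 pA on the NSI and σ = 50 pA on every
spiking neuron, zero mean, redrawn every integration step (piecewise-
constant current-noise semantics, not rescaled by dt); rate coding with
a 5 ms window sliding at 1 ms.

Synapses between spiking populations are current-based with exponential
decay: each presynaptic spike adds `weight` pA to every target neuron
after the delay, decaying with τ_syn. Because connectivity is all-to-all
with uniform weights, the engine tracks one synaptic current per
source/target population pair, which is exact. A second synaptic bank
with its own decay exists so a projection can carry a fast and a slow
component; the calibrated default uses a single bank.

## Calibration

The half-center weights, delays and bias currents are not constrained by
the study conditions, so they were fixed once against three published
operating-point bands and then frozen as code defaults:

* burst frequency 2.36–2.94 Hz with both half-centers at V_th = −56 mV
  (the zero-drive end of every threshold-manipulation test);
* burst frequency 8.01–8.94 Hz at the default characteristics
  (V_th = −51, V_reset = −46 mV);
* baseline average peak of the rate-coded motor output (no injection)
  in 23–24.26 spikes per 5 ms window, assessed on the across-seed mean.

Calibrated values: sCPG bias 480 pA per neuron; mutual inhibition
−30 pA/spike, τ_syn = 5 ms, delay 1 ms; sCPG adaptation τ_w = 180 ms
(the literature default of 120 ms cannot produce the required threefold
frequency ratio between the two operating points at any bias/inhibition
setting we explored — the ratio is governed by
τ_w·ln(w_burst-end/w_re-ignition), and at 120 ms it saturates near 2).

The motor population uses its own AdEx parameter set: C = 48 pF,
b = 50 pA, τ_w = 5 ms, plus a constant hyperpolarising bias of
−1100 pA, driven by the excitatory half-center at 300 pA/spike and
weakly inhibited (−10 pA/spike) by the other. The rationale:

* the small capacitance gives the population a near-linear rate response
  whose slope matches the published ≈29-spikes-per-window change per
  ±1050 pA of graded injection;
* the strong fixed bias does double duty. It sets the baseline operating
  point, and — because the fast adaptation (τ_w = 5 ms) acts only as a
  per-burst rate cap rather than a drive-dependent suppressor — it fixes
  an *injection-independent* firing floor between bursts. The rate-coded
  output therefore returns to zero between bursts for excitatory
  injections up to +1050 pA (w = 70 nS) and stops returning to zero one
  10 nS increment higher, reproducing the published "lifting" boundary.

`nsinet calibrate` re-checks the shipped defaults against the bands
(≥80 % of seeds inside each frequency band, across-seed mean inside the
peak band) and, on failure, grid-searches bias and inhibition around the
starting point, writing either a calibration YAML or a structured
failure report.

## Measurement conventions

* Peaks are local maxima of the rate signal with ≥2 counts of
  prominence; maxima closer than 50 ms are merged, keeping the largest
  (the rest are recorded as rejected double peaks).
* Burst frequency is the mean of per-gap frequencies 1000/gap_ms; gaps
  longer than 1.7× or shorter than 0.45× the median gap are removed as
  outliers (missed weak bursts and residual double peaks respectively).
  Multi-seed estimates pool gaps across seeds before trimming.
* Stepping-level measurements skip the first 200 ms of each level as
  settling time — the levels are held for 1 s precisely so the network
  can settle between input changes.
* Undefined measures (no peaks, fewer than two peaks) raise a distinct
  error rather than returning zero, because fully suppressed outputs are
  a legitimate outcome.

## Event-driven engine

The event NSI stores (V_m, V_rest, decay, C, t_updated). An input event
first decays V_m over the elapsed interval via decay^Δt and then adds
I/C; the per-ms decay factor relates to the clock engine through
decay = exp(−1 ms/τ_m). Synapses never read the neuron: they receive a
snapshot message on every update and reconstruct V_m(t) exactly, which
is the asynchronous contract this engine preserves (a single-process
priority-ordered event loop stands in for a distributed deployment).
The two AdEx neurons of the demo half-center are integrated clock-driven
between events because the exponential upstroke has no closed form; the
engine is noise-free, and left/right symmetry is broken by the initial
membrane potentials rather than by noise. The demo's V_th range is tied
to the clock-driven manipulation endpoints (−56 to −51 mV) through a
clamped affine map of the NSI potential, and its input step is encoded
with a 20-tap unit-sum Gaussian FIR and threshold 0.95 (standard
Ben's-Spiker-Algorithm practice; only monotone fidelity matters here).

## What the tests show, and known limitations

All inputs are generated from configuration — the simulator itself
defines the study conditions, so passing tests demonstrate internal
consistency with the published operating points, not fidelity to any
recorded biological data. Known limitations:

* **Inhibitory amplitude endpoint.** With −1050 pA of graded inhibition
  the motor output here is fully suppressed (average peak ≈ 0), whereas
  the published endpoint is 6.31 spikes per window. Matching baseline
  (23.6), the excitatory endpoint (52.6) *and* a residual inhibitory
  output simultaneously requires a convex population rate response
  (up-slope ≈ 0.028, down-slope ≈ 0.016 spikes/window per pA), which
  homogeneous motor neurons driven by a common carrier cannot produce;
  graded recruitment across heterogeneous neurons could, but per-neuron
  heterogeneity is out of scope here. The corresponding acceptance test
  is expected to fail and is left failing.
* The V_m-manipulation channel is unstable by construction (as in the
  original experiments) and its frequency effect is not monotone.
* Exact spike trains are not comparable to any other simulator's; only
  distributional and operating-point properties are.
* The calibrated parameters are one solution in a degenerate space; the
  published network's own (unpublished) weights are certainly different.
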