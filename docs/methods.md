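# Methods

This note documents the models, engine semantics, table construction and
numerical choices behind `spikesim`, including the places where the design
was genuinely open and what was decided.

## Units

All internal quantities use the consistent set pF, nS, mV, ms, pA
(`nS·mV = pA = pF·mV/ms`). Parameter files may state SI units (F, S, V, s,
A); the loader converts on read. Spike files on disk store time in seconds
with six decimals and 0-based neuron indices; delays in network files are
rounded to the nearest multiple of 0.1 ms (half up), with a warning when
rounding changes a value.

## Neuron models

All three models share two single-exponential conductances,
`dg/dt = −g/τ` with `τ_AMPA = 5 ms`, `τ_GABA = 10 ms`, `E_AMPA = 0`,
`E_GABA = −80 mV`, incremented instantaneously by the synaptic weight on
spike arrival (inhibition is a receptor type, never a negative weight).

**LIF** — `C dV/dt = g_L(E_L−V) + syn`, C = 190 pF, g_L = 10 nS,
E_L = −65 mV. Fires at `V ≥ V_T = −50 mV`; V resets to E_L (the reset value
is not separately parameterized in the source material; resetting to the
leak reversal is the standard choice for this family and is configurable
via `V_reset`). During the absolute refractory period `T_ref = 2.5 ms` the
membrane is clamped at the reset value while the conductances keep
decaying — whether the source implementation clamps or integrates freely is
unknown; clamping is our documented choice.

**AdEx** — adds `g_L·Δ_T·exp((V−V_T)/Δ_T) − w` to the membrane current and
`τ_w dw/dt = a(V−E_L) − w`, with C = 110 pF, Δ_T = 2 mV, τ_w = 50 ms,
a = 1 nS, b = 9 pA, V_r = −80 mV. The exponential term guarantees divergence
past a few Δ_T, so detection fires at `V ≥ V_T + 5Δ_T = −40 mV`
(configurable `V_detect`); on a spike V ← V_r and w ← w + b. The
exponential's argument is clipped at +15 slope factors so a coarse
integrator overshooting the cutoff produces a large finite current rather
than overflow; the clip never binds below the detection voltage.

**HH** — adds `g_Na m³h(E_Na−V) + g_Kd n⁴(E_K−V)` with first-order gating
`dx/dt = α_x(V)(1−x) − β_x(V)x`. The rate functions are the
Traub–Miles-type forms of the classic conductance-based benchmark network,
parameterized by the offset `V_T = −52 mV`; their removable 0/0
singularities are evaluated by analytic limit. They are defined once
(`spikesim.models.hh_rates`) and used identically by the time-driven
engines and the table compiler. Spikes are detected as upward crossings of
−30 mV (configurable), with a suppression window `T_spike = 1 ms` so one
action potential is never counted twice; no reset is applied — the ODE
produces the spike shape. Gating variables are clipped to [0, 1] after each
step (RK4 can overshoot the physiological range marginally).

**The sodium conductance.** The benchmark parameter table prints
`g_Na = 20 nS` against `g_Kd = 6000 nS`; 20 nS cannot regenerate an action
potential at all. The classic benchmark cell this parameter set derives
from uses 20 µS — but combined with the 120 pF capacitance printed here,
20 µS puts the spike-peak membrane eigenvalue (≈ total conductance / C ≈
70 ms⁻¹) outside classical RK4's stability region at the 1/15 ms step the
study itself prescribes for HH, and both the fixed and bi-fixed engines
verifiably diverge. Because the published HH runs at 1/15 ms evidently did
integrate, the default here is `g_Na = 10 µS`, calibrated so that
(a) the cell produces robust ≈ +47 mV action potentials, and (b) the
spike-peak `h·λ ≈ 2.2–2.9` stays inside RK4's stability region at 1/15 ms
(verified on one-second network runs). Both the printed 20 nS and the
original 20 µS remain selectable.

## Time-driven engines

The classical RK4 tableau is applied to the membrane (and w or m/h/n)
variables. Synaptic conductances, being linear and uncoupled, are advanced
with their exact exponential decay inside each step, and the tableau
evaluates the analytically decayed conductances at sub-step times; pure
RK4-on-everything is available (`analytic_conductances=False`) for strict
order tests. Any non-finite committed state aborts the run with a
`SimulationDivergedError` carrying the neuron ids, time and method — a
too-coarse step on a stiff model fails loudly, never silently.

Spike exchange is grid-based: an emission in the step ending at boundary
`t` is stamped `t`; a spike (input or recurrent) arriving at `t + delay` is
applied at the first grid boundary `≥ t + delay` (causality: never early).
All dynamic populations of one run share the boundary grid.

**Fixed step** — per-model benchmark steps: 0.5 ms (LIF, AdEx), 1/15 ms
(HH). The 1 µs fixed step is the accuracy reference and the table-compiler
integrator.

**Bi-fixed, per-neuron (adaptive)** — per global window `[t, t+T_g)`:
global-mode neurons take one tentative RK4 step of `T_g`; if the result
exceeds `V_s` it is discarded and the window re-integrated as `M_gl` local
steps, entering local mode; local mode persists until `V ≤ V_e` and at
least `T_p` has elapsed since the last spike (benchmark settings: T_g =
1 ms; T_l = 0.25 ms LIF/AdEx, 1/15 ms HH; V_s = V_e = −53/−50/−57 mV;
T_p = 0/0/1 ms). The hysteresis is evaluated once per window. Spikes are
detected at local steps but emitted at the closing global boundary, at most
one per neuron per window (multiple local crossings would be simultaneous
duplicates after quantization).

Two refinements keep the discard rule sound for stiff models. First, a
tentative global result is also discarded when it is non-finite, falls
below every reversal potential (minus a 15 mV margin), or jumps more than
30 mV in one global step — such results mean the global step was too coarse,
exactly like a `V > V_s` result. Second, a neuron skips the tentative
global step entirely when the gating-rate stability criterion
`T_g · max(α_x+β_x) > 2` flags it as unstable a priori: HH gating rates are
≈ 15 ms⁻¹ already at rest, so a 1 ms RK4 step is never stable for HH and
silently corrupts the gates while V still looks subthreshold; the criterion
routes such neurons to the local path deterministically. For LIF and AdEx
none of these conditions trigger in the benchmark regimes, which preserves
the exact equivalence *bi-fixed with unreachable V_s ≡ fixed at T_g*.

**Bi-fixed, batched** — every neuron unconditionally takes `M_gl` local
steps per global window; spikes detected during the window are reported
once, at the window's closing boundary. Conductance increments are applied
on the local grid within the window (the staged-input reading of lock-step
co-processing), while network spikes are exchanged at global boundaries.
Consequence: for a population whose afferent spike timing is unchanged (an
input-driven layer), the batched output equals the fixed-step-at-`T_l`
output with spike times rounded up to `T_g` multiples, exactly; downstream
populations see `T_g`-quantized deliveries, so the equivalence is
per-population.

## Look-up tables

For each model the compiler integrates the *free* dynamics (no input, no
reset) from every node of a state grid with the reference integrator and
stores:

* forecast payloads over axes `(Δt, g_AMPA, g_GABA, [w | m,h,n], V)`;
* two 2-D conductance tables filled from the closed form (no simulation);
* a prediction table over the state axes: `t_f`, the first time the firing
  condition holds within the horizon (`+inf` if never), and `t_e`, the
  suppression-window length (T_ref for LIF, the spike guard for HH; AdEx
  stores no t_e — it has no refractory period).

AdEx free dynamics diverge past threshold, so a trajectory is frozen once
it reaches the detection voltage; every stored value stays finite, and the
engine always consumes `t_f` before any frozen forecast could be observed.
For HH, `t_f` records upward crossings; a grid state already above the
detection voltage is not itself a firing event (the suppression window
handles the ongoing spike).

**Grids.** Defaults: Δt axis of 64 log-spaced nodes in [0.01, 100] ms plus
0 (node times snap to the compiler micro-grid so on-node queries are
exact); V axis 64 linear nodes over [−90, −40] mV; conductance axes 16
nodes (0 plus log-spaced to 1.5× the largest summed benchmark weight); w
axis 16 linear nodes over [−20, 180] pA; gating axes 12 linear nodes in
[0, 1]; horizon 100 ms; compiler micro-step 1 µs. `GridSpec.coarse` halves
the granularities and relaxes the micro-step to 10 µs for fast builds (the
documented accuracy cost is what the granularity-ladder tests measure);
`GridSpec.doubled` doubles every axis — one rung of the accuracy ladder.
Published table *sizes* are not reproduced: the granularities behind them
are not published, so the monotone granularity→accuracy ladder stands in.

**Queries** select the nearest node per axis (round-half-up, clamping at
axis ends; Δt beyond the axis maximum clamps — free trajectories have
settled by then). Granularity, not interpolation, is the accuracy knob;
multilinear interpolation is nevertheless available behind a flag. The
*direct* layout stores one payload per table, the *combined* layout stores
all same-axis payloads in one table; the values are numerically identical,
so direct and combined simulations produce identical spike trains while
differing in index computations per update. Tables round-trip bitwise
through HDF5 with a parameter fingerprint; loading against different
parameters is rejected.

## Event engine

A binary-heap event queue pops in nondecreasing time with the
deterministic tie-break (time, kind priority, neuron id) and kind order
td_step < propagated_spike < sync_check < internal_spike — deliveries
before grouping before firing at equal timestamps. Pushing an event into
the past raises a causality error.

A spike arriving at a neuron triggers the three-step process: table update
over the elapsed time (skipped when Δt = 0 — nothing has elapsed; without
the skip an equal-timestamp second arrival would snap the off-node state to
its grid node, breaking the exact `t_sync = 0 ≡ direct` equivalence),
conductance increment, and a firing prediction. Every new prediction
rotates the neuron's validity token; a pending internal spike popped with a
stale token is dropped ("discarded") — O(1) lazy invalidation instead of
queue surgery. A surviving internal spike records the soma spike at
`t* = quantize(t, t_sync)` (ceiling to the next multiple — never earlier
than the true event; `t_sync = 0` leaves times unchanged), applies the
post-spike action, schedules one propagated event per distinct output delay
at `t* + delay`, and re-predicts from the post-spike state. A LIF
prediction during the refractory window is deferred to the window's end.

Synchronous technique: the first member of an exactly-tied arrival group
updates the state and schedules one sync check at the same timestamp; all
members increment conductances; the sync check makes the single prediction.
"Simultaneous" means exactly equal timestamps — the synchrony this exploits
comes from quantized upstream emission, which produces exact ties; no
epsilon window. Instrumented counters (events, per-population updates,
predictions, deliveries, invalidations) support the prediction-economy
measurements; wall-clock performance is hardware-dependent and is neither
measured nor asserted.

Each run applies one technique to all dynamic populations; mixed
event/time-driven runs are out of scope (the benchmarks never mix within a
run).

## Benchmark generator

`build_benchmark` emulates driven random recurrent networks: independent
homogeneous Poisson relays (exponential inter-spike intervals) project onto
a recurrent conductance-based layer with exact in-degrees (10 input
afferents at 7 nS; K recurrent afferents, sampled without replacement, no
self-connections, no multapses — forbidding multapses keeps in-degree
counts deterministic). Excitatory/inhibitory identity is assigned by index
block (first 80 %), and recurrent afferents are sampled stratified 80/20
from the two blocks so the per-type synapse totals are exact. Weight
scaling for the connectivity experiment: K ≤ 80 keeps (0.5, 2.5) nS; each
doubling beyond 80 halves both weights. All delays are 0.1 ms. Neurons
start from rest (V = E_L, conductances 0, HH gating at its voltage-clamp
fixed point).

What the generator does *not* emulate: heterogeneous parameters,
distance-dependent or patterned connectivity, synaptic plasticity,
correlated or non-stationary input statistics, and conduction-delay
heterogeneity. Passing tests therefore certify the simulation machinery
under idealized Poisson drive, not fidelity to any biological circuit.

With the printed LIF parameters a single 7 nS input EPSP peaks at 6.93 mV
against the 15 mV threshold gap, so at low input rates the second layer
operates as a near-threshold coincidence detector: its mean rate at the
2 Hz input extreme is extremely sensitive to sub-millivolt implementation
details (≈ 1.1 Hz here, stable across step sizes 0.5/0.1 ms and seeds),
while the 5 Hz operating point robustly yields ≈ 9–9.6 Hz and the 16 Hz
extreme ≈ 43–44 Hz.

## Problem sizes used by tests and the acceptance script

The acceptance script runs the benchmark networks at full published size
(up to 16,000 neurons and 20.6 million synapses) for one second of
biological time. The test suite exercises the same code paths on
down-scaled topologies (100-relay, 400-neuron layers with identical
per-neuron input in-degree), 200–400 ms horizons, and coarse table grids
with a 10 µs compile micro-step; the 1 µs reference is computed once per
session on the miniature three-layer network. These sizes are the
package's own choice of test scale; every full-size quantity is produced
by `scripts/acceptance.py`.

## Known limitations

* Event-driven accuracy is bounded by table granularity; the default grids
  favor memory and compile time over the multi-hundred-MB tables a
  production build would use.
* The bi-fixed batched engine models lock-step co-processing semantics on
  the CPU; no actual device execution or threading is included.
* Only the 4th-order Runge-Kutta solver is provided; other solver families
  (Euler, RK2, BDF) are out of scope.
* The HH kinetics follow the standard Traub–Miles forms; the source
  material's exact gating equations are unpublished, so absolute HH spike
  times are model-assumption-dependent (all engines share the single
  definition, so cross-engine comparisons remain internally consistent).
* LIF behavior during the refractory period (clamp vs. free integration)
  and the event-queue ordering of simultaneous internal vs. propagated
  spikes at one neuron are undocumented in the source material; the choices
  above are fixed and documented.
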