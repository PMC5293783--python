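"""Time-driven integration engines: fixed-step and bi-fixed-step RK4.

Three engine variants share one classical 4th-order Runge-Kutta core:

``fixed``
    Every neuron advances with the same step size on every step.
``bifixed_adaptive``
    Per-neuron hysteresis between a global step T_g and a local step
    T_l = T_g / M_gl.  A neuron integrating at T_g whose membrane potential
    exceeds V_s has that result discarded; the window is re-integrated as
    M_gl local steps and the neuron stays in local mode until V <= V_e and
    at least T_p has elapsed since its last spike.  Spikes are detected at
    local steps but emitted at the closing global boundary.
``bifixed_batched``
    Every neuron unconditionally takes M_gl local steps per global window
    (the lock-step semantics of a device that synchronizes with the host
    once per global step); spikes are detected at local steps and reported
    at the closing global boundary.

Synaptic conductances are linear and uncoupled, so by default they are
advanced with their exact exponential decay and the RK4 tableau is applied
to the remaining variables, evaluating the analytically decayed
conductances at the sub-step times.  Set ``analytic_conductances=False``
to include the conductances in the RK4 vector (useful for strict
convergence-order checks).

A 1 us fixed step with this engine serves as the reference integrator for
accuracy analysis and look-up-table compilation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .models import (ModelKind, NeuronParameters, NeuronState,
                     derivatives_arrays, hh_gating_steady_state)
from .network import Network, SpikeTrain

__all__ = [
    "IntegrationConfig", "SimulationDivergedError", "rk4_step",
    "advance_bifixed_adaptive", "advance_bifixed_batched",
    "run_time_driven", "REFERENCE_STEP", "reference_config",
]

#: Step size (ms) of the reference integrator.
REFERENCE_STEP = 1e-3


class SimulationDivergedError(ArithmeticError):
    """A state variable became non-finite.

    Carries the offending neuron ids, the simulation time and the method,
    so a too-coarse step on a stiff model fails loudly instead of
    producing silent garbage.
    """

    def __init__(self, neuron_ids, time, method):
        self.neuron_ids = list(np.atleast_1d(neuron_ids))
        self.time = float(time)
        self.method = method
        super().__init__(
            f"non-finite state in method {method!r} at t={time:g} ms "
            f"(neuron ids {self.neuron_ids[:5]}...)")


@dataclass(frozen=True)
class IntegrationConfig:
    """Integration method selection and its step parameters (ms, mV).

    ``V_s`` (scale-down) and ``V_e`` (scale-up) form the hysteresis of the
    bi-fixed method; ``T_p`` holds the local step for at least that long
    after a spike (used by HH to cover the hyperpolarization phase).
    """

    method: str = "fixed"          # fixed | bifixed_adaptive | bifixed_batched
    step: float = 0.5              # fixed-step size
    T_g: float = 1.0               # global step
    T_l: float = 0.25              # local step
    V_s: float = -53.0
    V_e: float = -53.0
    T_p: float = 0.0
    analytic_conductances: bool = True

    def __post_init__(self):
        if self.method not in ("fixed", "bifixed_adaptive", "bifixed_batched"):
            raise ValueError(f"unknown integration method {self.method!r}")
        if self.method == "fixed":
            if self.step <= 0:
                raise ValueError("fixed step must be positive")
        else:
            if self.T_g <= 0 or self.T_l <= 0:
                raise ValueError("T_g and T_l must be positive")
            ratio = self.T_g / self.T_l
            if abs(ratio - round(ratio)) > 1e-9:
                raise ValueError("T_g must be an integer multiple of T_l")
            if self.V_e > self.V_s:
                raise ValueError("V_e must not exceed V_s")
            if self.T_p < 0:
                raise ValueError("T_p must be nonnegative")

    @property
    def M_gl(self) -> int:
        return int(round(self.T_g / self.T_l))

    @property
    def boundary_step(self) -> float:
        """Grid on which spikes are emitted and delivered."""
        return self.step if self.method == "fixed" else self.T_g

    @classmethod
    def benchmark(cls, kind, method="fixed", **overrides) -> "IntegrationConfig":
        """Per-model settings of the benchmark study.

        Fixed step 0.5 ms for LIF/AdEx and 1/15 ms for HH; bi-fixed
        T_g = 1 ms with T_l = 0.25 ms (LIF/AdEx) or 1/15 ms (HH);
        hysteresis thresholds -53 / -50 / -57 mV and T_p = 0 / 0 / 1 ms
        for LIF / AdEx / HH respectively.
        """
        kind = ModelKind.parse(kind)
        table = {
            ModelKind.LIF: dict(step=0.5, T_g=1.0, T_l=0.25,
                                V_s=-53.0, V_e=-53.0, T_p=0.0),
            ModelKind.ADEX: dict(step=0.5, T_g=1.0, T_l=0.25,
                                 V_s=-50.0, V_e=-50.0, T_p=0.0),
            ModelKind.HH: dict(step=1.0 / 15.0, T_g=1.0, T_l=1.0 / 15.0,
                               V_s=-57.0, V_e=-57.0, T_p=1.0),
        }[kind]
        table.update(overrides)
        return cls(method=method, **table)


def reference_config(step: float = REFERENCE_STEP) -> IntegrationConfig:
    """Fixed-step configuration of the reference integrator."""
    return IntegrationConfig(method="fixed", step=step)


# ---------------------------------------------------------------------------
# RK4 core on arrays
# ---------------------------------------------------------------------------

def _rk4_arrays(params: NeuronParameters, state: dict, h: float,
                analytic: bool) -> dict:
    """One RK4 step for a dict of state arrays sharing one parameter set.

    ``state`` holds V, g_ampa, g_gaba and, per model, w or m/h/n.  With
    ``analytic`` the conductances follow their closed-form decay and only
    the remaining variables enter the tableau.
    """
    names = params.state_variables()  # differential vars except conductances
    gA0, gG0 = state["g_ampa"], state["g_gaba"]
    if analytic:
        gA_h = gA0 * math.exp(-0.5 * h / params.tau_AMPA)
        gG_h = gG0 * math.exp(-0.5 * h / params.tau_GABA)
        gA_f = gA0 * math.exp(-h / params.tau_AMPA)
        gG_f = gG0 * math.exp(-h / params.tau_GABA)
        g_at = [(gA0, gG0), (gA_h, gG_h), (gA_h, gG_h), (gA_f, gG_f)]
    else:
        names = names + ("g_ampa", "g_gaba")
        g_at = None

    y0 = {k: state[k] for k in names}

    def f(y, stage):
        kw = {k: y.get(k, state.get(k)) for k in ("V", "w", "m", "h", "n")}
        if analytic:
            gA, gG = g_at[stage]
        else:
            gA, gG = y["g_ampa"], y["g_gaba"]
        d = derivatives_arrays(params, kw["V"], gA, gG, w=kw["w"],
                               m=kw["m"], h=kw["h"], n=kw["n"])
        return {k: d[k] for k in names}

    k1 = f(y0, 0)
    k2 = f({k: y0[k] + 0.5 * h * k1[k] for k in names}, 1)
    k3 = f({k: y0[k] + 0.5 * h * k2[k] for k in names}, 2)
    k4 = f({k: y0[k] + h * k3[k] for k in names}, 3)

    out = dict(state)
    for k in names:
        out[k] = y0[k] + (h / 6.0) * (k1[k] + 2 * k2[k] + 2 * k3[k] + k4[k])
    if analytic:
        out["g_ampa"], out["g_gaba"] = gA_f, gG_f
    if params.kind is ModelKind.HH:
        # Keep gating physiological: RK4 can overshoot [0, 1] marginally.
        for k in ("m", "h", "n"):
            out[k] = np.clip(out[k], 0.0, 1.0)
    return out


def rk4_step(kind, params: NeuronParameters, state: NeuronState, h: float,
             analytic_conductances: bool = True) -> NeuronState:
    """Classical RK4 update of a single neuron state over step ``h``.

    No spike detection or reset is applied; ``t_last`` advances by h.
    """
    kind = ModelKind.parse(kind)
    if h <= 0:
        raise ValueError("step size must be positive")
    arrs = {k: np.asarray(getattr(state, k), dtype=float)
            for k in ("V", "g_ampa", "g_gaba", "w", "m", "h", "n")}
    out = _rk4_arrays(params, arrs, h, analytic_conductances)
    if not all(np.isfinite(v).all() for v in out.values()):
        raise SimulationDivergedError([0], state.t_last + h, "rk4_step")
    new = state.copy()
    for k in ("V", "g_ampa", "g_gaba", "w", "m", "h", "n"):
        setattr(new, k, float(out[k]))
    new.t_last = state.t_last + h
    return new


# ---------------------------------------------------------------------------
# Population state
# ---------------------------------------------------------------------------

class _PopState:
    """Struct-of-arrays state for one dynamic population."""

    __slots__ = ("params", "V", "g_ampa", "g_gaba", "w", "m", "h", "n",
                 "refr_until", "last_spike", "local_mode", "V_prev")

    def __init__(self, params: NeuronParameters, size: int):
        self.params = params
        self.V = np.full(size, params.E_L)
        self.g_ampa = np.zeros(size)
        self.g_gaba = np.zeros(size)
        self.w = np.zeros(size)
        if params.kind is ModelKind.HH:
            m, h, n = hh_gating_steady_state(params, self.V)
            self.m, self.h, self.n = m.copy(), h.copy(), n.copy()
        else:
            self.m = np.zeros(size)
            self.h = np.ones(size)
            self.n = np.zeros(size)
        self.refr_until = np.full(size, -np.inf)
        self.last_spike = np.full(size, -np.inf)
        self.local_mode = np.zeros(size, dtype=bool)
        self.V_prev = self.V.copy()

    _VARS = ("V", "g_ampa", "g_gaba", "w", "m", "h", "n")
    _BOOK = ("refr_until", "last_spike", "V_prev")

    def as_dict(self) -> dict:
        d = {"V": self.V, "g_ampa": self.g_ampa, "g_gaba": self.g_gaba}
        if self.params.kind is ModelKind.ADEX:
            d["w"] = self.w
        elif self.params.kind is ModelKind.HH:
            d.update(m=self.m, h=self.h, n=self.n)
        return d

    def set_from(self, d: dict) -> None:
        for k, v in d.items():
            setattr(self, k, v)

    def snapshot(self) -> dict:
        return {k: getattr(self, k).copy()
                for k in self._VARS + self._BOOK}

    def extract(self, mask: np.ndarray) -> "_PopState":
        """Independent copy of the neurons selected by ``mask``."""
        sub = _PopState.__new__(_PopState)
        sub.params = self.params
        for k in self._VARS + self._BOOK:
            setattr(sub, k, getattr(self, k)[mask].copy())
        sub.local_mode = self.local_mode[mask].copy()
        return sub

    def commit(self, mask: np.ndarray, sub: "_PopState") -> None:
        idx = np.nonzero(mask)[0]
        for k in self._VARS + self._BOOK:
            getattr(self, k)[idx] = getattr(sub, k)


def _detect_and_reset(ps: _PopState, t_end: float) -> np.ndarray:
    """Apply the model's spike condition and post-spike action in place.

    Returns the boolean fired mask.  ``t_end`` is the time at the end of
    the just-integrated step (the detection time).
    """
    p = ps.params
    if p.kind is ModelKind.LIF:
        refr = t_end < ps.refr_until - 1e-9
        fired = (ps.V >= p.V_T) & ~refr
        ps.V[refr] = p.V_reset       # clamped during the refractory window
        if fired.any():
            ps.V[fired] = p.V_reset
            ps.refr_until[fired] = t_end + p.T_ref
    elif p.kind is ModelKind.ADEX:
        fired = ps.V >= p.V_detect
        if fired.any():
            ps.V[fired] = p.V_r
            ps.w[fired] += p.b
    else:  # HH: upward crossing outside the suppression window, no reset
        refr = t_end < ps.refr_until - 1e-9
        fired = (ps.V >= p.V_detect) & (ps.V_prev < p.V_detect) & ~refr
        if fired.any():
            ps.refr_until[fired] = t_end + p.T_spike
    if fired.any():
        ps.last_spike[fired] = t_end
    ps.V_prev = ps.V.copy()
    return fired


def _checked_step(ps: _PopState, h: float, analytic: bool, t_end: float,
                  method: str, offset: int) -> None:
    # overflow in a diverging step is reported via the explicit check below
    with np.errstate(all="ignore"):
        out = _rk4_arrays(ps.params, ps.as_dict(), h, analytic)
    bad = ~np.isfinite(out["V"])
    if bad.any():
        raise SimulationDivergedError(np.nonzero(bad)[0] + offset,
                                      t_end, method)
    ps.set_from(out)


# ---------------------------------------------------------------------------
# Single-population window updates (the spec-level operations)
# ---------------------------------------------------------------------------

def advance_bifixed_adaptive(kind, params: NeuronParameters, ps: _PopState,
                             cfg: IntegrationConfig, t_start: float,
                             offset: int = 0):
    """Advance one population across one global window [t, t+T_g).

    Global-mode neurons take one RK4 step of T_g; any whose resulting V
    exceeds V_s have that result discarded and the window re-integrated as
    M_gl local steps (entering local mode).  Local-mode neurons always take
    the M_gl local steps.  Local mode is left once V <= V_e and at least
    T_p has elapsed since the last spike.  Returns the fired mask; all
    spikes carry the timestamp t + T_g.
    """
    T_g, T_l, M = cfg.T_g, cfg.T_l, cfg.M_gl
    t_end = t_start + T_g
    start = ps.snapshot()
    p = ps.params

    # A global RK4 step is only meaningful where it is numerically stable.
    # The stiff part of the HH model is the gating subsystem, linear in
    # each gate with rate a_x(V) + b_x(V); a step h is unstable once
    # h * rate leaves the RK4 stability region (about 2.78 on the real
    # axis).  Neurons violating the criterion at the window start skip the
    # tentative global step and integrate locally, exactly as if the
    # result had been discarded.
    if p.kind is ModelKind.HH:
        from .models import hh_rates
        a_m, b_m, a_h, b_h, a_n, b_n = hh_rates(p, ps.V)
        rate = np.maximum(np.maximum(a_m + b_m, a_h + b_h), a_n + b_n)
        stiff = T_g * rate > 2.0
    else:
        stiff = np.zeros(len(ps.V), dtype=bool)

    # Tentative global step (vectorized); local-mode neurons, stiff
    # neurons and fresh violators are then recomputed from the saved
    # window-start state.  A tentative result that is non-finite or left
    # the model's physiological region is discarded like a V > V_s result;
    # only the local re-integration may fail fatally.
    with np.errstate(all="ignore"):
        out = _rk4_arrays(p, ps.as_dict(), T_g, cfg.analytic_conductances)
    ok = np.ones(len(ps.V), dtype=bool)
    for v in out.values():
        ok &= np.isfinite(v)
    v_floor = min(p.E_L, p.E_GABA, p.E_K if p.E_K is not None else 0.0) - 15.0
    with np.errstate(invalid="ignore"):
        ok &= out["V"] >= v_floor
        ok &= np.abs(out["V"] - start["V"]) <= 30.0
    ps.set_from(out)
    violators = (ps.V > cfg.V_s) | ~ok | stiff
    redo = violators | ps.local_mode
    fired = np.zeros(len(ps.V), dtype=bool)

    if redo.any():
        sub = ps.extract(redo)          # holds post-global values...
        for k in _PopState._VARS + _PopState._BOOK:
            getattr(sub, k)[:] = start[k][redo]   # ...restored to window start
        sub_fired = np.zeros(int(redo.sum()), dtype=bool)
        for j in range(M):
            tl = t_start + (j + 1) * T_l
            _checked_step(sub, T_l, cfg.analytic_conductances, tl,
                          "bifixed_adaptive", offset)
            sub_fired |= _detect_and_reset(sub, tl)
        # At most one emission per neuron per window, stamped at t_end.
        sub.last_spike[sub_fired] = t_end
        ps.commit(redo, sub)
        fired[np.nonzero(redo)[0]] = sub_fired

    stay = ~redo
    if stay.any():
        keep = ps.extract(stay)
        keep.V_prev = start["V_prev"][stay].copy()
        f2 = _detect_and_reset(keep, t_end)
        ps.commit(stay, keep)
        fired[np.nonzero(stay)[0]] = f2

    ps.V_prev = ps.V.copy()

    # Hysteresis, evaluated once per window: enter local on violation,
    # leave once V <= V_e and at least T_p has elapsed since the last spike.
    can_exit = (ps.V <= cfg.V_e) & (t_end - ps.last_spike >= cfg.T_p - 1e-9)
    ps.local_mode = (violators | ps.local_mode) & ~can_exit
    return fired


def advance_bifixed_batched(kind, params: NeuronParameters, ps: _PopState,
                            cfg: IntegrationConfig, t_start: float,
                            offset: int = 0):
    """Advance the whole population by M_gl unconditional local steps.

    Spikes are detected at local boundaries; the returned mask reports
    each neuron at most once, stamped at the closing global boundary.
    """
    M, T_l = cfg.M_gl, cfg.T_l
    fired = np.zeros(len(ps.V), dtype=bool)
    for j in range(M):
        tl = t_start + (j + 1) * T_l
        _checked_step(ps, T_l, cfg.analytic_conductances, tl,
                      "bifixed_batched", offset)
        fired |= _detect_and_reset(ps, tl)
    if fired.any():
        ps.last_spike[fired] = t_start + cfg.T_g
    return fired


# ---------------------------------------------------------------------------
# Full network loop
# ---------------------------------------------------------------------------

def _fanout_indices(row_ptr: np.ndarray, sources: np.ndarray) -> np.ndarray:
    """Indices of all synapses whose (sorted) source is in ``sources``."""
    counts = row_ptr[sources + 1] - row_ptr[sources]
    total = int(counts.sum())
    if total == 0:
        return np.empty(0, dtype=np.int64)
    shift = np.repeat(row_ptr[sources] - np.concatenate(
        ([0], np.cumsum(counts)[:-1])), counts)
    return shift + np.arange(total, dtype=np.int64)


class _DeliveryTable:
    """Synapses sorted by source with a CSR row pointer, plus a schedule of
    pending conductance increments keyed by delivery-grid step index."""

    def __init__(self, network: Network, h: float):
        syn = network.synapses
        self.h = h
        order = np.argsort(syn.source, kind="stable")
        self.src_sorted = syn.source[order].astype(np.int64)
        self.tgt = syn.target[order].astype(np.int64)
        self.wgt = syn.weight[order].astype(np.float64)
        self.dly = syn.delay[order].astype(np.float64)
        self.inh = syn.inhibitory[order]
        n = network.n_neurons
        self.n_neurons = n
        self.row_ptr = np.searchsorted(self.src_sorted, np.arange(n + 1))
        self.pending: dict[int, list[np.ndarray]] = {}

    def schedule_from_sources(self, sources: np.ndarray, t_emit) -> None:
        """Queue deliveries for spikes of ``sources`` emitted at ``t_emit``
        (scalar or per-source array)."""
        idx = _fanout_indices(self.row_ptr, sources)
        if len(idx) == 0:
            return
        if np.isscalar(t_emit):
            arrive = t_emit + self.dly[idx]
        else:
            counts = self.row_ptr[sources + 1] - self.row_ptr[sources]
            arrive = np.repeat(np.asarray(t_emit, dtype=float), counts) \
                + self.dly[idx]
        steps = np.ceil(arrive / self.h - 1e-9).astype(np.int64)
        order = np.argsort(steps, kind="stable")
        steps_s, idx_s = steps[order], idx[order]
        cuts = np.nonzero(np.diff(steps_s))[0] + 1
        firsts = np.concatenate(([0], cuts))
        for s, chunk in zip(steps_s[firsts], np.split(idx_s, cuts)):
            self.pending.setdefault(int(s), []).append(chunk)

    def collect(self, step: int):
        """Conductance increments (exc, inh) due at boundary ``step``."""
        parts = self.pending.pop(step, None)
        if not parts:
            return None, None
        idx = np.concatenate(parts)
        t, w, inh = self.tgt[idx], self.wgt[idx], self.inh[idx]
        exc_inc = np.bincount(t[~inh], weights=w[~inh],
                              minlength=self.n_neurons)
        inh_inc = np.bincount(t[inh], weights=w[inh],
                              minlength=self.n_neurons)
        return exc_inc, inh_inc


def run_time_driven(network: Network, inputs: SpikeTrain, duration: float,
                    cfg, seed=None, counters: dict | None = None
                    ) -> SpikeTrain:
    """Simulate all dynamic populations of ``network`` with one time-driven
    method for ``duration`` ms and return the emitted spikes.

    ``cfg`` is a single :class:`IntegrationConfig` applied to every dynamic
    population, or a dict mapping population names to configs; all configs
    must share the same boundary step (spikes are exchanged on a common
    grid).  ``inputs`` are relay-population spikes (ms, global indices),
    delivered through the relay neurons' output synapses after the synaptic
    delay, rounded up to the delivery grid.  Output spike times are exact
    multiples of the boundary step, sorted by (time, neuron index).
    """
    if duration <= 0:
        return SpikeTrain.empty()
    if not inputs.is_sorted():
        raise ValueError("input spikes must be sorted by time")
    dyn = network.dynamic_populations()
    if isinstance(cfg, IntegrationConfig):
        cfgs = {p.name: cfg for p in dyn}
    else:
        cfgs = dict(cfg)
        missing = [p.name for p in dyn if p.name not in cfgs]
        if missing:
            raise ValueError(f"no integration config for {missing}")
    steps = {round(cfgs[p.name].boundary_step, 12) for p in dyn}
    if len(steps) > 1:
        raise ValueError("all populations must share one boundary step")
    h_b = cfgs[dyn[0].name].boundary_step
    methods = {cfgs[p.name].method for p in dyn}
    # Delivery grid: the local step for the batched method (the device
    # stages the window's input per local step), the boundary otherwise.
    if "bifixed_batched" in methods:
        if len(methods) > 1:
            raise ValueError("the batched method cannot be mixed with "
                             "other methods in one run")
        h_d = cfgs[dyn[0].name].T_l
    else:
        h_d = h_b
    sub = int(round(h_b / h_d))

    n_steps = int(math.ceil(duration / h_b - 1e-9))
    table = _DeliveryTable(network, h_d)
    if len(inputs):
        table.schedule_from_sources(inputs.indices.astype(np.int64),
                                    inputs.times)

    states = {p.name: _PopState(p.params, p.size) for p in dyn}
    out_t, out_i = [], []
    if counters is not None:
        counters.setdefault("steps", 0)
        counters.setdefault("local_windows", 0)

    for k in range(n_steps):
        t0 = k * h_b
        t1 = (k + 1) * h_b
        fired_global: list[np.ndarray] = []
        if sub == 1:
            exc, inh = table.collect(k)
            if exc is not None:
                for p in dyn:
                    sl = slice(p.start, p.stop)
                    states[p.name].g_ampa += exc[sl]
                    states[p.name].g_gaba += inh[sl]
            for p in dyn:
                c, ps = cfgs[p.name], states[p.name]
                if c.method == "fixed":
                    _checked_step(ps, c.step, c.analytic_conductances, t1,
                                  "fixed", p.start)
                    fired = _detect_and_reset(ps, t1)
                    if fired.any():
                        ps.last_spike[fired] = t1
                elif c.method == "bifixed_adaptive":
                    fired = advance_bifixed_adaptive(p.model, p.params, ps,
                                                     c, t0, p.start)
                    if counters is not None:
                        counters["local_windows"] += int(ps.local_mode.sum())
                else:
                    fired = advance_bifixed_batched(p.model, p.params, ps,
                                                    c, t0, p.start)
                if fired.any():
                    fired_global.append(np.nonzero(fired)[0] + p.start)
        else:
            # Batched mode with a finer delivery grid: apply increments at
            # each local boundary, advance one local step at a time.
            fired_acc = {p.name: np.zeros(p.size, dtype=bool) for p in dyn}
            for j in range(sub):
                exc, inh = table.collect(k * sub + j)
                if exc is not None:
                    for p in dyn:
                        sl = slice(p.start, p.stop)
                        states[p.name].g_ampa += exc[sl]
                        states[p.name].g_gaba += inh[sl]
                tl = t0 + (j + 1) * h_d
                for p in dyn:
                    c, ps = cfgs[p.name], states[p.name]
                    _checked_step(ps, c.T_l, c.analytic_conductances, tl,
                                  "bifixed_batched", p.start)
                    fired_acc[p.name] |= _detect_and_reset(ps, tl)
            for p in dyn:
                fired = fired_acc[p.name]
                if fired.any():
                    states[p.name].last_spike[fired] = t1
                    fired_global.append(np.nonzero(fired)[0] + p.start)
        if counters is not None:
            counters["steps"] += 1
        if fired_global:
            ids = np.concatenate(fired_global)
            out_t.append(np.full(len(ids), t1))
            out_i.append(ids)
            table.schedule_from_sources(ids, t1)

    if not out_t:
        return SpikeTrain.empty()
    return SpikeTrain.from_records(np.concatenate(out_t),
                                   np.concatenate(out_i))


def run_reference(network: Network, inputs: SpikeTrain, duration: float,
                  step: float = REFERENCE_STEP) -> SpikeTrain:
    """Fixed-step reference simulation (default 1 us RK4)."""
    return run_time_driven(network, inputs, duration, reference_config(step))
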