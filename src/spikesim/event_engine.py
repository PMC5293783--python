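"""Discrete-event simulation core for table-driven neuron models.

Firing is a two-stage mechanism.  When an arriving spike changes a
neuron's state, the prediction table is consulted; a finite predicted
firing delay schedules an *internal spike* event.  Any later event that
re-predicts for the same neuron rotates a per-neuron validity token, so a
previously scheduled internal spike that is popped with a stale token is
silently dropped ("discarded").  A surviving internal spike records the
soma spike and schedules one *propagated spike* event per distinct output
delay, each delivering the spike to every target sharing that delay.

The *synchronous* technique exploits exact timestamp ties: the first
member of a group of simultaneous arrivals updates the neuron state and
schedules a single *sync check* event at the same timestamp; every member
only increments its conductance; the sync check then makes one firing
prediction for the whole group.  With a synchronization period
``t_sync > 0``, output spikes are emitted at the next multiple of
``t_sync`` (never earlier: causality), which makes downstream input
exactly synchronous.  With ``t_sync = 0`` the technique reduces to the
direct one.

Event ordering is total and deterministic: (time, kind priority, neuron
id), with kind priorities td_step < propagated_spike < sync_check <
internal_spike so that deliveries precede grouping, and grouping precedes
firing, at equal times.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field

import numpy as np

from .models import ModelKind, NeuronParameters, NeuronState
from .network import Network, SpikeTrain
from .lut import TableSet, query_update, predict_firing

__all__ = [
    "Event", "EventQueue", "SyncConfig", "quantize_spike_time",
    "run_event_driven", "EVENT_PRIORITY", "CausalityError",
]

#: Kind priority at equal timestamps (lower pops first).
EVENT_PRIORITY = {"td_step": 0, "propagated_spike": 1, "sync_check": 2,
                  "internal_spike": 3}


class CausalityError(ValueError):
    """An event was pushed into the past."""


@dataclass(frozen=True, order=True)
class Event:
    """A queued simulation event with a deterministic ordering key."""

    time: float
    priority: int
    neuron: int
    kind: str = field(compare=False)
    token: int = field(default=0, compare=False)      # internal spikes
    payload: object = field(default=None, compare=False)  # delay group

    @classmethod
    def make(cls, kind: str, time: float, neuron: int, token: int = 0,
             payload=None) -> "Event":
        if not (time >= 0 and math.isfinite(time)):
            raise ValueError(f"invalid event time {time!r}")
        return cls(time, EVENT_PRIORITY[kind], neuron, kind, token, payload)


class EventQueue:
    """Timestamp-ordered event queue with deterministic tie-breaking.

    Pops in nondecreasing time; ties break by kind priority then neuron
    id.  Pushing an event earlier than the last popped time raises
    :class:`CausalityError`.
    """

    def __init__(self):
        self._heap: list[Event] = []
        self._now = 0.0

    def __len__(self) -> int:
        return len(self._heap)

    @property
    def now(self) -> float:
        return self._now

    def push(self, event: Event) -> None:
        if event.time < self._now - 1e-12:
            raise CausalityError(
                f"event at t={event.time:g} pushed after t={self._now:g}")
        heapq.heappush(self._heap, event)

    def pop(self) -> Event:
        ev = heapq.heappop(self._heap)
        self._now = ev.time
        return ev


@dataclass(frozen=True)
class SyncConfig:
    """Synchronization period for the synchronous technique (ms).

    ``t_sync = 0`` disables output quantization (asynchronous behavior,
    identical to the direct technique)."""

    t_sync: float = 0.0

    def __post_init__(self):
        if self.t_sync < 0:
            raise ValueError("t_sync must be nonnegative")


def quantize_spike_time(t: float, t_sync: float) -> float:
    """Smallest multiple of ``t_sync`` that is >= t (t unchanged when
    ``t_sync`` is 0).  Never earlier than the true event: causality."""
    if t < 0 or t_sync < 0:
        raise ValueError("times must be nonnegative")
    if t_sync == 0:
        return t
    k = math.ceil(t / t_sync - 1e-12)
    return k * t_sync


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

class _Neuron:
    """Per-neuron bookkeeping for the event engine."""

    __slots__ = ("state", "token", "suppressed_until", "sync_mark")

    def __init__(self, params: NeuronParameters):
        self.state = NeuronState.resting(params)
        self.token = 0
        self.suppressed_until = -math.inf
        self.sync_mark = -1.0     # timestamp of the pending sync group


def _delay_groups(network: Network):
    """Per source neuron: list of (delay, target array, weight array,
    inhibitory array), one entry per distinct delay, ordered by delay."""
    syn = network.synapses
    groups: list[list] = [[] for _ in range(network.n_neurons)]
    if not len(syn):
        return groups
    order = np.lexsort((syn.delay, syn.source))
    src = syn.source[order]
    tgt = syn.target[order]
    wgt = syn.weight[order].astype(float)
    dly = syn.delay[order].astype(float)
    inh = syn.inhibitory[order]
    cuts = np.nonzero((np.diff(src) != 0) | (np.diff(dly) != 0))[0] + 1
    starts = np.concatenate(([0], cuts, [len(src)]))
    for a, b in zip(starts[:-1], starts[1:]):
        groups[src[a]].append((float(dly[a]), tgt[a:b], wgt[a:b], inh[a:b]))
    return groups


def run_event_driven(network: Network, inputs: SpikeTrain, duration: float,
                     mode: str, tables, sync: SyncConfig | None = None,
                     interpolate: bool = False,
                     counters: dict | None = None) -> SpikeTrain:
    """Event-driven simulation of all dynamic populations.

    ``mode`` selects the table layout and the input-handling technique:
    'direct', 'combined', 'synchronous' or 'combined_synchronous'.
    ``tables`` is a single :class:`TableSet` (applied to every dynamic
    population sharing its model kind) or a dict mapping population names
    to table sets; layouts are re-arranged to match ``mode``.  ``sync``
    supplies the synchronization period for the synchronous modes
    (default 0: asynchronous).

    Optional ``counters`` is filled with instrumentation: events processed,
    per-population state updates, firing predictions and deliveries, plus
    internal-spike and invalidation (stale-token) totals.
    """
    if mode not in ("direct", "combined", "synchronous",
                    "combined_synchronous"):
        raise ValueError(f"unknown event-driven mode {mode!r}")
    layout = "combined" if mode.startswith("combined") else "direct"
    synchronous = mode.endswith("synchronous")
    t_sync = (sync or SyncConfig()).t_sync if synchronous else 0.0
    if not inputs.is_sorted():
        raise ValueError("input spikes must be sorted by time")

    dyn = network.dynamic_populations()
    if isinstance(tables, TableSet):
        tset = {p.name: tables for p in dyn}
    else:
        tset = dict(tables)
    missing = [p.name for p in dyn if p.name not in tset]
    if missing:
        raise ValueError(f"no tables for populations {missing}")
    for name, ts in list(tset.items()):
        pop = network.population(name)
        if ts.kind is not pop.model:
            raise ValueError(f"tables for {name} are for {ts.kind.value}, "
                             f"population model is {pop.model.value}")
        tset[name] = ts.to_layout(layout)

    pop_of = np.full(network.n_neurons, -1, dtype=np.int64)
    for i, p in enumerate(dyn):
        pop_of[p.start:p.stop] = i
    neurons = {}
    for p in dyn:
        for gid in range(p.start, p.stop):
            neurons[gid] = _Neuron(p.params)

    groups = _delay_groups(network)
    queue = EventQueue()
    cnt = counters if counters is not None else {}
    cnt.setdefault("events", 0)
    cnt.setdefault("updates", {p.name: 0 for p in dyn})
    cnt.setdefault("predictions", {p.name: 0 for p in dyn})
    cnt.setdefault("deliveries", {p.name: 0 for p in dyn})
    cnt.setdefault("internal_spikes", 0)
    cnt.setdefault("invalidated", 0)

    out_t: list[float] = []
    out_i: list[int] = []

    def pop_name(gid: int) -> str:
        return dyn[pop_of[gid]].name

    def predict(gid: int, t: float) -> None:
        """Make a firing prediction for neuron gid at time t; rotate the
        validity token (discarding any pending internal spike) and schedule
        a new internal spike when the prediction is positive."""
        nrn = neurons[gid]
        name = pop_name(gid)
        t_f, _t_e = predict_firing(tset[name], nrn.state, interpolate)
        cnt["predictions"][name] += 1
        nrn.token += 1
        if math.isfinite(t_f):
            # Firing cannot complete inside the suppression window.
            t_int = max(t + t_f, nrn.suppressed_until)
            queue.push(Event.make("internal_spike", t_int, gid,
                                  token=nrn.token))

    def update_state(gid: int, t: float) -> None:
        nrn = neurons[gid]
        dt = t - nrn.state.t_last
        if dt < -1e-12:
            raise CausalityError(f"neuron {gid} updated backwards in time")
        if dt <= 0.0:
            return   # nothing elapsed: no table access, state already current
        nrn.state = query_update(tset[pop_name(gid)], nrn.state, dt,
                                 interpolate)
        cnt["updates"][pop_name(gid)] += 1

    def deliver(gid: int, t: float, weight: float, inhibitory: bool) -> None:
        """The arrival of one spike at one target neuron."""
        nrn = neurons[gid]
        cnt["deliveries"][pop_name(gid)] += 1
        if synchronous:
            if nrn.sync_mark != t:
                update_state(gid, t)
                nrn.sync_mark = t
                queue.push(Event.make("sync_check", t, gid))
            if inhibitory:
                nrn.state.g_gaba += weight
            else:
                nrn.state.g_ampa += weight
        else:
            update_state(gid, t)
            if inhibitory:
                nrn.state.g_gaba += weight
            else:
                nrn.state.g_ampa += weight
            predict(gid, t)

    def fire(gid: int, t: float) -> None:
        """A surviving internal spike: record, reset, propagate."""
        nrn = neurons[gid]
        params = dyn[pop_of[gid]].params
        update_state(gid, t)
        t_star = quantize_spike_time(t, t_sync)
        if t_star <= duration + 1e-12:
            out_t.append(t_star)
            out_i.append(gid)
        cnt["internal_spikes"] += 1
        # Post-spike action (the soma spike itself).
        if params.kind is ModelKind.LIF:
            nrn.state.V = params.V_reset
            nrn.suppressed_until = t + params.T_ref
        elif params.kind is ModelKind.ADEX:
            nrn.state.V = params.V_r
            nrn.state.w += params.b
        else:
            nrn.suppressed_until = t + params.T_spike
        for delay, _tgt, _w, _inh in groups[gid]:
            queue.push(Event.make("propagated_spike", t_star + delay, gid,
                                  payload=delay))
        # Re-predict from the post-spike state (conductances persist and
        # may drive immediate re-firing once suppression ends).
        predict(gid, t)

    # Seed the queue with the relay-input propagated spikes.
    for t_in, src in zip(inputs.times, inputs.indices):
        for delay, _tgt, _w, _inh in groups[int(src)]:
            queue.push(Event.make("propagated_spike", float(t_in) + delay,
                                  int(src), payload=delay))

    while len(queue):
        ev = queue.pop()
        if ev.time > duration + 1e-12:
            break
        cnt["events"] += 1
        if ev.kind == "propagated_spike":
            for delay, tgt, wgt, inh in groups[ev.neuron]:
                if delay == ev.payload:
                    for j in range(len(tgt)):
                        gid = int(tgt[j])
                        if pop_of[gid] >= 0:
                            deliver(gid, ev.time, float(wgt[j]),
                                    bool(inh[j]))
                    break
        elif ev.kind == "sync_check":
            nrn = neurons[ev.neuron]
            nrn.sync_mark = -1.0
            predict(ev.neuron, ev.time)
        elif ev.kind == "internal_spike":
            nrn = neurons[ev.neuron]
            if ev.token != nrn.token:
                cnt["invalidated"] += 1
                continue
            if ev.time < nrn.suppressed_until - 1e-12:
                # The prediction predates the suppression bookkeeping;
                # re-examine once the window closes.
                queue.push(Event.make("internal_spike",
                                      nrn.suppressed_until, ev.neuron,
                                      token=nrn.token))
                continue
            fire(ev.neuron, ev.time)
        else:
            raise ValueError(f"unexpected event kind {ev.kind!r}")

    return SpikeTrain.from_records(np.asarray(out_t),
                                   np.asarray(out_i, dtype=np.int64))
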