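"""Accuracy and activity metrics, and the method-comparison harness.

Simulation accuracy is measured with the van Rossum spike-train distance:
each train is convolved with a causal exponential kernel exp(-t/tau) and
the metric is the L2 norm of the difference, evaluated in closed form over
the merged event sequence (no time discretization).  For two trains with
spike times {t_i} and {s_j},

    D^2 = (1/tau) * Int (f - g)^2 dt
        = 1/2 [ sum_ii' e^(-|t_i - t_i'|/tau) + sum_jj' e^(-|s_j - s_j'|/tau)
                - 2 sum_ij e^(-|t_i - s_j|/tau) ]

so a single spike against an empty train gives 1/sqrt(2), and two single
spikes offset by tau give sqrt(1 - e^-1).  Distances are computed neuron by
neuron with matched indices and aggregated (mean by default) across the
population.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import Network, SpikeTrain
from .time_driven import IntegrationConfig, run_time_driven, REFERENCE_STEP

__all__ = [
    "VanRossumConfig", "van_rossum_distance", "mean_firing_rate",
    "run_method", "compare_methods",
]


@dataclass(frozen=True)
class VanRossumConfig:
    """Kernel time constant (ms) and across-neuron aggregation."""

    tau: float = 1.0
    aggregation: str = "mean"   # 'mean' | 'sum'

    def __post_init__(self):
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.aggregation not in ("mean", "sum"):
            raise ValueError("aggregation must be 'mean' or 'sum'")


def _pair_sum(t1: np.ndarray, t2: np.ndarray, tau: float) -> float:
    """sum_ij exp(-|t1_i - t2_j| / tau), via broadcasting."""
    if len(t1) == 0 or len(t2) == 0:
        return 0.0
    return float(np.exp(-np.abs(t1[:, None] - t2[None, :]) / tau).sum())


def _per_neuron(train: SpikeTrain, n_neurons: int) -> list:
    out = [np.empty(0)] * n_neurons
    if len(train) == 0:
        return out
    order = np.argsort(train.indices, kind="stable")
    idx = train.indices[order]
    tms = train.times[order]
    cuts = np.nonzero(np.diff(idx))[0] + 1
    for i, chunk in zip(idx[np.concatenate(([0], cuts))],
                        np.split(tms, cuts)):
        if not 0 <= i < n_neurons:
            raise ValueError(f"spike index {i} outside 0..{n_neurons - 1}")
        out[i] = np.sort(chunk)
    return out


def van_rossum_distance(a: SpikeTrain, b: SpikeTrain, n_neurons: int,
                        cfg: VanRossumConfig = VanRossumConfig()) -> float:
    """van Rossum distance between two spike trains over a shared neuron
    set, exact closed form, aggregated per ``cfg`` (mean over neurons by
    default)."""
    tau = cfg.tau
    ta, tb = _per_neuron(a, n_neurons), _per_neuron(b, n_neurons)
    dists = np.empty(n_neurons)
    for i in range(n_neurons):
        d2 = 0.5 * (_pair_sum(ta[i], ta[i], tau)
                    + _pair_sum(tb[i], tb[i], tau)
                    - 2.0 * _pair_sum(ta[i], tb[i], tau))
        dists[i] = np.sqrt(max(d2, 0.0))
    return float(dists.mean() if cfg.aggregation == "mean" else dists.sum())


def mean_firing_rate(train: SpikeTrain, n_neurons: int,
                     window: float) -> float:
    """Total spikes / (n_neurons * window), in Hz (window in ms)."""
    if window <= 0:
        raise ValueError("window must be positive")
    if n_neurons <= 0:
        raise ValueError("n_neurons must be positive")
    return len(train) / n_neurons / (window / 1000.0)


# ---------------------------------------------------------------------------
# Method dispatch and comparison harness
# ---------------------------------------------------------------------------

#: The eight benchmark method names.
TIME_DRIVEN_METHODS = ("td_fixed", "td_bifixed", "td_bifixed_batched")
EVENT_DRIVEN_METHODS = ("event_direct", "event_combined", "event_sync",
                        "event_combined_sync")


def run_method(network: Network, inputs: SpikeTrain, duration: float,
               method: str, *, cfg: IntegrationConfig | None = None,
               tables=None, t_sync: float = 1.0,
               counters: dict | None = None) -> SpikeTrain:
    """Run one named simulation method on a network.

    Time-driven methods take an :class:`IntegrationConfig` (benchmark
    defaults for the population model when omitted); event-driven methods
    require compiled ``tables``.  ``method='reference'`` runs the 1 us
    fixed-step reference.
    """
    from .event_engine import run_event_driven, SyncConfig

    model = network.dynamic_populations()[0].model
    if method == "reference":
        step = cfg.step if cfg is not None else REFERENCE_STEP
        return run_time_driven(
            network, inputs, duration,
            IntegrationConfig(method="fixed", step=step),
            counters=counters)
    if method in TIME_DRIVEN_METHODS:
        if cfg is None:
            engine = {"td_fixed": "fixed",
                      "td_bifixed": "bifixed_adaptive",
                      "td_bifixed_batched": "bifixed_batched"}[method]
            cfg = IntegrationConfig.benchmark(model, engine)
        return run_time_driven(network, inputs, duration, cfg,
                               counters=counters)
    if method in EVENT_DRIVEN_METHODS:
        if tables is None:
            raise ValueError(f"method {method} needs compiled tables")
        mode = {"event_direct": "direct", "event_combined": "combined",
                "event_sync": "synchronous",
                "event_combined_sync": "combined_synchronous"}[method]
        sync = SyncConfig(t_sync if mode.endswith("synchronous") else 0.0)
        return run_event_driven(network, inputs, duration, mode, tables,
                                sync=sync, counters=counters)
    raise ValueError(f"unknown method {method!r}")


def compare_methods(network: Network, inputs: SpikeTrain, duration: float,
                    methods, *, tables=None, t_sync: float = 1.0,
                    reference_step: float = REFERENCE_STEP, tau: float = 1.0,
                    measure_population: str | None = None,
                    out_csv=None):
    """Run each method against the fixed-step reference and tabulate the
    van Rossum distance, mean firing rate and event/step counters of the
    measured population (the last dynamic population by default).

    Returns a pandas DataFrame; also written as CSV when ``out_csv`` is
    given.  Deterministic for fixed network/input seeds.
    """
    import pandas as pd

    pop = network.population(measure_population) \
        if measure_population else network.dynamic_populations()[-1]
    ref = run_time_driven(
        network, inputs, duration,
        IntegrationConfig(method="fixed", step=reference_step))
    ref_sel = ref.select(pop.start, pop.stop).shifted(-pop.start)
    cfg_vr = VanRossumConfig(tau=tau)
    rows = []
    for method in methods:
        counters: dict = {}
        cfg = IntegrationConfig(method="fixed", step=reference_step) \
            if method == "reference" else None
        out = run_method(network, inputs, duration, method, cfg=cfg,
                         tables=tables, t_sync=t_sync, counters=counters)
        sel = out.select(pop.start, pop.stop).shifted(-pop.start)
        rows.append({
            "method": method,
            "van_rossum": van_rossum_distance(sel, ref_sel, pop.size,
                                              cfg_vr),
            "mean_rate_hz": mean_firing_rate(sel, pop.size, duration),
            "n_spikes": len(sel),
            "events": counters.get("events", counters.get("steps", 0)),
            "predictions": sum(counters.get("predictions", {}).values())
            if isinstance(counters.get("predictions"), dict) else 0,
        })
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
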