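"""Network construction, benchmark presets, Poisson inputs and file I/O.

The benchmark family used throughout the package is a two-layer random
network: an input layer of relay neurons that only forwards externally
generated Poisson spike trains, and a recurrently connected second layer of
LIF, AdEx or HH neurons (80% excitatory, 20% inhibitory).  Every
second-layer neuron receives exactly 10 input afferents (7 nS, excitatory)
and exactly K recurrent afferents (default K=80: 0.5 nS excitatory /
2.5 nS inhibitory).  All propagation delays are 0.1 ms.  Variants add a
third layer (accuracy experiments), scale the second-layer size, the input
rate, or the recurrent in-degree K with a compensating weight scaling.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .models import ModelKind, NeuronParameters

log = logging.getLogger(__name__)

__all__ = [
    "SpikeTrain", "SynapseSet", "Population", "Network", "BenchmarkSpec",
    "round_delay", "build_benchmark", "generate_poisson_train",
    "read_spikes", "write_spikes", "read_network", "write_network",
]

#: Delay grid (ms): all synaptic propagation delays are multiples of this.
DELAY_QUANTUM = 0.1


def round_delay(d: float) -> float:
    """Round a propagation delay to the nearest multiple of 0.1 ms.

    Half cases round up (0.25 -> 0.3).  A warning is logged whenever
    rounding changes the value.
    """
    if d < 0:
        raise ValueError("delays must be nonnegative")
    # Work in integer tenths-of-ms to avoid float-representation drift.
    k = math.floor(d / DELAY_QUANTUM + 0.5)
    rounded = k * DELAY_QUANTUM
    if abs(rounded - d) > 1e-9:
        log.warning("delay %.6g ms rounded to %.1f ms", d, rounded)
    return round(rounded, 10)


# ---------------------------------------------------------------------------
# Spike trains
# ---------------------------------------------------------------------------

@dataclass
class SpikeTrain:
    """An ordered set of (time, neuron index) records.

    Times are in ms, sorted lexicographically by (time, index).  This is
    the universal currency for inputs, outputs and accuracy analysis.
    """

    times: np.ndarray
    indices: np.ndarray

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=np.float64)
        self.indices = np.asarray(self.indices, dtype=np.int64)
        if self.times.shape != self.indices.shape:
            raise ValueError("times and indices must have equal length")

    @classmethod
    def empty(cls) -> "SpikeTrain":
        return cls(np.empty(0), np.empty(0, dtype=np.int64))

    @classmethod
    def from_records(cls, times, indices) -> "SpikeTrain":
        """Build a sorted train from unsorted records."""
        t = np.asarray(times, dtype=np.float64)
        i = np.asarray(indices, dtype=np.int64)
        order = np.lexsort((i, t))
        return cls(t[order], i[order])

    def __len__(self) -> int:
        return len(self.times)

    def __eq__(self, other) -> bool:
        if not isinstance(other, SpikeTrain):
            return NotImplemented
        return (np.array_equal(self.times, other.times)
                and np.array_equal(self.indices, other.indices))

    def is_sorted(self) -> bool:
        if len(self.times) < 2:
            return True
        dt = np.diff(self.times)
        ties = dt == 0
        return bool(np.all(dt >= 0)
                    and np.all(np.diff(self.indices)[ties] >= 0))

    def select(self, lo: int, hi: int) -> "SpikeTrain":
        """Sub-train of neurons with lo <= index < hi (indices preserved)."""
        mask = (self.indices >= lo) & (self.indices < hi)
        return SpikeTrain(self.times[mask], self.indices[mask])

    def shifted(self, offset: int) -> "SpikeTrain":
        return SpikeTrain(self.times.copy(), self.indices + offset)


def generate_poisson_train(n_neurons: int, rate: float, duration: float,
                           seed) -> SpikeTrain:
    """Independent homogeneous Poisson spike trains for ``n_neurons``.

    Inter-spike intervals are exponential with mean 1/rate; ``rate`` in Hz,
    ``duration`` in ms.  Output is sorted by (time, index).
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if rate == 0 or duration <= 0 or n_neurons == 0:
        return SpikeTrain.empty()
    rng = np.random.default_rng(seed)
    mean_isi = 1000.0 / rate  # ms
    times, indices = [], []
    for i in range(n_neurons):
        # Draw ISIs in blocks until the cumulative time passes `duration`.
        t, spikes = 0.0, []
        while True:
            block = rng.exponential(mean_isi, size=max(8, int(1.5 * duration / mean_isi) + 8))
            cum = t + np.cumsum(block)
            inside = cum[cum < duration]
            spikes.append(inside)
            if len(inside) < len(cum):
                break
            t = cum[-1]
        st = np.concatenate(spikes)
        times.append(st)
        indices.append(np.full(len(st), i, dtype=np.int64))
    return SpikeTrain.from_records(np.concatenate(times),
                                   np.concatenate(indices))


# ---------------------------------------------------------------------------
# Populations and synapses
# ---------------------------------------------------------------------------

@dataclass
class Population:
    """A homogeneous group of neurons occupying a contiguous index range.

    ``model`` is None for input-relay populations (no dynamics: they only
    forward externally supplied spikes).  ``n_excitatory`` marks how many
    of the leading indices emit excitatory synapses; the rest are
    inhibitory sources.
    """

    name: str
    start: int
    size: int
    model: ModelKind | None = None
    params: NeuronParameters | None = None
    n_excitatory: int | None = None

    @property
    def stop(self) -> int:
        return self.start + self.size

    @property
    def is_relay(self) -> bool:
        return self.model is None


@dataclass
class SynapseSet:
    """Flat arrays describing all synapses of a network.

    ``inhibitory`` encodes the receptor type; weights are nonnegative (nS).
    Delays are multiples of 0.1 ms.
    """

    source: np.ndarray      # int32 presynaptic global index
    target: np.ndarray      # int32 postsynaptic global index
    weight: np.ndarray      # float32 nS
    delay: np.ndarray       # float32 ms
    inhibitory: np.ndarray  # bool

    def __post_init__(self):
        n = len(self.source)
        for name in ("target", "weight", "delay", "inhibitory"):
            if len(getattr(self, name)) != n:
                raise ValueError("synapse arrays must share one length")

    def __len__(self) -> int:
        return len(self.source)

    @classmethod
    def concatenate(cls, parts) -> "SynapseSet":
        return cls(
            np.concatenate([p.source for p in parts]),
            np.concatenate([p.target for p in parts]),
            np.concatenate([p.weight for p in parts]),
            np.concatenate([p.delay for p in parts]),
            np.concatenate([p.inhibitory for p in parts]),
        )


@dataclass
class Network:
    """Populations plus the synapse set connecting them.

    Neuron indices are global and 0-based; population index ranges are
    contiguous and non-overlapping, with the input relay population first.
    """

    populations: list[Population]
    synapses: SynapseSet
    meta: dict = field(default_factory=dict)

    @property
    def n_neurons(self) -> int:
        return max(p.stop for p in self.populations)

    def population(self, name: str) -> Population:
        for p in self.populations:
            if p.name == name:
                return p
        raise KeyError(f"no population named {name!r}")

    def dynamic_populations(self) -> list[Population]:
        return [p for p in self.populations if not p.is_relay]

    def validate(self) -> None:
        n = self.n_neurons
        if len(self.synapses):
            if self.synapses.source.min() < 0 or self.synapses.source.max() >= n:
                raise ValueError("synapse source index out of range")
            if self.synapses.target.min() < 0 or self.synapses.target.max() >= n:
                raise ValueError("synapse target index out of range")
            tenths = np.round(self.synapses.delay / DELAY_QUANTUM)
            if not np.allclose(tenths * DELAY_QUANTUM, self.synapses.delay,
                               atol=1e-9):
                raise ValueError("delays must be multiples of 0.1 ms")


# ---------------------------------------------------------------------------
# Benchmark presets
# ---------------------------------------------------------------------------

@dataclass
class BenchmarkSpec:
    """Parameters selecting one of the benchmark network presets.

    preset
        'table2'  two-layer recurrent baseline (1,000 + 4,000 neurons);
        'table3'  three-layer feed-forward accuracy variant;
        'table4'  scalability variant (second layer 1000 * 2**scale_n);
        'table5'  input-rate variant (16,000 second-layer neurons);
        'table6'  connectivity variant (16,000 neurons, K recurrent
                  afferents with compensating weight scaling).
    """

    preset: str = "table2"
    model: ModelKind = ModelKind.LIF
    seed: int = 0
    scale_n: int = 0          # table4: second layer = 1000 * 2**scale_n
    recurrent_k: int = 80     # table6: recurrent in-degree
    n_input: int = 1000
    n_input_afferents: int = 10
    input_weight: float = 7.0     # nS
    exc_weight: float = 0.5       # nS (K <= 80)
    inh_weight: float = 2.5       # nS (K <= 80)
    delay: float = 0.1            # ms
    params: NeuronParameters | None = None
    # Optional uniform down-scaling of all layer sizes (e.g. 0.1 builds a
    # 100 + 400 neuron miniature with identical per-neuron in-degrees).
    size_factor: float = 1.0


def _exact_in_degree(rng, n_targets, pool_lo, pool_hi, k, target_offset,
                     forbid_self=False):
    """Sample, for each of ``n_targets`` targets, exactly ``k`` distinct
    afferents uniformly from [pool_lo, pool_hi), excluding the target
    itself when ``forbid_self``.  Returns (sources, targets) arrays."""
    pool = pool_hi - pool_lo
    need = pool - 1 if forbid_self else pool
    if k > need:
        raise ValueError(f"in-degree {k} exceeds afferent pool of {need}")
    sources = np.empty(n_targets * k, dtype=np.int32)
    targets = np.empty(n_targets * k, dtype=np.int32)
    for j in range(n_targets):
        tgt = target_offset + j
        if forbid_self and pool_lo <= tgt < pool_hi:
            pick = rng.choice(pool - 1, size=k, replace=False)
            local_self = tgt - pool_lo
            pick = np.where(pick >= local_self, pick + 1, pick)
        else:
            pick = rng.choice(pool, size=k, replace=False)
        sources[j * k:(j + 1) * k] = pool_lo + pick
        targets[j * k:(j + 1) * k] = tgt
    return sources, targets


def _stratified_recurrent(rng, n_targets, src_lo, src_hi, n_exc, k,
                          target_offset, forbid_self):
    """Exact-in-degree recurrent sampling stratified by source type:
    80% of the k afferents come from the excitatory block, 20% from the
    inhibitory block, so the printed excitatory/inhibitory synapse counts
    are met exactly."""
    k_exc = int(round(k * 0.8))
    k_inh = k - k_exc
    s1, t1 = _exact_in_degree(rng, n_targets, src_lo, src_lo + n_exc, k_exc,
                              target_offset, forbid_self)
    s2, t2 = _exact_in_degree(rng, n_targets, src_lo + n_exc, src_hi, k_inh,
                              target_offset, forbid_self)
    return np.concatenate([s1, s2]), np.concatenate([t1, t2])


def table6_weights(k: int, exc: float = 0.5, inh: float = 2.5):
    """Recurrent weight scaling of the connectivity experiment.

    In-degrees up to 80 keep the baseline (0.5, 2.5) nS; each doubling
    beyond 80 halves both weights, e.g. K=1280 -> (0.03125, 0.15625) nS.
    """
    if k <= 80:
        return exc, inh
    factor = k / 80.0
    if factor != 2 ** round(math.log2(factor)):
        raise ValueError("recurrent in-degree must be 10 * 2**n")
    return exc / factor, inh / factor


def build_benchmark(spec: BenchmarkSpec) -> Network:
    """Construct one of the benchmark networks.

    Construction is deterministic given ``spec.seed``: per-layer afferents
    are sampled without replacement (exact in-degrees, no self-connections,
    no multapses), and the excitatory/inhibitory identity of second-layer
    neurons is assigned by index block (first 80% excitatory).
    """
    model = ModelKind.parse(spec.model)
    params = spec.params or NeuronParameters.defaults(model)
    rng = np.random.default_rng(spec.seed)
    f = spec.size_factor

    def scaled(n):
        m = int(round(n * f))
        if m < 1:
            raise ValueError("size_factor too small")
        return m

    n_in = scaled(spec.n_input)
    if spec.preset in ("table2", "table3"):
        n_layer = scaled(4000)
    elif spec.preset == "table4":
        n_layer = scaled(1000 * 2 ** spec.scale_n)
    elif spec.preset in ("table5", "table6"):
        n_layer = scaled(16000)
    else:
        raise ValueError(f"unknown preset {spec.preset!r}")

    k_rec = spec.recurrent_k if spec.preset == "table6" else 80
    if f != 1.0:
        k_rec = max(5, int(round(k_rec * min(1.0, f * 4))))  # keep degrees sane
        k_rec = min(k_rec, int(0.8 * n_layer))
        k_rec -= k_rec % 5  # keep the 80/20 split exact
    w_exc, w_inh = table6_weights(spec.recurrent_k, spec.exc_weight,
                                  spec.inh_weight) \
        if spec.preset == "table6" else (spec.exc_weight, spec.inh_weight)
    k_in = min(spec.n_input_afferents, n_in)
    n_exc = int(round(n_layer * 0.8))
    delay = round_delay(spec.delay)

    pops = [Population("input", 0, n_in)]
    pops.append(Population("layer2", n_in, n_layer, model, params, n_exc))
    parts = []

    def input_block(target_pop):
        s, t = _exact_in_degree(rng, target_pop.size, 0, n_in, k_in,
                                target_pop.start)
        parts.append(SynapseSet(
            s, t,
            np.full(len(s), spec.input_weight, dtype=np.float32),
            np.full(len(s), delay, dtype=np.float32),
            np.zeros(len(s), dtype=bool)))

    def recurrent_block(src_pop, target_pop):
        forbid = src_pop is target_pop
        s, t = _stratified_recurrent(rng, target_pop.size, src_pop.start,
                                     src_pop.stop, src_pop.n_excitatory,
                                     k_rec, target_pop.start, forbid)
        inh = s >= src_pop.start + src_pop.n_excitatory
        parts.append(SynapseSet(
            s, t,
            np.where(inh, w_inh, w_exc).astype(np.float32),
            np.full(len(s), delay, dtype=np.float32),
            inh))

    layer2 = pops[1]
    input_block(layer2)
    if spec.preset == "table3":
        layer3 = Population("layer3", layer2.stop, n_layer, model, params,
                            n_exc)
        pops.append(layer3)
        input_block(layer3)
        recurrent_block(layer2, layer3)
    else:
        recurrent_block(layer2, layer2)

    net = Network(pops, SynapseSet.concatenate(parts),
                  meta={"preset": spec.preset, "model": model.value,
                        "seed": spec.seed, "recurrent_k": k_rec,
                        "exc_weight": float(w_exc),
                        "inh_weight": float(w_inh),
                        "size_factor": f,
                        "scale_n": spec.scale_n})
    net.validate()
    return net


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------
# Spike files: plain text, two whitespace-separated columns -- time in
# seconds (6 decimal places) and 0-based neuron index -- sorted by time.
# Network files: JSON holding either a benchmark generation rule plus seed
# (regenerated on load) or explicit synapse lists.

def write_spikes(train: SpikeTrain, path) -> None:
    with open(path, "w") as fh:
        for t, i in zip(train.times, train.indices):
            fh.write(f"{t / 1000.0:.6f} {i}\n")


def read_spikes(path) -> SpikeTrain:
    times, indices = [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split()
            if len(cols) != 2:
                raise ValueError(f"{path}:{lineno}: expected two columns")
            try:
                times.append(float(cols[0]) * 1000.0)
                indices.append(int(cols[1]))
            except ValueError:
                raise ValueError(f"{path}:{lineno}: malformed record "
                                 f"{line!r}") from None
    train = SpikeTrain(np.asarray(times), np.asarray(indices, dtype=np.int64))
    if not train.is_sorted():
        raise ValueError(f"{path}: spike records are not sorted by time")
    return train


def write_network(net: Network, path) -> None:
    """Serialize a network to JSON.

    Benchmark-built networks are stored as their generation rule plus seed
    (compact, bit-reproducible on load); other networks store explicit
    synapse lists.
    """
    if net.meta.get("preset"):
        doc = {"kind": "benchmark", "spec": {
            "preset": net.meta["preset"], "model": net.meta["model"],
            "seed": net.meta["seed"],
            "recurrent_k": net.meta.get("recurrent_k", 80),
            "size_factor": net.meta.get("size_factor", 1.0),
            "scale_n": net.meta.get("scale_n", 0),
        }}
    else:
        doc = {
            "kind": "explicit",
            "populations": [
                {"name": p.name, "start": p.start, "size": p.size,
                 "model": p.model.value if p.model else None,
                 "n_excitatory": p.n_excitatory}
                for p in net.populations],
            "synapses": {
                "source": net.synapses.source.tolist(),
                "target": net.synapses.target.tolist(),
                "weight": [float(w) for w in net.synapses.weight],
                "delay": [float(d) for d in net.synapses.delay],
                "inhibitory": net.synapses.inhibitory.tolist(),
            },
        }
    Path(path).write_text(json.dumps(doc))


def read_network(path) -> Network:
    doc = json.loads(Path(path).read_text())
    if doc.get("kind") == "benchmark":
        s = doc["spec"]
        return build_benchmark(BenchmarkSpec(
            preset=s["preset"], model=ModelKind.parse(s["model"]),
            seed=int(s["seed"]), recurrent_k=int(s.get("recurrent_k", 80)),
            size_factor=float(s.get("size_factor", 1.0)),
            scale_n=int(s.get("scale_n", 0))))
    if doc.get("kind") != "explicit":
        raise ValueError(f"{path}: unknown network file kind")
    pops = []
    for p in doc["populations"]:
        model = ModelKind.parse(p["model"]) if p["model"] else None
        pops.append(Population(
            p["name"], int(p["start"]), int(p["size"]), model,
            NeuronParameters.defaults(model) if model else None,
            p.get("n_excitatory")))
    syn = doc["synapses"]
    delays = np.array([round_delay(d) for d in syn["delay"]],
                      dtype=np.float32)
    net = Network(pops, SynapseSet(
        np.asarray(syn["source"], dtype=np.int32),
        np.asarray(syn["target"], dtype=np.int32),
        np.asarray(syn["weight"], dtype=np.float32),
        delays,
        np.asarray(syn["inhibitory"], dtype=bool)))
    net.validate()
    return net
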