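"""Look-up tables for event-driven neuron simulation.

The event-driven technique never integrates a neuron's ODEs during the
simulation.  Instead, the free dynamics (no input, no reset) of each model
are pre-compiled on a state-space grid:

* *forecast tables* map (elapsed time Dt, state at last update) to the state
  variables Dt later;
* *conductance tables* map (Dt, g) to the exponentially decayed conductance
  (filled from the closed form, the conductances being uncoupled);
* *prediction tables* map a state to the time ``t_f`` of the next firing
  under free dynamics (``+inf`` when the trajectory never fires within the
  horizon) and to ``t_e``, the length of the post-spike suppression window
  (the refractory period for LIF, the spike-duplication guard for HH; AdEx
  needs no ``t_e``).

Two layouts hold numerically identical values.  The *direct* layout keeps
one payload per table (one table per state variable), so a query computes
one grid index per variable.  The *combined* layout stores all state
variables that share axes as payloads of a single table, so one index
computation serves them all.  Queries select the nearest grid node per axis
(round-half-up), matching table-look-up semantics; multilinear
interpolation is available behind a flag.
"""

from __future__ import annotations

import json
from bisect import bisect_right
from dataclasses import dataclass, replace

import numpy as np

from .models import (ModelKind, NeuronParameters, NeuronState, NO_FIRE)

__all__ = [
    "GridSpec", "AxisSpec", "LookupTable", "TableSet",
    "compile_tables", "compile_state_tables", "compile_prediction_tables",
    "query_update", "predict_firing", "save_tables", "load_tables",
    "TableCompilationError", "FingerprintMismatchError",
]


class TableCompilationError(RuntimeError):
    """A grid point produced non-finite reference dynamics."""


class FingerprintMismatchError(ValueError):
    """A table file was compiled for different model parameters."""


@dataclass(frozen=True)
class AxisSpec:
    """One grid axis: variable name, number of nodes, range and spacing.

    ``spacing`` is 'linear' or 'log_zero' (node 0 followed by
    logarithmically spaced nodes from ``lo`` to ``hi``; used for
    conductances, which cluster near zero between spikes).
    """

    name: str
    n: int
    lo: float
    hi: float
    spacing: str = "linear"

    def __post_init__(self):
        if self.n < 2:
            raise ValueError(f"axis {self.name}: need at least 2 nodes")
        if self.hi <= self.lo:
            raise ValueError(f"axis {self.name}: empty range")
        if self.spacing not in ("linear", "log_zero"):
            raise ValueError(f"axis {self.name}: unknown spacing "
                             f"{self.spacing!r}")

    def points(self) -> np.ndarray:
        if self.spacing == "linear":
            return np.linspace(self.lo, self.hi, self.n)
        if self.lo <= 0:
            raise ValueError(f"axis {self.name}: log spacing needs lo > 0")
        return np.concatenate(([0.0],
                               np.geomspace(self.lo, self.hi, self.n - 1)))

    def doubled(self) -> "AxisSpec":
        return replace(self, n=2 * self.n)


@dataclass(frozen=True)
class GridSpec:
    """Grid specification for one model's table set.

    ``dt`` is the elapsed-time axis (a zero node plus ``dt_n - 1``
    log-spaced nodes in [dt_min, dt_max]); node times snap to the reference
    micro-step grid so that on-node queries reproduce compiled values
    exactly.  ``horizon`` bounds the firing-time search and ``ref_step`` is
    the micro-step of the reference integrator used for compilation.
    """

    kind: ModelKind
    state_axes: tuple[AxisSpec, ...]   # (g_ampa, g_gaba, [w | m,h,n], V)
    dt_n: int = 65
    dt_min: float = 0.01
    dt_max: float = 100.0
    horizon: float = 100.0
    ref_step: float = 1e-3

    def __post_init__(self):
        names = [a.name for a in self.state_axes]
        want = ["g_ampa", "g_gaba"] + \
            {ModelKind.LIF: ["V"], ModelKind.ADEX: ["w", "V"],
             ModelKind.HH: ["m", "h", "n", "V"]}[self.kind]
        if names != want:
            raise ValueError(f"state axes for {self.kind.value} must be "
                             f"{want}, got {names}")
        if self.horizon < self.dt_max:
            raise ValueError("horizon must cover the Dt axis")
        if self.dt_n < 2 or self.dt_min <= 0 or self.dt_max <= self.dt_min:
            raise ValueError("invalid Dt axis")

    def dt_points(self) -> np.ndarray:
        raw = np.concatenate(
            ([0.0], np.geomspace(self.dt_min, self.dt_max, self.dt_n - 1)))
        # Snap to the reference micro-grid, dropping duplicates.
        snapped = np.round(raw / self.ref_step) * self.ref_step
        return np.unique(snapped)

    @classmethod
    def default(cls, kind, g_ampa_max: float = 105.0,
                g_gaba_max: float = 60.0, **overrides) -> "GridSpec":
        """Default grids: 64-node Dt and V axes, 16-node conductance and w
        axes, 12-node gating axes.  Conductance ceilings default to 1.5x
        the largest summed weight of the benchmark networks."""
        kind = ModelKind.parse(kind)
        axes = [AxisSpec("g_ampa", 16, 0.05, g_ampa_max, "log_zero"),
                AxisSpec("g_gaba", 16, 0.05, g_gaba_max, "log_zero")]
        if kind is ModelKind.ADEX:
            axes.append(AxisSpec("w", 16, -20.0, 180.0))
        elif kind is ModelKind.HH:
            axes += [AxisSpec("m", 12, 0.0, 1.0),
                     AxisSpec("h", 12, 0.0, 1.0),
                     AxisSpec("n", 12, 0.0, 1.0)]
        v_hi = -40.0 if kind is not ModelKind.HH else -30.0
        axes.append(AxisSpec("V", 64, -90.0, v_hi))
        base = dict(kind=kind, state_axes=tuple(axes))
        base.update(overrides)
        return cls(**base)

    @classmethod
    def coarse(cls, kind, scale: int = 1, ref_step: float = 1e-2,
               horizon: float = 50.0, g_ampa_max: float = 105.0,
               g_gaba_max: float = 60.0) -> "GridSpec":
        """Small grids for fast builds: base granularities (8, 8, [6|4^3],
        12, Dt 16) multiplied by ``scale``.  The 10 us reference micro-step
        trades a documented accuracy cost for compile speed."""
        kind = ModelKind.parse(kind)
        axes = [AxisSpec("g_ampa", 8 * scale, 0.1, g_ampa_max, "log_zero"),
                AxisSpec("g_gaba", 8 * scale, 0.1, g_gaba_max, "log_zero")]
        if kind is ModelKind.ADEX:
            axes.append(AxisSpec("w", 6 * scale, -20.0, 180.0))
        elif kind is ModelKind.HH:
            axes += [AxisSpec("m", 4 * scale, 0.0, 1.0),
                     AxisSpec("h", 4 * scale, 0.0, 1.0),
                     AxisSpec("n", 4 * scale, 0.0, 1.0)]
        v_hi = -40.0 if kind is not ModelKind.HH else -30.0
        axes.append(AxisSpec("V", 12 * scale, -90.0, v_hi))
        return cls(kind=kind, state_axes=tuple(axes), dt_n=16 * scale,
                   dt_min=0.05, dt_max=horizon, horizon=horizon,
                   ref_step=ref_step)

    def doubled(self) -> "GridSpec":
        """Every axis granularity doubled (one rung of the accuracy
        ladder)."""
        return replace(self, state_axes=tuple(a.doubled()
                                              for a in self.state_axes),
                       dt_n=2 * self.dt_n)

    def to_json(self) -> str:
        return json.dumps({
            "kind": self.kind.value,
            "state_axes": [a.__dict__ for a in self.state_axes],
            "dt_n": self.dt_n, "dt_min": self.dt_min,
            "dt_max": self.dt_max, "horizon": self.horizon,
            "ref_step": self.ref_step})

    @classmethod
    def from_json(cls, blob: str) -> "GridSpec":
        d = json.loads(blob)
        return cls(kind=ModelKind.parse(d["kind"]),
                   state_axes=tuple(AxisSpec(**a) for a in d["state_axes"]),
                   dt_n=d["dt_n"], dt_min=d["dt_min"], dt_max=d["dt_max"],
                   horizon=d["horizon"], ref_step=d["ref_step"])


class LookupTable:
    """An n-dimensional grid with one or more payload arrays.

    Axes are ordered coordinate vectors; payloads are flat float64 arrays
    of length prod(axis lengths), indexed C-style.  ``query`` selects the
    nearest node per axis (ties round up); ``query_interp`` blends the
    2^d surrounding corners multilinearly.
    """

    def __init__(self, axis_names, axes, payloads):
        self.axis_names = list(axis_names)
        self.axes = [np.asarray(a, dtype=float) for a in axes]
        shape = tuple(len(a) for a in self.axes)
        self.shape = shape
        size = int(np.prod(shape))
        self.payloads = {}
        for k, v in payloads.items():
            v = np.asarray(v, dtype=float)
            if v.size != size:
                raise ValueError(f"payload {k}: size {v.size} != grid {size}")
            self.payloads[k] = v.reshape(-1)
        self._strides = [int(np.prod(shape[i + 1:], dtype=np.int64))
                         for i in range(len(shape))]
        # Midpoints per axis for nearest-node selection (half rounds up).
        self._mids = [((a[1:] + a[:-1]) / 2.0).tolist() for a in self.axes]

    def nearest_index(self, values) -> int:
        flat = 0
        for v, mids, stride in zip(values, self._mids, self._strides):
            flat += bisect_right(mids, v) * stride
        return flat

    def query(self, values) -> dict:
        i = self.nearest_index(values)
        return {k: p[i] for k, p in self.payloads.items()}

    def query_interp(self, values) -> dict:
        los, fracs = [], []
        for v, a in zip(values, self.axes):
            j = int(np.clip(np.searchsorted(a, v) - 1, 0, len(a) - 2))
            span = a[j + 1] - a[j]
            f = 0.0 if span == 0 else float(np.clip((v - a[j]) / span, 0, 1))
            los.append(j)
            fracs.append(f)
        d = len(self.axes)
        out = {k: 0.0 for k in self.payloads}
        for corner in range(1 << d):
            w = 1.0
            flat = 0
            for i in range(d):
                hi = (corner >> i) & 1
                w *= fracs[i] if hi else (1.0 - fracs[i])
                flat += (los[i] + hi) * self._strides[i]
            if w == 0.0:
                continue
            for k, p in self.payloads.items():
                out[k] += w * p[flat]
        return out


@dataclass
class TableSet:
    """The compiled tables of one neuron model.

    ``state_tables`` holds the forecast table(s) over axes
    (Dt, g_ampa, g_gaba, [w | m,h,n], V): a single multi-payload table in
    the combined layout, or one single-payload table per state variable in
    the direct layout.  ``cond_ampa`` / ``cond_gaba`` are the 2-D
    (Dt, g) decay tables and ``pred_tables`` the firing-prediction
    table(s) over the state axes without Dt.
    """

    kind: ModelKind
    layout: str                       # 'direct' | 'combined'
    grid: GridSpec
    fingerprint: str
    state_tables: list
    cond_ampa: LookupTable
    cond_gaba: LookupTable
    pred_tables: list
    n_lookups: int = 0

    def to_layout(self, layout: str) -> "TableSet":
        """Re-arrange between direct and combined layouts (values shared)."""
        if layout == self.layout:
            return self
        if layout == "combined":
            state = [LookupTable(
                self.state_tables[0].axis_names,
                self.state_tables[0].axes,
                {k: t.payloads[k] for t in self.state_tables
                 for k in t.payloads})]
            pred = [LookupTable(
                self.pred_tables[0].axis_names,
                self.pred_tables[0].axes,
                {k: t.payloads[k] for t in self.pred_tables
                 for k in t.payloads})]
        elif layout == "direct":
            state = [LookupTable(t.axis_names, t.axes, {k: v})
                     for t in self.state_tables
                     for k, v in t.payloads.items()]
            pred = [LookupTable(t.axis_names, t.axes, {k: v})
                    for t in self.pred_tables
                    for k, v in t.payloads.items()]
        else:
            raise ValueError(f"unknown layout {layout!r}")
        return TableSet(self.kind, layout, self.grid, self.fingerprint,
                        state, self.cond_ampa, self.cond_gaba, pred)


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

def _reference_sweep(params: NeuronParameters, grid: GridSpec):
    """Integrate the free dynamics of every grid state over the horizon.

    Returns (dt points, {var: forecasts, shape (n_dt, n_states)}, t_f).
    Uses the RK4 reference micro-step with closed-form conductance decay,
    vectorized across all grid states at once.  AdEx trajectories freeze
    once they reach the detection voltage: their free dynamics diverge past
    threshold, and the engine always consumes ``t_f`` first, so forecasts
    beyond the firing point are never observable.
    """
    from .time_driven import _rk4_arrays  # shared RK4 core

    axes_pts = [a.points() for a in grid.state_axes]
    names = [a.name for a in grid.state_axes]
    mesh = np.meshgrid(*axes_pts, indexing="ij")
    state = {n: m.reshape(-1).copy() for n, m in zip(names, mesh)}
    n_states = state["V"].size
    if params.kind is not ModelKind.ADEX:
        state.setdefault("w", np.zeros(n_states))
    if params.kind is not ModelKind.HH:
        for k, v in zip("mhn", (0.0, 1.0, 0.0)):
            state.setdefault(k, np.full(n_states, v))

    dt_pts = grid.dt_points()
    h = grid.ref_step
    n_micro = int(round(grid.horizon / h))
    sample_at = {int(round(t / h)): j for j, t in enumerate(dt_pts)}
    var_names = params.state_variables()
    forecasts = {v: np.empty((len(dt_pts), n_states)) for v in var_names}
    t_f = np.full(n_states, NO_FIRE)

    # t = 0: the forecast is the grid state itself; LIF/AdEx states already
    # at the firing condition fire immediately (HH counts upward crossings,
    # so a suprathreshold start is not itself a firing event).
    if 0 in sample_at:
        for v in var_names:
            forecasts[v][sample_at[0]] = state[v]
    frozen = np.zeros(n_states, dtype=bool)
    if params.kind is not ModelKind.HH:
        t_f[state["V"] >= params.V_detect] = 0.0
        if params.kind is ModelKind.ADEX:
            frozen = state["V"] >= params.V_detect

    prev_V = state["V"].copy()
    for i in range(1, n_micro + 1):
        t = i * h
        new = _rk4_arrays(params, state, h, analytic=True)
        if frozen.any():
            for k in new:
                new[k] = np.where(frozen, state[k], new[k])
        bad = ~np.isfinite(new["V"])
        if bad.any():
            j = int(np.nonzero(bad)[0][0])
            point = {n: float(state[n][j]) for n in names}
            raise TableCompilationError(
                f"non-finite free dynamics from grid point {point} "
                f"at t={t:g} ms")
        state = new
        if params.kind is ModelKind.HH:
            crossing = (state["V"] >= params.V_detect) & \
                       (prev_V < params.V_detect) & np.isinf(t_f)
            t_f[crossing] = t
            prev_V = state["V"].copy()
        else:
            hit = (state["V"] >= params.V_detect) & np.isinf(t_f)
            t_f[hit] = t
            if params.kind is ModelKind.ADEX:
                frozen |= hit
        j = sample_at.get(i)
        if j is not None:
            for v in var_names:
                forecasts[v][j] = state[v]
    return dt_pts, forecasts, t_f


def compile_tables(kind, params: NeuronParameters, grid: GridSpec,
                   layout: str = "combined") -> TableSet:
    """Compile the full table set for one model.

    Forecast values are the states reached by the reference integrator
    (RK4 at ``grid.ref_step`` with closed-form conductance decay) started
    from each grid state and run for each Dt with no input and no reset.
    Conductance tables come from the closed form directly.  ``t_f`` is the
    first time the firing condition holds within the horizon (+inf
    otherwise); ``t_e`` stores the suppression-window length (T_ref for
    LIF, the spike guard for HH; AdEx has none).
    """
    kind = ModelKind.parse(kind)
    if kind is not params.kind or kind is not grid.kind:
        raise ValueError("model kind mismatch between params and grid")
    if layout not in ("direct", "combined"):
        raise ValueError(f"unknown layout {layout!r}")

    dt_pts, forecasts, t_f = _reference_sweep(params, grid)
    state_axis_names = ["dt"] + [a.name for a in grid.state_axes]
    state_axes = [dt_pts] + [a.points() for a in grid.state_axes]
    state_table = LookupTable(state_axis_names, state_axes, forecasts)

    # Conductance tables: exact exponential decay, no simulation needed.
    ga_axis = next(a for a in grid.state_axes if a.name == "g_ampa").points()
    gg_axis = next(a for a in grid.state_axes if a.name == "g_gaba").points()
    cond_ampa = LookupTable(
        ["dt", "g_ampa"], [dt_pts, ga_axis],
        {"g_ampa": np.outer(np.exp(-dt_pts / params.tau_AMPA), ga_axis)})
    cond_gaba = LookupTable(
        ["dt", "g_gaba"], [dt_pts, gg_axis],
        {"g_gaba": np.outer(np.exp(-dt_pts / params.tau_GABA), gg_axis)})

    pred_payloads = {"t_f": t_f}
    if kind is ModelKind.LIF:
        pred_payloads["t_e"] = np.full_like(t_f, params.T_ref)
    elif kind is ModelKind.HH:
        pred_payloads["t_e"] = np.full_like(t_f, params.T_spike)
    pred_table = LookupTable([a.name for a in grid.state_axes],
                             [a.points() for a in grid.state_axes],
                             pred_payloads)

    ts = TableSet(kind, "combined", grid, params.fingerprint(),
                  [state_table], cond_ampa, cond_gaba, [pred_table])
    return ts.to_layout(layout)


def compile_state_tables(kind, params: NeuronParameters, grid: GridSpec,
                         layout: str = "combined") -> TableSet:
    """Forecast and conductance tables (the state portion of a TableSet)."""
    return compile_tables(kind, params, grid, layout)


def compile_prediction_tables(kind, params: NeuronParameters,
                              grid: GridSpec) -> LookupTable:
    """The (t_f, t_e) firing-prediction table alone."""
    return compile_tables(kind, params, grid, "combined").pred_tables[0]


# ---------------------------------------------------------------------------
# Queries
# ---------------------------------------------------------------------------

def _state_coords(tables: TableSet, state: NeuronState) -> list:
    return [getattr(state, a.name) for a in tables.grid.state_axes]


def query_update(tables: TableSet, state: NeuronState, dt: float,
                 interpolate: bool = False) -> NeuronState:
    """Forecast the state ``dt`` ms after its last update.

    State variables come from the forecast table(s) at the nearest grid
    node (or multilinear blend with ``interpolate``); conductances from the
    2-D decay tables.  ``t_last`` advances by ``dt``.  Out-of-range
    coordinates clamp to the axis ends (Dt beyond the axis maximum clamps:
    free trajectories have settled by then).
    """
    if dt < 0:
        raise ValueError("elapsed time must be nonnegative")
    coords = [dt] + _state_coords(tables, state)
    new = state.copy()
    for t in tables.state_tables:
        got = t.query_interp(coords) if interpolate else t.query(coords)
        tables.n_lookups += 1
        for k, v in got.items():
            setattr(new, k, float(v))
    ga = (tables.cond_ampa.query_interp([dt, state.g_ampa]) if interpolate
          else tables.cond_ampa.query([dt, state.g_ampa]))["g_ampa"]
    gg = (tables.cond_gaba.query_interp([dt, state.g_gaba]) if interpolate
          else tables.cond_gaba.query([dt, state.g_gaba]))["g_gaba"]
    tables.n_lookups += 2
    new.g_ampa, new.g_gaba = float(ga), float(gg)
    new.t_last = state.t_last + dt
    return new


def predict_firing(tables: TableSet, state: NeuronState,
                   interpolate: bool = False) -> tuple:
    """(t_f, t_e) at the nearest prediction-table node.

    ``t_f`` is the free-dynamics firing delay from now (+inf when the
    trajectory never fires within the horizon); ``t_e`` is the
    suppression-window length to apply after a spike (0 for AdEx).
    """
    coords = _state_coords(tables, state)
    out = {}
    for t in tables.pred_tables:
        got = t.query_interp(coords) if interpolate else t.query(coords)
        tables.n_lookups += 1
        out.update(got)
    return float(out["t_f"]), float(out.get("t_e", 0.0))


# ---------------------------------------------------------------------------
# Persistence (HDF5)
# ---------------------------------------------------------------------------

def save_tables(tables: TableSet, path) -> None:
    """Write a TableSet to an HDF5 file (bitwise round-trip)."""
    import h5py
    with h5py.File(path, "w") as f:
        f.attrs["kind"] = tables.kind.value
        f.attrs["layout"] = tables.layout
        f.attrs["fingerprint"] = tables.fingerprint
        f.attrs["grid"] = tables.grid.to_json()
        for group_name, tabs in (("state", tables.state_tables),
                                 ("pred", tables.pred_tables),
                                 ("cond_ampa", [tables.cond_ampa]),
                                 ("cond_gaba", [tables.cond_gaba])):
            g = f.create_group(group_name)
            for i, t in enumerate(tabs):
                sub = g.create_group(str(i))
                sub.attrs["axis_names"] = json.dumps(t.axis_names)
                for j, a in enumerate(t.axes):
                    sub.create_dataset(f"axis{j}", data=a)
                pg = sub.create_group("payloads")
                for k, v in t.payloads.items():
                    pg.create_dataset(k, data=v.reshape(t.shape))


def load_tables(path, params: NeuronParameters | None = None) -> TableSet:
    """Load a TableSet; verifies the parameter fingerprint when ``params``
    is given."""
    import h5py

    def read_group(g):
        out = []
        for i in sorted(g, key=int):
            sub = g[i]
            names = json.loads(sub.attrs["axis_names"])
            axes = [sub[f"axis{j}"][()] for j in range(len(names))]
            payloads = {k: sub["payloads"][k][()] for k in sub["payloads"]}
            out.append(LookupTable(names, axes, payloads))
        return out

    with h5py.File(path, "r") as f:
        fp = str(f.attrs["fingerprint"])
        if params is not None and params.fingerprint() != fp:
            raise FingerprintMismatchError(
                "table file was compiled for different model parameters")
        grid = GridSpec.from_json(f.attrs["grid"])
        return TableSet(
            ModelKind.parse(str(f.attrs["kind"])), str(f.attrs["layout"]),
            grid, fp,
            read_group(f["state"]), read_group(f["cond_ampa"])[0],
            read_group(f["cond_gaba"])[0], read_group(f["pred"]))
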