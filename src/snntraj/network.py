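"""Event-driven convolutional spiking network with STDP learning.

The network is a stack of retinotopic leaky integrate-and-fire (LIF)
layers with shared 5x5 synaptic kernels (valid convolution, stride 1), so
each layer's map shrinks by 4 pixels per side. Sensor events are
duplicated onto three delay lines before layer 1; with ON/OFF polarity
this gives 6 input channels, letting weight learning select the delay
combination that synchronizes inputs for a preferred motion direction.

Dynamics (all state updates happen only when a spike is delivered):

* leak:       u(t) = u_rest + (u(t_k) - u_rest) * exp(-(t - t_k)/tau_memb)
* integrate:  u += W_ij * w_max; spike when u >= u_thresh_base + U_long(t)
* reset:      u -> u_rest on spike; the membrane may go below rest after
              inhibition and simply decays back.
* STDP (at each postsynaptic spike, on the shared kernel):
      dW = (1 - W) * a_ltp   if t_post - t_pre < tau_ltp
      dW = -W * a_ltd        otherwise (including silent afferents)
  which soft-bounds weights to (0, 1).
* lateral inhibition: on a spike, every other filter at the same map
  position loses f_inst * U_propinh, where U_propinh is the mean squared
  membrane potential across filters at that position at spike time.
* homeostasis: each own spike adds a transient triangular threshold
  penalty of peak f_long * U_propinh, rising over t_thresh seconds and
  decaying back over another t_thresh.

Simultaneous events are processed in (time, layer asc, raster (y, x),
channel asc) order; within one delivery, crossing neurons fire in raster
order then filter order. Both tie-breaks are deterministic and stable.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

from .frontend import EventStream

__all__ = [
    "LayerParams",
    "DelayConfig",
    "LayerSpikes",
    "Network",
    "published_layer_params",
    "duplicate_with_delays",
    "leak_membrane",
    "integrate_event",
    "stdp_update",
    "lateral_inhibit",
    "threshold_penalty",
    "run_network",
    "train_network",
]

PATCH = 5  # receptive-field side; fixed by the architecture


@dataclass(frozen=True)
class LayerParams:
    """Per-layer neuron, plasticity and homeostasis parameters.

    Time constants are in seconds; ``w_max`` scales unit-bounded weights
    onto the membrane-potential scale set by ``u_thresh_base``.
    """

    w_max: float
    tau_memb: float
    n_filters: int
    tau_ltp: float
    a_ltp: float
    a_ltd: float
    f_inst: float
    f_long: float
    t_thresh: float
    patch_size: int = PATCH
    stride: int = 1
    u_thresh_base: float = 8.0
    u_rest: float = 0.0

    def __post_init__(self) -> None:
        if min(self.tau_memb, self.tau_ltp, self.t_thresh) <= 0:
            raise ValueError("time constants must be positive")
        if self.a_ltp <= 0 or self.a_ltd <= 0:
            raise ValueError("STDP amplitudes must be positive")
        if self.n_filters < 1:
            raise ValueError("need at least one filter")


def published_layer_params(n_filters: tuple[int, int, int] | None = None
                        ) -> list[LayerParams]:
    """The published three-layer parameter set (optionally resized maps).

    ``n_filters`` overrides the per-layer filter counts (60, 80, 100) for
    scaled-down experiments while keeping all dynamical constants.
    """
    rows = [
        dict(w_max=1.873, tau_memb=0.01, n_filters=60, tau_ltp=0.0754,
             a_ltp=0.00195, a_ltd=0.0005, f_inst=3.0, f_long=2.89,
             t_thresh=0.031),
        dict(w_max=0.813, tau_memb=0.052, n_filters=80, tau_ltp=0.0236,
             a_ltp=0.0131, a_ltd=0.00118, f_inst=2.82, f_long=2.41,
             t_thresh=0.023),
        dict(w_max=1.308, tau_memb=0.039, n_filters=100, tau_ltp=0.0368,
             a_ltp=0.00815, a_ltd=0.00198, f_inst=3.46, f_long=1.9,
             t_thresh=0.051),
    ]
    if n_filters is not None:
        for row, nf in zip(rows, n_filters):
            row["n_filters"] = nf
    return [LayerParams(**row) for row in rows]


@dataclass(frozen=True)
class DelayConfig:
    """Input delay lines, seconds. Defaults: 0, 1 and 2 frame periods."""

    delays: tuple[float, float, float] = (0.0, 1.0 / 240.0, 2.0 / 240.0)

    def __post_init__(self) -> None:
        d0, d1, d2 = self.delays
        if not (d0 == 0.0 <= d1 <= d2):
            raise ValueError("delays must satisfy 0 = d0 <= d1 <= d2")


@dataclass
class LayerSpikes:
    """Output spikes of one layer: parallel arrays (t, filter, y, x, u)."""

    t: np.ndarray
    f: np.ndarray
    y: np.ndarray
    x: np.ndarray
    u: np.ndarray       # membrane potential at spike time (pre-reset)
    layer: int

    def __len__(self) -> int:
        return len(self.t)

    @classmethod
    def from_lists(cls, rows: list[tuple], layer: int) -> "LayerSpikes":
        if rows:
            t, f, y, x, u = (np.asarray(col) for col in zip(*rows))
        else:
            t = u = np.empty(0)
            f = y = x = np.empty(0, dtype=np.int64)
        return cls(t=t, f=f.astype(np.int64), y=y.astype(np.int64),
                   x=x.astype(np.int64), u=u, layer=layer)

    def until(self, t_max: float) -> "LayerSpikes":
        keep = self.t <= t_max
        return LayerSpikes(self.t[keep], self.f[keep], self.y[keep],
                           self.x[keep], self.u[keep], self.layer)


def duplicate_with_delays(stream: EventStream, config: DelayConfig
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Expand sensor events onto (polarity x delay) input channels.

    Every event appears once per delay line; channel index is
    ``2 * delay_index + (0 if ON else 1)``, giving the 6 input synapse
    types per pixel. Returns time-sorted (t, y, x, channel) arrays with
    (t, y, x, channel) lexicographic tie-breaks.
    """
    n = len(stream)
    ts, ys, xs, cs = [], [], [], []
    off = (stream.polarity == 0).astype(np.int64)  # ON -> 0, OFF -> 1
    for d, delay in enumerate(config.delays):
        ts.append(stream.t + delay)
        ys.append(stream.y)
        xs.append(stream.x)
        cs.append(2 * d + off)
    t = np.concatenate(ts) if n else np.empty(0)
    y = np.concatenate(ys) if n else np.empty(0, dtype=np.int64)
    x = np.concatenate(xs) if n else np.empty(0, dtype=np.int64)
    c = np.concatenate(cs) if n else np.empty(0, dtype=np.int64)
    order = np.lexsort((c, x, y, t))
    return t[order], y[order], x[order], c[order]


# ---------------------------------------------------------------------------
# elementary state transitions (exposed for unit tests; the simulator
# inlines vectorized equivalents)

def leak_membrane(u: float, t_last: float, t: float, params: LayerParams) -> float:
    """Exponential decay of the membrane toward rest between updates."""
    if t < t_last:
        raise ValueError("time must not reverse")
    return params.u_rest + (u - params.u_rest) * np.exp(
        -(t - t_last) / params.tau_memb)


def integrate_event(u: float, weight: float, u_long: float,
                    params: LayerParams) -> tuple[float, bool]:
    """Add a weighted input; fire and reset on crossing the threshold."""
    u = u + weight * params.w_max
    if u >= params.u_thresh_base + u_long:
        return params.u_rest, True
    return u, False


def stdp_update(weights: np.ndarray, presyn_times: np.ndarray, t_post: float,
                params: LayerParams) -> np.ndarray:
    """Multiplicative STDP on one filter's kernel (returns a new array).

    Afferents whose last spike falls inside the LTP window are
    potentiated toward 1; all others — including afferents that never
    spiked (``presyn_times`` of -inf) — are depressed toward 0.
    """
    w = np.array(weights, dtype=float)
    ltp = (t_post - presyn_times) < params.tau_ltp
    w[ltp] += (1.0 - w[ltp]) * params.a_ltp
    w[~ltp] -= w[~ltp] * params.a_ltd
    return w


def lateral_inhibit(potentials: np.ndarray, spiking_filter: int,
                    params: LayerParams) -> tuple[np.ndarray, float]:
    """Reduce competitors at the spiking position; returns (u, U_propinh).

    U_propinh is the mean squared membrane potential over the filters at
    the position, taken at spike time (pre-reset values). Only
    suprathreshold-of-rest (positive) potentials contribute: neurons
    pushed below rest by earlier inhibition carry no excitation, and
    rectifying them keeps the homeostatic signal bounded.
    """
    u = np.array(potentials, dtype=float)
    up = np.maximum(u, 0.0)
    u_propinh = float(np.mean(up * up))
    mask = np.arange(len(u)) != spiking_filter
    u[mask] -= params.f_inst * u_propinh
    return u, u_propinh


def threshold_penalty(spikes: list[tuple[float, float]], t: float,
                      t_thresh: float) -> float:
    """Summed triangular threshold penalties from past own spikes.

    Each spike at ``t_s`` with amplitude A contributes an inverted-V
    ramp: rising linearly to A over ``t_thresh`` seconds, then decaying
    linearly back to zero over another ``t_thresh``.
    """
    total = 0.0
    for t_s, amp in spikes:
        dt = t - t_s
        if dt < 0 or dt >= 2.0 * t_thresh:
            continue
        frac = dt / t_thresh
        total += amp * (frac if frac <= 1.0 else 2.0 - frac)
    return total


def _prune_penalties(entries: list[tuple[float, float]], t: float,
                     t_thresh: float) -> list[tuple[float, float]]:
    return [(ts, a) for ts, a in entries if t < ts + 2.0 * t_thresh]


# ---------------------------------------------------------------------------
# network container

class Network:
    """Layer parameters plus shared synaptic kernels for one sensor size."""

    def __init__(self, input_shape: tuple[int, int],
                 layers: list[LayerParams] | None = None,
                 delay_config: DelayConfig | None = None,
                 seed: int = 0) -> None:
        self.input_shape = tuple(input_shape)        # (width, height)
        self.layers = layers if layers is not None else published_layer_params()
        self.delay_config = delay_config or DelayConfig()
        self.seed = seed
        self.kernels: list[np.ndarray] = []
        self.init_kernels(seed)

    def in_channels(self, layer: int) -> int:
        return 6 if layer == 0 else self.layers[layer - 1].n_filters

    def map_shape(self, layer: int) -> tuple[int, int]:
        """(height, width) of the retinotopic map of ``layer`` (0-based)."""
        w, h = self.input_shape
        shrink = (PATCH - 1) * (layer + 1)
        return h - shrink, w - shrink

    def init_kernels(self, seed: int) -> None:
        """Independent uniform weights on [0.3, 0.7], per-layer subseeds."""
        rng = np.random.default_rng(seed)
        self.kernels = []
        for k, lp in enumerate(self.layers):
            shape = (lp.n_filters, self.in_channels(k), PATCH, PATCH)
            self.kernels.append(rng.uniform(0.3, 0.7, size=shape))

    def copy(self) -> "Network":
        net = Network(self.input_shape, list(self.layers),
                      self.delay_config, self.seed)
        net.kernels = [k.copy() for k in self.kernels]
        return net


class _LayerState:
    """Mutable per-layer simulation state (fresh per trajectory)."""

    def __init__(self, net: Network, layer: int) -> None:
        lp = net.layers[layer]
        hm, wm = net.map_shape(layer)
        if layer == 0:
            w, h = net.input_shape
            in_shape = (6, h, w)
        else:
            hp, wp = net.map_shape(layer - 1)
            in_shape = (net.layers[layer - 1].n_filters, hp, wp)
        self.u = np.zeros((lp.n_filters, hm, wm))
        self.last_t = np.zeros((hm, wm))
        self.last_in = np.full(in_shape, -np.inf)
        self.penalties: dict[tuple[int, int, int], list[tuple[float, float]]] = {}
        self.map_shape = (hm, wm)


def run_network(stream: EventStream, network: Network,
                learning_layer: int | None = None,
                n_layers: int | None = None,
                collect_dw: bool = False,
                ) -> list[LayerSpikes]:
    """Event-driven simulation of ``stream`` through the network.

    Layers ``0 .. n_layers-1`` are simulated (default: all); if
    ``learning_layer`` is given, its shared kernels are updated in place
    by STDP at every postsynaptic spike. State is freshly initialized, so
    consecutive calls model trajectories separated by a long silent gap.
    Returns the spike records of every simulated layer.
    """
    if tuple(stream.sensor_shape) != tuple(network.input_shape):
        raise ValueError("event stream sensor shape does not match the network")
    if n_layers is None:
        n_layers = len(network.layers)
    n_layers = min(n_layers, len(network.layers))

    states = [_LayerState(network, k) for k in range(n_layers)]
    spikes: list[list[tuple]] = [[] for _ in range(n_layers)]
    dw_abs_sum = 0.0
    dw_count = 0

    t_in, y_in, x_in, c_in = duplicate_with_delays(stream, network.delay_config)
    heap: list[tuple[float, int, int, int, int]] = [
        (float(t_in[i]), 0, int(y_in[i]), int(x_in[i]), int(c_in[i]))
        for i in range(len(t_in))
    ]
    heapq.heapify(heap)

    while heap:
        t, layer, y, x, c = heapq.heappop(heap)
        if layer >= n_layers:
            continue
        st = states[layer]
        lp = network.layers[layer]
        kern = network.kernels[layer]
        st.last_in[c, y, x] = t

        hm, wm = st.map_shape
        my0, my1 = max(0, y - PATCH + 1), min(hm - 1, y)
        mx0, mx1 = max(0, x - PATCH + 1), min(wm - 1, x)
        if my0 > my1 or mx0 > mx1:
            continue

        # leak the affected region to the current time
        dt = t - st.last_t[my0:my1 + 1, mx0:mx1 + 1]
        decay = np.exp(-dt / lp.tau_memb)
        u_reg = st.u[:, my0:my1 + 1, mx0:mx1 + 1]
        u_reg *= decay[None, :, :]
        st.last_t[my0:my1 + 1, mx0:mx1 + 1] = t

        # integrate: kernel index ky = y - my decreases as my grows
        ksl = kern[:, c, y - my1:y - my0 + 1, x - mx1:x - mx0 + 1][:, ::-1, ::-1]
        u_reg += lp.w_max * ksl

        if u_reg.max() < lp.u_thresh_base:
            continue

        # threshold crossings: raster order over positions, filters ascending
        for my in range(my0, my1 + 1):
            for mx in range(mx0, mx1 + 1):
                col = st.u[:, my, mx]
                if col.max() < lp.u_thresh_base:
                    continue
                for f in range(lp.n_filters):
                    if col[f] < lp.u_thresh_base:
                        continue
                    key = (f, my, mx)
                    pen = st.penalties.get(key)
                    u_long = 0.0
                    if pen:
                        pen = _prune_penalties(pen, t, lp.t_thresh)
                        if pen:
                            st.penalties[key] = pen
                            u_long = threshold_penalty(pen, t, lp.t_thresh)
                        else:
                            del st.penalties[key]
                    if col[f] < lp.u_thresh_base + u_long:
                        continue

                    # --- spike ---
                    u_spike = float(col[f])
                    col_pos = np.maximum(col, 0.0)
                    u_propinh = float(np.mean(col_pos * col_pos))
                    spikes[layer].append((t, f, my, mx, u_spike))

                    if learning_layer == layer:
                        patch_t = st.last_in[:, my:my + PATCH, mx:mx + PATCH]
                        ltp = (t - patch_t) < lp.tau_ltp
                        w = kern[f]
                        if collect_dw:
                            before = w.copy()
                        w[ltp] += (1.0 - w[ltp]) * lp.a_ltp
                        w[~ltp] -= w[~ltp] * lp.a_ltd
                        if collect_dw:
                            dw_abs_sum += float(np.abs(w - before).sum())
                            dw_count += w.size

                    col[f] = lp.u_rest
                    inh = lp.f_inst * u_propinh
                    if inh > 0:
                        sel = np.arange(lp.n_filters) != f
                        col[sel] -= inh
                    amp = lp.f_long * u_propinh
                    if amp > 0:
                        st.penalties.setdefault(key, []).append((t, amp))

                    if layer + 1 < n_layers:
                        heapq.heappush(heap, (t, layer + 1, my, mx, f))

    records = [LayerSpikes.from_lists(spikes[k], k) for k in range(n_layers)]
    if collect_dw:
        for r in records:
            r.mean_abs_dw = dw_abs_sum / dw_count if dw_count else 0.0  # type: ignore[attr-defined]
    return records


def concatenate_with_gaps(streams: list[EventStream],
                          gap: float = 2.0) -> EventStream:
    """Merge trajectory streams into one, separated by silent gaps."""
    ts, xs, ys, ps = [], [], [], []
    offset = 0.0
    for s in streams:
        ts.append(s.t + offset)
        xs.append(s.x)
        ys.append(s.y)
        ps.append(s.polarity)
        span = float(s.t[-1]) if len(s) else 0.0
        offset += span + gap
    first = streams[0]
    return EventStream(np.concatenate(ts), np.concatenate(xs),
                       np.concatenate(ys), np.concatenate(ps),
                       first.sensor_shape, first.fps)


def train_network(streams: list[EventStream], network: Network,
                  epochs_per_layer: int | tuple[int, ...] = 1,
                  n_layers: int | None = None,
                  strict_gaps: bool = False,
                  verbose: bool = False,
                  ) -> dict:
    """Layer-by-layer unsupervised STDP training.

    Layer k learns while layers below run frozen inference and layers
    above stay inactive. Trajectories are presented individually with a
    full state reset between them (equivalent to a long silent gap: all
    membrane, penalty and timing state decays to baseline well within
    2 s at the published constants). ``strict_gaps`` instead simulates
    the 2 s silence literally: streams are concatenated with 2 s offsets
    and run as one continuous presentation per epoch. Kernels are
    updated in place; returns per-layer diagnostics (spike counts, mean
    |dW| per presentation).
    """
    if not streams:
        raise ValueError("need at least one training stream")
    if n_layers is None:
        n_layers = len(network.layers)
    if isinstance(epochs_per_layer, int):
        epochs_per_layer = tuple([epochs_per_layer] * n_layers)

    diag: dict = {"layers": []}
    for k in range(n_layers):
        layer_diag = {"layer": k, "presentations": [], "spike_counts": []}
        for epoch in range(epochs_per_layer[k]):
            epoch_streams = ([concatenate_with_gaps(streams)] if strict_gaps
                             else streams)
            for stream in epoch_streams:
                recs = run_network(stream, network, learning_layer=k,
                                   n_layers=k + 1, collect_dw=True)
                layer_diag["presentations"].append(
                    getattr(recs[k], "mean_abs_dw", 0.0))
                layer_diag["spike_counts"].append(len(recs[k]))
        diag["layers"].append(layer_diag)
        if verbose:
            total = sum(layer_diag["spike_counts"])
            print(f"layer {k}: {total} spikes over "
                  f"{len(layer_diag['spike_counts'])} presentations")
    return diag
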