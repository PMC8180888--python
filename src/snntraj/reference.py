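"""Dense clock-driven reference simulator for validation.

An intentionally independent re-implementation of the single-layer LIF
dynamics used to cross-check the event-driven simulator: instead of an
event queue with lazy analytic leaks, it advances a global clock in
fixed ticks (default 0.01 ms), multiplies every membrane potential by a
per-tick decay factor, and delivers events on their quantized tick.
Spike conditions, lateral inhibition and the triangular threshold
penalty follow the same model definition, written here as plain loops.

It is a test oracle, not a production path: it is orders of magnitude
slower than the event-driven simulator and only supports one layer.
"""

from __future__ import annotations

import numpy as np

from .frontend import EventStream
from .network import Network, LayerSpikes

__all__ = ["run_reference"]


def run_reference(stream: EventStream, network: Network,
                  tick: float = 1e-5) -> LayerSpikes:
    """Clock-driven single-layer simulation of ``stream``.

    Event times are quantized to the tick grid (streams whose times are
    exact tick multiples are reproduced exactly). Returns the layer's
    spike records with membrane potentials at spike time.
    """
    lp = network.layers[0]
    kern = network.kernels[0]
    hm, wm = network.map_shape(0)
    nf = lp.n_filters

    # expand delay lines (independent of the production expansion)
    evs: list[tuple[float, int, int, int]] = []
    for i in range(len(stream)):
        pol_off = 0 if stream.polarity[i] == 1 else 1
        for d, delay in enumerate(network.delay_config.delays):
            evs.append((float(stream.t[i] + delay), int(stream.y[i]),
                        int(stream.x[i]), 2 * d + pol_off))
    evs.sort()

    u = np.zeros((nf, hm, wm))
    decay = np.exp(-tick / lp.tau_memb)
    penalties: dict[tuple[int, int, int], list[tuple[float, float]]] = {}
    out: list[tuple] = []

    if not evs:
        return LayerSpikes.from_lists([], 0)
    n_ticks = int(round(evs[-1][0] / tick)) + 1
    ei = 0
    for it in range(n_ticks + 1):
        u *= decay
        while ei < len(evs) and int(round(evs[ei][0] / tick)) == it:
            t, y, x, c = evs[ei]
            ei += 1
            my0, my1 = max(0, y - 4), min(hm - 1, y)
            mx0, mx1 = max(0, x - 4), min(wm - 1, x)
            for my in range(my0, my1 + 1):
                for mx in range(mx0, mx1 + 1):
                    u[:, my, mx] += lp.w_max * kern[:, c, y - my, x - mx]
            # spike scan, raster order then filter order
            for my in range(my0, my1 + 1):
                for mx in range(mx0, mx1 + 1):
                    for f in range(nf):
                        if u[f, my, mx] < lp.u_thresh_base:
                            continue
                        u_long = 0.0
                        for ts, amp in penalties.get((f, my, mx), []):
                            dt = t - ts
                            if 0 <= dt < lp.t_thresh:
                                u_long += amp * dt / lp.t_thresh
                            elif lp.t_thresh <= dt < 2 * lp.t_thresh:
                                u_long += amp * (2.0 - dt / lp.t_thresh)
                        if u[f, my, mx] < lp.u_thresh_base + u_long:
                            continue
                        u_spike = float(u[f, my, mx])
                        col = u[:, my, mx]
                        pos = col[col > 0]
                        u_propinh = float((pos * pos).sum() / nf)
                        out.append((t, f, my, mx, u_spike))
                        col[f] = lp.u_rest
                        for g in range(nf):
                            if g != f:
                                col[g] -= lp.f_inst * u_propinh
                        if lp.f_long * u_propinh > 0:
                            key = (f, my, mx)
                            lst = [e for e in penalties.get(key, [])
                                   if t < e[0] + 2 * lp.t_thresh]
                            lst.append((t, lp.f_long * u_propinh))
                            penalties[key] = lst
        if ei >= len(evs):
            break
    return LayerSpikes.from_lists(out, 0)
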