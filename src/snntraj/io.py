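"""HDF5 and CSV persistence for events, frames, networks and readouts.

Formats
-------
* events HDF5: datasets ``/events/t|x|y|p`` with root attributes
  ``width``, ``height``, ``fps`` (CSV twin lives in :mod:`.frontend`);
* frames HDF5: dataset ``/frames`` (n, height, width) with ``fps``;
* model HDF5: ``/layers/<k>/weights`` with the layer parameters as
  attributes, the delay configuration, seed and a format version at the
  root, and optionally the fitted readout under ``/readout``.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np

from .frontend import EventStream
from .network import Network, LayerParams, DelayConfig
from .readout import ReadoutModel
from .scenes import FrameSequence

__all__ = [
    "save_events_h5", "load_events_h5",
    "save_frames_h5", "load_frames_h5",
    "save_model", "load_model",
    "FORMAT_VERSION",
]

FORMAT_VERSION = 1

_LAYER_FIELDS = ("w_max", "tau_memb", "n_filters", "tau_ltp", "a_ltp",
                 "a_ltd", "f_inst", "f_long", "t_thresh", "patch_size",
                 "stride", "u_thresh_base", "u_rest")


def save_events_h5(stream: EventStream, path: str | Path) -> None:
    with h5py.File(path, "w") as h:
        g = h.create_group("events")
        g.create_dataset("t", data=stream.t)
        g.create_dataset("x", data=stream.x)
        g.create_dataset("y", data=stream.y)
        g.create_dataset("p", data=stream.polarity)
        h.attrs["width"], h.attrs["height"] = stream.sensor_shape
        h.attrs["fps"] = stream.fps
        h.attrs["version"] = FORMAT_VERSION


def load_events_h5(path: str | Path) -> EventStream:
    with h5py.File(path, "r") as h:
        g = h["events"]
        return EventStream(g["t"][:], g["x"][:], g["y"][:], g["p"][:],
                           (int(h.attrs["width"]), int(h.attrs["height"])),
                           float(h.attrs["fps"]))


def save_frames_h5(frames: FrameSequence, path: str | Path) -> None:
    with h5py.File(path, "w") as h:
        h.create_dataset("frames", data=frames.frames, compression="gzip")
        h.attrs["fps"] = frames.fps
        h.attrs["version"] = FORMAT_VERSION


def load_frames_h5(path: str | Path) -> FrameSequence:
    with h5py.File(path, "r") as h:
        return FrameSequence(frames=h["frames"][:], fps=float(h.attrs["fps"]))


def save_model(network: Network, path: str | Path,
               readout: ReadoutModel | None = None,
               extra_attrs: dict | None = None) -> None:
    """Write kernels, layer parameters, delays and optional readout."""
    with h5py.File(path, "w") as h:
        h.attrs["version"] = FORMAT_VERSION
        h.attrs["seed"] = network.seed
        h.attrs["input_width"], h.attrs["input_height"] = network.input_shape
        h.attrs["delays"] = np.asarray(network.delay_config.delays)
        for key, val in (extra_attrs or {}).items():
            h.attrs[key] = val
        layers = h.create_group("layers")
        for k, (lp, kern) in enumerate(zip(network.layers, network.kernels)):
            g = layers.create_group(str(k))
            g.create_dataset("weights", data=kern)
            for field in _LAYER_FIELDS:
                g.attrs[field] = getattr(lp, field)
        if readout is not None:
            r = h.create_group("readout")
            r.create_dataset("coeffs", data=readout.coeffs)
            r.create_dataset("rmse", data=readout.rmse)
            r.create_dataset("usable", data=readout.usable)
            labels = [s.encode() for s in readout.direction_label]
            r.create_dataset("direction", data=labels)
            r.attrs["prior"] = readout.training_mean_y
            r.attrs["height"] = readout.height


def load_model(path: str | Path) -> tuple[Network, ReadoutModel | None]:
    with h5py.File(path, "r") as h:
        input_shape = (int(h.attrs["input_width"]), int(h.attrs["input_height"]))
        delays = DelayConfig(tuple(float(d) for d in h.attrs["delays"]))
        keys = sorted(h["layers"], key=int)
        params, kernels = [], []
        for k in keys:
            g = h["layers"][k]
            kw = {f: g.attrs[f] for f in _LAYER_FIELDS}
            kw["n_filters"] = int(kw["n_filters"])
            kw["patch_size"] = int(kw["patch_size"])
            kw["stride"] = int(kw["stride"])
            params.append(LayerParams(**kw))
            kernels.append(g["weights"][:])
        net = Network(input_shape, params, delays, seed=int(h.attrs["seed"]))
        net.kernels = kernels
        readout = None
        if "readout" in h:
            r = h["readout"]
            readout = ReadoutModel(
                coeffs=r["coeffs"][:], rmse=r["rmse"][:],
                direction_label=np.array([s.decode() for s in r["direction"][:]],
                                         dtype=object),
                usable=r["usable"][:].astype(bool),
                training_mean_y=float(r.attrs["prior"]),
                height=int(r.attrs["height"]))
    return net, readout
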