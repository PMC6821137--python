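"""Dataset containers and model serialization.

Stimulus/response data travel in a simple container with datasets ``stim``
(channels x time) and ``resp`` (trials x time) plus attributes ``dt``,
``trial_stim_id`` and ``trial_state``, stored as HDF5 or NPZ (chosen by
file extension).  Round trips are lossless.  Recorded datasets with other
on-disk layouts are supported through an adapter: any callable returning a
:class:`DatasetContainer` can feed the pipeline.

Model specifications serialize to/from JSON.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .model import (DampedOscillatorFilter, ModelSpec, OutputNL,
                    RectifierParams, SpectralWeights, STPParams)

__all__ = [
    "DatasetContainer",
    "SchemaError",
    "read_container",
    "write_container",
    "model_to_dict",
    "model_from_dict",
    "save_model",
    "load_model",
]


class SchemaError(KeyError):
    """A required dataset or attribute is missing from a container file."""


@dataclass
class DatasetContainer:
    """In-memory stimulus/response dataset shared by all pipeline stages."""

    stim: np.ndarray                 # channels x time
    dt: float
    resp: np.ndarray | None = None   # trials x time
    trial_stim_id: np.ndarray | None = None
    trial_state: np.ndarray | None = None
    pred: np.ndarray | None = None
    attrs: dict = field(default_factory=dict)

    def __post_init__(self):
        self.stim = np.asarray(self.stim, float)
        if self.resp is not None:
            self.resp = np.atleast_2d(np.asarray(self.resp))
            if self.resp.shape[1] != self.stim.shape[1]:
                raise ValueError("stim and resp must share the time axis")
        if self.dt <= 0:
            raise ValueError("dt must be > 0")


def write_container(container: DatasetContainer, path) -> None:
    path = Path(path)
    if path.suffix == ".npz":
        payload = {"stim": container.stim, "dt": np.float64(container.dt)}
        for name in ("resp", "trial_stim_id", "trial_state", "pred"):
            value = getattr(container, name)
            if value is not None:
                payload[name] = np.asarray(value)
        np.savez(path, **payload)
        return
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("stim", data=container.stim)
        f.attrs["dt"] = container.dt
        for name in ("resp", "pred"):
            value = getattr(container, name)
            if value is not None:
                f.create_dataset(name, data=np.asarray(value))
        for name in ("trial_stim_id", "trial_state"):
            value = getattr(container, name)
            if value is not None:
                value = np.asarray(value)
                if value.dtype.kind == "U":  # HDF5 attrs need byte strings
                    value = value.astype("S")
                f.attrs[name] = value
        for key, value in container.attrs.items():
            f.attrs[key] = value


def read_container(path) -> DatasetContainer:
    path = Path(path)
    if path.suffix == ".npz":
        with np.load(path, allow_pickle=False) as data:
            if "stim" not in data:
                raise SchemaError("missing dataset 'stim'")
            if "dt" not in data:
                raise SchemaError("missing attribute 'dt'")
            kwargs = {"stim": data["stim"], "dt": float(data["dt"])}
            for name in ("resp", "trial_stim_id", "trial_state", "pred"):
                if name in data:
                    kwargs[name] = data[name]
            return DatasetContainer(**kwargs)
    import h5py
    with h5py.File(path, "r") as f:
        if "stim" not in f:
            raise SchemaError("missing dataset 'stim'")
        if "dt" not in f.attrs:
            raise SchemaError("missing attribute 'dt'")
        kwargs = {"stim": f["stim"][...], "dt": float(f.attrs["dt"])}
        for name in ("resp", "pred"):
            if name in f:
                kwargs[name] = f[name][...]
        for name in ("trial_stim_id", "trial_state"):
            if name in f.attrs:
                value = np.asarray(f.attrs[name])
                if value.dtype.kind == "S":
                    value = value.astype("U")
                kwargs[name] = value
        return DatasetContainer(**kwargs)


# ---------------------------------------------------------------------------
# ModelSpec <-> JSON
# ---------------------------------------------------------------------------

def model_to_dict(model: ModelSpec) -> dict:
    stages = []
    w = model.weights
    if w.is_gaussian:
        stages.append({"type": "weights_gaussian",
                       "params": {"means": w.means.tolist(),
                                  "sds": w.sds.tolist(), "n_in": w.n_in}})
    else:
        stages.append({"type": "weights", "params": {"w": w.w.tolist()}})
    if model.stp is not None:
        stages.append({"type": "stp",
                       "params": {"v": model.stp.v.tolist(),
                                  "tau": model.stp.tau.tolist(),
                                  "d_min": model.stp.d_min,
                                  "d_max": model.stp.d_max,
                                  "recursion_mode": model.stp.recursion_mode}})
    if model.rect is not None:
        stages.append({"type": "rectifier",
                       "params": {"s0": model.rect.s0.tolist()}})
    for f in model.filters:
        if isinstance(f, DampedOscillatorFilter):
            stages.append({"type": "do_filter",
                           "params": {"gain": f.gain, "latency": f.latency,
                                      "decay": f.decay, "freq": f.freq,
                                      "n_lags": f.n_lags}})
        else:
            stages.append({"type": "fir_filter",
                           "params": {"kernel": np.asarray(f).tolist()}})
    if model.global_stp is not None:
        g = model.global_stp
        stages.append({"type": "global_stp",
                       "params": {"v": g.v.tolist(), "tau": g.tau.tolist(),
                                  "d_min": g.d_min, "d_max": g.d_max,
                                  "recursion_mode": g.recursion_mode,
                                  "common_input": model.common_input}})
    nl = model.out_nl
    stages.append({"type": "output_nl",
                   "params": {"kind": nl.kind, "base": nl.base,
                              "amplitude": nl.amplitude, "slope": nl.slope,
                              "rate_offset": nl.rate_offset}})
    return {"architecture": model.architecture,
            "rank": model.rank,
            "dt": model.dt,
            "compress": model.compress,
            "normalize_weights": model.normalize_weights,
            "behavior_split": model.behavior_split,
            "stages": stages}


def model_from_dict(data: dict) -> ModelSpec:
    weights = stp = rect = gstp = None
    filters = []
    out_nl = None
    common_input = False
    for stage in data["stages"]:
        kind, params = stage["type"], stage["params"]
        if kind == "weights":
            weights = SpectralWeights(w=np.array(params["w"]))
        elif kind == "weights_gaussian":
            weights = SpectralWeights(means=np.array(params["means"]),
                                      sds=np.array(params["sds"]),
                                      n_in=params["n_in"])
        elif kind == "stp":
            stp = STPParams(v=np.array(params["v"]),
                            tau=np.array(params["tau"]),
                            d_min=params["d_min"], d_max=params["d_max"],
                            recursion_mode=params["recursion_mode"])
        elif kind == "rectifier":
            rect = RectifierParams(s0=np.array(params["s0"]))
        elif kind == "do_filter":
            filters.append(DampedOscillatorFilter(
                gain=params["gain"], latency=params["latency"],
                decay=params["decay"], freq=params["freq"],
                n_lags=params["n_lags"]))
        elif kind == "fir_filter":
            filters.append(np.array(params["kernel"]))
        elif kind == "global_stp":
            common_input = params.get("common_input", False)
            gstp = STPParams(v=np.array(params["v"]),
                             tau=np.array(params["tau"]),
                             d_min=params["d_min"], d_max=params["d_max"],
                             recursion_mode=params["recursion_mode"])
        elif kind == "output_nl":
            out_nl = OutputNL(kind=params["kind"], base=params["base"],
                              amplitude=params["amplitude"],
                              slope=params["slope"],
                              rate_offset=params["rate_offset"])
        else:
            raise SchemaError(f"unknown stage type {kind!r}")
    return ModelSpec(architecture=data["architecture"], weights=weights,
                     filters=filters, out_nl=out_nl, stp=stp, rect=rect,
                     global_stp=gstp, common_input=common_input,
                     compress=data.get("compress", True),
                     normalize_weights=data.get("normalize_weights", False),
                     behavior_split=data.get("behavior_split", "none"),
                     dt=data.get("dt", 0.010))


def save_model(model: ModelSpec, path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model), indent=2))


def load_model(path) -> ModelSpec:
    return model_from_dict(json.loads(Path(path).read_text()))
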