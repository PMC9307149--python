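"""File formats and configuration.

Epoch sets travel as HDF5 containers: datasets ``/data`` (float32,
trials × channels × samples) and ``/labels`` (int, 0=left, 1=right) with
root attributes ``fs``, ``channel_names``, ``subject_id`` and
``schema_version``.  Pipeline settings load from YAML/JSON with defaults
fixed to the study parameters (250 S/s, 7–30 Hz order-5 Butterworth,
30 conv filters 5×5, 2×2 pool, dense 256/128/2, Adam lr 0.01, batch 264,
500 epochs, 80/20 split); unknown keys are rejected with a nearest-key hint.
"""

from __future__ import annotations

import difflib
import json
import logging
from pathlib import Path
from typing import Any, Dict, Optional, Tuple

import h5py
import numpy as np
import yaml

from .simulate import EpochSet

log = logging.getLogger(__name__)

SCHEMA_VERSION = 1


class SchemaError(ValueError):
    """The container file violates the epoch-set schema."""


def write_epochs(epochs: EpochSet, path, subject_id: str = "") -> None:
    """Write an epoch set to the HDF5 container (float32 at rest)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("data", data=epochs.data.astype(np.float32))
        f.create_dataset("labels", data=epochs.labels.astype(np.int64))
        f.attrs["fs"] = float(epochs.fs)
        f.attrs["channel_names"] = [str(c) for c in epochs.channel_names]
        f.attrs["subject_id"] = subject_id
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_epochs(path) -> Tuple[EpochSet, str]:
    """Read and schema-validate a container; returns (epochs, subject_id)."""
    with h5py.File(path, "r") as f:
        for ds in ("data", "labels"):
            if ds not in f:
                raise SchemaError(f"container missing dataset '/{ds}'")
        for attr in ("fs", "channel_names", "schema_version"):
            if attr not in f.attrs:
                raise SchemaError(f"container missing attribute '{attr}'")
        version = int(f.attrs["schema_version"])
        if version != SCHEMA_VERSION:
            raise SchemaError(
                f"schema_version {version} unsupported (expected {SCHEMA_VERSION})")
        data = f["data"][()]
        labels = f["labels"][()]
        if data.ndim != 3:
            raise SchemaError("'/data' must be (trials, channels, samples)")
        if labels.shape[0] != data.shape[0]:
            raise SchemaError("'/labels' length must equal the trial count")
        if not np.all(np.isin(labels, (0, 1))):
            raise SchemaError("'/labels' values must be 0 (left) or 1 (right)")
        names = tuple(str(c) for c in f.attrs["channel_names"])
        if len(names) != data.shape[1]:
            raise SchemaError("channel_names length must equal the channel count")
        subject_id = str(f.attrs.get("subject_id", ""))
        return EpochSet(data.astype(np.float64), labels.astype(int),
                        float(f.attrs["fs"]), names), subject_id


def write_epochs_csv(epochs: EpochSet, path) -> None:
    """Long-format CSV export (trial, channel, sample_index, value_uV).

    Interoperability escape hatch for tools without HDF5 support; the HDF5
    container remains the primary format.
    """
    n_tr, n_ch, n_s = epochs.data.shape
    with open(path, "w") as f:
        f.write("trial,channel,sample_index,value_uv\n")
        for t in range(n_tr):
            for c, name in enumerate(epochs.channel_names):
                row = epochs.data[t, c]
                f.writelines(f"{t},{name},{s},{row[s]:.6g}\n" for s in range(n_s))


# ---------------------------------------------------------------------------
# fitted-model containers


def write_csp_model(model, path) -> None:
    """Persist a fitted CSPModel (projection matrix + selection + metadata)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("W", data=model.W)
        f.create_dataset("eigenvalues", data=model.eigenvalues)
        f.create_dataset("selected", data=np.asarray(model.selected))
        f.attrs["kind"] = "csp"
        f.attrs["schema_version"] = SCHEMA_VERSION
        if model.band is not None:
            f.attrs["band"] = list(model.band)


def read_csp_model(path):
    from .cspline import CSPModel
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "csp":
            raise SchemaError("not a CSP model container")
        band = tuple(f.attrs["band"]) if "band" in f.attrs else None
        return CSPModel(W=f["W"][()], eigenvalues=f["eigenvalues"][()],
                        selected=f["selected"][()], band=band)


def write_lda_model(model, path) -> None:
    """Persist a fitted LDAModel (weights, bias, class moments)."""
    with h5py.File(path, "w") as f:
        f.create_dataset("w", data=model.w)
        f.create_dataset("class_means", data=model.class_means)
        f.create_dataset("pooled_cov", data=model.pooled_cov)
        f.attrs["b"] = float(model.b)
        f.attrs["kind"] = "lda"
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_lda_model(path):
    from .cspline import LDAModel
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "lda":
            raise SchemaError("not an LDA model container")
        return LDAModel(w=f["w"][()], b=float(f.attrs["b"]),
                        class_means=f["class_means"][()],
                        pooled_cov=f["pooled_cov"][()])


def write_cnn_params(model, path) -> None:
    """Persist all trainable tensors of a CNN, in layer order."""
    with h5py.File(path, "w") as f:
        for i, p in enumerate(model.params):
            f.create_dataset(f"param_{i:03d}", data=p)
        f.attrs["n_params"] = len(model.params)
        f.attrs["kind"] = "cnn"
        f.attrs["schema_version"] = SCHEMA_VERSION


def read_cnn_params(model, path) -> None:
    """Load persisted tensors into a freshly built CNN of the same spec."""
    with h5py.File(path, "r") as f:
        if f.attrs.get("kind") != "cnn":
            raise SchemaError("not a CNN parameter container")
        n = int(f.attrs["n_params"])
        if n != len(model.params):
            raise SchemaError(
                f"container has {n} tensors, model expects {len(model.params)}")
        for i, p in enumerate(model.params):
            stored = f[f"param_{i:03d}"][()]
            if stored.shape != p.shape:
                raise SchemaError(f"param_{i:03d} shape {stored.shape} != "
                                  f"model shape {p.shape}")
            p[...] = stored


def write_history_csv(history, path) -> None:
    """Training history (per-epoch loss and train accuracy) as CSV."""
    with open(path, "w") as f:
        f.write("epoch,loss,train_accuracy\n")
        for i, (l, a) in enumerate(zip(history.loss, history.train_accuracy)):
            f.write(f"{i},{l:.10g},{a:.10g}\n")


# ---------------------------------------------------------------------------
# configuration

DEFAULT_CONFIG: Dict[str, Dict[str, Any]] = {
    "simulate": {
        "n_channels": 16,
        "fs": 250.0,
        "n_trials": 120,
        "epoch_s": 4.0,
        "acquisition_band": [0.5, 30.0],
        "erd_depth": 1.0,
        "waveform_contrast": 0.6,
        "snr_efficient": 20.0,
        "snr_inefficient": 2.0,
        "fraction_inefficient": 0.5,
    },
    "preprocess": {
        "bandpass": [7.0, 30.0],
        "order": 5,
        "window": [4.0, 8.0],
    },
    "csp": {
        "m_pairs": 3,
        "trace_normalize": True,
    },
    "lda": {
        "ridge": 1e-8,
    },
    "cnn": {
        "filters": 30,
        "kernel": [5, 5],
        "pool": [2, 2],
        "dense": [256, 128],
    },
    "train": {
        "lr": 0.01,
        "batch_size": 264,
        "max_epochs": 500,
        "normalize": True,
    },
    "evaluate": {
        "train_fraction": 0.8,
    },
    "seed": 0,
}


class ConfigError(ValueError):
    pass


def _merge(defaults: Dict[str, Any], overrides: Dict[str, Any],
           path: str = "") -> Dict[str, Any]:
    out = dict(defaults)
    for key, value in overrides.items():
        full = f"{path}.{key}" if path else key
        if key not in defaults:
            hint = difflib.get_close_matches(key, defaults.keys(), n=1)
            suffix = f"; did you mean '{hint[0]}'?" if hint else ""
            raise ConfigError(f"unknown config key '{full}'{suffix}")
        if isinstance(defaults[key], dict):
            if not isinstance(value, dict):
                raise ConfigError(f"config key '{full}' must be a mapping")
            out[key] = _merge(defaults[key], value, full)
        else:
            out[key] = value
    return out


def load_config(path: Optional[str] = None) -> Dict[str, Any]:
    """Resolve a YAML/JSON config file against the study defaults.

    With no path (or an empty file), returns the defaults.  Unknown keys
    raise :class:`ConfigError` naming the nearest valid key.
    """
    overrides: Dict[str, Any] = {}
    if path is not None:
        text = Path(path).read_text()
        try:
            loaded = yaml.safe_load(text)  # YAML is a superset of JSON
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config {path}: {exc}") from exc
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigError("config root must be a mapping")
            overrides = loaded
    resolved = _merge(DEFAULT_CONFIG, overrides)
    log.info("resolved config: %s", json.dumps(resolved, default=str))
    return resolved
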