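"""HDF5 containers for recordings and epoch sets.

One file per object: chunked float32 voltage arrays plus a JSON sidecar
attribute (``meta``) holding the sampling rate, the channel table (geometry)
and the label names.  Round trips are lossless at float32.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .geometry import ArrayGeometry
from .recording import CONDITIONS, EpochSet, Recording

SCHEMA_VERSION = 1


class ContainerError(ValueError):
    """Raised for unsupported or incomplete container files."""


def _check_schema(f: h5py.File, kind: str):
    if f.attrs.get("microsep_schema") != SCHEMA_VERSION:
        raise ContainerError("unsupported or missing container schema version")
    if f.attrs.get("kind") != kind:
        raise ContainerError(
            f"container holds {f.attrs.get('kind')!r}, expected {kind!r}")


def write_recording(rec: Recording, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["microsep_schema"] = SCHEMA_VERSION
        f.attrs["kind"] = "recording"
        f.attrs["meta"] = json.dumps({
            "fs_hz": rec.fs_hz,
            "geometry": json.loads(rec.geometry.to_json()),
            "condition_names": [str(c) for c in CONDITIONS],
        })
        f.create_dataset("voltage_uv", data=rec.voltage_uv.astype(np.float32),
                         chunks=(rec.n_channels, min(rec.n_samples, 65536)))
        f.create_dataset("trigger_idx", data=rec.trigger_idx)
        f.create_dataset("label_codes", data=rec.label_codes)


def read_recording(path) -> Recording:
    with h5py.File(path, "r") as f:
        _check_schema(f, "recording")
        for name in ("voltage_uv", "trigger_idx", "label_codes"):
            if name not in f:
                raise ContainerError(f"container is missing {name!r}")
        meta = json.loads(f.attrs["meta"])
        return Recording(
            fs_hz=float(meta["fs_hz"]),
            voltage_uv=f["voltage_uv"][()],
            trigger_idx=f["trigger_idx"][()],
            label_codes=f["label_codes"][()],
            geometry=ArrayGeometry.from_json(json.dumps(meta["geometry"])),
        )


def write_epochs(epochs: EpochSet, path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["microsep_schema"] = SCHEMA_VERSION
        f.attrs["kind"] = "epochs"
        f.attrs["meta"] = json.dumps({
            "fs_hz": epochs.fs_hz,
            "pre": epochs.pre,
            "condition_names": [str(c) for c in CONDITIONS],
        })
        f.create_dataset("data_uv", data=epochs.data_uv.astype(np.float32))
        f.create_dataset("label_codes", data=epochs.label_codes)
        f.create_dataset("channel_ids", data=epochs.channel_ids)
        if epochs.trigger_idx is not None:
            f.create_dataset("trigger_idx", data=epochs.trigger_idx)


def read_epochs(path) -> EpochSet:
    with h5py.File(path, "r") as f:
        _check_schema(f, "epochs")
        for name in ("data_uv", "label_codes", "channel_ids"):
            if name not in f:
                raise ContainerError(f"container is missing {name!r}")
        meta = json.loads(f.attrs["meta"])
        return EpochSet(
            data_uv=f["data_uv"][()],
            label_codes=f["label_codes"][()],
            channel_ids=f["channel_ids"][()],
            pre=int(meta["pre"]),
            fs_hz=float(meta["fs_hz"]),
            trigger_idx=f["trigger_idx"][()] if "trigger_idx" in f else None,
        )
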