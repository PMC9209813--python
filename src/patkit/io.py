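"""Containers and run configuration: HDF5 datasets, checkpoints, YAML config.

Datasets are stored as an HDF5 file with datasets ``X`` and ``Y`` of shape
(n, 128, 128) in 64-bit reals plus a ``meta`` attribute group (schema
version, preset, seeds).  Checkpoints are an ``.npz`` of the network state
with a JSON sidecar recording the :class:`~patkit.nets.NetConfig`.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import yaml

from .datasets import PairedDataset
from .nets import NetConfig, UNet, build_network

__all__ = [
    "SchemaError",
    "save_dataset",
    "load_dataset",
    "save_checkpoint",
    "load_checkpoint",
    "RunConfig",
    "load_config",
    "save_config",
]

SCHEMA_VERSION = 1


class SchemaError(RuntimeError):
    """Raised when a container is missing required groups or versions."""


def save_dataset(path: str | Path, dataset: PairedDataset) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("X", data=np.asarray(dataset.x, dtype=np.float64))
        f.create_dataset("Y", data=np.asarray(dataset.y, dtype=np.float64))
        f.attrs["schema_version"] = SCHEMA_VERSION
        f.attrs["meta"] = json.dumps(dataset.meta)


def load_dataset(path: str | Path) -> PairedDataset:
    with h5py.File(path, "r") as f:
        if "schema_version" not in f.attrs or "meta" not in f.attrs:
            raise SchemaError(f"{path}: missing schema metadata")
        if int(f.attrs["schema_version"]) != SCHEMA_VERSION:
            raise SchemaError(
                f"{path}: schema version {f.attrs['schema_version']} != {SCHEMA_VERSION}"
            )
        if "X" not in f or "Y" not in f:
            raise SchemaError(f"{path}: missing X/Y image groups")
        return PairedDataset(f["X"][...], f["Y"][...], json.loads(f.attrs["meta"]))


def save_checkpoint(path: str | Path, network: UNet) -> None:
    path = Path(path)
    np.savez(path, **network.state_dict())
    sidecar = path.with_suffix(path.suffix + ".json")
    sidecar.write_text(json.dumps(dataclasses.asdict(network.config), indent=2))


def load_checkpoint(path: str | Path) -> UNet:
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".json")
    if not sidecar.exists():
        raise SchemaError(f"missing config sidecar {sidecar}")
    config = NetConfig(**json.loads(sidecar.read_text()))
    net = build_network(config)
    with np.load(path if path.exists() else path.with_suffix(path.suffix + ".npz")) as data:
        net.load_state_dict({k: data[k] for k in data.files})
    return net


@dataclass
class RunConfig:
    """End-to-end pipeline configuration (desk scale by default)."""

    preset: str = "1ust"
    n_pairs: int = 100
    variants: tuple[str, ...] = ("hd",)
    fi: int = 16
    epochs: int = 10
    batch_size: int = 2
    repeats: int = 2
    seed: int = 0
    outdir: str = "patkit_run"
    scale: str = "desk"  # desk | full

    def __post_init__(self) -> None:
        if self.scale not in ("desk", "full"):
            raise ValueError("scale must be 'desk' or 'full'")


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "variants" in raw:
        raw["variants"] = tuple(raw["variants"])
    return RunConfig(**raw)


def save_config(path: str | Path, config: RunConfig) -> None:
    d = dataclasses.asdict(config)
    d["variants"] = list(d["variants"])
    Path(path).write_text(yaml.safe_dump(d, sort_keys=False))
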