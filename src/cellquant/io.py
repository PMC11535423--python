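"""File I/O: multi-page TIFF stacks, label masks, YAML configs and
parameter sidecars."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .spots import ImageStack, SpotCallingConfig

__all__ = [
    "read_stack",
    "write_stack",
    "read_labels",
    "write_labels",
    "load_spot_config",
    "write_params_sidecar",
]


def read_stack(path, voxel_size_z: float, pixel_size_xy: float) -> ImageStack:
    """Read a z-major multi-page TIFF as an ImageStack (µm voxel sizes are
    not stored reliably in TIFF tags, so they are passed explicitly)."""
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    return ImageStack(np.asarray(data, dtype=float), voxel_size_z, pixel_size_xy)


def write_stack(path, stack: ImageStack) -> None:
    """Write the stack as a float32 multi-page TIFF, z-major."""
    tifffile.imwrite(path, stack.data.astype(np.float32))


def read_labels(path) -> np.ndarray:
    """Read a 2D label image (0 = background)."""
    labels = tifffile.imread(path)
    if labels.ndim != 2:
        raise ValueError(f"label image must be 2D, got shape {labels.shape}")
    return labels.astype(np.int32)


def write_labels(path, labels: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(labels).astype(np.uint16))


def load_spot_config(path) -> SpotCallingConfig:
    """Load a SpotCallingConfig from a YAML mapping; missing keys keep their
    defaults, unknown keys are an error."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    valid = {f.name for f in dataclasses.fields(SpotCallingConfig)}
    unknown = set(raw) - valid
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return SpotCallingConfig(**raw)


def write_params_sidecar(path, params) -> None:
    """Echo a parameter dataclass (or mapping) to a YAML sidecar so every
    generated dataset records how it was made."""
    if dataclasses.is_dataclass(params) and not isinstance(params, type):
        payload = dataclasses.asdict(params)
    else:
        payload = dict(params)
    payload = {k: (list(v) if isinstance(v, tuple) else v) for k, v in payload.items()}
    Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))
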