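"""File formats: multi-page TIFF stacks, CSV tables, YAML configs."""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .image import ImageStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_table",
    "read_table",
    "config_to_yaml",
    "config_from_yaml",
]


def write_stack(path, stack: ImageStack) -> None:
    """Write a stack as a multi-page float32 TIFF, slices in ascending z."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, stack.voxels.astype(np.float32))


def read_stack(path, z_aspect: float = 3.0) -> ImageStack:
    """Read a grayscale multi-page TIFF (8/16-bit or float) as an ImageStack."""
    voxels = np.asarray(tifffile.imread(path), dtype=float)
    if voxels.ndim == 2:
        voxels = voxels[None]
    return ImageStack(voxels, z_aspect=z_aspect)


def write_table(path, table: pd.DataFrame) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def _as_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _as_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def config_to_yaml(path, config) -> None:
    """Serialize a (possibly nested) config dataclass or dict to YAML."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(_as_plain(config), sort_keys=True))


def config_from_yaml(path, cls=None):
    """Load YAML into a dict, or into *cls* if a dataclass type is given.

    List-valued fields whose dataclass default is a tuple are converted
    back to tuples so round-tripped configs compare equal.
    """
    data = yaml.safe_load(Path(path).read_text())
    if cls is None:
        return data
    kwargs = {}
    defaults = {f.name: f.default for f in dataclasses.fields(cls)}
    for key, value in data.items():
        if isinstance(value, list) and isinstance(defaults.get(key), tuple):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)
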