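"""Reading/writing the pipeline's file formats.

Label volumes are multi-page TIFFs (pages = AP slices, unsigned integer
labels); tables are CSV; models and summaries are JSON; configuration echoes
are YAML with a content hash used as the provenance key for a run.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml


def write_label_volume(path, volume: np.ndarray, voxel_size_um: float) -> None:
    tifffile.imwrite(
        path,
        volume,
        metadata={"voxel_size_um": voxel_size_um, "axes_order": "AP,DV,ML"},
    )


def read_label_volume(path):
    with tifffile.TiffFile(path) as tif:
        volume = tif.asarray()
        meta = tif.shaped_metadata or tif.imagej_metadata or {}
        if isinstance(meta, (list, tuple)):
            meta = meta[0] if meta else {}
    voxel = float(meta.get("voxel_size_um", np.nan)) if meta else float("nan")
    return volume, voxel


def write_table(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.10g")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def config_to_yaml(config) -> str:
    return yaml.safe_dump(_to_plain(config), sort_keys=True)


def config_hash(config) -> str:
    return hashlib.sha256(config_to_yaml(config).encode()).hexdigest()[:16]


def write_config_echo(path, config) -> None:
    Path(path).write_text(config_to_yaml(config))


def write_json(path, obj) -> None:
    with open(path, "w") as fh:
        json.dump(_to_plain(obj), fh, indent=1, sort_keys=True)
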