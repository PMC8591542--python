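"""Reading and writing the pipeline's on-disk formats.

Channels are multi-page TIFF (one file per channel, pages = z slices), label
and truth masks 16-bit integer TIFF, tables CSV, and parameter/spec echoes
YAML.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .synth.fields import FieldSpec, NoiseModel, SyntheticField


def write_stack(path: str | Path, stack: np.ndarray) -> None:
    """Write a (n_slices, H, W) float stack as multi-page float32 TIFF."""
    tifffile.imwrite(str(path), np.asarray(stack, dtype=np.float32))


def read_stack(path: str | Path) -> np.ndarray:
    arr = tifffile.imread(str(path))
    return arr[None] if arr.ndim == 2 else arr


def write_labels(path: str | Path, labels: np.ndarray) -> None:
    tifffile.imwrite(str(path), np.asarray(labels, dtype=np.uint16))


def read_labels(path: str | Path) -> np.ndarray:
    return tifffile.imread(str(path)).astype(np.int32)


def _spec_to_dict(spec) -> dict:
    d = dataclasses.asdict(spec)
    return d


def write_field(field: SyntheticField, outdir: str | Path) -> None:
    """Write a synthetic field: channel TIFFs, truth TIFFs, truth CSV, spec YAML."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for name, stack in field.channels.items():
        write_stack(out / f"{name}.tif", stack)
    write_labels(out / "truth_cells.tif", field.truth_cells)
    for name in ("truth_tubules", "truth_sheets", "truth_clusters"):
        write_labels(out / f"{name}.tif", getattr(field, name).astype(np.uint16))
    field.per_cell_truth.to_csv(out / "per_cell_truth.csv", index=False)
    meta = _spec_to_dict(field.spec)
    meta["focus_slice"] = field.focus_slice
    with open(out / "spec.yaml", "w") as fh:
        yaml.safe_dump(meta, fh, sort_keys=False)


def load_field_spec(path: str | Path) -> FieldSpec:
    """Load a FieldSpec from YAML (tuples coerced, extra keys ignored)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    data.pop("focus_slice", None)
    if "noise_model" in data and isinstance(data["noise_model"], dict):
        data["noise_model"] = NoiseModel(**data["noise_model"])
    for key in ("image_size", "cell_radius_range"):
        if key in data:
            data[key] = tuple(data[key])
    known = {f.name for f in dataclasses.fields(FieldSpec)}
    data = {k: v for k, v in data.items() if k in known}
    return FieldSpec(**data)


def load_params(path: str | Path, cls):
    """Instantiate a params dataclass from a YAML mapping (extra keys ignored)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(cls)}
    clean = {}
    for k, v in data.items():
        if k not in known:
            continue
        clean[k] = tuple(v) if isinstance(v, list) else v
    return cls(**clean)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
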