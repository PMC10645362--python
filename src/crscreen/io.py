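"""File-format adapters: images, tables, YAML specs, run manifests."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

from .types import PlateImage

__all__ = [
    "read_plate_image", "write_plate_image",
    "read_colony_table", "write_colony_table",
    "read_layout", "load_yaml_spec", "write_manifest", "sha256_file",
]


def read_plate_image(path, **meta) -> PlateImage:
    """Read a PNG/TIFF scan into a :class:`PlateImage`.

    Grayscale images are broadcast to three channels; an alpha channel is
    dropped. Keyword arguments (plate_id, condition, grid_rows, ...)
    populate the metadata fields.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        px = tifffile.imread(path)
    else:
        px = iio.imread(path)
    px = np.asarray(px)
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    if px.shape[-1] == 4:
        px = px[..., :3]
    if px.dtype != np.uint8:
        px = np.clip(px, 0, 255).astype(np.uint8)
    meta.setdefault("plate_id", path.stem)
    return PlateImage(pixels=px, **meta)


def write_plate_image(image: PlateImage, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, image.pixels)
    else:
        iio.imwrite(path, image.pixels)
    return path


COLONY_COLUMNS = ["plate_id", "condition", "replicate", "row", "col",
                  "strain", "growth", "red_intensity", "present"]


def write_colony_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in COLONY_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, sep="\t", index=False)
    return path


def read_colony_table(path) -> pd.DataFrame:
    t = pd.read_csv(path, sep="\t")
    if "present" in t.columns:
        t["present"] = t["present"].astype(bool)
    return t


def read_layout(path) -> dict[tuple[int, int], str]:
    """Read a position -> strain layout map from CSV (row, col, strain)."""
    t = pd.read_csv(path)
    cols = {c.lower(): c for c in t.columns}
    for need in ("row", "col", "strain"):
        if need not in cols:
            raise ValueError(f"layout file must have a '{need}' column")
    return {(int(r), int(c)): str(s)
            for r, c, s in zip(t[cols["row"]], t[cols["col"]], t[cols["strain"]])}


def load_yaml_spec(path, spec_cls):
    """Instantiate a generator spec dataclass from a YAML mapping.

    Keys mirror the dataclass fields; ``planted_hits`` may be a list of
    ``[row, col, redness_multiplier, growth_multiplier]`` entries.
    """
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if "planted_hits" in data and isinstance(data["planted_hits"], list):
        data["planted_hits"] = {(int(r), int(c)): (float(rm), float(gm))
                                for r, c, rm, gm in data["planted_hits"]}
    return spec_cls(**data)


def sha256_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def write_manifest(out_dir, config: dict, inputs: list = (), seeds: dict | None = None) -> Path:
    """Write a run manifest (config echo, seeds, versions, input checksums)."""
    from . import __version__

    def _clean(obj):
        if is_dataclass(obj) and not isinstance(obj, type):
            obj = asdict(obj)
        if isinstance(obj, dict):
            return {str(k): _clean(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [_clean(v) for v in obj]
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        if isinstance(obj, Path):
            return str(obj)
        return obj

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "crscreen_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "config": _clean(config),
        "seeds": _clean(seeds or {}),
        "inputs": [{"path": str(p), "sha256": sha256_file(p)} for p in inputs],
    }
    path = out_dir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return path
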