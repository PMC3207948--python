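"""Reading and writing images, masks, reports and synthetic-set manifests.

Supported inputs are single-plane grayscale TIFF or PNG images, 8- or
16-bit.  RGB or multi-channel files are rejected with an instruction to
split channels first; floating-point TIFFs are rejected outright.
Reports are written as JSON (mirroring the coefficient dataclasses) or as
one-row CSV.
"""

from __future__ import annotations

import csv
import dataclasses
import json
from pathlib import Path
from typing import Union

import imageio.v3 as iio
import numpy as np
import tifffile

from .coefficients import ChannelImage
from .synthetic import GridSpec, SpotPair, generate_grid_pair, generate_spot_pair

__all__ = [
    "read_channel_image",
    "write_channel_image",
    "read_mask",
    "percent_threshold",
    "write_report",
    "run_simulate",
]

PathLike = Union[str, Path]


def read_channel_image(path: PathLike) -> ChannelImage:
    """Load one grayscale channel, preserving intensities and bit depth."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        raise ValueError(
            f"{path.name} has {arr.shape[-1]} channels; split channels first "
            "and analyze one grayscale plane per channel"
        )
    if arr.ndim != 2:
        raise ValueError(f"{path.name} is not a single 2-D image plane (shape {arr.shape})")
    if np.issubdtype(arr.dtype, np.floating):
        raise ValueError(f"{path.name} is floating point; only 8/16-bit integer images are supported")
    if arr.dtype == np.uint8:
        depth = 8
    elif arr.dtype == np.uint16:
        depth = 16
    else:
        raise ValueError(f"{path.name} has unsupported dtype {arr.dtype}")
    return ChannelImage(arr, depth)


def write_channel_image(path: PathLike, img: ChannelImage) -> None:
    """Write a channel as grayscale TIFF or PNG (by extension)."""
    path = Path(path)
    dtype = np.uint8 if img.bit_depth == 8 else np.uint16
    arr = img.pixels.astype(dtype)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr)
    else:
        iio.imwrite(path, arr)


def read_mask(path: PathLike) -> np.ndarray:
    """Load a binary ROI mask (any nonzero pixel is included)."""
    img = read_channel_image(path)
    return img.pixels > 0


def percent_threshold(img: ChannelImage, percent: float) -> int:
    """Threshold at ``percent`` % of the maximum intensity present, floored."""
    if not (0.0 <= percent <= 100.0):
        raise ValueError(f"percent must be in [0, 100], got {percent}")
    return int(percent / 100.0 * int(img.pixels.max()))


def _to_jsonable(value):
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {k: _to_jsonable(v) for k, v in dataclasses.asdict(value).items()}
    if isinstance(value, dict):
        return {k: _to_jsonable(v) for k, v in value.items()}
    if isinstance(value, (list, tuple)):
        return [_to_jsonable(v) for v in value]
    if isinstance(value, np.ndarray):
        return value.tolist()
    if isinstance(value, (np.integer,)):
        return int(value)
    if isinstance(value, (np.floating, float)):
        v = float(value)
        return v if np.isfinite(v) else None  # NaN -> null, explicitly flagged
    return value


def write_report(path: PathLike, record: dict, fmt: str = "json") -> None:
    """Serialize one analysis record as JSON or one-row CSV.

    Non-finite coefficient values become JSON ``null`` / empty CSV cells,
    so "not computable" stays distinguishable from 0.
    """
    path = Path(path)
    record = _to_jsonable(record)
    if fmt == "json":
        path.write_text(json.dumps(record, indent=2, sort_keys=True) + "\n")
    elif fmt == "csv":
        flat = _flatten(record)
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(flat))
            writer.writeheader()
            writer.writerow(flat)
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def _flatten(record: dict, prefix: str = "") -> dict:
    out = {}
    for key, value in record.items():
        name = f"{prefix}{key}"
        if isinstance(value, dict):
            out.update(_flatten(value, f"{name}."))
        elif isinstance(value, list):
            out[name] = json.dumps(value)
        else:
            out[name] = "" if value is None else value
    return out


def run_simulate(spec: Union[GridSpec, "SpotPair"], out_dir: PathLike) -> dict:
    """Generate a synthetic pair, write TIFFs plus a JSON manifest.

    Accepts a :class:`~rwcoloc.synthetic.GridSpec` or
    :class:`~rwcoloc.synthetic.SpotSpec`; returns the manifest dict.
    Deterministic: the same spec (including seed) produces byte-identical
    files.
    """
    from .synthetic import SpotSpec  # local import to keep module load light

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if isinstance(spec, GridSpec):
        a, b = generate_grid_pair(spec)
        manifest = {"family": "grid", "spec": dataclasses.asdict(spec)}
    elif isinstance(spec, SpotSpec):
        pair = generate_spot_pair(spec)
        a, b = pair.a, pair.b
        manifest = pair.manifest()
    else:
        raise TypeError(f"unsupported spec type {type(spec).__name__}")
    write_channel_image(out_dir / "channel_a.tif", a)
    write_channel_image(out_dir / "channel_b.tif", b)
    (out_dir / "manifest.json").write_text(
        json.dumps(_to_jsonable(manifest), indent=2, sort_keys=True) + "\n"
    )
    return manifest
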