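"""Reading and writing masks, fields, populations and parameter files.

Masks travel as single-channel PNG/TIFF (0 = avascular, 255 = vascular);
fields and populations as delimited text with headers; parameters and
geometry specs as YAML or JSON.  All round-trips are lossless: floats are
written with 17 significant digits.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import yaml

from .geometry import FieldSet, GeometrySpec, VesselMask

__all__ = [
    "read_mask",
    "write_mask",
    "read_fields",
    "write_fields",
    "read_population",
    "write_population",
    "load_spec",
    "save_spec",
    "load_params",
    "save_params",
]

_FLOAT_FMT = "%.17g"


def write_mask(mask: VesselMask, path: str | Path) -> None:
    iio.imwrite(Path(path), (mask.grid.astype(np.uint8) * 255))


def read_mask(path: str | Path, pixel_size: float = 1.0, threshold: float | None = None) -> VesselMask:
    """Read a binary mask image.

    Non-binary or multi-channel images are rejected unless ``threshold``
    is given, in which case channels are averaged and pixels strictly
    above the threshold become vascular.
    """
    img = np.asarray(iio.imread(Path(path)))
    if img.ndim == 3:
        if threshold is None:
            raise ValueError("multi-channel image: pass an explicit threshold")
        img = img.mean(axis=2)
    if img.dtype == bool:
        grid = img
    else:
        values = np.unique(img)
        if threshold is not None:
            grid = img > threshold
        elif set(values.tolist()) <= {0, 1} or set(values.tolist()) <= {0, 255}:
            grid = img > 0
        else:
            raise ValueError("non-binary image: pass an explicit threshold")
    return VesselMask(grid, pixel_size)


def write_fields(fields: FieldSet, path: str | Path) -> None:
    """Write per-lumen-pixel field values as CSV (x_px, y_px, vx, vy, tau)."""
    defined = np.isfinite(fields.interior_shear)
    rows, cols = np.nonzero(defined)
    df = pd.DataFrame(
        {
            "x_px": cols,
            "y_px": rows,
            "vx_um_s": fields.velocity[rows, cols, 0],
            "vy_um_s": fields.velocity[rows, cols, 1],
            "tau_pa": fields.interior_shear[rows, cols],
            "tau_wall_pa": fields.wall_shear[rows, cols],
        }
    )
    df.to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def read_fields(path: str | Path, shape: tuple[int, int]) -> FieldSet:
    df = pd.read_csv(Path(path), float_precision="round_trip")
    velocity = np.zeros(shape + (2,))
    interior = np.full(shape, np.nan)
    wall = np.full(shape, np.nan)
    r = df["y_px"].to_numpy(dtype=int)
    c = df["x_px"].to_numpy(dtype=int)
    velocity[r, c, 0] = df["vx_um_s"]
    velocity[r, c, 1] = df["vy_um_s"]
    interior[r, c] = df["tau_pa"]
    wall[r, c] = df["tau_wall_pa"]
    return FieldSet(velocity, wall, interior)


def write_population(pop, path: str | Path) -> None:
    pop.to_dataframe().to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def read_population(path: str | Path):
    from .model import Population

    return Population.from_dataframe(
        pd.read_csv(Path(path), float_precision="round_trip"))


def _dump(obj: dict, path: Path) -> None:
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(obj, sort_keys=False))
    else:
        path.write_text(json.dumps(obj, indent=2))


def _load(path: Path) -> dict:
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        return yaml.safe_load(text)
    return json.loads(text)


def save_spec(spec: GeometrySpec, path: str | Path) -> None:
    _dump(dataclasses.asdict(spec), Path(path))


def load_spec(path: str | Path) -> GeometrySpec:
    return GeometrySpec(**_load(Path(path)))


def save_params(params, path: str | Path) -> None:
    _dump(dataclasses.asdict(params), Path(path))


def load_params(path: str | Path):
    from .model import ModelParams

    return ModelParams(**_load(Path(path)))
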