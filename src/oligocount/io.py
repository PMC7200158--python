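"""Shared readers/writers: CSV tables, TIFF stacks, PDB centroids, and
the provenance records that make every run reproducible from its output."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .tirf import ImageStack

__all__ = [
    "read_table",
    "write_table",
    "read_stack",
    "write_stack",
    "write_provenance",
    "detections_to_frame",
]

#: floats are written with 9 significant digits
_FLOAT_FMT = "%.9g"


def read_table(path, required_columns: list[str] | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        df = pd.read_csv(path)
    except Exception as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    if required_columns:
        missing = [c for c in required_columns if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required columns {missing}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_stack(path, pixel_size_nm: float = 65.0, exposure_ms: float = 100.0) -> ImageStack:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return ImageStack(np.asarray(data), pixel_size_nm, exposure_ms)


def write_stack(stack: ImageStack, path) -> None:
    """Write a multi-frame TIFF; integer data round-trips bit-exactly."""
    tifffile.imwrite(str(path), stack.data)


def detections_to_frame(detections) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "frame": d.frame,
                "x": d.x,
                "y": d.y,
                "amplitude": d.amplitude,
                "background": d.background,
                "sigma": d.sigma,
                "p_value": d.p_value,
            }
            for d in detections
        ]
    )


def write_provenance(path, *, command: str, parameters: dict, seed=None) -> None:
    """Record how an output was produced (inputs, parameters, seed)."""
    from . import __version__

    record = {
        "package": "oligocount",
        "version": __version__,
        "command": command,
        "parameters": parameters,
        "seed": seed,
    }
    Path(path).write_text(json.dumps(record, indent=2, default=str) + "\n")
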