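"""Artifact I/O with provenance headers.

Tables go to CSV (UTF-8, comma, '.' decimal, mandatory header row) with a
leading comment block recording the package version, the seed and a hash
of the generating config, so any artifact is reproducible from its header.
Images and label masks go to 16-bit TIFF (multi-page, one page per
channel).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from . import __version__

__all__ = [
    "config_hash",
    "write_table",
    "read_table",
    "write_image",
    "read_image",
    "write_mask",
    "read_mask",
]


def _jsonable(obj):
    if hasattr(obj, "__dataclass_fields__"):
        obj = {k: getattr(obj, k) for k in obj.__dataclass_fields__}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return str(obj)


def config_hash(config) -> str:
    """Stable short hash of a config-like object (dict or dataclass)."""
    payload = json.dumps(_jsonable(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def write_table(df: pd.DataFrame, path, seed: int | None = None,
                config=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(f"# oralcyto {__version__}\n")
        if seed is not None:
            fh.write(f"# seed {seed}\n")
        if config is not None:
            fh.write(f"# config_hash {config_hash(config)}\n")
        df.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def _to_uint16(img: np.ndarray) -> np.ndarray:
    return np.clip(np.asarray(img, dtype=float) * 65535.0, 0, 65535).astype(np.uint16)


def write_image(image: np.ndarray, path) -> None:
    """(n_channels, H, W) float [0,1] -> multi-page 16-bit TIFF."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, _to_uint16(image), photometric="minisblack")


def read_image(path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    return arr.astype(float) / 65535.0


def write_mask(mask: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint16))


def read_mask(path) -> np.ndarray:
    return tifffile.imread(path).astype(np.int32)
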