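"""File I/O: TIFF movies, configuration files and localization tables.

Localization tables are CSV with header ``frame,x_nm,y_nm,n_psf,n_b``
(optionally ``reliability``); coordinates are sample-plane nm with the
origin at the outer corner of pixel (0, 0) and x along the column axis.
Configuration is YAML holding the :class:`~smlmbayes.camera.CameraOptics`
keys plus optional analysis settings.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .camera import CameraOptics

__all__ = ["load_config", "save_config", "read_movie", "write_movie",
           "read_localizations", "write_localizations"]

CAMERA_KEYS = ("offset", "gain", "pixel_size_nm", "magnification", "na", "wavelength_nm")
TABLE_COLUMNS = ("frame", "x_nm", "y_nm", "n_psf", "n_b")


def load_config(path) -> tuple[CameraOptics, dict]:
    """Load a YAML config; returns (CameraOptics, extra settings dict)."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    missing = [k for k in CAMERA_KEYS if k not in raw]
    if missing:
        raise KeyError(f"config is missing camera keys: {missing}")
    cam = CameraOptics(**{k: float(raw[k]) for k in CAMERA_KEYS})
    extra = {k: v for k, v in raw.items() if k not in CAMERA_KEYS}
    return cam, extra


def save_config(path, cam: CameraOptics, **extra) -> None:
    data = {k: getattr(cam, k) for k in CAMERA_KEYS}
    data.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def read_movie(path) -> np.ndarray:
    """Read a grayscale TIFF stack as (frames, H, W)."""
    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    if arr.ndim != 3:
        raise ValueError(f"expected a 2D/3D grayscale TIFF, got shape {arr.shape}")
    return arr


def write_movie(path, movie: np.ndarray) -> None:
    tifffile.imwrite(path, np.asarray(movie))


def read_localizations(path) -> pd.DataFrame:
    """Read a localization CSV; requires at least frame, x_nm, y_nm."""
    df = pd.read_csv(path)
    missing = {"frame", "x_nm", "y_nm"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    df["frame"] = df["frame"].astype(int)
    return df


def write_localizations(path, table: pd.DataFrame) -> None:
    table.to_csv(path, index=False, float_format="%.6g")


def write_image(path, image: np.ndarray) -> None:
    """Write a rendered image as 32-bit float TIFF."""
    tifffile.imwrite(path, np.asarray(image, dtype=np.float32))


def write_image_png(path, image: np.ndarray, cmap: str = "inferno") -> None:
    """Write a color-mapped 8-bit PNG of a rendered image for inspection."""
    import matplotlib

    matplotlib.use("Agg")
    from PIL import Image

    arr = np.asarray(image, dtype=float)
    peak = arr.max()
    if peak > 0:
        arr = arr / peak
    rgba = (matplotlib.colormaps[cmap](arr) * 255).astype(np.uint8)
    Image.fromarray(rgba).save(path)
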