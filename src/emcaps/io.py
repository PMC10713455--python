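"""Raster, table and configuration I/O.

Images are 8/16-bit grayscale TIFF or PNG; label maps are 8-bit indexed
rasters with a fixed class palette (0 background, 1..6 classes, 7
pattern).  The physical pixel size travels either as an explicit
argument or in a JSON sidecar ``<image>.meta.json`` with key
``nm_per_pixel`` (default 1.81 nm/px).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from PIL import Image

from .core import BarcodeClass, Micrograph, PixelScale

__all__ = [
    "PALETTE",
    "read_image",
    "write_image",
    "read_labels",
    "write_labels",
    "write_instances_csv",
    "read_instances_csv",
    "load_config",
    "config_hash",
    "overlay",
]

#: RGB palette, one entry per raster label (0..7): background, six
#: barcode classes, pattern channel.
PALETTE: tuple[tuple[int, int, int], ...] = (
    (0, 0, 0),        # 0 background
    (0, 255, 255),    # 1 1M-Qt  cyan
    (0, 128, 255),    # 2 2M-Qt  azure
    (0, 0, 255),      # 3 3M-Qt  blue
    (255, 160, 0),    # 4 1M-Mx  orange
    (255, 0, 0),      # 5 2M-Mx  red
    (255, 0, 255),    # 6 1M-Tm  magenta
    (255, 255, 0),    # 7 pattern yellow
)


def _sidecar_scale(path: Path) -> PixelScale | None:
    side = path.with_suffix(path.suffix + ".meta.json")
    if side.exists():
        meta = json.loads(side.read_text())
        if "nm_per_pixel" in meta:
            return PixelScale(float(meta["nm_per_pixel"]))
    return None


def read_image(path: str | Path, nm_per_pixel: float | None = None) -> Micrograph:
    """Read an 8/16-bit grayscale TIFF/PNG micrograph.

    Pixel size: explicit argument, else JSON sidecar, else 1.81 nm/px.
    Multi-channel input is rejected.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = np.asarray(Image.open(path))
    if data.ndim != 2:
        raise IOError(f"{path}: expected single-channel grayscale, "
                      f"got shape {data.shape}")
    if nm_per_pixel is not None:
        scale = PixelScale(nm_per_pixel)
    else:
        scale = _sidecar_scale(path) or PixelScale()
    return Micrograph(data, scale)


def write_image(micrograph: Micrograph | np.ndarray, path: str | Path,
                nm_per_pixel: float | None = None) -> None:
    """Write a micrograph as 16-bit TIFF or PNG (8-bit for PNG floats).

    Integer rasters round-trip bit for bit.  Float rasters are clipped
    to [0, 1] and scaled to the full 16-bit (TIFF) or 8-bit (PNG) range.
    A pixel-size sidecar is written alongside.
    """
    path = Path(path)
    if isinstance(micrograph, Micrograph):
        data = micrograph.pixels
        scale = micrograph.scale
    else:
        data = np.asarray(micrograph)
        scale = PixelScale(nm_per_pixel) if nm_per_pixel else PixelScale()
    is_png = path.suffix.lower() == ".png"
    if np.issubdtype(data.dtype, np.floating):
        top = 255 if is_png else 65535
        data = np.round(np.clip(data, 0.0, 1.0) * top).astype(
            np.uint8 if is_png else np.uint16)
    if is_png:
        Image.fromarray(data).save(path)
    else:
        tifffile.imwrite(path, data)
    path.with_suffix(path.suffix + ".meta.json").write_text(
        json.dumps({"nm_per_pixel": scale.nm_per_pixel}) + "\n")


def write_labels(labels: np.ndarray, path: str | Path) -> None:
    """Write a label raster (0..7) as an indexed PNG or 8-bit TIFF.

    PNGs carry the fixed class palette so the files render color-coded
    in any viewer; values round-trip exactly either way.
    """
    labels = np.asarray(labels)
    if labels.ndim != 2:
        raise ValueError("label raster must be 2D")
    if labels.min() < 0 or labels.max() > 7:
        raise ValueError(f"labels must lie in 0..7, got max {labels.max()}")
    path = Path(path)
    data = labels.astype(np.uint8)
    if path.suffix.lower() == ".png":
        img = Image.fromarray(data, mode="P")
        pal = [v for rgb in PALETTE for v in rgb]
        img.putpalette(pal + [0] * (768 - len(pal)))
        img.save(path)
    else:
        tifffile.imwrite(path, data)


def read_labels(path: str | Path) -> np.ndarray:
    """Read a label raster written by :func:`write_labels`."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such label raster: {path}")
    if path.suffix.lower() in (".tif", ".tiff"):
        data = tifffile.imread(path)
    else:
        data = np.asarray(Image.open(path))
    if data.ndim != 2:
        raise IOError(f"{path}: label raster must be single-channel")
    if data.max() > 7:
        raise ValueError(f"{path}: labels exceed 7")
    return data.astype(np.uint8)


_INSTANCE_COLUMNS = ["id", "class", "center_y_px", "center_x_px",
                     "center_y_nm", "center_x_nm", "radius_nm", "pattern_id"]


def write_instances_csv(instances, path: str | Path) -> None:
    """Write simulator ground-truth instances (or records) to CSV."""
    rows = []
    for inst in instances:
        if hasattr(inst, "center_px"):  # simulator TrueInstance
            ry, cx = inst.center_px
            ny, nx = inst.center_nm
            rows.append([inst.id, int(inst.class_id), ry, cx, ny, nx,
                         inst.radius_nm,
                         -1 if inst.pattern_id is None else inst.pattern_id])
        else:  # InstanceRecord
            ry, cx = inst.centroid
            rows.append([inst.id, int(inst.class_id), ry, cx,
                         np.nan, np.nan, np.nan, -1])
    pd.DataFrame(rows, columns=_INSTANCE_COLUMNS).to_csv(path, index=False)


def read_instances_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_INSTANCE_COLUMNS) - set(df.columns)
    if missing:
        raise IOError(f"{path}: missing instance columns {sorted(missing)}")
    return df


def records_to_frame(records) -> pd.DataFrame:
    """Instance records (with scores) as a flat table."""
    rows = []
    for r in records:
        row = {
            "id": r.id, "class": r.class_id,
            "centroid_row_px": r.centroid[0], "centroid_col_px": r.centroid[1],
            "area_px": r.area_px, "perimeter_px": r.perimeter_px,
            "circularity": r.circularity,
            "bbox_r0": r.bbox[0], "bbox_c0": r.bbox[1],
            "bbox_r1": r.bbox[2], "bbox_c1": r.bbox[3],
            "touches_border": r.touches_border,
            "exclusion_reason": r.exclusion_reason.value,
        }
        scores = r.scores if r.scores is not None else [np.nan] * 6
        for cls, s in zip(BarcodeClass, scores):
            row[f"score_{cls.name.lower()}"] = s
        rows.append(row)
    return pd.DataFrame(rows)


def load_config(path: str | Path) -> dict:
    """Load a YAML config file as a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def config_hash(config: dict) -> str:
    """SHA-256 of the canonicalized (sorted-key) YAML form of a config."""
    canon = yaml.safe_dump(config, sort_keys=True, default_flow_style=True)
    return hashlib.sha256(canon.encode()).hexdigest()


def overlay(micrograph: Micrograph | np.ndarray, labels: np.ndarray,
            alpha: float = 0.45) -> np.ndarray:
    """Alpha-blend a color-coded label map onto a grayscale raster (uint8 RGB)."""
    img = micrograph.pixels if isinstance(micrograph, Micrograph) else micrograph
    img = np.asarray(img, float)
    lo, hi = img.min(), img.max()
    gray = (img - lo) / (hi - lo) if hi > lo else np.zeros_like(img)
    rgb = np.repeat(gray[..., None], 3, axis=2)
    pal = np.asarray(PALETTE, float) / 255.0
    color = pal[np.asarray(labels)]
    fg = (np.asarray(labels) > 0)[..., None]
    out = np.where(fg, (1 - alpha) * rgb + alpha * color, rgb)
    return np.round(out * 255).astype(np.uint8)
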