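"""Calibrated multi-channel images, mat-surface delineation, and file I/O.

Images are confocal cross-sections with a known physical pixel size and
named channels (``probe`` = FISH signal, ``counterstain`` = general DNA
stain, ``reflectance`` = mineral signal).  TIFF round-trips store one page
per channel with the channel order and calibration in the image description,
so a written image reloads identically.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
import yaml
from scipy.ndimage import median_filter

from .exceptions import NoSurfaceError, ParameterError

#: Canonical channel order used in multi-page TIFF exports.
CHANNEL_ORDER = ("probe", "counterstain", "reflectance")


@dataclass
class CalibratedImage:
    """Multi-channel raster with physical calibration.

    All channels share one shape; intensities are finite and non-negative.
    """

    channels: dict[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise ParameterError("pixel_size_um must be > 0")
        if not self.channels:
            raise ParameterError("image needs at least one channel")
        shapes = {ch.shape for ch in self.channels.values()}
        if len(shapes) != 1:
            raise ParameterError("all channels must share one shape")
        for name, ch in self.channels.items():
            arr = np.asarray(ch, dtype=float)
            if not np.all(np.isfinite(arr)) or (arr < 0).any():
                raise ParameterError(f"channel {name!r} has non-finite or negative values")
            self.channels[name] = arr

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.channels)

    def stack(self) -> np.ndarray:
        """Channels stacked to (n_channels, rows, cols) in canonical order."""
        names = [n for n in CHANNEL_ORDER if n in self.channels]
        names += [n for n in self.channels if n not in names]
        return np.stack([self.channels[n] for n in names])

    # -- I/O ---------------------------------------------------------------
    def to_tiff(self, path) -> None:
        names = [n for n in CHANNEL_ORDER if n in self.channels]
        names += [n for n in self.channels if n not in names]
        meta = {"pixel_size_um": self.pixel_size_um, "channels": names}
        data = np.stack([self.channels[n] for n in names]).astype(np.float32)
        tifffile.imwrite(
            path, data, description=json.dumps(meta), photometric="minisblack"
        )

    @classmethod
    def from_tiff(cls, path) -> "CalibratedImage":
        with tifffile.TiffFile(path) as tif:
            data = tif.asarray()
            desc = tif.pages[0].description
        meta = json.loads(desc)
        if data.ndim == 2:
            data = data[None]
        channels = {name: data[i].astype(float) for i, name in enumerate(meta["channels"])}
        return cls(channels=channels, pixel_size_um=float(meta["pixel_size_um"]))


@dataclass
class SurfaceLine:
    """Per-column surface depth in pixel rows (float), one value per column."""

    depth_px: np.ndarray
    smooth_window_px: int
    pixel_size_um: float

    def __post_init__(self) -> None:
        self.depth_px = np.asarray(self.depth_px, dtype=float)
        if self.depth_px.ndim != 1:
            raise ParameterError("surface line must be one value per column")

    @property
    def depth_um(self) -> np.ndarray:
        return self.depth_px * self.pixel_size_um

    def at_x_um(self, x_um: np.ndarray) -> np.ndarray:
        """Surface depth (um) at horizontal positions, nearest-column lookup."""
        cols = np.clip(
            (np.asarray(x_um, dtype=float) / self.pixel_size_um - 0.5).round().astype(int),
            0,
            len(self.depth_px) - 1,
        )
        return self.depth_px[cols] * self.pixel_size_um


def detect_surface(
    mask: np.ndarray,
    smooth_window_px: int = 5,
    pixel_size_um: float = 682.67 / 512.0,
) -> SurfaceLine:
    """Delineate the mat surface from a foreground mask.

    For every column the topmost foreground pixel row is taken; columns with
    no foreground are linearly interpolated from their nearest defined
    neighbours (edges extend the nearest value); the line is then median
    smoothed over ``smooth_window_px`` columns.  The mask should be the union
    of all foreground classes, since Type-1 surfaces are cell/EPS-bound and
    Type-2 surfaces are crust-bound.
    """
    mask = np.asarray(mask, dtype=bool)
    if mask.ndim != 2:
        raise ParameterError("mask must be 2-D")
    if not mask.any():
        raise NoSurfaceError("mask is entirely empty; no surface to delineate")
    n_rows, n_cols = mask.shape
    any_fg = mask.any(axis=0)
    top = np.where(any_fg, mask.argmax(axis=0), np.nan).astype(float)

    cols = np.arange(n_cols)
    defined = ~np.isnan(top)
    top = np.interp(cols, cols[defined], top[defined])

    if smooth_window_px > 1:
        top = median_filter(top, size=smooth_window_px, mode="nearest")
    return SurfaceLine(depth_px=top, smooth_window_px=smooth_window_px, pixel_size_um=pixel_size_um)


# ---------------------------------------------------------------------------
# plain-text I/O helpers (points as um CSV, masks as single-page TIFF, YAML)
# ---------------------------------------------------------------------------

def write_points_csv(path, points_um: np.ndarray, classes=None) -> None:
    """Write object centroids as CSV with um coordinates at 4 decimals."""
    pts = np.asarray(points_um, dtype=float).reshape(-1, 2)
    df = pd.DataFrame({"x_um": pts[:, 0], "y_um": pts[:, 1]})
    if classes is not None:
        df.insert(0, "class", list(classes))
    df.to_csv(path, index=False, float_format="%.4f")


def read_points_csv(path) -> np.ndarray:
    df = pd.read_csv(path)
    return df[["x_um", "y_um"]].to_numpy(dtype=float)


def write_mask_tiff(path, mask: np.ndarray, pixel_size_um: float) -> None:
    meta = {"pixel_size_um": pixel_size_um, "binary_mask": True}
    tifffile.imwrite(path, np.asarray(mask, dtype=np.uint8), description=json.dumps(meta))


def read_mask_tiff(path) -> tuple[np.ndarray, float]:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = json.loads(tif.pages[0].description)
    return data.astype(bool), float(meta["pixel_size_um"])


def write_yaml(path, obj: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
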