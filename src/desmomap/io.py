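"""Readers and writers for localization tables, ROI lists and rendered images.

Canonical coordinates throughout the package: nanometres, origin at the
top-left of the image, x to the right, y increasing downward (matching
array indexing ``data[row=y, col=x]``).

Localization tables are plain CSV with a header.  Three dialects are
accepted:

``canonical``
    columns ``id, frame, x_nm, y_nm, precision_nm, channel`` (only
    ``x_nm``/``y_nm`` are required; the rest are defaulted),
``smlm``
    the common SMLM export header ``"x [nm]", "y [nm]", "uncertainty [nm]"``,
``px``
    pixel-unit columns ``x_px, y_px`` converted via a declared pixel size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import DataError, FormatError, ParseError

logger = logging.getLogger(__name__)

CANONICAL_COLUMNS = ["id", "frame", "x_nm", "y_nm", "precision_nm", "channel"]

_SMLM_MAP = {
    "x [nm]": "x_nm",
    "y [nm]": "y_nm",
    "uncertainty [nm]": "precision_nm",
    "frame": "frame",
    "id": "id",
    "channel": "channel",
}


@dataclass(frozen=True)
class RenderedImage:
    """A rendered super-resolution image: non-negative pixel grid at fixed nm/pixel.

    ``origin`` is the nm coordinate of the top-left corner of pixel (0, 0),
    so absolute positions remain traceable through ROI excision.
    """

    data: np.ndarray
    pixel_size: float = 4.0
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise DataError(f"pixel_size must be > 0, got {self.pixel_size}")
        if np.asarray(self.data).ndim != 2:
            raise DataError("image data must be 2D")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def extent(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) in nm."""
        nrows, ncols = self.data.shape
        x0, y0 = self.origin
        return (x0, x0 + ncols * self.pixel_size, y0, y0 + nrows * self.pixel_size)


@dataclass(frozen=True)
class DesmosomeROI:
    """Axis-aligned rectangular region of interest around one desmosome (nm)."""

    center_x: float
    center_y: float
    half_width: float
    half_height: float
    label: str = ""

    def __post_init__(self):
        if self.half_width <= 0 or self.half_height <= 0:
            raise DataError(
                f"ROI {self.label!r}: half extents must be positive "
                f"({self.half_width}, {self.half_height})"
            )

    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, xmax, ymin, ymax) in nm."""
        return (
            self.center_x - self.half_width,
            self.center_x + self.half_width,
            self.center_y - self.half_height,
            self.center_y + self.half_height,
        )


def _coerce_numeric(df: pd.DataFrame, columns: Sequence[str], path) -> pd.DataFrame:
    for col in columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} in column "
                f"{col!r} at data row {row}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ParseError(f"{path}: missing value in column {col!r} at data row {row}")
        df[col] = coerced
    return df


def read_localizations(
    path, dialect: str = "canonical", pixel_size: Optional[float] = None
) -> pd.DataFrame:
    """Read a localization table into canonical nm coordinates.

    Row order is preserved.  Missing optional columns are defaulted
    (``id`` = row index, ``frame`` = 0, ``precision_nm`` = 0, ``channel`` = 0).
    Raises :class:`FormatError` for missing required columns and
    :class:`ParseError` (with the row number) for non-numeric cells.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    df.columns = [c.strip() for c in df.columns]

    if dialect == "canonical":
        required = ["x_nm", "y_nm"]
    elif dialect == "smlm":
        df = df.rename(columns=_SMLM_MAP)
        required = ["x_nm", "y_nm"]
    elif dialect == "px":
        if pixel_size is None or pixel_size <= 0:
            raise DataError("px dialect requires a positive pixel_size")
        required = ["x_px", "y_px"]
    else:
        raise DataError(f"unknown dialect {dialect!r}")

    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")

    numeric = [c for c in set(required) | set(CANONICAL_COLUMNS) if c in df.columns]
    df = _coerce_numeric(df, numeric, path)

    if dialect == "px":
        df["x_nm"] = df["x_px"] * pixel_size
        df["y_nm"] = df["y_px"] * pixel_size

    n = len(df)
    if "id" not in df.columns:
        df["id"] = np.arange(n)
    if "frame" not in df.columns:
        df["frame"] = 0
    if "precision_nm" not in df.columns:
        df["precision_nm"] = 0.0
    if "channel" not in df.columns:
        df["channel"] = 0

    if (df["precision_nm"] < 0).any():
        raise DataError(f"{path}: negative localization precision")
    if not np.isfinite(df[["x_nm", "y_nm"]].to_numpy(dtype=float)).all():
        raise DataError(f"{path}: non-finite coordinates")

    out = df[CANONICAL_COLUMNS].copy()
    out["id"] = out["id"].astype(int)
    out["frame"] = out["frame"].astype(int)
    out["channel"] = out["channel"].astype(int)
    return out


def write_localizations(table: pd.DataFrame, path) -> None:
    """Write a localization table as canonical CSV."""
    cols = [c for c in CANONICAL_COLUMNS if c in table.columns]
    table[cols].to_csv(path, index=False)


def read_roi_list(path, image: Optional[RenderedImage] = None) -> list[DesmosomeROI]:
    """Read a CSV of desmosome ROIs.

    Required columns: ``center_x_nm, center_y_nm, half_width_nm,
    half_height_nm``; optional ``label``.  If ``image`` is given, ROIs that
    fall outside it are skipped with a logged warning rather than raising.
    Non-positive half extents raise :class:`DataError`.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    try:
        df = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        return []
    if df.empty and len(df.columns) == 0:
        return []
    required = ["center_x_nm", "center_y_nm", "half_width_nm", "half_height_nm"]
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    df = _coerce_numeric(df, required, path)

    rois = []
    for i, row in df.iterrows():
        label = str(row["label"]) if "label" in df.columns and pd.notna(row.get("label")) else f"roi{i}"
        roi = DesmosomeROI(
            center_x=float(row["center_x_nm"]),
            center_y=float(row["center_y_nm"]),
            half_width=float(row["half_width_nm"]),
            half_height=float(row["half_height_nm"]),
            label=label,
        )
        if image is not None:
            xmin, xmax, ymin, ymax = roi.bounds()
            ix0, ix1, iy0, iy1 = image.extent()
            if xmin < ix0 or xmax > ix1 or ymin < iy0 or ymax > iy1:
                logger.warning("ROI %s outside image bounds; skipped", roi.label)
                continue
        rois.append(roi)
    return rois


def write_image(image: RenderedImage, path) -> None:
    """Write a rendered image as single-channel 32-bit TIFF.

    Pixel size and origin are stored in the TIFF's shaped metadata so a
    round-trip through :func:`read_image` is lossless.
    """
    tifffile.imwrite(
        str(path),
        np.asarray(image.data, dtype=np.float32),
        metadata={
            "pixel_size_nm": image.pixel_size,
            "origin_x_nm": image.origin[0],
            "origin_y_nm": image.origin[1],
        },
    )


def read_image(path, pixel_size: Optional[float] = None) -> RenderedImage:
    """Read a single-channel TIFF; pixel size from metadata unless overridden."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        meta = (tif.shaped_metadata or [{}])[0]
    if data.ndim != 2:
        raise FormatError(f"{path}: expected a single-channel 2D image, got shape {data.shape}")
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_nm", 4.0)
    origin = (float(meta.get("origin_x_nm", 0.0)), float(meta.get("origin_y_nm", 0.0)))
    return RenderedImage(data=np.asarray(data, dtype=np.float32), pixel_size=float(px), origin=origin)
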