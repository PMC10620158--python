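"""Readers and writers for the rasters and tables the pipeline touches.

Images are single-channel 8/16-bit TIFFs; profiles and results are
plain CSV (comma-separated, '.' decimal, UTF-8). Every image carries an
explicit micrometre-per-pixel calibration supplied by the caller or a
JSON sidecar — there is no default pixel size.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

from .types import CalibratedImage, IntensityProfile, LineROI

__all__ = [
    "load_image",
    "save_image",
    "read_profile_csv",
    "read_roi_json",
    "write_roi_json",
    "write_results",
    "read_area_csv",
]

log = logging.getLogger("epiwound")


def load_image(
    path: str | Path,
    pixel_size_um: float | None = None,
    channel: str = "",
) -> CalibratedImage:
    """Load a single-channel 8/16-bit TIFF as a :class:`CalibratedImage`.

    ``pixel_size_um`` may be omitted only when a JSON sidecar
    (``<path>.json``) written by :func:`save_image` provides it; the
    calibration is never guessed.
    """
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2-D image, got shape {arr.shape}; "
            "export each channel to its own file"
        )
    if arr.dtype == np.uint8:
        bit_depth = 8
    elif arr.dtype == np.uint16:
        bit_depth = 16
    else:
        raise ValueError(f"{path}: expected uint8 or uint16 pixels, got {arr.dtype}")
    if pixel_size_um is None:
        sidecar = path.with_suffix(path.suffix + ".json")
        if sidecar.exists():
            meta = json.loads(sidecar.read_text())
            pixel_size_um = meta.get("pixel_size_um")
        if pixel_size_um is None:
            raise ValueError(
                f"{path}: no pixel_size_um given and no sidecar found; "
                "a µm/px calibration is required"
            )
    return CalibratedImage(arr.astype(float), float(pixel_size_um), channel, bit_depth)


def save_image(
    image: CalibratedImage,
    path: str | Path,
    sidecar: Mapping | None = None,
) -> Path:
    """Write a CalibratedImage as TIFF plus a JSON calibration sidecar.

    Pixels are clipped to the dtype range implied by ``bit_depth`` and
    rounded; the sidecar always records ``pixel_size_um`` and merges any
    extra metadata mapping passed by the caller (e.g. seed, params).
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    dtype = np.uint8 if image.bit_depth == 8 else np.uint16
    hi = np.iinfo(dtype).max
    raster = np.clip(np.round(image.pixels), 0, hi).astype(dtype)
    tifffile.imwrite(path, raster)
    meta = {"pixel_size_um": image.pixel_size_um, "channel": image.channel}
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_profile_csv(path: str | Path) -> IntensityProfile:
    """Read a (position_um, intensity) profile CSV.

    The file needs a header and at least two numeric columns; the first
    two are used (extra columns are ignored with a logged warning).
    Lines starting with ``#`` are comments. Positions must be strictly
    increasing and at least 5 samples are required.
    """
    path = Path(path)
    df = pd.read_csv(path, comment="#")
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need at least two columns (position_um, intensity)")
    if df.shape[1] > 2:
        log.warning(
            "%s: %d extra column(s) ignored (%s)",
            path, df.shape[1] - 2, ", ".join(map(str, df.columns[2:])),
        )
    pos = pd.to_numeric(df.iloc[:, 0], errors="raise").to_numpy(float)
    val = pd.to_numeric(df.iloc[:, 1], errors="raise").to_numpy(float)
    if pos.size < 5:
        raise ValueError(f"{path}: profile has {pos.size} samples, need >= 5")
    bad = np.nonzero(np.diff(pos) <= 0)[0]
    if bad.size:
        # +2: 1 for the header line, 1 because the offender is the *next* row
        raise ValueError(
            f"{path}: positions not strictly increasing at data row {bad[0] + 2} "
            f"(position {pos[bad[0] + 1]!r} after {pos[bad[0]]!r})"
        )
    return IntensityProfile(pos, val)


def read_roi_json(path: str | Path) -> list[LineROI]:
    """Read a list of line ROIs from JSON.

    Schema: ``[{"start_px": [row, col], "end_px": [row, col],
    "wound_end": "start"|"end"}, ...]`` — pixel coordinates, because ROI
    lines are drawn in an image viewer.
    """
    items = json.loads(Path(path).read_text())
    return [
        LineROI(tuple(d["start_px"]), tuple(d["end_px"]), d.get("wound_end", "start"))
        for d in items
    ]


def write_roi_json(rois: Sequence[LineROI], path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(
        [
            {"start_px": list(r.start_px), "end_px": list(r.end_px),
             "wound_end": r.wound_end}
            for r in rois
        ],
        indent=1,
    ))
    return path


def write_results(records: Iterable[Mapping] | pd.DataFrame, path: str | Path) -> Path:
    """Write tidy result records to CSV.

    One row per record (e.g. per animal/wound/line or per image), stable
    column order taken from the records, floats printed at 6 significant
    digits. Empty input is an error — silently writing an empty table
    hides upstream failures.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        df = pd.DataFrame(list(records))
    if df.empty:
        raise ValueError("no records to write")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_area_csv(path: str | Path) -> pd.DataFrame:
    """Read a wound-area table (wound_id, animal, treatment, frame, area_mm2).

    Single-series files may omit the id columns; frame and area_mm2 are
    required.
    """
    df = pd.read_csv(Path(path), comment="#")
    cols = {c.lower(): c for c in df.columns}
    for req in ("frame", "area_mm2"):
        if req not in cols:
            raise ValueError(f"{path}: required column '{req}' missing")
    return df.rename(columns={v: k for k, v in cols.items()})
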