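"""Core unit-bearing containers shared across the pipeline.

Conventions used throughout the package:

* image coordinates are 0-based ``(row, col)`` with the origin at the
  top-left pixel;
* lengths are micrometres everywhere except raw ROI files, which come
  from an image viewer and are therefore in pixels;
* intensities are arbitrary units (a.u.) and non-negative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CalibratedImage", "LineROI", "IntensityProfile"]


@dataclass(frozen=True)
class CalibratedImage:
    """A single-channel 2-D intensity grid with a physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of non-negative intensities (a.u.).
    pixel_size_um
        Edge length of one pixel in micrometres; must be positive. No
        operation in this package ever guesses a pixel size, so the
        calibration is mandatory.
    channel
        Free-text label of the stain/channel (e.g. ``"phalloidin"``,
        ``"hoechst"``).
    bit_depth
        Bit depth of the source raster (8 or 16). Pixels are held as
        float64 internally regardless.
    """

    pixels: np.ndarray
    pixel_size_um: float
    channel: str = ""
    bit_depth: int = 16

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must be a non-empty 2-D array")
        if not np.isfinite(px).all():
            raise ValueError("pixels must be finite")
        if (px < 0).any():
            raise ValueError("pixel intensities must be >= 0")
        if not (self.pixel_size_um > 0):
            raise ValueError(f"pixel_size_um must be > 0, got {self.pixel_size_um}")
        if self.bit_depth not in (8, 16):
            raise ValueError(f"bit_depth must be 8 or 16, got {self.bit_depth}")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape  # type: ignore[return-value]

    @property
    def extent_um(self) -> tuple[float, float]:
        """(height, width) of the field in micrometres."""
        r, c = self.pixels.shape
        return r * self.pixel_size_um, c * self.pixel_size_um


@dataclass(frozen=True)
class LineROI:
    """A straight measurement line in pixel coordinates.

    The line is drawn perpendicular from the wound edge into the field
    of cells; ``wound_end`` records which endpoint abuts the wound so
    that extracted profiles can be oriented with position 0 at the
    wound side.
    """

    start_px: tuple[float, float]
    end_px: tuple[float, float]
    wound_end: str = "start"  # "start" | "end"

    def __post_init__(self) -> None:
        if self.wound_end not in ("start", "end"):
            raise ValueError("wound_end must be 'start' or 'end'")
        if tuple(self.start_px) == tuple(self.end_px):
            raise ValueError("line endpoints must be distinct")

    def length_px(self) -> float:
        (r0, c0), (r1, c1) = self.start_px, self.end_px
        return float(np.hypot(r1 - r0, c1 - c0))

    def oriented(self) -> "LineROI":
        """Return an equivalent ROI whose start is the wound end."""
        if self.wound_end == "start":
            return self
        return LineROI(self.end_px, self.start_px, "start")


@dataclass(frozen=True)
class IntensityProfile:
    """1-D intensity sampled along a line, positions in micrometres.

    For wound-perpendicular lines position 0 is at the wound-edge end
    and increases into the field of cells.
    """

    positions_um: np.ndarray
    intensities: np.ndarray
    pixel_size_um: float | None = None

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions_um, dtype=float)
        val = np.asarray(self.intensities, dtype=float)
        if pos.ndim != 1 or val.ndim != 1 or pos.shape != val.shape:
            raise ValueError("positions and intensities must be 1-D and equal length")
        if pos.size >= 2 and not (np.diff(pos) > 0).all():
            raise ValueError("positions_um must be strictly increasing")
        if not np.isfinite(val).all():
            raise ValueError("intensities must be finite")
        object.__setattr__(self, "positions_um", pos)
        object.__setattr__(self, "intensities", val)

    def __len__(self) -> int:
        return self.positions_um.size

    @property
    def step_um(self) -> float:
        """Median sample spacing in micrometres."""
        if len(self) < 2:
            raise ValueError("profile too short to have a step")
        return float(np.median(np.diff(self.positions_um)))
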