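"""Independent brute-force oracles used by the test suite.

These re-derive peak detection and morphological baseline correction by
direct scans from the textbook definitions — every interior local
maximum enumerated, prominence as the height above the highest saddle
toward a larger neighbour, width at half prominence by linear
interpolation, and the opening as explicit min-then-max over clipped
windows. They share no code path with the package implementation.
"""

from __future__ import annotations

import numpy as np


def local_maxima(y: np.ndarray) -> list[int]:
    """Interior local maxima; a plateau resolves to its center sample."""
    out = []
    i = 1
    n = len(y)
    while i < n - 1:
        if y[i - 1] < y[i]:
            j = i
            while j + 1 < n and y[j + 1] == y[i]:
                j += 1
            if j + 1 < n and y[j + 1] < y[i]:
                out.append((i + j) // 2)
            i = j + 1
        else:
            i += 1
    return out


def prominence_of(y: np.ndarray, peak: int) -> float:
    """Height above the highest of the two bases.

    Each base is the minimum of the signal between the peak and the
    nearest strictly higher sample on that side (or the signal end).
    """
    h = y[peak]
    left_min = h
    i = peak - 1
    while i >= 0 and y[i] <= h:
        left_min = min(left_min, y[i])
        i -= 1
    right_min = h
    i = peak + 1
    while i < len(y) and y[i] <= h:
        right_min = min(right_min, y[i])
        i += 1
    return float(h - max(left_min, right_min))


def _base_index(y: np.ndarray, peak: int, direction: int) -> int:
    """Index of the base minimum toward ``direction`` (-1 left, +1 right)."""
    h = y[peak]
    best = peak
    i = peak + direction
    while 0 <= i < len(y) and y[i] <= h:
        if y[i] < y[best]:
            best = i
        i += direction
    return best


def width_at_half_prominence(y: np.ndarray, peak: int, prom: float) -> float:
    """Width (in samples) where the peak crosses height - prominence/2."""
    h_eval = y[peak] - prom / 2.0
    lb = _base_index(y, peak, -1)
    i = peak
    while i > lb and y[i] > h_eval:
        i -= 1
    if y[i] > h_eval:
        left = float(i)
    else:
        left = i + (h_eval - y[i]) / (y[i + 1] - y[i])
    rb = _base_index(y, peak, +1)
    i = peak
    while i < rb and y[i] > h_eval:
        i += 1
    if y[i] > h_eval:
        right = float(i)
    else:
        right = i - (h_eval - y[i]) / (y[i - 1] - y[i])
    return right - left


def brute_force_peaks(
    y: np.ndarray,
    step_um: float,
    min_width_um: float,
    max_width_um: float,
    min_prominence: float,
) -> list[tuple[int, float, float]]:
    """All retained (index, prominence, width_um), by exhaustive scan."""
    y = np.asarray(y, dtype=float)
    out = []
    for p in local_maxima(y):
        prom = prominence_of(y, p)
        if prom < min_prominence:
            continue
        w = width_at_half_prominence(y, p, prom) * step_um
        if min_width_um <= w <= max_width_um:
            out.append((p, prom, w))
    return out


def brute_force_opening(y: np.ndarray, size: int) -> np.ndarray:
    """Flat grey opening by direct min-then-max over clipped windows."""
    y = np.asarray(y, dtype=float)
    n = len(y)
    half = size // 2
    eroded = np.array([y[max(0, i - half):min(n, i + half + 1)].min()
                       for i in range(n)])
    return np.array([eroded[max(0, i - half):min(n, i + half + 1)].max()
                     for i in range(n)])
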