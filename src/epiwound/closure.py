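"""Wound-closure kinetics: percent-of-original-area curves and group summaries.

Areas arrive as per-frame measurements (one row per measured frame of a
time-lapse shot at 11-s intervals, with the area typically measured
every 10th frame). The primary output is the percent-of-original curve
``100 * A(t) / A(0)``; an initial closure rate (least-squares slope of
percent vs time over the first minutes) is provided as a scalar
summary, and groups of wounds are compared per timepoint with the
classical tests from :mod:`epiwound.stats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .stats import GroupSample, one_way_anova, summarize, unpaired_t_test, holm_adjust

__all__ = [
    "WoundAreaSeries",
    "ClosureConfig",
    "percent_of_original",
    "initial_closure_rate",
    "group_closure_summary",
    "series_from_table",
    "plot_group_summary",
]


@dataclass(frozen=True)
class WoundAreaSeries:
    """Timed wound areas, optionally with the percent-of-original column."""

    frames: np.ndarray
    times_s: np.ndarray
    areas_mm2: np.ndarray
    percent_of_original: np.ndarray | None = None

    def __post_init__(self) -> None:
        f = np.asarray(self.frames)
        t = np.asarray(self.times_s, dtype=float)
        a = np.asarray(self.areas_mm2, dtype=float)
        if not (f.shape == t.shape == a.shape) or t.ndim != 1:
            raise ValueError("frames, times_s, areas_mm2 must be equal-length 1-D")
        if t.size >= 2 and not (np.diff(t) > 0).all():
            raise ValueError("times_s must be strictly increasing")
        if (a < 0).any():
            raise ValueError("areas must be >= 0")
        if self.percent_of_original is not None:
            p = np.asarray(self.percent_of_original, dtype=float)
            if p.shape != t.shape:
                raise ValueError("percent column length mismatch")
            if abs(p[0] - 100.0) > 1e-9:
                raise ValueError("percent_of_original must start at 100")
            object.__setattr__(self, "percent_of_original", p)
        object.__setattr__(self, "frames", f)
        object.__setattr__(self, "times_s", t)
        object.__setattr__(self, "areas_mm2", a)

    def __len__(self) -> int:
        return self.times_s.size


@dataclass(frozen=True)
class ClosureConfig:
    frame_interval_s: float = 11.0
    measure_every_k_frames: int = 10
    rate_window_min: float = 10.0

    def __post_init__(self) -> None:
        if not (self.frame_interval_s > 0 and self.measure_every_k_frames > 0
                and self.rate_window_min > 0):
            raise ValueError("all ClosureConfig fields must be > 0")


def percent_of_original(
    series: WoundAreaSeries, config: ClosureConfig = ClosureConfig()
) -> WoundAreaSeries:
    """Resample to every k-th frame and normalize to the first measured area.

    The first measured frame defines 100%; values above 100 (transient
    wound expansion) are kept uncapped.
    """
    f = np.asarray(series.frames)
    keep = (f - f[0]) % config.measure_every_k_frames == 0
    if keep.sum() < 2:
        raise ValueError("need >= 2 measured frames after resampling")
    frames = f[keep]
    times = series.times_s[keep]
    areas = series.areas_mm2[keep]
    if areas[0] <= 0:
        raise ValueError("first measured area is 0; percent undefined")
    pct = 100.0 * areas / areas[0]
    return WoundAreaSeries(frames, times, areas, pct)


def initial_closure_rate(
    series: WoundAreaSeries, config: ClosureConfig = ClosureConfig()
) -> float:
    """Least-squares slope of percent vs time over the first minutes.

    Returns %/min; negative for a closing wound. The series is
    percent-normalized first if it does not carry the percent column.
    """
    if series.percent_of_original is None:
        series = percent_of_original(series, config)
    t_min = (series.times_s - series.times_s[0]) / 60.0
    sel = t_min <= config.rate_window_min + 1e-12
    if sel.sum() < 3:
        raise ValueError(
            f"only {int(sel.sum())} points within the first "
            f"{config.rate_window_min} min; need >= 3"
        )
    slope = np.polyfit(t_min[sel], series.percent_of_original[sel], 1)[0]
    return float(slope)


def _align_to_grid(
    series: WoundAreaSeries, grid_s: np.ndarray, half_tol_s: float
) -> np.ndarray:
    """Percent values matched to grid times (NaN where no sample is close)."""
    out = np.full(grid_s.size, np.nan)
    t = series.times_s - series.times_s[0]
    for i, g in enumerate(grid_s):
        j = int(np.argmin(np.abs(t - g)))
        if abs(t[j] - g) <= half_tol_s:
            out[i] = series.percent_of_original[j]
    return out


def group_closure_summary(
    labeled_series: Sequence[tuple[str, WoundAreaSeries]],
    config: ClosureConfig = ClosureConfig(),
    adjust: str = "none",
) -> pd.DataFrame:
    """Per-timepoint mean ± SEM per group plus a per-timepoint test.

    Each (treatment label, series) pair is one wound in an independent
    animal — the experimental unit. Series are percent-normalized and
    aligned to a common timepoint grid by nearest-time matching within
    half a sampling interval. Two groups get an unpaired two-tailed t
    test at each timepoint, three or more a one-way ANOVA. P-values are
    reported unadjusted by default (``adjust="holm"`` applies a Holm
    correction across timepoints).
    """
    if adjust not in ("none", "holm"):
        raise ValueError("adjust must be 'none' or 'holm'")
    if not labeled_series:
        raise ValueError("no series given")
    norm = [(lab, percent_of_original(s, config)
             if s.percent_of_original is None else s)
            for lab, s in labeled_series]
    longest = max((s for _, s in norm), key=len)
    grid = longest.times_s - longest.times_s[0]
    step = config.frame_interval_s * config.measure_every_k_frames
    aligned: dict[str, list[np.ndarray]] = {}
    for lab, s in norm:
        aligned.setdefault(lab, []).append(_align_to_grid(s, grid, step / 2.0))

    rows = []
    tests: list[tuple[int, float]] = []
    for i, t in enumerate(grid):
        groups = []
        for lab, cols in aligned.items():
            vals = np.array([c[i] for c in cols])
            vals = vals[np.isfinite(vals)]
            if vals.size:
                groups.append(GroupSample(lab, vals))
        stat = p = math.nan
        method = ""
        testable = [g for g in groups if g.n >= 2]
        if len(groups) == 2 and len(testable) == 2:
            res = unpaired_t_test(groups[0], groups[1])
            stat, p, method = res.statistic, res.p, res.method
        elif len(groups) > 2 and len(testable) == len(groups):
            res = one_way_anova(groups)
            stat, p, method = res.statistic, res.p, res.method
        if np.isfinite(p):
            tests.append((len(rows), p))
        for g in groups:
            mean, sem, n = summarize(g)
            rows.append({
                "time_s": float(t), "time_min": float(t) / 60.0,
                "group": g.label, "mean": mean, "sem": sem, "n": n,
                "statistic": stat, "p": p, "method": method,
            })
    df = pd.DataFrame(rows)
    if adjust == "holm" and tests:
        # one p per timepoint; write the adjusted value back to every
        # group row of that timepoint
        uniq = df[["time_s", "p"]].drop_duplicates("time_s").dropna()
        adj = holm_adjust(uniq["p"].to_numpy())
        mapping = dict(zip(uniq["time_s"], adj))
        df["p_adj"] = df["time_s"].map(mapping)
    return df


def series_from_table(df: pd.DataFrame, config: ClosureConfig = ClosureConfig()):
    """Yield (wound_id, animal, treatment, WoundAreaSeries) from a tidy table.

    Expects columns frame, area_mm2 and optionally wound_id, animal,
    treatment, time_s; missing times are reconstructed from the frame
    interval.
    """
    id_cols = [c for c in ("wound_id", "animal", "treatment") if c in df.columns]
    grouped = df.groupby(id_cols, sort=True) if id_cols else [((), df)]
    for key, sub in grouped:
        key = key if isinstance(key, tuple) else (key,)
        ids = dict(zip(id_cols, key))
        sub = sub.sort_values("frame")
        frames = sub["frame"].to_numpy()
        if "time_s" in sub.columns:
            times = sub["time_s"].to_numpy(float)
        else:
            times = frames * config.frame_interval_s
        yield (
            ids.get("wound_id"), ids.get("animal"), ids.get("treatment"),
            WoundAreaSeries(frames, times, sub["area_mm2"].to_numpy(float)),
        )


def plot_group_summary(summary: pd.DataFrame, path=None):
    """Mean ± SEM percent-of-original curve per group (matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 3.5))
    for lab, sub in summary.groupby("group"):
        ax.errorbar(sub["time_min"], sub["mean"], yerr=sub["sem"],
                    label=str(lab), capsize=2)
    ax.set_xlabel("time (min)")
    ax.set_ylabel("percent of original wound area")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
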