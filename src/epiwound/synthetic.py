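"""Seeded generators of images, profiles and time series with ground truth.

The generators emulate the measured structures of the study system — a
squamous epithelial monolayer of ~50 µm cells on a transparent gel, with
cortical (edge-localized) actin whose amplitude decays with cell rank
from a small wound (0.02–0.125 mm²); diffraction-limited dye particles
over stained nuclei; bimodal nuclear intensities of a nascent-RNA
label; and monotone decay of wound area sampled at 11-s frame
intervals. Every generator returns the exact quantities the downstream
estimators try to recover, so each analysis stage has a recovery test.

All randomness in one call flows from a single integer seed; identical
(params, seed) give bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import Delaunay, cKDTree

from .closure import WoundAreaSeries
from .types import CalibratedImage, LineROI, IntensityProfile

__all__ = [
    "SheetParams",
    "SpotFieldParams",
    "ClosureModelParams",
    "SyntheticGroundTruth",
    "UptakeField",
    "make_epithelial_sheet_image",
    "make_profile",
    "make_uptake_images",
    "make_closure_series",
    "radial_line_rois",
]


@dataclass(frozen=True)
class SheetParams:
    """Geometry and signal parameters of a synthetic epithelial sheet.

    ``edge_amplitudes`` lists the cortical peak amplitude (a.u.) by cell
    rank from the wound: ``[wound-margin, cell 1, cell 2, cell 3,
    background ranks]``. Edges are rendered as bands of
    ``edge_thickness_um`` so that, after blurring with the PSF, their
    width at half prominence falls inside the 20–40 µm detection band
    used downstream.
    """

    cell_diameter_um: float = 50.0
    edge_amplitudes: tuple[float, ...] = (200.0, 100.0, 80.0, 60.0, 10.0)
    edge_thickness_um: float = 28.0
    wound_area_mm2: float = 0.05
    psf_sigma_um: float = 2.0
    noise_sd: float = 5.0
    pixel_size_um: float = 0.5
    jitter_frac: float = 0.05
    field_size_um: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.cell_diameter_um > 0:
            raise ValueError("cell_diameter_um must be > 0")
        if not self.wound_area_mm2 > 0:
            raise ValueError("wound_area_mm2 must be > 0")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        if any(a < 0 for a in self.edge_amplitudes):
            raise ValueError("edge amplitudes must be >= 0")
        if len(self.edge_amplitudes) < 4:
            raise ValueError("need amplitudes for margin plus >= 3 submarginal ranks")


@dataclass(frozen=True)
class SpotFieldParams:
    """Parameters of a synthetic dye-particle / nucleus field."""

    n_particles: int = 40
    particle_sigma_um: float = 1.0
    particle_amplitude: float = 150.0
    n_nuclei: int = 30
    nucleus_radius_um: float = 5.0
    nucleus_amplitude: float = 120.0
    min_separation_um: float = 12.0
    noise_sd: float = 3.0
    pixel_size_um: float = 0.5
    field_size_um: float = 256.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 0 or self.n_nuclei < 0:
            raise ValueError("counts must be >= 0")
        if self.min_separation_um < 0:
            raise ValueError("min_separation_um must be >= 0")


@dataclass(frozen=True)
class ClosureModelParams:
    """Known monotone wound-closure model sampled at the camera frame rate.

    The default model is exponential area decay
    ``A(t) = A0 * exp(-k t)``; setting ``speed_um_per_min`` switches to
    a linear-front model where the wound radius shrinks at constant
    speed. Multiplicative lognormal noise with coefficient of variation
    ``noise_cv`` emulates segmentation jitter.
    """

    initial_area_mm2: float = 0.05
    rate_constant_per_min: float = 0.1
    speed_um_per_min: float | None = None
    frame_interval_s: float = 11.0
    n_frames: int = 220
    noise_cv: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.initial_area_mm2 > 0:
            raise ValueError("initial_area_mm2 must be > 0")
        if not self.frame_interval_s > 0:
            raise ValueError("frame_interval_s must be > 0")
        if self.n_frames < 2:
            raise ValueError("need n_frames >= 2")


@dataclass
class SyntheticGroundTruth:
    """Everything a downstream estimator might try to recover."""

    seed: int
    params: dict = field(default_factory=dict)
    # sheet / profile truth
    true_edge_amplitudes: list[float] | None = None
    peak_centers_um: np.ndarray | None = None
    peak_amplitudes: np.ndarray | None = None
    wound_center_um: tuple[float, float] | None = None
    wound_radius_um: float | None = None
    cell_centers_um: np.ndarray | None = None
    cell_ranks: np.ndarray | None = None
    # spot-field truth
    particle_coords_um: np.ndarray | None = None
    nucleus_coords_um: np.ndarray | None = None
    eu_positive_flags: np.ndarray | None = None
    nucleus_eu_levels: np.ndarray | None = None
    # closure truth
    true_area_series_mm2: np.ndarray | None = None
    times_s: np.ndarray | None = None


@dataclass(frozen=True)
class UptakeField:
    """The rendered channels of one synthetic uptake/transcription field."""

    particles: CalibratedImage
    nuclei: CalibratedImage
    eu: CalibratedImage | None = None


# --------------------------------------------------------------------------
# epithelial sheet
# --------------------------------------------------------------------------

def _hex_lattice(half_um: float, diameter: float, rng: np.random.Generator,
                 jitter_frac: float) -> np.ndarray:
    """Jittered hexagonal lattice of cell centers covering the field."""
    dy = diameter * math.sqrt(3.0) / 2.0
    rows = np.arange(-half_um - diameter, half_um + diameter + dy, dy)
    pts = []
    for i, y in enumerate(rows):
        off = 0.0 if i % 2 == 0 else diameter / 2.0
        xs = np.arange(-half_um - diameter + off, half_um + diameter, diameter)
        pts.extend((y, x) for x in xs)
    centers = np.asarray(pts, dtype=float)
    centers += rng.normal(0.0, jitter_frac * diameter, size=centers.shape)
    return centers


def _cell_ranks(centers: np.ndarray, margin_idx: np.ndarray) -> np.ndarray:
    """Breadth-first cell rank from the wound margin (margin = 0)."""
    n = len(centers)
    ranks = np.full(n, np.iinfo(np.int32).max, dtype=np.int64)
    ranks[margin_idx] = 0
    if n >= 4:
        tri = Delaunay(centers)
        indptr, indices = tri.vertex_neighbor_vertices
        frontier = list(margin_idx)
        r = 0
        while frontier:
            nxt = []
            for i in frontier:
                for j in indices[indptr[i]:indptr[i + 1]]:
                    if ranks[j] > r + 1:
                        ranks[j] = r + 1
                        nxt.append(j)
            frontier = nxt
            r += 1
    return ranks


def make_epithelial_sheet_image(
    params: SheetParams,
) -> tuple[CalibratedImage, SyntheticGroundTruth]:
    """Render a wounded epithelial sheet with rank-dependent cortical edges.

    The sheet is a jittered hexagonal tessellation of
    ``cell_diameter_um`` cells. The wound is a zero-signal disk at the
    field center; its boundary carries the wound-margin amplitude, and
    each cell-cell edge carries the amplitude of the deeper of its two
    cells' ranks (edges between equal-rank cells get the background
    amplitude, since the labelled actin accumulates on wound-facing
    edges). The raster is blurred with a Gaussian PSF and Gaussian
    noise is added.
    """
    rng = np.random.default_rng(params.seed)
    amps = np.asarray(params.edge_amplitudes, dtype=float)
    R = math.sqrt(params.wound_area_mm2 * 1e6 / math.pi)  # wound radius, µm
    d = params.cell_diameter_um
    needed_half = R + (len(amps) + 1) * d
    if params.field_size_um is None:
        half = needed_half
    else:
        half = params.field_size_um / 2.0
        field_area_mm2 = (2 * half) ** 2 / 1e6
        if half <= R + 4 * d:
            raise ValueError(
                f"wound of {params.wound_area_mm2} mm² does not fit a "
                f"{field_area_mm2:.4g} mm² field with >= 4 cell ranks around it"
            )
    px = params.pixel_size_um
    n = int(round(2 * half / px))
    coords = (np.arange(n) + 0.5) * px - half  # pixel-center coordinates, µm

    centers = _hex_lattice(half, d, rng, params.jitter_frac)
    keep = np.hypot(centers[:, 0], centers[:, 1]) > R
    centers = centers[keep]

    yy, xx = np.meshgrid(coords, coords, indexing="ij")
    pts = np.column_stack([yy.ravel(), xx.ravel()])
    d_wound = np.hypot(pts[:, 0], pts[:, 1])

    tree = cKDTree(centers)
    dist, idx = tree.query(pts, k=2)
    d1, d2 = dist[:, 0], dist[:, 1]
    i1, i2 = idx[:, 0], idx[:, 1]

    T = params.edge_thickness_um
    # margin cells: those owning pixels in a thin annulus just outside the wound
    annulus = (d_wound > R) & (d_wound < R + T)
    margin_idx = np.unique(i1[annulus])
    ranks = _cell_ranks(centers, margin_idx)

    img = np.zeros(n * n, dtype=float)
    edge = (d2 - d1) < T
    r1, r2 = ranks[i1[edge]], ranks[i2[edge]]
    amp_idx = np.where(
        r1 == r2,
        len(amps) - 1,                                 # lateral edge -> background
        np.minimum(np.maximum(r1, r2), len(amps) - 1)  # proximal edge of deeper cell
    )
    img[edge] = amps[amp_idx]
    img[np.abs(d_wound - R) < T / 2.0] = amps[0]  # wound-margin band
    img[d_wound < R - T / 2.0] = 0.0              # wound interior: no signal
    img = img.reshape(n, n)

    img = gaussian_filter(img, sigma=params.psf_sigma_um / px)
    if params.noise_sd > 0:
        img = img + rng.normal(0.0, params.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, None)

    truth = SyntheticGroundTruth(
        seed=params.seed,
        params=asdict(params),
        true_edge_amplitudes=list(amps),
        wound_center_um=(half, half),  # (row, col) from the top-left corner
        wound_radius_um=R,
        cell_centers_um=centers + half,
        cell_ranks=ranks,
    )
    image = CalibratedImage(img, px, channel="phalloidin")
    return image, truth


def radial_line_rois(
    image: CalibratedImage,
    truth: SyntheticGroundTruth,
    n_lines: int,
    seed: int = 0,
    inset_um: float = 20.0,
    reach_um: float | None = None,
) -> list[LineROI]:
    """Wound-perpendicular line ROIs for a generated sheet image.

    Lines start ``inset_um`` inside the wound (so the margin peak is an
    interior maximum of the profile) and extend ``reach_um`` beyond the
    wound boundary, at evenly spaced angles with a seeded offset.
    """
    if truth.wound_radius_um is None:
        raise ValueError("truth does not describe a sheet image")
    R = truth.wound_radius_um
    d = truth.params.get("cell_diameter_um", 50.0)
    if reach_um is None:
        reach_um = 4.0 * d
    half_r = image.shape[0] * image.pixel_size_um / 2.0
    half_c = image.shape[1] * image.pixel_size_um / 2.0
    if R + reach_um >= min(half_r, half_c):
        raise ValueError("requested reach extends beyond the image")
    rng = np.random.default_rng(seed)
    theta0 = rng.uniform(0.0, 2.0 * math.pi)
    cr, cc = truth.wound_center_um
    rois = []
    for k in range(n_lines):
        th = theta0 + 2.0 * math.pi * k / n_lines
        u = (math.sin(th), math.cos(th))  # (row, col) direction
        r0 = max(R - inset_um, 1.0)
        start = ((cr + r0 * u[0]) / image.pixel_size_um,
                 (cc + r0 * u[1]) / image.pixel_size_um)
        end = ((cr + (R + reach_um) * u[0]) / image.pixel_size_um,
               (cc + (R + reach_um) * u[1]) / image.pixel_size_um)
        rois.append(LineROI(start, end, wound_end="start"))
    return rois


# --------------------------------------------------------------------------
# 1-D profiles
# --------------------------------------------------------------------------

def make_profile(
    n_peaks: int,
    spacing_um: float = 50.0,
    amplitudes: Sequence[float] | None = None,
    peak_fwhm_um: float = 30.0,
    baseline: float | tuple[float, float] = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    pixel_size_um: float = 0.5,
    first_center_um: float = 30.0,
    shape: str = "compact",
    length_um: float | None = None,
) -> tuple[IntensityProfile, SyntheticGroundTruth]:
    """1-D surrogate of a wound-perpendicular intensity profile.

    Peaks sit at ``first_center_um + k * spacing_um`` (default spacing
    50 µm, one cell diameter). ``baseline`` is either a constant or an
    ``(intercept, slope_per_um)`` linear drift. The default peak shape
    is a generalized Gaussian of exponent 4 ("compact"): its width at
    half maximum equals ``peak_fwhm_um`` but its flanks fall much
    faster than a Gaussian's, matching the steep-sided cortical bands
    the profile emulates and keeping 50 µm-spaced peaks resolved;
    ``shape="gaussian"`` is available.
    """
    if n_peaks < 0:
        raise ValueError("n_peaks must be >= 0")
    if n_peaks > 0:
        if amplitudes is None:
            raise ValueError("amplitudes required when n_peaks > 0")
        amplitudes = list(amplitudes)
        if len(amplitudes) != n_peaks:
            raise ValueError("len(amplitudes) must equal n_peaks")
        if any(a < 0 for a in amplitudes):
            raise ValueError("peak amplitudes must be >= 0")
        if spacing_um <= peak_fwhm_um:
            raise ValueError("spacing_um must exceed peak_fwhm_um")
    else:
        amplitudes = []
    if shape not in ("compact", "gaussian"):
        raise ValueError("shape must be 'compact' or 'gaussian'")

    if length_um is None:
        length_um = first_center_um + max(n_peaks - 1, 0) * spacing_um + 45.0
    x = np.arange(0.0, length_um + pixel_size_um / 2.0, pixel_size_um)
    centers = first_center_um + spacing_um * np.arange(n_peaks)

    y = np.zeros_like(x)
    for c, a in zip(centers, amplitudes):
        if shape == "compact":
            hw = peak_fwhm_um / 2.0
            y += a * np.exp(-math.log(2.0) * ((x - c) / hw) ** 4)
        else:
            sig = peak_fwhm_um / (2.0 * math.sqrt(2.0 * math.log(2.0)))
            y += a * np.exp(-0.5 * ((x - c) / sig) ** 2)

    if isinstance(baseline, tuple):
        b0, slope = baseline
        y = y + b0 + slope * x
    else:
        y = y + float(baseline)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    y = np.clip(y, 0.0, None)

    truth = SyntheticGroundTruth(
        seed=seed,
        params={
            "n_peaks": n_peaks, "spacing_um": spacing_um,
            "peak_fwhm_um": peak_fwhm_um, "baseline": baseline,
            "noise_sd": noise_sd, "shape": shape,
        },
        peak_centers_um=centers,
        peak_amplitudes=np.asarray(amplitudes, dtype=float),
    )
    return IntensityProfile(x, y, pixel_size_um), truth


# --------------------------------------------------------------------------
# spot fields (dye uptake + nascent transcription)
# --------------------------------------------------------------------------

def _place_points(
    n: int, lo: float, hi: float, min_sep: float, rng: np.random.Generator,
    max_tries_per_point: int = 500,
) -> np.ndarray:
    """Rejection-sample n points in [lo, hi]^2 at pairwise min_sep."""
    if n == 0:
        return np.empty((0, 2), dtype=float)
    if hi <= lo:
        raise ValueError("field too small for the requested margins")
    pts: list[tuple[float, float]] = []
    tries = 0
    budget = max_tries_per_point * n
    while len(pts) < n:
        if tries >= budget:
            raise ValueError(
                f"could not place {n} points at separation {min_sep} µm "
                f"in a {hi - lo:.0f} µm box after {budget} tries"
            )
        cand = rng.uniform(lo, hi, size=2)
        tries += 1
        if all((cand[0] - p[0]) ** 2 + (cand[1] - p[1]) ** 2 >= min_sep ** 2
               for p in pts):
            pts.append((cand[0], cand[1]))
    return np.asarray(pts, dtype=float)


def make_uptake_images(
    params: SpotFieldParams,
    eu_positive_fraction: float | None = None,
    eu_pos_mean: float = 150.0,
    eu_neg_mean: float = 30.0,
    eu_level_sd: float = 8.0,
) -> tuple[UptakeField, SyntheticGroundTruth]:
    """Render a particle channel over a nuclear channel, with ground truth.

    Particles are isotropic Gaussian spots; nuclei are filled disks.
    When ``eu_positive_fraction`` is given, a third channel is emitted
    in which each nucleus is filled at a per-nucleus level drawn from
    one of two well-separated modes (positive vs negative for nascent
    transcription); ``round(fraction * n_nuclei)`` nuclei are positive.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    px = p.pixel_size_um
    n = int(round(p.field_size_um / px))
    margin = p.nucleus_radius_um + 3.0 * p.particle_sigma_um + 2.0

    nuc_xy = _place_points(p.n_nuclei, margin, p.field_size_um - margin,
                           p.min_separation_um, rng)
    par_xy = _place_points(p.n_particles, margin, p.field_size_um - margin,
                           p.min_separation_um, rng)

    coords = (np.arange(n) + 0.5) * px
    yy, xx = np.meshgrid(coords, coords, indexing="ij")

    par_img = np.zeros((n, n), dtype=float)
    sig2 = 2.0 * p.particle_sigma_um ** 2
    for cy, cx in par_xy:
        # render only a local window for speed
        w = 5.0 * p.particle_sigma_um
        r0, r1 = np.searchsorted(coords, [cy - w, cy + w])
        c0, c1 = np.searchsorted(coords, [cx - w, cx + w])
        sub_y = yy[r0:r1, c0:c1]
        sub_x = xx[r0:r1, c0:c1]
        par_img[r0:r1, c0:c1] += p.particle_amplitude * np.exp(
            -((sub_y - cy) ** 2 + (sub_x - cx) ** 2) / sig2
        )

    nuc_img = np.zeros((n, n), dtype=float)
    for cy, cx in nuc_xy:
        mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= p.nucleus_radius_um ** 2
        nuc_img[mask] = p.nucleus_amplitude

    eu_img = None
    flags = None
    levels = None
    if eu_positive_fraction is not None:
        if not 0.0 <= eu_positive_fraction <= 1.0:
            raise ValueError("eu_positive_fraction must be in [0, 1]")
        n_pos = int(round(eu_positive_fraction * p.n_nuclei))
        flags = np.zeros(p.n_nuclei, dtype=bool)
        flags[rng.permutation(p.n_nuclei)[:n_pos]] = True
        levels = np.where(flags, eu_pos_mean, eu_neg_mean) + rng.normal(
            0.0, eu_level_sd, size=p.n_nuclei
        )
        levels = np.clip(levels, 0.0, None)
        eu_arr = np.zeros((n, n), dtype=float)
        for (cy, cx), lvl in zip(nuc_xy, levels):
            mask = (yy - cy) ** 2 + (xx - cx) ** 2 <= p.nucleus_radius_um ** 2
            eu_arr[mask] = lvl
        if p.noise_sd > 0:
            eu_arr = eu_arr + rng.normal(0.0, p.noise_sd, size=eu_arr.shape)
        eu_img = CalibratedImage(np.clip(eu_arr, 0.0, None), px, channel="eu")

    if p.noise_sd > 0:
        par_img = par_img + rng.normal(0.0, p.noise_sd, size=par_img.shape)
        nuc_img = nuc_img + rng.normal(0.0, p.noise_sd, size=nuc_img.shape)
    par_img = np.clip(par_img, 0.0, None)
    nuc_img = np.clip(nuc_img, 0.0, None)

    field_imgs = UptakeField(
        particles=CalibratedImage(par_img, px, channel="yopro"),
        nuclei=CalibratedImage(nuc_img, px, channel="hoechst"),
        eu=eu_img,
    )
    truth = SyntheticGroundTruth(
        seed=p.seed,
        params=asdict(p),
        particle_coords_um=par_xy,
        nucleus_coords_um=nuc_xy,
        eu_positive_flags=flags,
        nucleus_eu_levels=levels,
    )
    return field_imgs, truth


# --------------------------------------------------------------------------
# closure time series
# --------------------------------------------------------------------------

def make_closure_series(
    params: ClosureModelParams,
) -> tuple[WoundAreaSeries, SyntheticGroundTruth]:
    """Sample a known monotone closure model at the camera frame rate."""
    p = params
    frames = np.arange(p.n_frames)
    t_s = frames * p.frame_interval_s
    t_min = t_s / 60.0
    if p.speed_um_per_min is not None:
        r0_mm = math.sqrt(p.initial_area_mm2 / math.pi)
        r = np.clip(r0_mm - (p.speed_um_per_min / 1000.0) * t_min, 0.0, None)
        areas = math.pi * r ** 2
    else:
        areas = p.initial_area_mm2 * np.exp(-p.rate_constant_per_min * t_min)
    true_areas = areas.copy()
    if p.noise_cv > 0:
        rng = np.random.default_rng(p.seed)
        sigma = math.sqrt(math.log(1.0 + p.noise_cv ** 2))
        factors = rng.lognormal(mean=-sigma ** 2 / 2.0, sigma=sigma,
                                size=areas.shape)
        areas = np.clip(areas * factors, 0.0, None)
    series = WoundAreaSeries(frames=frames, times_s=t_s, areas_mm2=areas)
    truth = SyntheticGroundTruth(
        seed=p.seed, params=asdict(p),
        true_area_series_mm2=true_areas, times_s=t_s,
    )
    return series, truth
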