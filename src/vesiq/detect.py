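"""Particle-detection chain for one channel.

Pipeline: low-pass filter → per-column rolling-ball background (grayscale
opening with a semicircular element) → 3×3 median smoothing of the background
→ subtraction (clipped at 0) → Gaussian filter → per-column fluctuation-based
threshold → connected spots → 5×5 enlargement → integrated intensities →
background-vs-size model from 100 random empty regions → normalized
intensities I_tot and I_peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PreprocessConfig",
    "ThresholdMap",
    "Spot",
    "BackgroundModel",
    "BackgroundSample",
    "preprocess",
    "threshold_map",
    "detect_spots",
    "enlarge_spot",
    "integrate_spot",
    "sample_background",
    "fit_background_model",
    "normalize_spot",
    "occupied_mask",
    "analyze_channel",
]


@dataclass(frozen=True)
class PreprocessConfig:
    """Filtering, background and thresholding parameters for one channel."""

    lowpass_sigma: float = 1.0
    ball_radius: float = 25.0
    sample_spacing: float = 1.0
    bg_median_window: int = 3
    post_gauss_sigma: float = 1.0
    sfr: float = 2.0
    min_core_px: int = 2
    connectivity: int = 8
    bg_samples: int = 100
    bg_size_range: tuple[int, int] = (10, 100)

    def __post_init__(self) -> None:
        if self.ball_radius <= 0:
            raise ValueError("ball_radius must be > 0")
        if self.sfr <= 0:
            raise ValueError("sfr must be > 0")
        if self.sample_spacing <= 0:
            raise ValueError("sample_spacing must be > 0")
        if self.bg_median_window % 2 != 1:
            raise ValueError("bg_median_window must be odd")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.min_core_px < 1:
            raise ValueError("min_core_px must be >= 1")
        lo, hi = self.bg_size_range
        if not (1 <= lo <= hi):
            raise ValueError(f"invalid bg_size_range {self.bg_size_range}")


@dataclass
class ThresholdMap:
    """Per-pixel detection thresholds: SFR × 2·(median − min) per column."""

    values: np.ndarray
    sfr: float
    fluctuation: np.ndarray

    def __post_init__(self) -> None:
        if self.values.shape != self.fluctuation.shape:
            raise ValueError("threshold and fluctuation shapes differ")
        if np.any(self.values < 0):
            raise ValueError("threshold values must be non-negative")


@dataclass
class Spot:
    """A detected vesicle: core pixel set, 5×5-enlarged set and intensities.

    Pixel sets are ``(n, 2)`` integer arrays of ``(row, col)`` coordinates.
    ``sigma`` is the enlarged pixel count; intensities are NaN until computed.
    """

    id: int
    core: np.ndarray
    image_shape: tuple[int, int]
    channel: str = ""
    enlarged: Optional[np.ndarray] = None
    centroid: tuple[float, float] = (math.nan, math.nan)
    sigma: int = 0
    i_int: float = math.nan
    i_max: float = math.nan
    i_tot: float = math.nan
    i_peak: float = math.nan
    border_flag: bool = False
    colocalized: bool = False
    partner_id: Optional[int] = None

    @property
    def core_size(self) -> int:
        return len(self.core)


@dataclass(frozen=True)
class BackgroundSample:
    """One vesicle-free pseudo-spot: pixel count, integrated value, pixels."""

    sigma: int
    intensity: float
    pixels: np.ndarray


@dataclass
class BackgroundModel:
    """Linear fit I_BG(σ) = a0 + a1·σ to empty-region integrated intensities."""

    a0: float
    a1: float
    samples: list[BackgroundSample] = field(default_factory=list)
    channel: str = ""

    def predict(self, sigma) -> np.ndarray:
        return self.a0 + self.a1 * np.asarray(sigma, dtype=float)


def rolling_ball_baseline(grid: np.ndarray, radius: float, spacing: float = 1.0) -> np.ndarray:
    """Per-column rolling-ball baseline of a 2-D grid.

    Equivalent to a 1-D grayscale opening of each column with the
    semicircular element b(k) = sqrt(r² − (k·dx)²), |k·dx| ≤ r: the highest
    position of a ball of radius ``radius`` rolled along the underside of the
    column profile. At the image edges the ball rests on the available pixels
    only.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    if radius <= 0:
        raise ValueError("radius must be > 0")
    n = grid.shape[0]
    if radius >= n:
        raise ValueError(f"ball radius {radius} must be smaller than column length {n}")
    half = int(math.floor(radius / spacing))
    offsets = np.arange(-half, half + 1)
    ball = np.sqrt(radius**2 - (offsets * spacing) ** 2)

    # erosion: e[p] = min_k (grid[p+k] - ball[k]) over in-bounds k
    ero = np.full_like(grid, np.inf)
    for k, b in zip(offsets, ball):
        if k >= 0:
            ero[: n - k] = np.minimum(ero[: n - k], grid[k:] - b)
        else:
            ero[-k:] = np.minimum(ero[-k:], grid[: n + k] - b)
    # dilation: bg[i] = max_p (e[p] + ball[i-p]) over in-bounds p
    bg = np.full_like(grid, -np.inf)
    for k, b in zip(offsets, ball):
        if k >= 0:
            bg[k:] = np.maximum(bg[k:], ero[: n - k] + b)
        else:
            bg[: n + k] = np.maximum(bg[: n + k], ero[-k:] + b)
    return bg


def preprocess(grid: np.ndarray, cfg: PreprocessConfig) -> tuple[np.ndarray, np.ndarray]:
    """Filter a raw grid and estimate/subtract its illumination background.

    Returns ``(corrected, background)``: the background is the median-smoothed
    per-column rolling-ball baseline of the low-passed grid; the corrected
    grid is the low-passed grid minus background, clipped at 0, then Gaussian
    filtered.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 2:
        raise ValueError("grid must be 2-D")
    if not np.all(np.isfinite(grid)):
        raise ValueError("grid contains non-finite values")
    if min(grid.shape) < cfg.bg_median_window:
        raise ValueError(f"image {grid.shape} smaller than filter window {cfg.bg_median_window}")
    lowpassed = ndimage.gaussian_filter(grid, cfg.lowpass_sigma)
    baseline = rolling_ball_baseline(lowpassed, cfg.ball_radius, cfg.sample_spacing)
    background = ndimage.median_filter(baseline, size=cfg.bg_median_window)
    corrected = np.clip(lowpassed - background, 0.0, None)
    corrected = ndimage.gaussian_filter(corrected, cfg.post_gauss_sigma)
    return corrected, background


def threshold_map(corrected: np.ndarray, sfr: float) -> ThresholdMap:
    """Pixel-specific thresholds: SFR × 2·(column median − column min)."""
    corrected = np.asarray(corrected, dtype=float)
    if corrected.ndim != 2:
        raise ValueError("corrected grid must be 2-D")
    if sfr <= 0:
        raise ValueError("sfr must be > 0")
    med = np.median(corrected, axis=0)
    mn = corrected.min(axis=0)
    fluct = 2.0 * (med - mn)
    fluct_map = np.broadcast_to(fluct, corrected.shape).copy()
    return ThresholdMap(values=sfr * fluct_map, sfr=sfr, fluctuation=fluct_map)


def detect_spots(
    corrected: np.ndarray,
    th: ThresholdMap,
    min_core_px: int = 2,
    connectivity: int = 8,
    channel: str = "",
) -> list[Spot]:
    """Connected components of ``corrected > threshold`` as core-mask spots.

    Components smaller than ``min_core_px`` are discarded; centroids are
    intensity-weighted means of the core pixels.
    """
    corrected = np.asarray(corrected, dtype=float)
    if corrected.shape != th.values.shape:
        raise ValueError("corrected grid and threshold map shapes differ")
    mask = corrected > th.values
    structure = np.ones((3, 3), dtype=bool) if connectivity == 8 else ndimage.generate_binary_structure(2, 1)
    labels, n_labels = ndimage.label(mask, structure=structure)
    spots: list[Spot] = []
    for idx, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        local = labels[sl] == idx
        rr, cc = np.nonzero(local)
        rows = rr + sl[0].start
        cols = cc + sl[1].start
        if len(rows) < min_core_px:
            continue
        weights = corrected[rows, cols]
        total = weights.sum()
        if total > 0:
            centroid = (float((rows * weights).sum() / total), float((cols * weights).sum() / total))
        else:
            centroid = (float(rows.mean()), float(cols.mean()))
        spots.append(
            Spot(
                id=len(spots),
                core=np.column_stack([rows, cols]),
                image_shape=corrected.shape,
                channel=channel,
                centroid=centroid,
            )
        )
    return spots


_ENLARGE_OFFSETS = np.array(
    [(dr, dc) for dr in range(-2, 3) for dc in range(-2, 3)], dtype=int
)


def enlarge_spot(spot: Spot) -> Spot:
    """Dilate the core mask by a 5×5 square (±2 px), clipped to the image.

    Sets ``enlarged``, ``sigma`` and ``border_flag`` (set when clipping
    removed pixels, which biases σ and hence I_tot).
    """
    if spot.core_size == 0:
        raise ValueError("cannot enlarge an empty spot")
    n_rows, n_cols = spot.image_shape
    grown = spot.core[:, None, :] + _ENLARGE_OFFSETS[None, :, :]
    grown = grown.reshape(-1, 2)
    inside = (
        (grown[:, 0] >= 0)
        & (grown[:, 0] < n_rows)
        & (grown[:, 1] >= 0)
        & (grown[:, 1] < n_cols)
    )
    clipped = not bool(inside.all())
    enlarged = np.unique(grown[inside], axis=0)
    spot.enlarged = enlarged
    spot.sigma = len(enlarged)
    spot.border_flag = clipped
    return spot


def integrate_spot(grid: np.ndarray, spot: Spot) -> Spot:
    """I_int = sum over the enlarged mask; I_max = max over the core mask.

    Intensities are taken from the background-subtracted grid.
    """
    if spot.enlarged is None:
        raise ValueError("spot must be enlarged before integration")
    grid = np.asarray(grid, dtype=float)
    spot.i_int = float(grid[spot.enlarged[:, 0], spot.enlarged[:, 1]].sum())
    spot.i_max = float(grid[spot.core[:, 0], spot.core[:, 1]].max())
    return spot


def occupied_mask(shape: tuple[int, int], spots: Sequence[Spot]) -> np.ndarray:
    """Boolean grid of all pixels covered by the spots' enlarged masks."""
    mask = np.zeros(shape, dtype=bool)
    for s in spots:
        px = s.enlarged if s.enlarged is not None else s.core
        mask[px[:, 0], px[:, 1]] = True
    return mask


def sample_background(
    corrected: np.ndarray,
    occupied: np.ndarray,
    n_samples: int = 100,
    size_range: tuple[int, int] = (10, 100),
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
    guard: int = 2,
    max_attempts_per_sample: int = 200,
) -> list[BackgroundSample]:
    """Integrate ``n_samples`` random vesicle-free pseudo-spots.

    Pixel counts are uniform on ``size_range``. Each pseudo-spot is grown by
    dilation from a random free seed pixel, entirely outside the occupied
    masks plus a ``guard``-px band, mimicking real spot shapes (only
    ``(σ, sum)`` enters the fit, so the shape choice is free).
    """
    corrected = np.asarray(corrected, dtype=float)
    if corrected.shape != occupied.shape:
        raise ValueError("grid and occupancy shapes differ")
    if rng is None:
        rng = np.random.default_rng(seed)
    lo, hi = size_range
    if guard > 0:
        footprint = np.ones((2 * guard + 1, 2 * guard + 1), dtype=bool)
        forbidden = ndimage.binary_dilation(occupied, structure=footprint)
    else:
        forbidden = occupied
    free = ~forbidden
    free_frac = free.mean()
    free_idx = np.flatnonzero(free.ravel())
    if len(free_idx) < hi:
        raise RuntimeError(
            f"insufficient vesicle-free area for background sampling "
            f"(free fraction {free_frac:.3f})"
        )
    n_cols = corrected.shape[1]
    samples: list[BackgroundSample] = []
    for _ in range(n_samples):
        target = int(rng.integers(lo, hi + 1))
        placed = None
        for _attempt in range(max_attempts_per_sample):
            seed_flat = int(rng.choice(free_idx))
            seed_rc = (seed_flat // n_cols, seed_flat % n_cols)
            region = _pseudo_spot(free, seed_rc, target)
            if region is not None:
                placed = region
                break
        if placed is None:
            raise RuntimeError(
                f"could not place a {target}-px background sample after "
                f"{max_attempts_per_sample} attempts (free fraction {free_frac:.3f})"
            )
        value = float(corrected[placed[:, 0], placed[:, 1]].sum())
        samples.append(BackgroundSample(sigma=len(placed), intensity=value, pixels=placed))
    return samples


def _pseudo_spot(free: np.ndarray, seed_rc: tuple[int, int], target: int):
    """Disk-like region of exactly ``target`` pixels dilated around a seed.

    The shape is fixed by the seed alone (pixels in increasing distance from
    it), so the region geometry is independent of the intensity field; the
    placement is rejected unless every pixel is free and in bounds.
    """
    r0, c0 = seed_rc
    radius = int(math.ceil(math.sqrt(target / math.pi))) + 1
    rr, cc = np.mgrid[r0 - radius : r0 + radius + 1, c0 - radius : c0 + radius + 1]
    rr, cc = rr.ravel(), cc.ravel()
    d2 = (rr - r0) ** 2 + (cc - c0) ** 2
    order = np.lexsort((cc, rr, d2))[:target]
    rr, cc = rr[order], cc[order]
    n_rows, n_cols = free.shape
    if rr.min() < 0 or cc.min() < 0 or rr.max() >= n_rows or cc.max() >= n_cols:
        return None
    if not free[rr, cc].all():
        return None
    return np.column_stack([rr, cc])


def fit_background_model(samples: Sequence[BackgroundSample], channel: str = "") -> BackgroundModel:
    """Ordinary least-squares line I_BG(σ) = a0 + a1·σ through the samples.

    The sample sums are non-negative, so a negative fitted intercept is a
    finite-sample artefact that would make the σ→1 extrapolation of Eq-style
    normalization ill-defined; in that case the line is refit through the
    origin (a0 = 0, a1 = Σσy/Σσ²), keeping predictions positive wherever the
    sums are not all zero.
    """
    if len(samples) < 10:
        raise ValueError(f"need >= 10 background samples, got {len(samples)}")
    sigma = np.array([s.sigma for s in samples], dtype=float)
    values = np.array([s.intensity for s in samples], dtype=float)
    if np.ptp(sigma) == 0:
        raise ValueError("degenerate background samples: all sizes equal")
    a1, a0 = np.polyfit(sigma, values, 1)
    if a0 < 0:
        a0 = 0.0
        a1 = float(np.dot(sigma, values) / np.dot(sigma, sigma))
    return BackgroundModel(a0=float(a0), a1=float(a1), samples=list(samples), channel=channel)


def normalize_spot(spot: Spot, model: BackgroundModel) -> Spot:
    """Background-normalized intensities.

    I_tot = (I_int − I_BG(σ)) / I_BG(σ) and
    I_peak = (I_max − I_BG(1 px)) / I_BG(1 px).
    """
    if not np.isfinite(spot.i_int):
        raise ValueError("spot must be integrated before normalization")
    bg_sigma = float(model.predict(spot.sigma))
    bg_one = float(model.predict(1.0))
    if bg_sigma <= 0 or bg_one <= 0:
        raise ValueError(
            f"background model predicts non-positive intensity "
            f"(I_BG({spot.sigma})={bg_sigma:.3g}, I_BG(1)={bg_one:.3g}); model invalid for this image"
        )
    spot.i_tot = (spot.i_int - bg_sigma) / bg_sigma
    spot.i_peak = (spot.i_max - bg_one) / bg_one
    return spot


def analyze_channel(
    grid: np.ndarray,
    cfg: PreprocessConfig,
    channel: str = "",
    rng: Optional[np.random.Generator] = None,
    seed: Optional[int] = None,
):
    """Run the full single-channel chain.

    Returns ``(spots, model, corrected, background)`` with all spots
    enlarged, integrated and normalized.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    corrected, background = preprocess(grid, cfg)
    th = threshold_map(corrected, cfg.sfr)
    spots = detect_spots(
        corrected, th, min_core_px=cfg.min_core_px, connectivity=cfg.connectivity, channel=channel
    )
    for s in spots:
        enlarge_spot(s)
        integrate_spot(corrected, s)
    occupied = occupied_mask(corrected.shape, spots)
    samples = sample_background(
        corrected, occupied, n_samples=cfg.bg_samples, size_range=cfg.bg_size_range, rng=rng
    )
    model = fit_background_model(samples, channel=channel)
    for s in spots:
        normalize_spot(s, model)
    return spots, model, corrected, background
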