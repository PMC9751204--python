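"""Synthetic two-channel single-vesicle scenes with known ground truth.

Each scene renders sub-resolution point emitters with a pixel-integrated
Gaussian PSF, per-vesicle flux drawn from a Weibull distribution, an optional
smooth Gaussian illumination field, additive background with shot-like noise,
and an integer chromatic offset applied to the red channel — the ingredients
needed to exercise the detection and colocalization chain against truth.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import ndtr

from vesiq.io import ChannelFrame

__all__ = [
    "SceneParams",
    "SceneTruth",
    "generate_scene",
    "render_concentration_series",
    "flux_for_snr",
    "scene_for_snr",
    "PlacementError",
]

WeibullPair = tuple[float, float]


class PlacementError(RuntimeError):
    """Raised when emitters cannot be placed at the requested density."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic two-channel scene.

    ``intensity_weibull`` holds per-channel ``(shape k, scale λ)`` of the
    per-vesicle total photon flux: either one pair applied to both channels
    or a ``(blue_pair, red_pair)`` tuple.
    ``illumination`` is ``None`` (flat) or ``(amplitude, (row, col), width)``
    of a Gaussian field multiplying emitter flux.
    ``noise_model`` is ``"poisson"``, ``("gaussian", sd)`` or ``"none"``.
    """

    image_shape: tuple[int, int] = (256, 256)
    n_vesicles: int = 100
    frac_colocalized: float = 0.0
    frac_blue_only: float = 0.5
    frac_red_only: float = 0.5
    intensity_weibull: Union[WeibullPair, tuple[WeibullPair, WeibullPair]] = (4.0, 2000.0)
    psf_sigma: float = 1.2
    illumination: Optional[tuple[float, tuple[float, float], float]] = None
    background_level: float = 100.0
    noise_model: Union[str, tuple[str, float]] = "poisson"
    channel_offset: tuple[int, int] = (2, 1)
    min_separation: float = 6.0
    edge_margin: float = 6.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        rows, cols = self.image_shape
        if rows <= 0 or cols <= 0:
            raise ValueError(f"image_shape must be positive, got {self.image_shape}")
        if self.n_vesicles < 0:
            raise ValueError("n_vesicles must be >= 0")
        fracs = (self.frac_colocalized, self.frac_blue_only, self.frac_red_only)
        if any(f < 0 or f > 1 for f in fracs):
            raise ValueError(f"fractions must lie in [0, 1], got {fracs}")
        if abs(sum(fracs) - 1.0) > 1e-9:
            raise ValueError(f"fractions must sum to 1 within 1e-9, got sum={sum(fracs)!r}")
        for k, lam in (self.weibull_blue, self.weibull_red):
            if k <= 0 or lam <= 0:
                raise ValueError(f"Weibull shape/scale must be > 0, got ({k}, {lam})")
        if self.psf_sigma <= 0:
            raise ValueError("psf_sigma must be > 0")
        if self.background_level < 0:
            raise ValueError("background_level must be >= 0")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")
        dr, dc = self.channel_offset
        if int(dr) != dr or int(dc) != dc:
            raise ValueError("channel_offset must be integer pixels")
        if isinstance(self.noise_model, str):
            if self.noise_model not in ("poisson", "none"):
                raise ValueError(f"unknown noise_model {self.noise_model!r}")
        else:
            kind, sd = self.noise_model
            if kind != "gaussian" or sd < 0:
                raise ValueError(f"unknown noise_model {self.noise_model!r}")
        if self.illumination is not None:
            amp, _center, width = self.illumination
            if amp <= 0 or width <= 0:
                raise ValueError("illumination amplitude and width must be > 0")

    @property
    def weibull_blue(self) -> WeibullPair:
        return _channel_weibull(self.intensity_weibull, 0)

    @property
    def weibull_red(self) -> WeibullPair:
        return _channel_weibull(self.intensity_weibull, 1)


def _channel_weibull(value, index: int) -> WeibullPair:
    first = value[0]
    if np.isscalar(first):
        return float(value[0]), float(value[1])
    return float(value[index][0]), float(value[index][1])


@dataclass
class SceneTruth:
    """Ground-truth emitter table of one rendered scene.

    ``channel[i]`` is ``"blue"``, ``"red"`` or ``"both"``; coordinates are the
    blue-frame sub-pixel centers (red rendering adds ``channel_offset``).
    Flux is NaN in a channel the emitter does not emit in.
    """

    ids: np.ndarray
    rows: np.ndarray
    cols: np.ndarray
    channel: np.ndarray
    flux_blue: np.ndarray
    flux_red: np.ndarray
    params: SceneParams

    def __len__(self) -> int:
        return len(self.ids)

    @property
    def n_colocalized(self) -> int:
        return int(np.sum(self.channel == "both"))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.ids,
                "row": self.rows,
                "col": self.cols,
                "channel": self.channel,
                "flux_blue": self.flux_blue,
                "flux_red": self.flux_red,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def flux_for_snr(snr: float, background_level: float, psf_sigma: float, noise_sd: Optional[float] = None) -> float:
    """Total flux giving a centred emitter a peak-pixel SNR of ``snr``.

    SNR is the expected central-pixel signal over the per-pixel noise SD
    (``sqrt(background_level)`` for Poisson unless ``noise_sd`` is given).
    """
    if noise_sd is None:
        noise_sd = math.sqrt(background_level) if background_level > 0 else 1.0
    # mass of the pixel-integrated Gaussian in the central pixel
    edge = ndtr(0.5 / psf_sigma) - ndtr(-0.5 / psf_sigma)
    return snr * noise_sd / (edge * edge)


def scene_for_snr(
    snr: float,
    weibull_shape: float = 8.0,
    background_level: float = 100.0,
    psf_sigma: float = 1.0,
    **kwargs,
) -> SceneParams:
    """Scene parameters whose dimmest emitters sit at the requested SNR.

    The per-vesicle flux is Weibull with the given shape; the scale is set so
    the 1st-percentile flux reaches ``snr`` (per :func:`flux_for_snr`), i.e.
    essentially every emitter in the scene is at or above the stated SNR.
    """
    q01 = (-math.log(0.99)) ** (1.0 / weibull_shape)
    lam = flux_for_snr(snr, background_level, psf_sigma) / q01
    return SceneParams(
        intensity_weibull=(weibull_shape, lam),
        background_level=background_level,
        psf_sigma=psf_sigma,
        **kwargs,
    )


def _place_centers(
    params: SceneParams, rng: np.random.Generator, channel: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Rejection-sample emitter centers.

    ``min_separation`` is enforced between emitters that share a wavelength
    channel; a blue-only and a red-only vesicle may sit arbitrarily close
    (distinct physical vesicles from independently mixed populations), which
    is what produces chance "false" colocalization.
    """
    rows, cols = params.image_shape
    m = params.edge_margin
    lo_r, hi_r = m, rows - 1 - m
    lo_c, hi_c = m, cols - 1 - m
    if hi_r < lo_r or hi_c < lo_c:
        raise PlacementError(f"edge_margin {m} leaves no interior in image {params.image_shape}")
    in_blue = (channel == "both") | (channel == "blue")
    in_red = (channel == "both") | (channel == "red")
    placed_r = np.empty(params.n_vesicles)
    placed_c = np.empty(params.n_vesicles)
    max_attempts = max(1000, 1000 * params.n_vesicles)
    attempts = 0
    min_sep2 = params.min_separation**2
    n_placed = 0
    while n_placed < params.n_vesicles:
        if attempts >= max_attempts:
            raise PlacementError(
                f"could not place {params.n_vesicles} emitters with min_separation="
                f"{params.min_separation} in {params.image_shape} after {attempts} attempts; "
                "scene density too high"
            )
        attempts += 1
        r = rng.uniform(lo_r, hi_r)
        c = rng.uniform(lo_c, hi_c)
        if n_placed:
            shared = (in_blue[:n_placed] & in_blue[n_placed]) | (
                in_red[:n_placed] & in_red[n_placed]
            )
            if shared.any():
                d2 = (placed_r[:n_placed][shared] - r) ** 2 + (placed_c[:n_placed][shared] - c) ** 2
                if d2.min() < min_sep2:
                    continue
        placed_r[n_placed] = r
        placed_c[n_placed] = c
        n_placed += 1
    return placed_r, placed_c


def _render_emitters(
    shape: tuple[int, int],
    rows: np.ndarray,
    cols: np.ndarray,
    fluxes: np.ndarray,
    psf_sigma: float,
    illumination,
) -> np.ndarray:
    """Sum of flux × pixel-integrated Gaussians on a truncated ±4σ support."""
    img = np.zeros(shape, dtype=float)
    half = int(math.ceil(4.0 * psf_sigma))
    n_rows, n_cols = shape
    for r0, c0, flux in zip(rows, cols, fluxes):
        if illumination is not None:
            amp, (ir, ic), width = illumination
            flux = flux * amp * math.exp(-((r0 - ir) ** 2 + (c0 - ic) ** 2) / (2.0 * width**2))
        r_lo = max(0, int(math.floor(r0)) - half)
        r_hi = min(n_rows, int(math.ceil(r0)) + half + 1)
        c_lo = max(0, int(math.floor(c0)) - half)
        c_hi = min(n_cols, int(math.ceil(c0)) + half + 1)
        if r_lo >= r_hi or c_lo >= c_hi:
            continue
        ri = np.arange(r_lo, r_hi)
        ci = np.arange(c_lo, c_hi)
        wr = ndtr((ri + 0.5 - r0) / psf_sigma) - ndtr((ri - 0.5 - r0) / psf_sigma)
        wc = ndtr((ci + 0.5 - c0) / psf_sigma) - ndtr((ci - 0.5 - c0) / psf_sigma)
        img[r_lo:r_hi, c_lo:c_hi] += flux * np.outer(wr, wc)
    return img


def generate_scene(
    params: SceneParams, rng: Optional[np.random.Generator] = None
) -> tuple[ChannelFrame, SceneTruth]:
    """Render one two-channel scene and its ground-truth emitter table.

    The RNG stream is consumed in a fixed, documented order so that draws can
    be reproduced independently from the same seed:

    1. ``rng.binomial(n_vesicles, frac_colocalized)`` → number of dual-label
       emitters (ids ``0..n_both-1``);
    2. ``rng.binomial(n_rest, frac_blue_only / (frac_blue_only + frac_red_only))``
       → number of blue-only emitters (next ids; remaining ids are red-only);
    3. rejection sampling of centers: per candidate one ``uniform`` row then
       one ``uniform`` col draw, accepted iff ``min_separation`` holds;
    4. blue fluxes: ``λ_b · rng.weibull(k_b, size=n_blue_emitting)`` over the
       blue-emitting ids in ascending id order;
    5. red fluxes likewise;
    6. blue-channel noise, then 7. red-channel noise.

    Red-channel emitters are rendered at ``center + channel_offset``.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    n = params.n_vesicles

    n_both = int(rng.binomial(n, params.frac_colocalized)) if n > 0 else 0
    n_rest = n - n_both
    denom = params.frac_blue_only + params.frac_red_only
    p_blue = params.frac_blue_only / denom if denom > 0 else 0.0
    n_blue = int(rng.binomial(n_rest, p_blue)) if n_rest > 0 else 0

    channel = np.array(["both"] * n_both + ["blue"] * n_blue + ["red"] * (n_rest - n_blue), dtype=object)
    rows, cols = _place_centers(params, rng, channel) if n > 0 else (np.empty(0), np.empty(0))
    blue_mask = (channel == "both") | (channel == "blue")
    red_mask = (channel == "both") | (channel == "red")

    kb, lb = params.weibull_blue
    kr, lr = params.weibull_red
    flux_blue = np.full(n, np.nan)
    flux_red = np.full(n, np.nan)
    flux_blue[blue_mask] = lb * rng.weibull(kb, size=int(blue_mask.sum()))
    flux_red[red_mask] = lr * rng.weibull(kr, size=int(red_mask.sum()))

    blue_img = _render_emitters(
        params.image_shape, rows[blue_mask], cols[blue_mask], flux_blue[blue_mask],
        params.psf_sigma, params.illumination,
    )
    dr, dc = params.channel_offset
    red_img = _render_emitters(
        params.image_shape, rows[red_mask] + dr, cols[red_mask] + dc, flux_red[red_mask],
        params.psf_sigma, params.illumination,
    )

    blue_img += params.background_level
    red_img += params.background_level
    blue_img = _apply_noise(blue_img, params.noise_model, rng)
    red_img = _apply_noise(red_img, params.noise_model, rng)

    frame = ChannelFrame(blue_img, red_img, frame_index=0, source=None, layout="split_lr")
    truth = SceneTruth(
        ids=np.arange(n),
        rows=rows,
        cols=cols,
        channel=channel,
        flux_blue=flux_blue,
        flux_red=flux_red,
        params=params,
    )
    return frame, truth


def _apply_noise(img: np.ndarray, noise_model, rng: np.random.Generator) -> np.ndarray:
    if noise_model == "none":
        return img
    if noise_model == "poisson":
        return rng.poisson(img).astype(float)
    kind, sd = noise_model
    return img + rng.normal(0.0, sd, size=img.shape)


def render_concentration_series(
    base: SceneParams, counts: Sequence[int]
) -> list[tuple[ChannelFrame, SceneTruth]]:
    """One scene per vesicle count, all other parameters shared.

    Child scenes draw from independent, reproducible streams spawned from
    ``base.seed``.
    """
    if any(c < 0 for c in counts):
        raise ValueError("counts must be non-negative")
    children = np.random.SeedSequence(base.seed).spawn(len(counts))
    out = []
    for count, child in zip(counts, children):
        params = replace(base, n_vesicles=int(count))
        out.append(generate_scene(params, rng=np.random.default_rng(child)))
    return out
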