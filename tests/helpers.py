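"""Shared helpers for the test suite: validation scene/config presets and
truth-vs-detection matching."""

from __future__ import annotations

import numpy as np

from vesiq import (
    DriftOffset,
    PreprocessConfig,
    analyze_channel,
    apply_drift_grid,
    apply_drift_spots,
    colocalize_by_intensity,
    colocalize_by_position,
    estimate_drift,
    scene_for_snr,
)

# operating point used for synthetic validation scenes
VAL_CFG = PreprocessConfig(sfr=3.0, lowpass_sigma=0.7, post_gauss_sigma=0.5, min_core_px=3)
COLOC_SFR = 1.5
COLOC_RADIUS = 2.0


def coloc_scene_params(level_pct: float, seed: int, n: int = 200, shape=(400, 400),
                       offset=(2, 1), snr: float = 10.0, **kwargs):
    """Scene whose theoretical per-channel colocalization is ``level_pct``.

    A per-channel colocalized fraction x requires a dual-label fraction
    d = x / (2 − x) among all vesicles (the rest split evenly), since each
    channel holds the duals plus half the singles.
    """
    x = level_pct / 100.0
    d = 1.0 if x >= 1.0 else x / (2.0 - x)
    single = (1.0 - d) / 2.0
    return scene_for_snr(
        snr,
        image_shape=shape,
        n_vesicles=n,
        frac_colocalized=d,
        frac_blue_only=single,
        frac_red_only=single,
        channel_offset=offset,
        seed=seed,
        **kwargs,
    )


def match_detections(spots, rows, cols, tol: float = 2.0):
    """Greedy one-to-one matching of detections to truth centers.

    Returns ``(n_matched, n_truth, n_spots)``; a match is a centroid within
    ``tol`` pixels of a truth center, each used at most once, taken in
    ascending-distance order.
    """
    cents = np.array([s.centroid for s in spots]) if spots else np.zeros((0, 2))
    candidates = []
    for i, (r, c) in enumerate(zip(rows, cols)):
        if len(cents) == 0:
            break
        d = np.hypot(cents[:, 0] - r, cents[:, 1] - c)
        for j in np.flatnonzero(d <= tol):
            candidates.append((float(d[j]), i, int(j)))
    candidates.sort()
    used_truth: set[int] = set()
    used_spot: set[int] = set()
    for _, i, j in candidates:
        if i in used_truth or j in used_spot:
            continue
        used_truth.add(i)
        used_spot.add(j)
    return len(used_truth), len(rows), len(spots)


def analyze_frame_pair(frame, seed: int, cfg: PreprocessConfig = VAL_CFG,
                       drift: str = "auto", max_shift: int = 10,
                       coloc_sfr: float = COLOC_SFR, radius: float = COLOC_RADIUS):
    """Detect both channels, drift-align, and run both colocalization methods."""
    bs, bm, bc, _ = analyze_channel(frame.blue, cfg, channel="blue", seed=seed)
    rs, rm, rc, _ = analyze_channel(frame.red, cfg, channel="red", seed=seed + 1)
    if drift == "auto":
        offset = estimate_drift(bc, rc, max_shift=max_shift)
    else:
        offset = DriftOffset(0, 0, mode="none")
    rs_aligned = apply_drift_spots(rs, offset)
    rc_aligned = apply_drift_grid(rc, offset)
    pos = colocalize_by_position(bs, rs_aligned, radius=radius, drift=offset)
    inten = colocalize_by_intensity(
        bs, rs_aligned, bc, rc_aligned, bm, rm, sfr=coloc_sfr, drift=offset
    )
    return {
        "blue_spots": bs, "red_spots": rs_aligned, "blue_model": bm, "red_model": rm,
        "blue_corr": bc, "red_corr": rc_aligned, "offset": offset,
        "position": pos, "intensity": inten,
    }
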