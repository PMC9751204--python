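"""Two-channel vesicle colocalization and drift correction.

Two methods: position-detected (centroid within a radius, greedy one-to-one
matching) and intensity-detected (enlarged mask transferred to the other
channel; colocalized when the transferred normalized intensity I_tot meets
the SFR-based threshold, i.e. I_int − I_BG(σ) ≥ SFR·I_BG(σ)).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from vesiq.detect import BackgroundModel, Spot

__all__ = [
    "DriftOffset",
    "ColocalizationResult",
    "estimate_drift",
    "apply_drift_grid",
    "apply_drift_spots",
    "colocalize_by_position",
    "colocalize_by_intensity",
]


@dataclass(frozen=True)
class DriftOffset:
    """Integer shift of the red channel relative to blue.

    ``red[r, c] ≈ blue[r − drow, c − dcol]``; aligning translates red
    content by ``(−drow, −dcol)``.
    """

    drow: int
    dcol: int
    peak: float = math.nan
    mode: str = "auto"


@dataclass
class ColocalizationResult:
    """Matched spots between the channels for one method.

    ``pairs`` holds ``(blue_id, red_id, score)`` tuples — score is the
    centroid distance (position method) or the transferred I_tot of the
    flagged spot's own channel (intensity method; the partner is the nearest
    opposite-channel spot, −1 if none exists). Fractions are percentages of
    each channel's spots with a partner.
    """

    method: str
    pairs: list[tuple[int, int, float]]
    frac_blue: float
    frac_red: float
    params: dict = field(default_factory=dict)
    drift: Optional[DriftOffset] = None

    def __post_init__(self) -> None:
        for frac in (self.frac_blue, self.frac_red):
            if not (0.0 <= frac <= 100.0):
                raise ValueError(f"fraction {frac} outside [0, 100]")

    @property
    def fraction(self) -> float:
        """Mean of the two per-channel colocalized percentages."""
        return 0.5 * (self.frac_blue + self.frac_red)


def estimate_drift(
    blue: np.ndarray,
    red: np.ndarray,
    max_shift: int = 10,
    mode: str = "auto",
) -> DriftOffset:
    """Offset maximizing the normalized cross-correlation of the two grids.

    Scans integer shifts in ``[−max_shift, max_shift]²``, correlating
    ``blue[r, c]`` with ``red[r + drow, c + dcol]`` over the overlap. Ties are
    broken by the smallest Euclidean shift, then row-major order.
    """
    blue = np.asarray(blue, dtype=float)
    red = np.asarray(red, dtype=float)
    if blue.shape != red.shape:
        raise ValueError("channel shapes differ")
    if max_shift < 0:
        raise ValueError("max_shift must be >= 0")
    if np.ptp(blue) == 0 or np.ptp(red) == 0:
        raise ValueError("flat (zero-variance) input: drift cannot be estimated")
    n_rows, n_cols = blue.shape
    best = None
    for drow in range(-max_shift, max_shift + 1):
        for dcol in range(-max_shift, max_shift + 1):
            b = blue[max(0, -drow): n_rows - max(0, drow), max(0, -dcol): n_cols - max(0, dcol)]
            r = red[max(0, drow): n_rows + min(0, drow), max(0, dcol): n_cols + min(0, dcol)]
            if b.size < 2:
                continue
            bs = b.std()
            rs = r.std()
            if bs == 0 or rs == 0:
                continue
            ncc = float(np.mean((b - b.mean()) * (r - r.mean())) / (bs * rs))
            key = (-ncc, drow * drow + dcol * dcol, drow, dcol)
            if best is None or key < best[0]:
                best = (key, drow, dcol, ncc)
    if best is None:
        raise ValueError("no valid overlap within max_shift")
    return DriftOffset(drow=best[1], dcol=best[2], peak=best[3], mode=mode)


def apply_drift_grid(grid: np.ndarray, offset: DriftOffset) -> np.ndarray:
    """Translate a red-channel grid by ``(−drow, −dcol)`` to align it to blue.

    Pixels shifted out of bounds are dropped; vacated pixels are zero.
    """
    grid = np.asarray(grid, dtype=float)
    out = np.zeros_like(grid)
    n_rows, n_cols = grid.shape
    dr, dc = offset.drow, offset.dcol
    src_r = slice(max(0, dr), n_rows + min(0, dr))
    src_c = slice(max(0, dc), n_cols + min(0, dc))
    dst_r = slice(max(0, -dr), n_rows - max(0, dr) + max(0, -dr))
    dst_c = slice(max(0, -dc), n_cols - max(0, dc) + max(0, -dc))
    out[dst_r, dst_c] = grid[src_r, src_c]
    return out


def apply_drift_spots(spots: Sequence[Spot], offset: DriftOffset) -> list[Spot]:
    """Translate red-channel spots by ``(−drow, −dcol)``.

    Returns copies; spots whose pixels leave the image keep only the
    in-bounds pixels and are border-flagged.
    """
    shift = np.array([offset.drow, offset.dcol], dtype=int)
    out = []
    for spot in spots:
        s = copy.deepcopy(spot)
        n_rows, n_cols = s.image_shape
        for attr in ("core", "enlarged"):
            px = getattr(s, attr)
            if px is None:
                continue
            moved = px - shift
            inside = (
                (moved[:, 0] >= 0)
                & (moved[:, 0] < n_rows)
                & (moved[:, 1] >= 0)
                & (moved[:, 1] < n_cols)
            )
            if not inside.all():
                s.border_flag = True
            setattr(s, attr, moved[inside])
        s.centroid = (s.centroid[0] - offset.drow, s.centroid[1] - offset.dcol)
        if s.enlarged is not None:
            s.sigma = len(s.enlarged)
        out.append(s)
    return out


def colocalize_by_position(
    blue_spots: Sequence[Spot],
    red_spots: Sequence[Spot],
    radius: float = 2.0,
    drift: Optional[DriftOffset] = None,
) -> ColocalizationResult:
    """One-to-one greedy matching of centroids within ``radius`` pixels.

    Candidate pairs are taken in ascending (distance, blue id, red id) order;
    each spot is used at most once.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    candidates = []
    for b in blue_spots:
        for r in red_spots:
            d = math.hypot(b.centroid[0] - r.centroid[0], b.centroid[1] - r.centroid[1])
            if d <= radius:
                candidates.append((d, b.id, r.id))
    candidates.sort()
    used_blue: set[int] = set()
    used_red: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for d, bid, rid in candidates:
        if bid in used_blue or rid in used_red:
            continue
        used_blue.add(bid)
        used_red.add(rid)
        pairs.append((bid, rid, d))
    _flag_pairs(blue_spots, red_spots, pairs)
    return ColocalizationResult(
        method="position",
        pairs=pairs,
        frac_blue=_pct(len(pairs), len(blue_spots)),
        frac_red=_pct(len(pairs), len(red_spots)),
        params={"radius": radius},
        drift=drift,
    )


def colocalize_by_intensity(
    blue_spots: Sequence[Spot],
    red_spots: Sequence[Spot],
    blue_grid: np.ndarray,
    red_grid: np.ndarray,
    blue_model: BackgroundModel,
    red_model: BackgroundModel,
    sfr: float = 2.0,
    drift: Optional[DriftOffset] = None,
) -> ColocalizationResult:
    """Transferred-mask intensity colocalization, run symmetrically.

    A blue spot is colocalized when the red grid integrated over the blue
    spot's enlarged mask gives I_tot ≥ SFR under the red channel's background
    model (equivalently I_int ≥ (1 + SFR)·I_BG(σ)); and vice versa. Grids are
    the background-subtracted channel images, already drift-aligned.
    """
    if sfr < 0:
        raise ValueError("sfr must be >= 0")
    flagged_blue = _transfer_flags(blue_spots, np.asarray(red_grid, dtype=float), red_model, sfr)
    flagged_red = _transfer_flags(red_spots, np.asarray(blue_grid, dtype=float), blue_model, sfr)
    pairs: list[tuple[int, int, float]] = []
    for b, itot in flagged_blue:
        pairs.append((b.id, _nearest_id(b, red_spots), itot))
    for r, itot in flagged_red:
        pairs.append((_nearest_id(r, blue_spots), r.id, itot))
    for b, _ in flagged_blue:
        b.colocalized = True
    for r, _ in flagged_red:
        r.colocalized = True
    return ColocalizationResult(
        method="intensity",
        pairs=pairs,
        frac_blue=_pct(len(flagged_blue), len(blue_spots)),
        frac_red=_pct(len(flagged_red), len(red_spots)),
        params={"sfr": sfr},
        drift=drift,
    )


def _transfer_flags(spots, other_grid, other_model, sfr):
    flagged = []
    for s in spots:
        if s.enlarged is None or len(s.enlarged) == 0:
            continue
        i_int = float(other_grid[s.enlarged[:, 0], s.enlarged[:, 1]].sum())
        bg = float(other_model.predict(len(s.enlarged)))
        if bg <= 0:
            raise ValueError(
                f"background model predicts non-positive I_BG({len(s.enlarged)})={bg:.3g}"
            )
        i_tot = (i_int - bg) / bg
        if i_tot >= sfr:
            flagged.append((s, i_tot))
    return flagged


def _nearest_id(spot: Spot, others: Sequence[Spot]) -> int:
    if not others:
        return -1
    dists = [
        (math.hypot(spot.centroid[0] - o.centroid[0], spot.centroid[1] - o.centroid[1]), o.id)
        for o in others
    ]
    return min(dists)[1]


def _flag_pairs(blue_spots, red_spots, pairs) -> None:
    blue_by_id = {s.id: s for s in blue_spots}
    red_by_id = {s.id: s for s in red_spots}
    for bid, rid, _ in pairs:
        if bid in blue_by_id:
            blue_by_id[bid].colocalized = True
            blue_by_id[bid].partner_id = rid
        if rid in red_by_id:
            red_by_id[rid].colocalized = True
            red_by_id[rid].partner_id = bid


def _pct(k: int, n: int) -> float:
    return 100.0 * k / n if n > 0 else 0.0
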