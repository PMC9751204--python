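"""Image stack reading, dual-view frame splitting, and tabular/overlay output.

Conventions used throughout the package (stated once, here):

* pixel coordinates are 0-based, row-major, ``(row, col)`` with the origin at
  the top-left pixel;
* region bounds are half-open;
* a dual-view frame stores the blue sub-image on the left and the red
  sub-image on the right (``split_lr``), overridable per call.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

LAYOUTS = ("split_lr", "split_tb", "two_files", "single")

#: column order of the per-spot CSV table
SPOT_COLUMNS = [
    "id",
    "channel",
    "centroid_row",
    "centroid_col",
    "sigma_px",
    "I_int",
    "I_max",
    "I_tot",
    "I_peak",
    "colocalized_flag",
    "partner_id",
]


@dataclass
class ChannelFrame:
    """One acquisition frame split into its two wavelength channels.

    Either grid may be ``None`` in single-channel mode. When both are
    present they have identical shape.
    """

    blue: Optional[np.ndarray]
    red: Optional[np.ndarray]
    frame_index: int = 0
    source: Optional[str] = None
    layout: str = "split_lr"

    def __post_init__(self) -> None:
        for name in ("blue", "red"):
            grid = getattr(self, name)
            if grid is None:
                continue
            grid = np.asarray(grid)
            if grid.ndim != 2:
                raise ValueError(f"{name} grid must be 2-D, got ndim={grid.ndim}")
            if not np.all(np.isfinite(grid)):
                raise ValueError(f"{name} grid contains non-finite values")
            setattr(self, name, grid)
        if self.blue is not None and self.red is not None:
            if self.blue.shape != self.red.shape:
                raise ValueError(
                    f"channel shapes differ: blue {self.blue.shape} vs red {self.red.shape}"
                )
        if self.layout not in LAYOUTS:
            raise ValueError(f"unknown layout {self.layout!r}; expected one of {LAYOUTS}")

    @property
    def shape(self) -> tuple[int, int]:
        grid = self.blue if self.blue is not None else self.red
        assert grid is not None
        return grid.shape  # type: ignore[return-value]

    def join(self) -> np.ndarray:
        """Re-assemble the dual-view page this frame was split from."""
        if self.blue is None or self.red is None:
            raise ValueError("both channels required to join a frame")
        if self.layout == "split_lr":
            return np.concatenate([self.blue, self.red], axis=1)
        if self.layout == "split_tb":
            return np.concatenate([self.blue, self.red], axis=0)
        raise ValueError(f"cannot join layout {self.layout!r}")


def split_page(page: np.ndarray, layout: str = "split_lr") -> tuple[np.ndarray, np.ndarray]:
    """Split one dual-view page into (blue, red) halves."""
    page = np.asarray(page)
    if layout == "split_lr":
        if page.shape[1] % 2 != 0:
            raise ValueError(f"odd width {page.shape[1]} cannot be split left/right")
        half = page.shape[1] // 2
        return page[:, :half], page[:, half:]
    if layout == "split_tb":
        if page.shape[0] % 2 != 0:
            raise ValueError(f"odd height {page.shape[0]} cannot be split top/bottom")
        half = page.shape[0] // 2
        return page[:half, :], page[half:, :]
    raise ValueError(f"layout {layout!r} is not a splittable layout")


def read_stack(path, layout: str = "split_lr") -> list[ChannelFrame]:
    """Read a grayscale multi-page TIFF stack into per-frame channel grids.

    Parameters
    ----------
    path
        TIFF file path, or for ``layout="two_files"`` a ``(blue, red)`` pair
        of single-channel TIFF paths.
    layout
        ``split_lr`` (default, blue left), ``split_tb`` (blue top),
        ``two_files``, or ``single`` (one-channel stack; red grid left empty).

    Frames are returned in page order.
    """
    if layout not in LAYOUTS:
        raise ValueError(f"unknown layout {layout!r}; expected one of {LAYOUTS}")

    if layout == "two_files":
        try:
            blue_path, red_path = path
        except (TypeError, ValueError) as exc:
            raise ValueError("two_files layout needs a (blue, red) path pair") from exc
        blue_pages = _read_pages(blue_path)
        red_pages = _read_pages(red_path)
        if len(blue_pages) != len(red_pages):
            raise ValueError(
                f"page count mismatch: {len(blue_pages)} blue vs {len(red_pages)} red"
            )
        return [
            ChannelFrame(b, r, frame_index=i, source=str(blue_path), layout=layout)
            for i, (b, r) in enumerate(zip(blue_pages, red_pages))
        ]

    pages = _read_pages(path)
    frames = []
    for i, page in enumerate(pages):
        if layout == "single":
            frames.append(ChannelFrame(page, None, frame_index=i, source=str(path), layout=layout))
        else:
            blue, red = split_page(page, layout)
            frames.append(ChannelFrame(blue, red, frame_index=i, source=str(path), layout=layout))
    return frames


def _read_pages(path) -> list[np.ndarray]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    with tifffile.TiffFile(str(path)) as tif:
        pages = []
        for i, page in enumerate(tif.pages):
            arr = page.asarray()
            if arr.ndim != 2:
                raise ValueError(f"page {i} of {path} is not 2-D grayscale (ndim={arr.ndim})")
            if not np.issubdtype(arr.dtype, np.number):
                raise ValueError(f"page {i} of {path} has non-numeric dtype {arr.dtype}")
            pages.append(arr)
    if not pages:
        raise ValueError(f"{path} contains no pages")
    return pages


def quantize_u16(grid: np.ndarray) -> np.ndarray:
    """Round and clip a float grid to the 16-bit range used on disk."""
    return np.clip(np.round(np.asarray(grid, dtype=float)), 0, 65535).astype(np.uint16)


def write_stack(frames: Sequence[ChannelFrame], path, layout: Optional[str] = None) -> None:
    """Write frames as a 16-bit grayscale multi-page TIFF (dual-view pages)."""
    if not frames:
        raise ValueError("no frames to write")
    pages = []
    for f in frames:
        frame = f
        if layout is not None and layout != f.layout:
            frame = ChannelFrame(f.blue, f.red, f.frame_index, f.source, layout)
        pages.append(quantize_u16(frame.join()))
    tifffile.imwrite(str(path), np.stack(pages))


def write_spot_table(spots: Sequence, path) -> pd.DataFrame:
    """Write the per-spot CSV table (one row per spot, ``SPOT_COLUMNS`` order)."""
    rows = []
    for s in spots:
        rows.append(
            {
                "id": s.id,
                "channel": s.channel,
                "centroid_row": s.centroid[0],
                "centroid_col": s.centroid[1],
                "sigma_px": s.sigma,
                "I_int": s.i_int,
                "I_max": s.i_max,
                "I_tot": s.i_tot,
                "I_peak": s.i_peak,
                "colocalized_flag": bool(s.colocalized),
                "partner_id": -1 if s.partner_id is None else s.partner_id,
            }
        )
    table = pd.DataFrame(rows, columns=SPOT_COLUMNS)
    table.to_csv(path, index=False)
    return table


def read_spot_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj: dict, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_overlay(
    frame: ChannelFrame,
    blue_spots: Sequence = (),
    red_spots: Sequence = (),
    pairs: Sequence[tuple[int, int]] = (),
    path=None,
):
    """Render a detection overlay PNG.

    Detected spots are circled in their channel colour; colocalized pairs get
    an extra white ring, mirroring the original program's composite view.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    blue = frame.blue if frame.blue is not None else np.zeros(frame.shape)
    red = frame.red if frame.red is not None else np.zeros(frame.shape)
    rgb = np.zeros(blue.shape + (3,))
    for idx, grid in ((2, blue), (0, red)):
        span = np.ptp(grid)
        rgb[..., idx] = (grid - grid.min()) / span if span > 0 else 0.0

    fig, ax = plt.subplots(figsize=(6, 6))
    ax.imshow(rgb, interpolation="nearest")
    for spots, color in ((blue_spots, "cyan"), (red_spots, "orange")):
        for s in spots:
            ax.add_patch(plt.Circle((s.centroid[1], s.centroid[0]), 4, fill=False, color=color, lw=0.8))
    paired_blue = {p[0] for p in pairs}
    for s in blue_spots:
        if s.id in paired_blue:
            ax.add_patch(plt.Circle((s.centroid[1], s.centroid[0]), 6, fill=False, color="white", lw=1.2))
    ax.set_axis_off()
    if path is not None:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
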