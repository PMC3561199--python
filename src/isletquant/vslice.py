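"""Virtual-slice assembly and raster I/O.

A whole tissue section imaged at 10x does not fit in one microscope field of
view; the stage acquires a grid of overlapping tiles which are assembled into
a single high-resolution montage (a "virtual slice"). Tiles are trusted to be
stage-aligned: no registration or illumination correction is performed, and
overlapping strips are blended by the arithmetic mean, which is
order-independent.

Coordinate convention: row-major rasters, origin at the top-left, 0-based
indices, pixel centers at integer coordinates.
"""

from __future__ import annotations

import pathlib
from dataclasses import dataclass, field, replace

import numpy as np
import tifffile

#: Canonical acquisition channels: one hormone stain per endocrine type plus
#: a nuclear counterstain.
CHANNELS = ("insulin", "glucagon", "somatostatin", "pp", "nuclei")

#: Hormone channel -> endocrine cell type secreting it.
HORMONE_TO_TYPE = {
    "insulin": "beta",
    "glucagon": "alpha",
    "somatostatin": "delta",
    "pp": "pp",
}

#: Fixed endocrine type order; doubles as the deterministic tie-break order
#: when a pixel is contested between channels.
CELL_TYPES = ("beta", "alpha", "delta", "pp")


class StitchError(ValueError):
    """Raised when a tile grid cannot be assembled into a slice."""


@dataclass
class ChannelStack:
    """Co-registered per-channel rasters for one section.

    Parameters
    ----------
    channels
        Mapping of channel name to a 2-D intensity raster. All rasters must
        share one shape. Intensities are typically floats in [0, 1] for
        synthetic data or integer counts for acquired data.
    pixel_size
        Physical edge length of one pixel in micrometres.
    section_id
        Free-text identifier of the section.
    block_index
        Position of the section's tissue block along the head-to-tail axis,
        or ``None`` when the section is not part of a block series.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float
    section_id: str = "section"
    block_index: int | None = None

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ChannelStack requires at least one channel")
        shapes = {name: arr.shape for name, arr in self.channels.items()}
        if len(set(shapes.values())) != 1:
            raise ValueError(f"channel rasters differ in shape: {shapes}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be positive, got {self.pixel_size}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not a 2-D raster")
            if np.issubdtype(arr.dtype, np.floating) and not np.all(np.isfinite(arr)):
                raise ValueError(f"channel {name!r} contains non-finite values")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    def copy(self) -> "ChannelStack":
        return replace(self, channels={k: v.copy() for k, v in self.channels.items()})


@dataclass
class Tile:
    """One microscope field of view within a tile grid."""

    channels: dict[str, np.ndarray]
    grid_pos: tuple[int, int]  # (row, col) in the acquisition grid
    origin: tuple[int, int]  # (row0, col0) pixel offset in slice coordinates

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape


@dataclass
class TileGrid:
    """A complete rectangular grid of tiles covering one section."""

    tiles: list[Tile]
    n_rows: int
    n_cols: int
    overlap: int
    pixel_size: float
    section_id: str = "section"
    block_index: int | None = None


def stitch(grid: TileGrid) -> ChannelStack:
    """Assemble a tile grid into one composite multichannel slice.

    Stage coordinates (tile origins) are trusted; in strips covered by more
    than one tile the arithmetic mean of the contributing tiles is used.
    Because duplicated overlap strips are pixelwise identical in this
    artifact, mean blending makes stitching an exact inverse of tiling.

    Raises
    ------
    StitchError
        If grid cells are missing or tile channel sets / dtypes disagree.
    """
    if not grid.tiles:
        raise StitchError("empty tile grid")
    seen = {t.grid_pos for t in grid.tiles}
    expected = {(r, c) for r in range(grid.n_rows) for c in range(grid.n_cols)}
    missing = sorted(expected - seen)
    if missing:
        raise StitchError(f"missing grid cells (row, col): {missing}")

    channel_names = tuple(sorted(grid.tiles[0].channels))
    for t in grid.tiles:
        if tuple(sorted(t.channels)) != channel_names:
            raise StitchError(
                f"tile {t.grid_pos} channel set {sorted(t.channels)} != {list(channel_names)}"
            )

    h = max(t.origin[0] + t.shape[0] for t in grid.tiles)
    w = max(t.origin[1] + t.shape[1] for t in grid.tiles)
    out: dict[str, np.ndarray] = {}
    weight = np.zeros((h, w), dtype=np.float64)
    for t in grid.tiles:
        r0, c0 = t.origin
        th, tw = t.shape
        weight[r0 : r0 + th, c0 : c0 + tw] += 1.0
    if np.any(weight == 0):
        raise StitchError("tile origins leave uncovered pixels inside the bounding box")

    for name in channel_names:
        acc = np.zeros((h, w), dtype=np.float64)
        for t in grid.tiles:
            r0, c0 = t.origin
            th, tw = t.shape
            acc[r0 : r0 + th, c0 : c0 + tw] += np.asarray(
                t.channels[name], dtype=np.float64
            )
        blended = acc / weight
        dtype = grid.tiles[0].channels[name].dtype
        if np.issubdtype(dtype, np.integer):
            blended = np.rint(blended)
        out[name] = blended.astype(dtype)
    return ChannelStack(
        channels=out,
        pixel_size=grid.pixel_size,
        section_id=grid.section_id,
        block_index=grid.block_index,
    )


def write_stack(stack: ChannelStack, out_dir: str | pathlib.Path) -> dict[str, pathlib.Path]:
    """Write one grayscale TIFF per channel, named ``<section>_<channel>.tif``.

    Integer rasters are written as-is (lossless round trip for 8/16-bit
    data); float rasters in [0, 1] are quantized to 16-bit.
    """
    out_dir = pathlib.Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, pathlib.Path] = {}
    for name, arr in stack.channels.items():
        path = out_dir / f"{stack.section_id}_{name}.tif"
        if np.issubdtype(arr.dtype, np.integer):
            data = arr
        else:
            data = np.rint(np.clip(arr, 0.0, 1.0) * 65535).astype(np.uint16)
        tifffile.imwrite(path, data)
        paths[name] = path
    return paths


def read_stack(
    paths: dict[str, str | pathlib.Path],
    pixel_size: float,
    section_id: str = "section",
    block_index: int | None = None,
    require: tuple[str, ...] = CHANNELS,
) -> ChannelStack:
    """Read per-channel rasters from disk into a :class:`ChannelStack`.

    Raises
    ------
    KeyError
        If a required channel has no path, naming the channel.
    ValueError
        If channel shapes disagree, naming the offending channel.
    """
    for name in require:
        if name not in paths:
            raise KeyError(f"missing path for channel {name!r}")
    channels: dict[str, np.ndarray] = {}
    ref_shape: tuple[int, int] | None = None
    ref_name = ""
    for name, path in paths.items():
        arr = tifffile.imread(pathlib.Path(path))
        if ref_shape is None:
            ref_shape, ref_name = arr.shape, name
        elif arr.shape != ref_shape:
            raise ValueError(
                f"channel {name!r} shape {arr.shape} != {ref_name!r} shape {ref_shape}"
            )
        channels[name] = arr
    return ChannelStack(channels, pixel_size, section_id, block_index)
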