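"""Raster-order tile addressing within a pyramid layer.

Tiles of a layer are numbered in raster order (left-to-right, then
row-by-row downward)::

    t = y * x_tiles + x

where ``x_tiles`` is the number of tile columns in the layer. Layer indices
are 0-based with layer 0 the lowest resolution; ``y`` grows downward
(image convention).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from iris_restful.metadata import LayerInfo


class TileRangeError(IndexError):
    """A tile coordinate or raster index falls outside its layer."""


@dataclass(frozen=True)
class TileCoordinate:
    """(layer, x, y) tile location; all indices 0-based."""

    layer: int
    x: int
    y: int


def raster_index(coord: TileCoordinate, layer: LayerInfo) -> int:
    """Map an (x, y) tile coordinate to its raster index ``t``."""
    if not (0 <= coord.x < layer.x_tiles and 0 <= coord.y < layer.y_tiles):
        raise TileRangeError(
            f"tile ({coord.x}, {coord.y}) outside layer extent "
            f"{layer.x_tiles}x{layer.y_tiles}"
        )
    return coord.y * layer.x_tiles + coord.x


def raster_coords(t: int, layer: LayerInfo, layer_index: int = 0) -> TileCoordinate:
    """Invert :func:`raster_index`: recover (x, y) from the raster index."""
    if not 0 <= t < layer.tile_count:
        raise TileRangeError(
            f"raster index {t} outside layer of {layer.tile_count} tiles"
        )
    return TileCoordinate(layer=layer_index, x=t % layer.x_tiles, y=t // layer.x_tiles)


def layer_tiling(width: int, height: int, scale: float, tile_size: int) -> LayerInfo:
    """Tiling extent of a layer: the number of tile windows covering it.

    ``x_tiles = ceil(scale * width / tile_size)`` and likewise for rows.
    """
    if width < 1 or height < 1 or tile_size < 1:
        raise ValueError(
            f"width, height and tile_size must be positive, got "
            f"{width}, {height}, {tile_size}"
        )
    if not (0.0 < scale <= 1.0):
        raise ValueError(f"scale must lie in (0, 1], got {scale}")
    return LayerInfo(
        x_tiles=math.ceil(scale * width / tile_size),
        y_tiles=math.ceil(scale * height / tile_size),
        scale=scale,
    )
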