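"""Client-side tile-source logic for a tiled viewer.

Mirrors what a pyramidal renderer's tile source does against the server:
fetch the slide metadata once, derive one level configuration per pyramid
layer, translate (level, x, y) tile requests into URL targets using the
raster index ``t = y * x_tiles + x``, and assemble pixel regions by
downloading, decoding, cropping edge padding and stitching tiles.

Levels map 1:1 to container layers; tiles abut exactly (overlap 0). Edge
tiles are stored fully padded, so cropping against the level pixel extent
happens here, on the client.
"""

from __future__ import annotations

import io
import math
import ssl
import urllib.error
import urllib.request
from dataclasses import dataclass

import numpy as np
from PIL import Image

from iris_restful import api
from iris_restful.addressing import TileRangeError


class TileSourceError(Exception):
    """Client-side failure: bad metadata, HTTP error, or undecodable tile."""


class ConfigurationError(TileSourceError):
    """The served metadata document is inconsistent or incomplete."""


@dataclass(frozen=True)
class LevelConfig:
    """Viewer configuration of one pyramid level."""

    level: int
    pixel_width: int
    pixel_height: int
    x_tiles: int
    y_tiles: int
    scale: float


def configure_from_metadata(document: str | bytes) -> list[LevelConfig]:
    """Derive the per-level viewer configuration from a served metadata document.

    Rejects documents whose tiling extents are inconsistent with their scale.
    """
    try:
        meta = api.metadata_from_json(document)
    except ValueError as exc:
        raise ConfigurationError(str(exc)) from exc
    levels = []
    for i, layer in enumerate(meta.layers):
        pw, ph = meta.layer_pixel_extent(i)
        if (layer.x_tiles, layer.y_tiles) != (
            math.ceil(pw / meta.tile_size),
            math.ceil(ph / meta.tile_size),
        ):
            raise ConfigurationError(
                f"level {i}: tiling {layer.x_tiles}x{layer.y_tiles} inconsistent "
                f"with pixel extent {pw}x{ph} at tile size {meta.tile_size}"
            )
        levels.append(
            LevelConfig(
                level=i, pixel_width=pw, pixel_height=ph,
                x_tiles=layer.x_tiles, y_tiles=layer.y_tiles, scale=layer.scale,
            )
        )
    return levels


def tile_url(server_url: str, slide_id: str, level: LevelConfig, x: int, y: int) -> str:
    """URL target of one tile: ``{server}/slides/{id}/layers/{l}/tiles/{t}``."""
    if not (0 <= x < level.x_tiles and 0 <= y < level.y_tiles):
        raise TileRangeError(
            f"tile ({x}, {y}) outside level extent {level.x_tiles}x{level.y_tiles}"
        )
    t = y * level.x_tiles + x
    return f"{server_url.rstrip('/')}/slides/{slide_id}/layers/{level.level}/tiles/{t}"


class IrisTileSource:
    """A configured client for one slide on one server.

    Viewer configuration is automatic: the constructor retrieves and parses
    the slide metadata and derives the level list.
    """

    def __init__(
        self,
        server_url: str,
        slide_id: str,
        *,
        ssl_context: ssl.SSLContext | None = None,
        timeout: float = 10.0,
    ) -> None:
        self.server_url = server_url.rstrip("/")
        self.slide_id = slide_id
        self._ctx = ssl_context
        self._timeout = timeout
        document = self._get(f"{self.server_url}/slides/{slide_id}/metadata")
        self.levels = configure_from_metadata(document)
        self.tile_size = api.metadata_from_json(document).tile_size

    def _get(self, url: str) -> bytes:
        try:
            with urllib.request.urlopen(
                url, timeout=self._timeout, context=self._ctx
            ) as resp:
                return resp.read()
        except urllib.error.HTTPError as exc:
            narrative = exc.read().decode("utf-8", "replace")
            raise TileSourceError(f"HTTP {exc.code}: {narrative}") from exc

    def tile_url(self, level: int, x: int, y: int) -> str:
        return tile_url(self.server_url, self.slide_id, self.levels[level], x, y)

    def fetch_tile(self, level: int, x: int, y: int) -> np.ndarray:
        """Download and decode one tile (full stored shape, padding included)."""
        payload = self._get(self.tile_url(level, x, y))
        try:
            with Image.open(io.BytesIO(payload)) as img:
                return np.asarray(img.convert("RGB"))
        except Exception as exc:
            raise TileSourceError(f"tile ({level}, {x}, {y}) failed to decode: {exc}") from exc

    def fetch_region(
        self, level: int, x0: int, y0: int, width: int, height: int
    ) -> np.ndarray:
        """Assemble the exact pixel rectangle from its covering tiles."""
        cfg = self.levels[level]
        if width < 1 or height < 1:
            raise TileRangeError("region extent must be positive")
        if x0 < 0 or y0 < 0 or x0 + width > cfg.pixel_width or y0 + height > cfg.pixel_height:
            raise TileRangeError(
                f"region [{x0}, {x0 + width}) x [{y0}, {y0 + height}) exceeds "
                f"level extent {cfg.pixel_width}x{cfg.pixel_height}"
            )
        ts = self.tile_size
        out = np.zeros((height, width, 3), dtype=np.uint8)
        for ty in range(y0 // ts, (y0 + height - 1) // ts + 1):
            for tx in range(x0 // ts, (x0 + width - 1) // ts + 1):
                tile = self.fetch_tile(level, tx, ty)
                # crop stored replicate-padding against the level pixel extent
                valid_w = min(ts, cfg.pixel_width - tx * ts)
                valid_h = min(ts, cfg.pixel_height - ty * ts)
                tile = tile[:valid_h, :valid_w]
                # intersection of this tile with the requested rectangle
                ax0 = max(x0, tx * ts)
                ay0 = max(y0, ty * ts)
                ax1 = min(x0 + width, tx * ts + valid_w)
                ay1 = min(y0 + height, ty * ts + valid_h)
                out[ay0 - y0 : ay1 - y0, ax0 - x0 : ax1 - x0] = tile[
                    ay0 - ty * ts : ay1 - ty * ts, ax0 - tx * ts : ax1 - tx * ts
                ]
        return out


def fetch_region(
    server_url: str,
    slide_id: str,
    level: int,
    x0: int,
    y0: int,
    width: int,
    height: int,
    *,
    ssl_context: ssl.SSLContext | None = None,
) -> np.ndarray:
    """One-shot convenience wrapper around :class:`IrisTileSource`."""
    source = IrisTileSource(server_url, slide_id, ssl_context=ssl_context)
    return source.fetch_region(level, x0, y0, width, height)
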