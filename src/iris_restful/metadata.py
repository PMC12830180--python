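"""Slide geometry types: per-layer tiling extents and the slide metadata contract.

A slide is a resolution pyramid. Every layer is tiled into fixed-size square
tiles (default 256 px); the layer's ``scale`` is its linear resolution as a
fraction of the highest-resolution layer. Layers are stored lowest resolution
first, so ``scale`` is strictly increasing and the final layer has scale 1.0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


class MetadataError(ValueError):
    """A slide metadata document violates the geometry contract."""


@dataclass(frozen=True)
class LayerInfo:
    """Tiling extent of one pyramid layer.

    Parameters
    ----------
    x_tiles, y_tiles:
        Number of tile columns / rows covering the layer.
    scale:
        Linear resolution of the layer relative to the full-resolution
        layer, in ``(0, 1]``.
    """

    x_tiles: int
    y_tiles: int
    scale: float

    def __post_init__(self) -> None:
        if self.x_tiles < 1 or self.y_tiles < 1:
            raise MetadataError(
                f"layer tile extents must be positive, got "
                f"{self.x_tiles}x{self.y_tiles}"
            )
        if not (0.0 < self.scale <= 1.0):
            raise MetadataError(f"layer scale must lie in (0, 1], got {self.scale}")

    @property
    def tile_count(self) -> int:
        return self.x_tiles * self.y_tiles

    def to_dict(self) -> dict:
        return {"x_tiles": self.x_tiles, "y_tiles": self.y_tiles, "scale": self.scale}

    @classmethod
    def from_dict(cls, d: dict) -> "LayerInfo":
        try:
            return cls(
                x_tiles=int(d["x_tiles"]),
                y_tiles=int(d["y_tiles"]),
                scale=float(d["scale"]),
            )
        except KeyError as exc:  # pragma: no cover - exercised via SlideMetadata
            raise MetadataError(f"layer document missing field {exc}") from exc


@dataclass
class SlideMetadata:
    """The metadata contract served to clients.

    ``width`` and ``height`` are the pixel extent of the highest-resolution
    layer; every stored tile is ``tile_size`` x ``tile_size`` pixels
    (edge tiles are replicate-padded on disk and cropped by clients using the
    layer pixel extent).
    """

    width: int
    height: int
    tile_size: int = 256
    encoding: str = "jpeg"
    layers: list[LayerInfo] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        if self.width < 1 or self.height < 1:
            raise MetadataError(
                f"slide extent must be positive, got {self.width}x{self.height}"
            )
        if self.tile_size < 16:
            raise MetadataError(f"tile_size must be >= 16, got {self.tile_size}")
        if not self.layers:
            raise MetadataError("slide must have at least one layer")
        prev_scale = 0.0
        for i, layer in enumerate(self.layers):
            if not isinstance(layer, LayerInfo):
                raise MetadataError("layers must be LayerInfo instances")
            if layer.scale <= prev_scale:
                raise MetadataError(
                    "layer scales must be strictly increasing "
                    f"(layer {i} has scale {layer.scale} after {prev_scale})"
                )
            prev_scale = layer.scale
            expect_x = math.ceil(layer.scale * self.width / self.tile_size)
            expect_y = math.ceil(layer.scale * self.height / self.tile_size)
            if (layer.x_tiles, layer.y_tiles) != (expect_x, expect_y):
                raise MetadataError(
                    f"layer {i} tiling {layer.x_tiles}x{layer.y_tiles} is "
                    f"inconsistent with scale {layer.scale} "
                    f"(expected {expect_x}x{expect_y})"
                )
        if self.layers[-1].scale != 1.0:
            raise MetadataError(
                f"final layer must have scale 1.0, got {self.layers[-1].scale}"
            )

    @property
    def total_tiles(self) -> int:
        return sum(layer.tile_count for layer in self.layers)

    def layer_pixel_extent(self, layer: int) -> tuple[int, int]:
        """Pixel (width, height) of one layer, rounded from its scale."""
        s = self.layers[layer].scale
        return round(s * self.width), round(s * self.height)

    def to_dict(self) -> dict:
        # Fixed key order: the JSON serialisation is byte-stable.
        return {
            "extent": {"width": self.width, "height": self.height},
            "tile_size": self.tile_size,
            "encoding": self.encoding,
            "layers": [layer.to_dict() for layer in self.layers],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SlideMetadata":
        try:
            extent = d["extent"]
            return cls(
                width=int(extent["width"]),
                height=int(extent["height"]),
                tile_size=int(d["tile_size"]),
                encoding=str(d["encoding"]),
                layers=[LayerInfo.from_dict(x) for x in d["layers"]],
            )
        except (KeyError, TypeError) as exc:
            raise MetadataError(f"malformed metadata document: {exc!r}") from exc
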