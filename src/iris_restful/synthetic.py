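"""Deterministic fixture pyramids and DZI export.

Two generation modes:

``identity``
    Every tile is a solid colour that encodes its own address:
    ``R = 8 * ((t >> 5) % 32)``, ``G = 8 * (t % 32)``, ``B = 8 * (layer % 32)``.
    Channel values are multiples of 8 so the colour survives JPEG
    quantisation; :func:`decode_tile_identity` inverts the encoding after a
    full write -> serve -> fetch cycle. Capacity follows from the 5-bit
    fields: at most 1024 tiles per layer and 32 layers.

``pyramid``
    A seeded smooth procedural texture at full resolution; lower layers are
    produced by block-mean downsampling, which preserves the global pixel
    mean across layers -- the natural consistency property of an image
    pyramid.

Both modes write through the container writer; layer ``l`` of an
``n``-layer pyramid has scale ``downsample ** (l - (n - 1))``.

:func:`export_dzi` re-expresses a 2x container as a DeepZoom tree (XML
descriptor plus one directory per level of ``{x}_{y}.jpg`` files) for
cross-format comparison; interior tiles reuse the stored JPEG bytes
unchanged.
"""

from __future__ import annotations

import io
import math
import os
from dataclasses import dataclass, field
from xml.etree import ElementTree as ET

import numpy as np
from PIL import Image

from iris_restful.addressing import layer_tiling
from iris_restful.container import open_slide, write_container
from iris_restful.metadata import LayerInfo, SlideMetadata

DZI_XMLNS = "http://schemas.microsoft.com/deepzoom/2008"


class IdentityDecodeError(ValueError):
    """A pixel does not decode as an identity-encoded tile colour."""


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Parameters of a deterministic fixture pyramid."""

    width: int = 1024
    height: int = 1024
    tile_size: int = 256
    downsample: int = 2
    n_layers: int = 3
    mode: str = "identity"
    jpeg_quality: int = 90
    seed: int = 0

    def __post_init__(self) -> None:
        if self.downsample not in (2, 4):
            raise ValueError(f"downsample must be 2 or 4, got {self.downsample}")
        if self.mode not in ("identity", "pyramid"):
            raise ValueError(f"mode must be identity or pyramid, got {self.mode!r}")
        if not 1 <= self.jpeg_quality <= 100:
            raise ValueError(f"jpeg_quality must be in 1..100, got {self.jpeg_quality}")
        if self.n_layers < 1:
            raise ValueError("n_layers must be positive")
        if self.mode == "identity":
            if self.n_layers > 32:
                raise ValueError("identity mode supports at most 32 layers")
            for layer in self.layer_infos():
                if layer.tile_count > 1024:
                    raise ValueError(
                        "identity mode supports at most 1024 tiles per layer, "
                        f"got {layer.tile_count}"
                    )

    def layer_scale(self, layer: int) -> float:
        return float(self.downsample) ** (layer - (self.n_layers - 1))

    def layer_infos(self) -> list[LayerInfo]:
        return [
            layer_tiling(self.width, self.height, self.layer_scale(l), self.tile_size)
            for l in range(self.n_layers)
        ]

    def metadata(self) -> SlideMetadata:
        return SlideMetadata(
            width=self.width,
            height=self.height,
            tile_size=self.tile_size,
            encoding="jpeg",
            layers=self.layer_infos(),
        )


@dataclass
class GeneratedSlide:
    """A written container plus its pre-compression ground truth."""

    path: str
    spec: SyntheticSlideSpec
    metadata: SlideMetadata
    #: per-level reference pixel arrays (level pixel extent, before JPEG)
    level_pixels: list[np.ndarray] = field(default_factory=list)


def identity_color(layer: int, t: int) -> tuple[int, int, int]:
    """Solid colour encoding tile ``t`` of ``layer``."""
    return 8 * ((t >> 5) % 32), 8 * (t % 32), 8 * (layer % 32)


def decode_tile_identity(pixels: np.ndarray) -> tuple[int, int]:
    """Invert :func:`identity_color` from a decoded tile's central pixel.

    Each channel is rounded to the nearest multiple of 8, tolerating JPEG
    loss of up to 3 grey levels per channel (safe for quality >= 75).
    """
    h, w = pixels.shape[:2]
    center = pixels[h // 2, w // 2]
    quantized = []
    for value in (int(center[0]), int(center[1]), int(center[2])):
        q = int(round(value / 8.0))
        if abs(value - 8 * q) > 3:
            raise IdentityDecodeError(
                f"channel value {value} is farther than 3 from any multiple of 8"
            )
        quantized.append(q % 32)
    r, g, b = quantized
    return b, r * 32 + g


def _encode_jpeg(tile: np.ndarray, quality: int) -> bytes:
    buf = io.BytesIO()
    # 4:4:4 sampling: chroma subsampling would dominate the reconstruction
    # error of fine colour detail at any quality setting
    Image.fromarray(tile, mode="RGB").save(
        buf, format="JPEG", quality=quality, subsampling=0
    )
    return buf.getvalue()


def _pad_to(image: np.ndarray, height: int, width: int) -> np.ndarray:
    """Replicate-pad on the right/bottom to the requested shape."""
    pad_h = height - image.shape[0]
    pad_w = width - image.shape[1]
    if pad_h == 0 and pad_w == 0:
        return image
    return np.pad(image, ((0, pad_h), (0, pad_w), (0, 0)), mode="edge")


def _tiles_of_level(level: np.ndarray, layer: LayerInfo, tile_size: int):
    for ty in range(layer.y_tiles):
        for tx in range(layer.x_tiles):
            block = level[
                ty * tile_size : (ty + 1) * tile_size,
                tx * tile_size : (tx + 1) * tile_size,
            ]
            yield _pad_to(block, tile_size, tile_size)


def _procedural_texture(spec: SyntheticSlideSpec) -> np.ndarray:
    """A seeded smooth RGB field at full resolution."""
    rng = np.random.default_rng(spec.seed)
    coarse_w = max(2, math.ceil(spec.width / 64))
    coarse_h = max(2, math.ceil(spec.height / 64))
    coarse = rng.uniform(32, 224, size=(coarse_h, coarse_w, 3))
    smooth = np.asarray(
        Image.fromarray(coarse.astype(np.uint8), mode="RGB").resize(
            (spec.width, spec.height), Image.BILINEAR
        ),
        dtype=np.float64,
    )
    # fine detail at a 4-px grain: band-limited like real scanner optics, so
    # JPEG at the default quality preserves it closely
    fine_h, fine_w = math.ceil(spec.height / 4), math.ceil(spec.width / 4)
    fine = rng.normal(0.0, 10.0, size=(fine_h, fine_w, 3))
    detail = np.asarray(
        Image.fromarray(np.clip(fine + 128, 0, 255).astype(np.uint8), mode="RGB")
        .resize((spec.width, spec.height), Image.BILINEAR),
        dtype=np.float64,
    ) - 128.0
    return np.clip(smooth + detail, 0, 255).astype(np.uint8)


def block_mean_downsample(image: np.ndarray, factor: int) -> np.ndarray:
    """Downsample by averaging ``factor`` x ``factor`` pixel blocks.

    Dimensions not divisible by ``factor`` are replicate-padded first.
    """
    if factor == 1:
        return image
    h = math.ceil(image.shape[0] / factor) * factor
    w = math.ceil(image.shape[1] / factor) * factor
    padded = _pad_to(image, h, w).astype(np.float64)
    blocks = padded.reshape(h // factor, factor, w // factor, factor, 3)
    return (blocks.mean(axis=(1, 3)) + 0.5).astype(np.uint8)


def generate_slide(spec: SyntheticSlideSpec, path: str | os.PathLike) -> GeneratedSlide:
    """Write a deterministic fixture container; returns it with ground truth."""
    metadata = spec.metadata()
    level_pixels: list[np.ndarray] = []
    tiles: list[bytes] = []

    if spec.mode == "identity":
        for l, layer in enumerate(metadata.layers):
            pw, ph = metadata.layer_pixel_extent(l)
            level = np.zeros((ph, pw, 3), dtype=np.uint8)
            for t in range(layer.tile_count):
                tx, ty = t % layer.x_tiles, t // layer.x_tiles
                color = identity_color(l, t)
                tile = np.empty((spec.tile_size, spec.tile_size, 3), dtype=np.uint8)
                tile[:] = color
                ts = spec.tile_size
                level[ty * ts : (ty + 1) * ts, tx * ts : (tx + 1) * ts] = color
                tiles.append(_encode_jpeg(tile, spec.jpeg_quality))
            level_pixels.append(level)
    else:
        full = _procedural_texture(spec)
        for l, layer in enumerate(metadata.layers):
            factor = spec.downsample ** (spec.n_layers - 1 - l)
            level = block_mean_downsample(full, factor)
            level_pixels.append(level)
            tiles.extend(
                _encode_jpeg(tile, spec.jpeg_quality)
                for tile in _tiles_of_level(level, layer, spec.tile_size)
            )

    write_container(path, metadata, tiles)
    return GeneratedSlide(
        path=os.fspath(path), spec=spec, metadata=metadata, level_pixels=level_pixels
    )


def dzi_level_for_layer(metadata: SlideMetadata, layer: int) -> int:
    """DeepZoom level number of container layer ``layer``.

    DeepZoom numbers levels so that level ``ceil(log2(max(w, h)))`` is full
    resolution and each level below halves it.
    """
    max_level = math.ceil(math.log2(max(metadata.width, metadata.height)))
    return max_level - (len(metadata.layers) - 1 - layer)


def export_dzi(container_path: str | os.PathLike, out_dir: str | os.PathLike,
               name: str, *, edge_quality: int = 95) -> str:
    """Export a 2x-downsampled container as a DeepZoom tree.

    Writes ``{name}.dzi`` plus ``{name}_files/{level}/{x}_{y}.jpg``.
    Interior tiles reuse the container's JPEG bytes unchanged; edge tiles
    are decoded, cropped to the level pixel extent and re-encoded (DeepZoom
    stores edge tiles at their true size, while the container pads them).
    Only 2x pyramids are supported -- DeepZoom levels halve by definition.
    """
    handle = open_slide(container_path)
    try:
        meta = handle.metadata
        scales = [layer.scale for layer in meta.layers]
        for lo, hi in zip(scales, scales[1:]):
            if abs(hi / lo - 2.0) > 1e-9:
                raise ValueError(
                    "DZI export requires a 2x-downsampled pyramid; got scale "
                    f"step {hi / lo:g}"
                )
        out_dir = os.fspath(out_dir)
        files_dir = os.path.join(out_dir, f"{name}_files")
        ts = meta.tile_size
        for l, layer in enumerate(meta.layers):
            level_dir = os.path.join(files_dir, str(dzi_level_for_layer(meta, l)))
            os.makedirs(level_dir, exist_ok=True)
            pw, ph = meta.layer_pixel_extent(l)
            for t in range(layer.tile_count):
                tx, ty = t % layer.x_tiles, t // layer.x_tiles
                payload = handle.read_tile(l, t)
                valid_w = min(ts, pw - tx * ts)
                valid_h = min(ts, ph - ty * ts)
                if (valid_w, valid_h) != (ts, ts):
                    with Image.open(io.BytesIO(payload)) as img:
                        cropped = np.asarray(img.convert("RGB"))[:valid_h, :valid_w]
                    payload = _encode_jpeg(cropped, edge_quality)
                with open(os.path.join(level_dir, f"{tx}_{ty}.jpg"), "wb") as fh:
                    fh.write(payload)
        root = ET.Element(
            "Image",
            {"xmlns": DZI_XMLNS, "TileSize": str(ts), "Overlap": "0", "Format": "jpg"},
        )
        ET.SubElement(
            root, "Size", {"Width": str(meta.width), "Height": str(meta.height)}
        )
        descriptor = os.path.join(out_dir, f"{name}.dzi")
        ET.ElementTree(root).write(
            descriptor, encoding="utf-8", xml_declaration=True
        )
        return descriptor
    finally:
        handle.close()
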