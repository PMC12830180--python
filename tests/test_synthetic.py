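"""Fixture pyramids: identity encoding, determinism, downsampling, DZI export."""

import io
import math
import os
from xml.etree import ElementTree as ET

import numpy as np
import pytest
from PIL import Image

from iris_restful.container import open_slide
from iris_restful.synthetic import (
    IdentityDecodeError,
    SyntheticSlideSpec,
    block_mean_downsample,
    decode_tile_identity,
    dzi_level_for_layer,
    export_dzi,
    generate_slide,
    identity_color,
)


def solid(rgb, shape=(16, 16)):
    tile = np.empty((*shape, 3), dtype=np.uint8)
    tile[:] = rgb
    return tile


@pytest.mark.parametrize(
    "layer, t, rgb",
    [(1, 0, (0, 0, 8)), (0, 33, (8, 8, 0)), (2, 1023, (248, 248, 16))],
)
def test_identity_color_examples(layer, t, rgb):
    assert identity_color(layer, t) == rgb


def test_decode_exact_and_rounded():
    assert decode_tile_identity(solid((8, 8, 0))) == (0, 33)
    assert decode_tile_identity(solid((9, 7, 1))) == (0, 33)  # JPEG-style drift


def test_decode_rejects_off_lattice_pixels():
    with pytest.raises(IdentityDecodeError):
        decode_tile_identity(solid((12, 8, 0)))


def test_identity_capacity_limits():
    with pytest.raises(ValueError, match="1024 tiles"):
        SyntheticSlideSpec(width=16384, height=16384, n_layers=1)
    with pytest.raises(ValueError, match="32 layers"):
        SyntheticSlideSpec(n_layers=33)


def test_layer_scales_follow_downsample_chain():
    spec = SyntheticSlideSpec(n_layers=3, downsample=2)
    assert [spec.layer_scale(l) for l in range(3)] == [0.25, 0.5, 1.0]
    spec4 = SyntheticSlideSpec(n_layers=2, downsample=4, width=512, height=512)
    assert [spec4.layer_scale(l) for l in range(2)] == [0.25, 1.0]


def test_every_generated_tile_decodes_to_its_address(identity_slide):
    handle = open_slide(identity_slide.path)
    try:
        for l, layer in enumerate(handle.metadata.layers):
            for t in range(layer.tile_count):
                with Image.open(io.BytesIO(handle.read_tile(l, t))) as img:
                    pixels = np.asarray(img.convert("RGB"))
                assert pixels.shape == (256, 256, 3)
                assert decode_tile_identity(pixels) == (l, t)
    finally:
        handle.close()


def test_pyramid_mode_is_deterministic(tmp_path):
    spec = SyntheticSlideSpec(width=512, height=512, n_layers=2, mode="pyramid",
                              seed=5)
    generate_slide(spec, tmp_path / "a.iris")
    generate_slide(spec, tmp_path / "b.iris")
    assert (tmp_path / "a.iris").read_bytes() == (tmp_path / "b.iris").read_bytes()
    generate_slide(
        SyntheticSlideSpec(width=512, height=512, n_layers=2, mode="pyramid",
                           seed=6),
        tmp_path / "c.iris",
    )
    assert (tmp_path / "a.iris").read_bytes() != (tmp_path / "c.iris").read_bytes()


def test_block_mean_preserves_global_mean(tmp_path):
    """Each pyramid level keeps the global pixel mean within 1 grey level."""
    slide = generate_slide(
        SyntheticSlideSpec(width=1024, height=768, n_layers=3, mode="pyramid",
                           seed=3),
        tmp_path / "p.iris",
    )
    means = [level.mean() for level in slide.level_pixels]
    for lo, hi in zip(means, means[1:]):
        assert abs(lo - hi) <= 1.0


def test_block_mean_downsample_of_constant_blocks():
    image = np.zeros((4, 4, 3), dtype=np.uint8)
    image[:2, :2] = 10
    image[:2, 2:] = 20
    image[2:, :2] = 30
    image[2:, 2:] = 40
    out = block_mean_downsample(image, 2)
    assert out[:, :, 0].tolist() == [[10, 20], [30, 40]]


def test_dzi_levels_and_interior_byte_reuse(tmp_path):
    slide = generate_slide(
        SyntheticSlideSpec(width=512, height=512, n_layers=2), tmp_path / "d.iris"
    )
    descriptor = export_dzi(slide.path, tmp_path / "dzi", "d")
    meta = slide.metadata
    assert [dzi_level_for_layer(meta, l) for l in range(2)] == [8, 9]
    root = ET.parse(descriptor).getroot()
    assert root.attrib["TileSize"] == "256" and root.attrib["Overlap"] == "0"
    size = root.find("{http://schemas.microsoft.com/deepzoom/2008}Size")
    assert (size.attrib["Width"], size.attrib["Height"]) == ("512", "512")

    handle = open_slide(slide.path)
    try:
        # every tile of this slide is interior: bytes are reused unchanged
        for l, dzi_level in ((0, 8), (1, 9)):
            for t in range(meta.layers[l].tile_count):
                tx, ty = t % meta.layers[l].x_tiles, t // meta.layers[l].x_tiles
                path = tmp_path / "dzi" / "d_files" / str(dzi_level) / f"{tx}_{ty}.jpg"
                assert path.read_bytes() == handle.read_tile(l, t)
    finally:
        handle.close()


def test_dzi_edge_tiles_match_cropped_originals(tmp_path):
    slide = generate_slide(
        SyntheticSlideSpec(width=600, height=500, n_layers=2, mode="pyramid",
                           jpeg_quality=92, seed=9),
        tmp_path / "e.iris",
    )
    export_dzi(slide.path, tmp_path / "dzi", "e")
    meta = slide.metadata
    handle = open_slide(slide.path)
    try:
        checked = 0
        for l in range(2):
            layer = meta.layers[l]
            pw, ph = meta.layer_pixel_extent(l)
            dzi_level = dzi_level_for_layer(meta, l)
            for t in range(layer.tile_count):
                tx, ty = t % layer.x_tiles, t // layer.x_tiles
                w = min(256, pw - tx * 256)
                h = min(256, ph - ty * 256)
                tile_path = (
                    tmp_path / "dzi" / "e_files" / str(dzi_level) / f"{tx}_{ty}.jpg"
                )
                with Image.open(tile_path) as img:
                    exported = np.asarray(img.convert("RGB"), dtype=float)
                with Image.open(io.BytesIO(handle.read_tile(l, t))) as img:
                    original = np.asarray(img.convert("RGB"), dtype=float)[:h, :w]
                if (w, h) == (256, 256):
                    continue
                assert exported.shape == (h, w, 3)  # true size, padding cropped
                assert np.abs(exported - original).mean() <= 2.0
                checked += 1
        assert checked > 0
    finally:
        handle.close()


def test_dzi_export_requires_2x_pyramid(tmp_path):
    slide = generate_slide(
        SyntheticSlideSpec(width=512, height=512, n_layers=2, downsample=4),
        tmp_path / "f.iris",
    )
    with pytest.raises(ValueError, match="2x"):
        export_dzi(slide.path, tmp_path / "dzi", "f")


def test_dzi_level_arithmetic_general():
    spec = SyntheticSlideSpec(width=1024, height=1024, n_layers=3)
    meta = spec.metadata()
    assert math.ceil(math.log2(1024)) == 10
    assert [dzi_level_for_layer(meta, l) for l in range(3)] == [8, 9, 10]
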