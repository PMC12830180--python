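"""The on-disk pyramidal slide container: write, validate, map, read.

Byte layout (all integers little-endian)::

    offset 0   magic            4 bytes, b"IRST"
    offset 4   format version   uint16 (currently 1)
    offset 6   flags            uint16 (reserved, 0)
    offset 8   metadata length  uint32 (bytes of UTF-8 JSON that follow)
    offset 12  tile count       uint32 (entries in the tile table; must equal
                                the metadata's total tile count)
    offset 16  metadata block   JSON document (the SlideMetadata contract)
    ...        tile table       one (uint64 offset, uint32 length) pair per
                                tile, layers in stored (ascending-scale)
                                order, raster order within a layer
    ...        tile payloads    concatenated compressed tile bytestreams
    EOF-4      checksum         uint32 CRC32 of every preceding byte

Every container is fully validated -- magic, version, metadata geometry,
table bounds and overlap, tile counts, checksum -- before a single tile is
served. Validation is detection only: a container that fails any check is
refused, never repaired.
"""

from __future__ import annotations

import io
import json
import mmap
import os
import struct
import threading
import zlib
from dataclasses import dataclass

from iris_restful.metadata import MetadataError, SlideMetadata

MAGIC = b"IRST"
FORMAT_VERSION = 1
CONTAINER_SUFFIX = ".iris"

_HEADER = struct.Struct("<4sHHII")
_TABLE_ENTRY = struct.Struct("<QI")
_CRC = struct.Struct("<I")


class ValidationError(Exception):
    """Base class for container validation failures.

    ``narrative`` is a human-readable plain-text explanation, suitable for
    an HTTP error body.
    """

    @property
    def narrative(self) -> str:
        return str(self)


class BadMagicError(ValidationError):
    """The file does not start with the container magic bytes."""


class UnsupportedVersionError(ValidationError):
    """The container format version is not one this reader understands."""


class CorruptMetadataError(ValidationError):
    """The embedded metadata block is unparseable or geometrically invalid."""


class TableBoundsError(ValidationError):
    """A tile-table entry points outside the file, or the file is too short."""


class TileCountMismatchError(ValidationError):
    """The tile table disagrees with the metadata's total tile count."""


class ChecksumError(ValidationError):
    """The trailing whole-file CRC32 does not verify."""


def build_container_bytes(
    metadata: SlideMetadata,
    tiles: list[bytes],
    *,
    table_entries: list[tuple[int, int]] | None = None,
) -> bytes:
    """Serialise a container to bytes.

    ``table_entries`` overrides the computed tile table (and the count
    precondition); it exists so tests can craft deliberately inconsistent
    containers.
    """
    metadata.validate()
    if table_entries is None and len(tiles) != metadata.total_tiles:
        raise ValueError(
            f"got {len(tiles)} tile payloads but metadata declares "
            f"{metadata.total_tiles} tiles"
        )
    for i, payload in enumerate(tiles):
        if not payload:
            raise ValueError(f"tile payload {i} is empty")

    meta_bytes = json.dumps(metadata.to_dict(), separators=(",", ":")).encode()
    table = table_entries
    if table is None:
        data_start = _HEADER.size + len(meta_bytes) + _TABLE_ENTRY.size * len(tiles)
        table = []
        offset = data_start
        for payload in tiles:
            table.append((offset, len(payload)))
            offset += len(payload)

    buf = io.BytesIO()
    buf.write(_HEADER.pack(MAGIC, FORMAT_VERSION, 0, len(meta_bytes), len(table)))
    buf.write(meta_bytes)
    for entry in table:
        buf.write(_TABLE_ENTRY.pack(*entry))
    for payload in tiles:
        buf.write(payload)
    buf.write(_CRC.pack(zlib.crc32(buf.getvalue())))
    return buf.getvalue()


def write_container(path: str | os.PathLike, metadata: SlideMetadata, tiles: list[bytes]) -> str:
    """Write a slide container; returns the path written.

    ``tiles`` must hold exactly ``metadata.total_tiles`` non-empty compressed
    payloads, layers in stored order, raster order within each layer.
    """
    data = build_container_bytes(metadata, list(tiles))
    path = os.fspath(path)
    with open(path, "wb") as fh:
        fh.write(data)
    return path


def _parse_table(
    data: bytes, metadata: SlideMetadata, table_start: int
) -> list[tuple[int, int]]:
    n = metadata.total_tiles
    table_end = table_start + _TABLE_ENTRY.size * n
    data_end = len(data) - _CRC.size
    if table_end > data_end:
        raise TileCountMismatchError(
            f"tile table needs {table_end - table_start} bytes for "
            f"{n} declared tiles but only {max(data_end - table_start, 0)} remain"
        )
    entries: list[tuple[int, int]] = []
    for i in range(n):
        off, length = _TABLE_ENTRY.unpack_from(data, table_start + i * _TABLE_ENTRY.size)
        if length <= 0:
            raise TableBoundsError(f"tile {i} has non-positive length {length}")
        if off < table_end or off + length > data_end:
            raise TableBoundsError(
                f"tile {i} region [{off}, {off + length}) falls outside the "
                f"payload area [{table_end}, {data_end})"
            )
        entries.append((off, length))
    # Regions must not overlap each other.
    last_end = table_end
    for off, length in sorted(entries):
        if off < last_end:
            raise TableBoundsError("tile payload regions overlap")
        last_end = off + length
    return entries


def _validate_bytes(data: bytes) -> tuple[SlideMetadata, list[tuple[int, int]]]:
    if len(data) < _HEADER.size + _CRC.size:
        raise TableBoundsError(
            f"file of {len(data)} bytes is shorter than the fixed header"
        )
    magic, version, _flags, meta_len, tile_count = _HEADER.unpack_from(data, 0)
    if magic != MAGIC:
        raise BadMagicError(f"bad magic bytes {magic!r}, expected {MAGIC!r}")
    if version != FORMAT_VERSION:
        raise UnsupportedVersionError(
            f"unsupported container version {version}, expected {FORMAT_VERSION}"
        )
    meta_end = _HEADER.size + meta_len
    if meta_end > len(data) - _CRC.size:
        raise TableBoundsError(
            f"declared metadata block of {meta_len} bytes overruns the file"
        )
    try:
        meta_doc = json.loads(data[_HEADER.size:meta_end])
        metadata = SlideMetadata.from_dict(meta_doc)
    except (ValueError, MetadataError) as exc:
        raise CorruptMetadataError(f"metadata block failed validation: {exc}") from exc
    if tile_count != metadata.total_tiles:
        raise TileCountMismatchError(
            f"metadata declares {metadata.total_tiles} tiles but the tile "
            f"table holds {tile_count} entries"
        )
    entries = _parse_table(data, metadata, meta_end)
    (stored_crc,) = _CRC.unpack_from(data, len(data) - _CRC.size)
    actual_crc = zlib.crc32(data[: -_CRC.size])
    if stored_crc != actual_crc:
        raise ChecksumError(
            f"checksum mismatch: stored {stored_crc:#010x}, "
            f"computed {actual_crc:#010x}"
        )
    return metadata, entries


def validate_container(path: str | os.PathLike) -> SlideMetadata:
    """Run every container invariant check; return the parsed metadata.

    Raises a :class:`ValidationError` subclass naming the first failed check.
    """
    with open(path, "rb") as fh:
        data = fh.read()
    metadata, _ = _validate_bytes(data)
    return metadata


@dataclass
class _LayerSlice:
    start: int  # index of the layer's first entry in the tile table
    count: int


class SlideHandle:
    """An open, validated, memory-mapped container.

    Tile reads slice the mapped view directly; nothing is re-parsed per
    request. ``refcount`` counts the live client sessions sharing the handle
    (managed by the server's handle cache); the mapping is released exactly
    when the count returns to zero.
    """

    def __init__(self, path: str | os.PathLike):
        self.path = os.path.realpath(os.fspath(path))
        with open(self.path, "rb") as fh:
            self._mm = mmap.mmap(fh.fileno(), 0, access=mmap.ACCESS_READ)
        try:
            self.metadata, self._table = _validate_bytes(self._mm[:])
        except ValidationError:
            self._mm.close()
            raise
        self._layers: list[_LayerSlice] = []
        start = 0
        for layer in self.metadata.layers:
            self._layers.append(_LayerSlice(start, layer.tile_count))
            start += layer.tile_count
        self.refcount = 1
        self._lock = threading.Lock()
        self._closed = False

    def read_tile(self, layer: int, t: int) -> bytes:
        """Return the stored compressed payload of tile ``t`` of ``layer``."""
        if not 0 <= layer < len(self._layers):
            raise IndexError(
                f"layer {layer} out of range for {len(self._layers)}-layer slide"
            )
        sl = self._layers[layer]
        if not 0 <= t < sl.count:
            raise IndexError(
                f"tile index {t} out of range for layer {layer} with {sl.count} tiles"
            )
        off, length = self._table[sl.start + t]
        return self._mm[off : off + length]

    def incref(self) -> None:
        with self._lock:
            self.refcount += 1

    def decref(self) -> int:
        with self._lock:
            self.refcount -= 1
            remaining = self.refcount
        if remaining == 0:
            self.close()
        return remaining

    def close(self) -> None:
        with self._lock:
            if not self._closed:
                self._mm.close()
                self._closed = True

    @property
    def closed(self) -> bool:
        return self._closed


def open_slide(path: str | os.PathLike) -> SlideHandle:
    """Validate and memory-map a container, returning a handle with refcount 1."""
    return SlideHandle(path)


def read_tile(handle: SlideHandle, layer: int, t: int) -> bytes:
    """Functional alias for :meth:`SlideHandle.read_tile`."""
    return handle.read_tile(layer, t)
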