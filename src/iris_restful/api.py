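"""Strict request parsing for the two API dialects, and the error taxonomy.

Exactly four GET targets touch slide data::

    /slides/{slide}/metadata                               (iris)
    /slides/{slide}/layers/{l}/tiles/{t}                   (iris)
    /studies/{s}/series/{slide}/metadata                   (wado)
    /studies/{s}/series/{slide}/instances/{i}/frames/{f}   (wado)

Anything else -- wrong verb, extra or missing segments, non-decimal indices,
empty identifiers, a ``..`` or percent-encoded separator in an identifier --
is rejected before any file-system access. When a document root is
configured, unmatched GET targets may instead resolve to restricted static
file service; the same traversal rules apply.

The WADO dialect follows the DICOM convention of 1-based instances and
frames: instance ``i`` is pyramid layer ``i - 1`` and frame ``f`` is raster
tile ``f - 1``. Only single-frame requests are served.

Errors are plain-text: an HTTP status plus a one-line narrative.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from typing import Union

from iris_restful.metadata import MetadataError, SlideMetadata

#: characters permitted in a slide identifier (one path segment, no traversal)
_ID_RE = re.compile(r"^[A-Za-z0-9][A-Za-z0-9._~-]*$")
_DECIMAL_RE = re.compile(r"^[0-9]+$")


@dataclass(frozen=True)
class ErrorBody:
    """An HTTP error: status code plus a plain-text narrative."""

    http_status: int
    narrative: str

    def __post_init__(self) -> None:
        if not self.narrative:
            raise ValueError("error narrative must be non-empty")


@dataclass(frozen=True)
class ParsedRequest:
    """A strictly validated API request."""

    dialect: str  # "iris" | "wado" | "static"
    slide_id: str = ""
    resource: str = ""  # "metadata" | "tile" | "file"
    layer: int | None = None
    tile: int | None = None
    file_path: str | None = None


@dataclass(frozen=True)
class HttpResponse:
    """A fully rendered HTTP response (status, content type, body)."""

    status: int
    body: bytes
    content_type: str = "text/plain; charset=utf-8"
    headers: dict = field(default_factory=dict)


def build_error(status: int, narrative: str) -> HttpResponse:
    """Render an error as a plain-text HTTP response."""
    return HttpResponse(status=status, body=narrative.encode("utf-8", "replace"))


def error_response(err: ErrorBody) -> HttpResponse:
    return build_error(err.http_status, err.narrative)


def _traversal(segment: str) -> bool:
    # '..' anywhere, a percent-encoded separator, or a backslash in an
    # identifier is treated as a path-traversal attempt.
    return ".." in segment or "%" in segment or "\\" in segment


def _check_id(segment: str) -> ErrorBody | None:
    if _traversal(segment):
        return ErrorBody(403, f"path traversal attempt in identifier {segment!r}")
    if not _ID_RE.match(segment):
        return ErrorBody(400, f"malformed identifier {segment!r}")
    return None


def _check_index(segment: str, what: str) -> ErrorBody | None:
    if _traversal(segment):
        return ErrorBody(403, f"path traversal attempt in {what} {segment!r}")
    if not _DECIMAL_RE.match(segment):
        return ErrorBody(400, f"{what} must be a decimal integer, got {segment!r}")
    return None


def wado_frame_to_tile(instance: str, frame: str) -> Union[tuple[int, int], ErrorBody]:
    """Map a 1-based WADO (instance, frame) pair to a 0-based (layer, t).

    DICOM instances and frames are numbered from 1; a comma-separated frame
    list (the multi-frame form) is refused -- only single-frame retrieval is
    supported.
    """
    if "," in frame:
        return ErrorBody(
            400,
            "multi-frame retrieval is not supported: request a single frame "
            f"per call, got frame list {frame!r}",
        )
    for value, what in ((instance, "instance"), (frame, "frame")):
        err = _check_index(value, what)
        if err is not None:
            return err
    i, f = int(instance), int(frame)
    if i == 0 or f == 0:
        return ErrorBody(400, "WADO instance and frame numbers are 1-based; 0 is invalid")
    return i - 1, f - 1


def parse_target(
    method: str, target: str, *, allow_static: bool = False
) -> Union[ParsedRequest, ErrorBody]:
    """Parse an HTTP request line into a validated request, or reject it.

    Never raises and never touches the file system: every outcome is a
    :class:`ParsedRequest` or an :class:`ErrorBody` (400 malformed, 403
    traversal, 405 bad verb).
    """
    if method not in ("GET", "OPTIONS"):
        return ErrorBody(405, f"method {method} not allowed; use GET or OPTIONS")
    if not target.startswith("/"):
        return ErrorBody(400, f"request target must be an absolute path, got {target!r}")
    if "?" in target or "#" in target:
        return ErrorBody(400, "query strings and fragments are not accepted")
    if "\\" in target or "%" in target:
        return ErrorBody(403, "encoded separators are not accepted in request targets")
    if ".." in target:
        return ErrorBody(403, f"path traversal attempt in target {target!r}")

    segments = target.split("/")[1:]
    if segments and segments[-1] == "":  # tolerate exactly one trailing slash? no: strict
        return ErrorBody(400, "trailing slash is not part of any API target")
    if any(seg == "" for seg in segments):
        return ErrorBody(400, "empty path segment in request target")

    if segments[0] == "slides":
        if len(segments) == 3 and segments[2] == "metadata":
            err = _check_id(segments[1])
            if err:
                return err
            return ParsedRequest("iris", slide_id=segments[1], resource="metadata")
        if len(segments) == 6 and segments[2] == "layers" and segments[4] == "tiles":
            for check in (
                _check_id(segments[1]),
                _check_index(segments[3], "layer index"),
                _check_index(segments[5], "tile index"),
            ):
                if check:
                    return check
            return ParsedRequest(
                "iris",
                slide_id=segments[1],
                resource="tile",
                layer=int(segments[3]),
                tile=int(segments[5]),
            )
        return ErrorBody(400, f"target {target!r} does not match the slide API")

    if segments[0] == "studies":
        if len(segments) == 5 and segments[2] == "series" and segments[4] == "metadata":
            for check in (_check_id(segments[1]), _check_id(segments[3])):
                if check:
                    return check
            return ParsedRequest("wado", slide_id=segments[3], resource="metadata")
        if (
            len(segments) == 8
            and segments[2] == "series"
            and segments[4] == "instances"
            and segments[6] == "frames"
        ):
            for check in (_check_id(segments[1]), _check_id(segments[3])):
                if check:
                    return check
            mapped = wado_frame_to_tile(segments[5], segments[7])
            if isinstance(mapped, ErrorBody):
                return mapped
            layer, tile = mapped
            return ParsedRequest(
                "wado", slide_id=segments[3], resource="tile", layer=layer, tile=tile
            )
        return ErrorBody(400, f"target {target!r} does not match the WADO-RS mapping")

    if allow_static:
        # Segments are already screened for '..', '%' and '\'; keep only
        # conservatively named path components.
        for seg in segments:
            if not _ID_RE.match(seg):
                return ErrorBody(400, f"malformed static path segment {seg!r}")
        return ParsedRequest("static", resource="file", file_path="/".join(segments))

    return ErrorBody(400, f"target {target!r} does not match any API route")


def metadata_to_json(meta: SlideMetadata) -> str:
    """Serialise slide metadata to its canonical JSON document.

    Key order and separators are fixed, so serialise -> parse -> serialise
    is byte-stable.
    """
    return json.dumps(meta.to_dict(), separators=(",", ":"))


def metadata_from_json(document: str | bytes) -> SlideMetadata:
    """Parse the served JSON document back into :class:`SlideMetadata`."""
    try:
        doc = json.loads(document)
    except json.JSONDecodeError as exc:
        raise MetadataError(f"metadata document is not valid JSON: {exc}") from exc
    return SlideMetadata.from_dict(doc)


def cors_headers(origin: str | None, method: str = "GET") -> dict:
    """CORS response headers for a configured origin policy.

    ``origin`` of ``None`` disables CORS entirely; the value ``"anonymous"``
    (or ``"*"``) allows any origin.
    """
    if origin is None:
        return {}
    value = "*" if origin.lower() in ("anonymous", "*") else origin
    headers = {"Access-Control-Allow-Origin": value}
    if method == "OPTIONS":
        headers["Access-Control-Allow-Methods"] = "GET, OPTIONS"
        headers["Access-Control-Allow-Headers"] = "Content-Type"
    return headers
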