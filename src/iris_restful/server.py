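"""The two-stack tile service.

The service separates network work from slide work:

- the **network stack** (one thread per live connection) accepts
  connections, strictly parses request targets, and immediately rejects
  anything malformed;
- the **file-system stack** (a single FIFO queue drained by a configurable
  pool of worker threads) owns every container access: validation, handle
  opening, metadata serialisation and tile reads.

A slow or stalled slide read therefore never blocks connection acceptance or
the rejection of bad requests, and file-system jobs complete in submission
order per worker pool. Any exception inside a job is caught per-request and
converted to a 500 response; the worker then proceeds with the next item.

Open containers are memory-mapped once and shared: the handle cache keys
handles by canonical path and reference-counts the client sessions (HTTP
connections) that touched each slide. The mapping is released exactly when
the last referencing session closes.
"""

from __future__ import annotations

import json
import logging
import os
import queue
import ssl
import subprocess
import tempfile
import threading
import time
from concurrent.futures import Future
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from iris_restful import api
from iris_restful.api import ErrorBody, HttpResponse, ParsedRequest
from iris_restful.container import CONTAINER_SUFFIX, SlideHandle, ValidationError

logger = logging.getLogger("iris_restful.server")

#: extensions the restricted static-file mode will serve; container files are
#: always refused regardless of location.
STATIC_ALLOW_LIST = frozenset(
    {".html", ".htm", ".js", ".css", ".json", ".xml", ".dzi", ".png",
     ".jpg", ".jpeg", ".ico", ".svg", ".wasm"}
)

_STATIC_CONTENT_TYPES = {
    ".html": "text/html; charset=utf-8",
    ".htm": "text/html; charset=utf-8",
    ".js": "text/javascript",
    ".css": "text/css",
    ".json": "application/json",
    ".xml": "application/xml",
    ".dzi": "application/xml",
    ".png": "image/png",
    ".jpg": "image/jpeg",
    ".jpeg": "image/jpeg",
    ".ico": "image/x-icon",
    ".svg": "image/svg+xml",
    ".wasm": "application/wasm",
}


@dataclass
class ServerConfig:
    """Runtime configuration.

    Parameters
    ----------
    slide_dir:
        Directory holding the ``.iris`` slide containers (required).
    document_root:
        Optional directory for restricted static file service; when unset,
        only the two slide API dialects are served.
    origin:
        CORS policy: ``None`` disables CORS headers, ``"anonymous"`` (or
        ``"*"``) allows any origin, any other value is echoed verbatim.
    port:
        TCP port; 0 picks a free port.
    tls:
        ``"off"``, ``"self-signed"`` (a 2048-bit RSA certificate is
        generated at startup) or ``"custom"`` (``cert_file``/``key_file``).
    fs_workers:
        Thread count of the file-system stack; defaults to the CPU count.
    tile_delay:
        Test hook: seconds each tile read sleeps inside its worker, used to
        demonstrate stack decoupling and FIFO ordering.
    debug:
        Enables the ``/internal/handles`` introspection route.
    """

    slide_dir: str
    document_root: str | None = None
    origin: str | None = None
    host: str = "127.0.0.1"
    port: int = 0
    tls: str = "off"
    cert_file: str | None = None
    key_file: str | None = None
    fs_workers: int | None = None
    tile_delay: float = 0.0
    debug: bool = False

    def __post_init__(self) -> None:
        self.slide_dir = os.path.realpath(self.slide_dir)
        if not os.path.isdir(self.slide_dir):
            raise ValueError(f"slide directory {self.slide_dir!r} does not exist")
        if self.document_root is not None:
            self.document_root = os.path.realpath(self.document_root)
            if not os.path.isdir(self.document_root):
                raise ValueError(
                    f"document root {self.document_root!r} does not exist"
                )
        if self.tls not in ("off", "self-signed", "custom"):
            raise ValueError(f"tls must be off, self-signed or custom, got {self.tls!r}")
        if self.tls == "custom" and not (self.cert_file and self.key_file):
            raise ValueError("tls='custom' requires cert_file and key_file")
        if self.fs_workers is None:
            self.fs_workers = os.cpu_count() or 1
        if self.fs_workers < 1:
            raise ValueError("fs_workers must be positive")


class HandleCache:
    """Canonical-path keyed cache of shared, reference-counted slide handles."""

    def __init__(self) -> None:
        self._lock = threading.Lock()
        self._handles: dict[str, SlideHandle] = {}

    def acquire(self, path: str) -> SlideHandle:
        """Return the shared handle for ``path``, opening it on first use.

        A cache hit increments the refcount; a miss validates and
        memory-maps the container (refcount 1). Raises
        ``FileNotFoundError`` or :class:`ValidationError` on a miss without
        mutating the cache.
        """
        path = os.path.realpath(path)
        with self._lock:
            handle = self._handles.get(path)
            if handle is not None:
                handle.incref()
                return handle
            handle = SlideHandle(path)  # refcount starts at 1
            self._handles[path] = handle
            return handle

    def release(self, path: str) -> None:
        """Drop one session reference; evict and unmap at zero."""
        path = os.path.realpath(path)
        with self._lock:
            handle = self._handles.get(path)
            if handle is None:
                return
            if handle.decref() == 0:
                del self._handles[path]

    def stats(self) -> dict[str, int]:
        with self._lock:
            return {p: h.refcount for p, h in self._handles.items()}

    def clear(self) -> None:
        with self._lock:
            for handle in self._handles.values():
                handle.close()
            self._handles.clear()


class _FsStack:
    """A single FIFO queue drained by N worker threads.

    Exceptions raised by a job land in its future; the worker moves on.
    """

    _SENTINEL = object()

    def __init__(self, workers: int) -> None:
        self._queue: queue.SimpleQueue = queue.SimpleQueue()
        self._threads = [
            threading.Thread(target=self._run, name=f"iris-fs-{i}", daemon=True)
            for i in range(workers)
        ]
        for t in self._threads:
            t.start()

    def _run(self) -> None:
        while True:
            item = self._queue.get()
            if item is self._SENTINEL:
                return
            fn, future = item
            if not future.set_running_or_notify_cancel():
                continue
            try:
                future.set_result(fn())
            except BaseException as exc:  # contain every fault in the response
                future.set_exception(exc)

    def submit(self, fn) -> Future:
        future: Future = Future()
        self._queue.put((fn, future))
        return future

    def close(self) -> None:
        for _ in self._threads:
            self._queue.put(self._SENTINEL)
        for t in self._threads:
            t.join(timeout=5)


def generate_self_signed_cert(
    out_dir: str, *, key_bits: int = 2048, common_name: str = "localhost",
    days: int = 30,
) -> tuple[str, str]:
    """Generate a self-signed RSA certificate; returns (cert_path, key_path).

    The key modulus is ``key_bits`` (default 2048) bits.
    """
    cert_path = os.path.join(out_dir, "iris-selfsigned-cert.pem")
    key_path = os.path.join(out_dir, "iris-selfsigned-key.pem")
    cmd = [
        "openssl", "req", "-x509", "-newkey", f"rsa:{key_bits}", "-nodes",
        "-keyout", key_path, "-out", cert_path, "-days", str(days),
        "-subj", f"/CN={common_name}",
    ]
    proc = subprocess.run(cmd, capture_output=True, text=True)
    if proc.returncode != 0:
        raise RuntimeError(f"self-signed certificate generation failed: {proc.stderr}")
    return cert_path, key_path


def certificate_rsa_bits(cert_path: str) -> int:
    """Bit length of the RSA modulus of an X.509 certificate's public key."""
    proc = subprocess.run(
        ["openssl", "x509", "-noout", "-modulus", "-in", cert_path],
        capture_output=True, text=True, check=True,
    )
    modulus_hex = proc.stdout.strip().split("=", 1)[1]
    return int(modulus_hex, 16).bit_length()


class _Handler(BaseHTTPRequestHandler):
    protocol_version = "HTTP/1.1"
    server_version = "IrisRESTful/0.1"
    timeout = 60
    # headers and body go out as separate writes; without this, Nagle +
    # delayed ACK adds ~40 ms to every small response
    disable_nagle_algorithm = True

    # one instance == one client connection == one session
    def setup(self) -> None:
        super().setup()
        self._session: dict[str, SlideHandle] = {}
        self._session_lock = threading.Lock()

    def finish(self) -> None:
        try:
            super().finish()
        finally:
            iris: IrisServer = self.server.iris  # type: ignore[attr-defined]
            with self._session_lock:
                paths = list(self._session)
                self._session.clear()
            for path in paths:
                iris.cache.release(path)

    # -- network stack ----------------------------------------------------
    def do_GET(self) -> None:
        start = time.perf_counter()
        iris: IrisServer = self.server.iris  # type: ignore[attr-defined]
        cfg = iris.config
        if cfg.debug and self.path == "/internal/handles":
            self._send(
                HttpResponse(200, json.dumps(iris.cache.stats()).encode(),
                             "application/json"),
                start,
            )
            return
        parsed = api.parse_target(
            "GET", self.path, allow_static=cfg.document_root is not None
        )
        if isinstance(parsed, ErrorBody):
            # rejected on the network stack: no file-system work at all
            self._send(api.error_response(parsed), start)
            return
        future = iris.stack.submit(lambda: iris.execute(parsed, self._session,
                                                        self._session_lock))
        try:
            response = future.result()
        except Exception as exc:
            logger.exception("file-system stack fault for %s", self.path)
            response = api.build_error(500, f"internal server error: {exc}")
        self._send(response, start)

    def do_OPTIONS(self) -> None:
        start = time.perf_counter()
        self._send(HttpResponse(204, b""), start)

    def _method_not_allowed(self) -> None:
        start = time.perf_counter()
        self._send(
            api.build_error(
                405, f"method {self.command} not allowed; use GET or OPTIONS"
            ),
            start,
        )

    def __getattr__(self, name: str):
        # any verb without an explicit handler is answered 405, not 501
        if name.startswith("do_"):
            return self._method_not_allowed
        raise AttributeError(name)

    def _send(self, response: HttpResponse, start: float) -> None:
        iris: IrisServer = self.server.iris  # type: ignore[attr-defined]
        try:
            self.send_response(response.status)
            self.send_header("Content-Type", response.content_type)
            self.send_header("Content-Length", str(len(response.body)))
            for key, value in response.headers.items():
                self.send_header(key, value)
            for key, value in api.cors_headers(
                iris.config.origin, self.command or "GET"
            ).items():
                self.send_header(key, value)
            self.end_headers()
            if response.body:
                self.wfile.write(response.body)
        except (BrokenPipeError, ConnectionResetError):
            self.close_connection = True
        latency_ms = (time.perf_counter() - start) * 1e3
        logger.info(
            "%s %s %d %.2fms", self.command, self.path, response.status, latency_ms
        )

    def log_message(self, format: str, *args) -> None:  # stdlib chatter -> logging
        logger.debug(format, *args)


class IrisServer:
    """The running service; also usable as a context manager in tests.

    ``start()`` binds the socket (TLS-wrapped if configured) and serves in a
    background thread; ``base_url`` reports the bound address.
    """

    def __init__(self, config: ServerConfig) -> None:
        self.config = config
        self.cache = HandleCache()
        self.stack = _FsStack(config.fs_workers)
        self._httpd = ThreadingHTTPServer((config.host, config.port), _Handler)
        self._httpd.daemon_threads = True
        self._httpd.iris = self  # type: ignore[attr-defined]
        self._thread: threading.Thread | None = None
        self._tls_dir: tempfile.TemporaryDirectory | None = None
        self.cert_file = config.cert_file
        self.key_file = config.key_file
        if config.tls != "off":
            if config.tls == "self-signed" and not self.cert_file:
                self._tls_dir = tempfile.TemporaryDirectory(prefix="iris-tls-")
                self.cert_file, self.key_file = generate_self_signed_cert(
                    self._tls_dir.name
                )
            ctx = ssl.SSLContext(ssl.PROTOCOL_TLS_SERVER)
            ctx.load_cert_chain(self.cert_file, self.key_file)
            self._httpd.socket = ctx.wrap_socket(
                self._httpd.socket, server_side=True
            )

    # -- file-system stack ------------------------------------------------
    def execute(
        self,
        parsed: ParsedRequest,
        session: dict[str, SlideHandle],
        session_lock: threading.Lock,
    ) -> HttpResponse:
        """Run one validated request on the file-system stack."""
        if parsed.resource == "file":
            return self._static_fetch(parsed.file_path or "")
        slide_path = os.path.join(
            self.config.slide_dir, parsed.slide_id + CONTAINER_SUFFIX
        )
        slide_path = os.path.realpath(slide_path)
        if os.path.dirname(slide_path) != self.config.slide_dir:
            return api.build_error(403, "slide identifier escapes the slide directory")
        with session_lock:
            handle = session.get(slide_path)
        if handle is None:
            try:
                handle = self.cache.acquire(slide_path)
            except FileNotFoundError:
                return api.build_error(
                    404, f"no slide named {parsed.slide_id!r} is available"
                )
            except ValidationError as exc:
                return api.build_error(
                    500, f"slide {parsed.slide_id!r} failed validation: {exc.narrative}"
                )
            with session_lock:
                session[slide_path] = handle
        meta = handle.metadata
        if parsed.resource == "metadata":
            return HttpResponse(
                200, api.metadata_to_json(meta).encode(), "application/json"
            )
        assert parsed.resource == "tile" and parsed.layer is not None
        if parsed.layer >= len(meta.layers):
            return api.build_error(
                400,
                f"request range violation: layer {parsed.layer} out of range "
                f"for {len(meta.layers)}-layer slide",
            )
        layer = meta.layers[parsed.layer]
        if parsed.tile is None or parsed.tile >= layer.tile_count:
            return api.build_error(
                400,
                f"request range violation: tile {parsed.tile} out of range "
                f"for layer {parsed.layer} with {layer.tile_count} tiles",
            )
        if self.config.tile_delay:
            time.sleep(self.config.tile_delay)
        payload = handle.read_tile(parsed.layer, parsed.tile)
        content_type = "image/jpeg" if meta.encoding == "jpeg" else \
            "application/octet-stream"
        return HttpResponse(200, payload, content_type)

    def _static_fetch(self, rel_path: str) -> HttpResponse:
        """Serve a file from the document root, restricted by extension and scope."""
        root = self.config.document_root
        assert root is not None
        resolved = os.path.realpath(os.path.join(root, rel_path))
        if resolved != root and not resolved.startswith(root + os.sep):
            return api.build_error(403, "static path escapes the document root")
        ext = os.path.splitext(resolved)[1].lower()
        if ext == CONTAINER_SUFFIX:
            return api.build_error(
                403, "slide container files may not be downloaded as static files"
            )
        if ext not in STATIC_ALLOW_LIST:
            return api.build_error(
                403, f"file type {ext or '(none)'} is not on the static allow-list"
            )
        if not os.path.isfile(resolved):
            return api.build_error(404, f"no static file at {rel_path!r}")
        with open(resolved, "rb") as fh:
            body = fh.read()
        return HttpResponse(200, body, _STATIC_CONTENT_TYPES[ext])

    # -- lifecycle ---------------------------------------------------------
    def start(self) -> "IrisServer":
        self._thread = threading.Thread(
            target=self._httpd.serve_forever, name="iris-accept", daemon=True
        )
        self._thread.start()
        return self

    def stop(self) -> None:
        if self._thread is not None:  # shutdown() blocks unless serving
            self._httpd.shutdown()
        self._httpd.server_close()
        if self._thread is not None:
            self._thread.join(timeout=5)
        self.stack.close()
        self.cache.clear()
        if self._tls_dir is not None:
            self._tls_dir.cleanup()

    def __enter__(self) -> "IrisServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()

    @property
    def port(self) -> int:
        return self._httpd.server_address[1]

    @property
    def base_url(self) -> str:
        scheme = "https" if self.config.tls != "off" else "http"
        return f"{scheme}://{self.config.host}:{self.port}"
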