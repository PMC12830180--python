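"""Utilities for exercising a live server: raw HTTP, fuzz targets, polling."""

from __future__ import annotations

import random
import socket
import time
import urllib.error
import urllib.request


def http_get(url: str) -> tuple[int, dict, bytes]:
    """GET returning (status, headers, body) without raising on 4xx/5xx."""
    try:
        with urllib.request.urlopen(url, timeout=10) as resp:
            return resp.status, dict(resp.headers), resp.read()
    except urllib.error.HTTPError as exc:
        return exc.code, dict(exc.headers), exc.read()


class RawHttpClient:
    """A keep-alive HTTP/1.1 client speaking raw sockets.

    Used where urllib is too well-behaved: arbitrary byte-string request
    targets, arbitrary verbs, and persistent connections whose lifetime the
    caller controls (one connection == one server session).
    """

    def __init__(self, host: str, port: int, timeout: float = 10.0) -> None:
        self.host, self.port, self.timeout = host, port, timeout
        self._sock: socket.socket | None = None
        self._buf = b""

    def _connect(self) -> None:
        self._sock = socket.create_connection(
            (self.host, self.port), timeout=self.timeout
        )
        self._sock.setsockopt(socket.IPPROTO_TCP, socket.TCP_NODELAY, 1)
        self._buf = b""

    def _read_until(self, marker: bytes) -> bytes:
        while marker not in self._buf:
            chunk = self._sock.recv(65536)
            if not chunk:
                raise ConnectionError("server closed the connection")
            self._buf += chunk
        head, self._buf = self._buf.split(marker, 1)
        return head

    def _read_exact(self, n: int) -> bytes:
        while len(self._buf) < n:
            chunk = self._sock.recv(65536)
            if not chunk:
                raise ConnectionError("server closed the connection")
            self._buf += chunk
        body, self._buf = self._buf[:n], self._buf[n:]
        return body

    def request(self, target: str, method: str = "GET") -> tuple[int, bytes]:
        """Issue one request, reconnecting transparently if needed."""
        line = f"{method} {target} HTTP/1.1\r\nHost: t\r\n\r\n".encode("latin-1")
        for attempt in (0, 1):
            if self._sock is None:
                self._connect()
            try:
                self._sock.sendall(line)
                head = self._read_until(b"\r\n\r\n").decode("latin-1")
                break
            except (ConnectionError, OSError):
                self.close()
                if attempt:
                    raise
        status = int(head.split(None, 2)[1])
        headers = {}
        for header_line in head.split("\r\n")[1:]:
            key, _, value = header_line.partition(":")
            headers[key.strip().lower()] = value.strip()
        body = self._read_exact(int(headers.get("content-length", "0")))
        if headers.get("connection", "").lower() == "close":
            self.close()
        return status, body

    def close(self) -> None:
        if self._sock is not None:
            try:
                self._sock.close()
            finally:
                self._sock = None
                self._buf = b""


def fuzz_targets(seed: int, n: int):
    """Deterministic stream of adversarial request targets."""
    rng = random.Random(seed)
    charset = (
        "abcdefghijklmnopqrstuvwxyzABCDEFGHIJ0123456789"
        "/._-%~\\:;=&?#[]@!$'()*+,"
    )
    for _ in range(n):
        length = rng.randint(1, 48)
        target = "".join(rng.choice(charset) for _ in range(length))
        if rng.random() < 0.85:
            target = "/" + target
        if rng.random() < 0.3:
            stem = rng.choice(
                ["/slides/", "/slides/s1/", "/studies/a/series/s1/", "/slides/../"]
            )
            target = stem + target.lstrip("/")
        yield target


def wait_until(predicate, timeout: float = 5.0, interval: float = 0.02) -> bool:
    """Poll ``predicate`` until true or the timeout elapses."""
    deadline = time.perf_counter() + timeout
    while time.perf_counter() < deadline:
        if predicate():
            return True
        time.sleep(interval)
    return predicate()
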