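"""Ramped virtual-user load harness.

Virtual users are started at a fixed ramp rate. Each user fetches the slide
metadata once to learn the pyramid bounds, then loops: draw a uniformly
random in-bounds (layer, x, y) tile, GET it, record the latency, and sleep a
uniformly random think time (default 1-2 ms) before the next request. There
is no client-side caching; every request goes to the server.

The report aggregates fixed-width time windows into rows of request count,
failure count and latency percentiles (50/75/95), and can be written as CSV.
Tile sampling is deterministic per seed: user ``i`` draws its coordinate
sequence from its own generator seeded by ``(seed, i)``, so the sequence of
sampled tiles is reproducible across runs (the number actually issued
depends on timing).
"""

from __future__ import annotations

import csv
import http.client
import random
import ssl
import threading
import time
from dataclasses import dataclass, field
from urllib.parse import urlsplit

from iris_restful import api
from iris_restful.metadata import SlideMetadata


@dataclass(frozen=True)
class LoadReportRow:
    """One aggregation window of the load report."""

    window_start_s: float
    requests: int
    failures: int
    p50_ms: float
    p75_ms: float
    p95_ms: float


@dataclass
class LoadReport:
    rows: list[LoadReportRow] = field(default_factory=list)
    total_requests: int = 0
    total_failures: int = 0

    def write_csv(self, path: str) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(
                ["window_start_s", "requests", "failures", "p50_ms", "p75_ms", "p95_ms"]
            )
            for row in self.rows:
                writer.writerow(
                    [f"{row.window_start_s:.1f}", row.requests, row.failures,
                     f"{row.p50_ms:.2f}", f"{row.p75_ms:.2f}", f"{row.p95_ms:.2f}"]
                )


def user_seed(seed: int, user: int) -> int:
    """Stable per-user sub-seed (kept below 2**31)."""
    return (seed * 1_000_003 + user) % (2**31 - 1)


def tile_sample_stream(metadata: SlideMetadata, seed: int):
    """Infinite deterministic stream of uniform in-bounds (layer, x, y) draws."""
    rng = random.Random(seed)
    layers = metadata.layers
    while True:
        l = rng.randrange(len(layers))
        yield l, rng.randrange(layers[l].x_tiles), rng.randrange(layers[l].y_tiles)


def _percentile(sorted_values: list[float], q: float) -> float:
    if not sorted_values:
        return float("nan")
    idx = min(len(sorted_values) - 1, int(round(q * (len(sorted_values) - 1))))
    return sorted_values[idx]


def run_load_profile(
    server_url: str,
    slide_id: str,
    *,
    users: int,
    ramp_rate: float,
    duration: float,
    think_time: tuple[float, float] = (0.001, 0.002),
    seed: int = 0,
    window_s: float = 1.0,
    ssl_context: ssl.SSLContext | None = None,
    csv_path: str | None = None,
) -> LoadReport:
    """Ramp ``users`` virtual users at ``ramp_rate`` users/s for ``duration`` s.

    Every non-200 tile response is counted as a failure and reported, never
    fatal. Returns the windowed latency/throughput report.
    """
    if users < 1 or ramp_rate <= 0 or duration <= 0:
        raise ValueError("users, ramp_rate and duration must be positive")
    split = urlsplit(server_url)
    conn_cls = http.client.HTTPSConnection if split.scheme == "https" else \
        http.client.HTTPConnection
    conn_kwargs = {"context": ssl_context} if split.scheme == "https" else {}

    # (relative timestamp s, latency ms, http status)
    samples: list[tuple[float, float, int]] = []
    samples_lock = threading.Lock()
    stop = threading.Event()
    t0 = time.perf_counter()

    def request(conn, target: str) -> tuple[int, bytes]:
        conn.request("GET", target)
        resp = conn.getresponse()
        return resp.status, resp.read()

    def user_loop(user: int) -> None:
        rng_coords = random.Random(user_seed(seed, user))
        rng_think = random.Random(user_seed(seed, user) ^ 0x5F5F5F5F)
        meta = None
        conn = None
        while not stop.is_set():
            try:
                if conn is None:
                    conn = conn_cls(split.hostname, split.port, timeout=10,
                                    **conn_kwargs)
                if meta is None:
                    status, body = request(conn, f"/slides/{slide_id}/metadata")
                    if status != 200:
                        raise OSError(f"metadata fetch failed with {status}")
                    meta = api.metadata_from_json(body)
                    stream = tile_sample_stream(meta, user_seed(seed, user))
                l, x, y = next(stream)
                t = y * meta.layers[l].x_tiles + x
                begin = time.perf_counter()
                status, _ = request(conn, f"/slides/{slide_id}/layers/{l}/tiles/{t}")
                latency_ms = (time.perf_counter() - begin) * 1e3
                with samples_lock:
                    samples.append((begin - t0, latency_ms, status))
                stop.wait(rng_think.uniform(*think_time))
            except (OSError, http.client.HTTPException):
                if conn is not None:
                    conn.close()
                    conn = None
                with samples_lock:
                    samples.append((time.perf_counter() - t0, float("nan"), 0))
                stop.wait(0.05)
        if conn is not None:
            conn.close()

    threads: list[threading.Thread] = []
    try:
        for i in range(users):
            if stop.is_set():
                break
            start_at = i / ramp_rate
            now = time.perf_counter() - t0
            if start_at > now:
                if stop.wait(min(start_at - now, max(duration - now, 0))):
                    break
            if time.perf_counter() - t0 >= duration:
                break
            thread = threading.Thread(target=user_loop, args=(i,), daemon=True)
            thread.start()
            threads.append(thread)
        remaining = duration - (time.perf_counter() - t0)
        if remaining > 0:
            time.sleep(remaining)
    finally:
        stop.set()
        for thread in threads:
            thread.join(timeout=10)

    report = LoadReport()
    with samples_lock:
        recorded = sorted(samples)
    if recorded:
        n_windows = int(recorded[-1][0] // window_s) + 1
        for w in range(n_windows):
            in_window = [s for s in recorded if w * window_s <= s[0] < (w + 1) * window_s]
            if not in_window:
                continue
            latencies = sorted(lat for _, lat, st in in_window if st == 200)
            failures = sum(1 for _, _, st in in_window if st != 200)
            report.rows.append(
                LoadReportRow(
                    window_start_s=w * window_s,
                    requests=len(in_window),
                    failures=failures,
                    p50_ms=_percentile(latencies, 0.50),
                    p75_ms=_percentile(latencies, 0.75),
                    p95_ms=_percentile(latencies, 0.95),
                )
            )
        report.total_requests = len(recorded)
        report.total_failures = sum(1 for _, _, st in recorded if st != 200)
    if csv_path is not None:
        report.write_csv(csv_path)
    return report
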