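"""The two-stack service: dispatch, handle lifecycle, static mode, TLS, faults."""

import json
import os
import random
import socket
import ssl
import threading
import time
import urllib.request

import pytest

from iris_restful.container import open_slide, write_container
from iris_restful.metadata import SlideMetadata
from iris_restful.addressing import layer_tiling
from iris_restful.server import (
    HandleCache,
    IrisServer,
    ServerConfig,
    certificate_rsa_bits,
    generate_self_signed_cert,
)
from iris_restful.synthetic import SyntheticSlideSpec, generate_slide
from tests.conftest import RawHttpClient, http_get, wait_until


def test_http_dispatch_matches_direct_reads(server, identity_slide):
    """Tiles through HTTP equal slide_container reads, on both dialects."""
    handle = open_slide(identity_slide.path)
    try:
        for l, layer in enumerate(handle.metadata.layers):
            for t in range(layer.tile_count):
                direct = handle.read_tile(l, t)
                status, headers, body = http_get(
                    f"{server.base_url}/slides/s1/layers/{l}/tiles/{t}"
                )
                assert status == 200 and body == direct
                assert headers["Content-Type"] == "image/jpeg"
                status, _, wado_body = http_get(
                    f"{server.base_url}/studies/x/series/s1/instances/{l + 1}"
                    f"/frames/{t + 1}"
                )
                assert status == 200 and wado_body == direct
    finally:
        handle.close()


def test_metadata_identical_across_dialects(server):
    _, h1, iris_doc = http_get(f"{server.base_url}/slides/s1/metadata")
    _, _, wado_doc = http_get(f"{server.base_url}/studies/x/series/s1/metadata")
    assert iris_doc == wado_doc
    assert h1["Content-Type"] == "application/json"
    assert json.loads(iris_doc)["tile_size"] == 256


def test_unknown_slide_is_404_without_cache_side_effects(server):
    status, _, body = http_get(f"{server.base_url}/slides/absent/metadata")
    assert status == 404 and b"absent" in body
    assert server.cache.stats() == {}


def test_range_violations_are_400(server):
    for target in ("/slides/s1/layers/3/tiles/0", "/slides/s1/layers/0/tiles/1"):
        status, _, body = http_get(server.base_url + target)
        assert status == 400 and b"range violation" in body


def test_shared_handle_refcount_tracks_sessions(server, identity_slide):
    """Two keep-alive connections on one slide share a single handle."""
    key = os.path.realpath(identity_slide.path)
    c1 = RawHttpClient("127.0.0.1", server.port)
    c2 = RawHttpClient("127.0.0.1", server.port)
    try:
        assert c1.request("/slides/s1/metadata")[0] == 200
        assert wait_until(lambda: server.cache.stats().get(key) == 1)
        assert c2.request("/slides/s1/layers/0/tiles/0")[0] == 200
        assert wait_until(lambda: server.cache.stats().get(key) == 2)
        # repeat requests on the same connection do not grow the count
        assert c1.request("/slides/s1/layers/2/tiles/5")[0] == 200
        assert server.cache.stats().get(key) == 2
        c1.close()
        assert wait_until(lambda: server.cache.stats().get(key) == 1)
    finally:
        c1.close()
        c2.close()
    assert wait_until(lambda: server.cache.stats() == {})


def test_randomized_session_schedule_leaves_empty_cache(server, identity_slide):
    """Refcount equals live touching sessions at every step; cache ends empty."""
    key = os.path.realpath(identity_slide.path)
    rng = random.Random(42)
    live: list[RawHttpClient] = []
    touched = 0
    try:
        for _ in range(40):
            if live and rng.random() < 0.4:
                victim = live.pop(rng.randrange(len(live)))
                victim.close()
                touched -= 1
            else:
                client = RawHttpClient("127.0.0.1", server.port)
                t = rng.randrange(16)
                assert client.request(f"/slides/s1/layers/2/tiles/{t}")[0] == 200
                live.append(client)
                touched += 1
            expected = touched
            assert wait_until(
                lambda: server.cache.stats().get(key, 0) == expected
            ), f"refcount != {expected} live sessions"
    finally:
        for client in live:
            client.close()
    assert wait_until(lambda: server.cache.stats() == {})


def test_debug_introspection_route(server):
    status, _, body = http_get(f"{server.base_url}/internal/handles")
    assert status == 200
    assert isinstance(json.loads(body), dict)


def test_stalled_worker_does_not_block_request_parsing(slide_dir):
    """With one stalled fs worker, malformed requests still answer fast."""
    config = ServerConfig(slide_dir=slide_dir, fs_workers=1, tile_delay=2.0)
    with IrisServer(config) as srv:
        slow = threading.Thread(
            target=http_get, args=(f"{srv.base_url}/slides/s1/layers/0/tiles/0",)
        )
        slow.start()
        time.sleep(0.3)  # the single worker is now inside its 2 s stall
        begin = time.perf_counter()
        status, _, _ = http_get(f"{srv.base_url}/slides/../x/metadata")
        elapsed = time.perf_counter() - begin
        slow.join()
        assert status == 403
        assert elapsed < 0.1, f"malformed request took {elapsed * 1e3:.0f} ms"


def test_fs_jobs_complete_in_fifo_order(slide_dir):
    config = ServerConfig(slide_dir=slide_dir, fs_workers=1, tile_delay=0.25)
    completions = []
    lock = threading.Lock()

    def fetch(tag, t):
        http_get(f"{srv.base_url}/slides/s1/layers/2/tiles/{t}")
        with lock:
            completions.append(tag)

    with IrisServer(config) as srv:
        threads = []
        for i in range(4):
            thread = threading.Thread(target=fetch, args=(i, i))
            thread.start()
            threads.append(thread)
            time.sleep(0.05)  # stagger submissions well below the job length
        for thread in threads:
            thread.join()
    assert completions == [0, 1, 2, 3]


def test_corrupt_container_yields_500_and_server_survives(tmp_path):
    generate_slide(SyntheticSlideSpec(width=256, height=256, n_layers=1),
                   tmp_path / "good.iris")
    meta = SlideMetadata(width=256, height=256,
                         layers=[layer_tiling(256, 256, 1.0, 256)])
    write_container(tmp_path / "bad.iris", meta, [b"x" * 32])
    blob = bytearray((tmp_path / "bad.iris").read_bytes())
    blob[-10] ^= 0xFF
    (tmp_path / "bad.iris").write_bytes(bytes(blob))

    with IrisServer(ServerConfig(slide_dir=str(tmp_path))) as srv:
        status, _, body = http_get(f"{srv.base_url}/slides/bad/metadata")
        assert status == 500 and b"failed validation" in body
        # the fault is contained: the next request proceeds normally
        status, _, _ = http_get(f"{srv.base_url}/slides/good/metadata")
        assert status == 200


def test_static_mode_rules(tmp_path, slide_dir):
    root = tmp_path / "www"
    (root / "a").mkdir(parents=True)
    (root / "index.html").write_text("<html>hi</html>")
    (root / "a" / "app.js").write_text("console.log(1)")
    (root / "secret.txt").write_text("no")
    (root / "slide.iris").write_bytes(b"IRST fake")

    config = ServerConfig(slide_dir=slide_dir, document_root=str(root))
    with IrisServer(config) as srv:
        status, headers, body = http_get(f"{srv.base_url}/index.html")
        assert (status, body) == (200, b"<html>hi</html>")
        assert headers["Content-Type"].startswith("text/html")
        assert http_get(f"{srv.base_url}/a/app.js")[0] == 200
        # container downloads are always refused, even inside the root
        assert http_get(f"{srv.base_url}/slide.iris")[0] == 403
        assert http_get(f"{srv.base_url}/secret.txt")[0] == 403
        assert http_get(f"{srv.base_url}/missing.html")[0] == 404
        client = RawHttpClient("127.0.0.1", srv.port)
        try:
            assert client.request("/a/../../etc/hosts")[0] == 403
        finally:
            client.close()


def test_static_mode_disabled_by_default(server):
    assert http_get(f"{server.base_url}/index.html")[0] == 400


def test_self_signed_cert_is_2048_bit_rsa(tmp_path):
    cert, key = generate_self_signed_cert(str(tmp_path))
    assert certificate_rsa_bits(cert) == 2048


def test_tls_server_serves_and_rejects_plaintext(slide_dir):
    config = ServerConfig(slide_dir=slide_dir, tls="self-signed")
    with IrisServer(config) as srv:
        assert srv.cert_file and certificate_rsa_bits(srv.cert_file) == 2048
        ctx = ssl.create_default_context()
        ctx.check_hostname = False
        ctx.verify_mode = ssl.CERT_NONE
        with urllib.request.urlopen(
            f"{srv.base_url}/slides/s1/metadata", context=ctx, timeout=10
        ) as resp:
            assert resp.status == 200
        # a plaintext HTTP request against the TLS port must not be served
        with socket.create_connection(("127.0.0.1", srv.port), timeout=5) as sock:
            sock.sendall(b"GET /slides/s1/metadata HTTP/1.1\r\nHost: x\r\n\r\n")
            try:
                reply = sock.recv(200)
            except ConnectionError:
                reply = b""
        assert b"200" not in reply.split(b"\r\n", 1)[0]


def test_supplied_cert_is_used_verbatim(tmp_path, slide_dir):
    cert, key = generate_self_signed_cert(str(tmp_path))
    config = ServerConfig(slide_dir=slide_dir, tls="custom",
                          cert_file=cert, key_file=key)
    srv = IrisServer(config)
    try:
        assert srv.cert_file == cert  # no generation occurred
    finally:
        srv.stop()


def test_options_preflight(slide_dir):
    config = ServerConfig(slide_dir=slide_dir, origin="anonymous")
    with IrisServer(config) as srv:
        client = RawHttpClient("127.0.0.1", srv.port)
        try:
            status, _ = client.request("/slides/s1/layers/0/tiles/0",
                                       method="OPTIONS")
            assert status == 204
            status, body = client.request("/slides/s1/metadata")
            assert status == 200
        finally:
            client.close()


def test_cors_header_presence_follows_configuration(slide_dir, server):
    # default server: no origin configured -> no CORS header
    _, headers, _ = http_get(f"{server.base_url}/slides/s1/metadata")
    assert "Access-Control-Allow-Origin" not in headers
    with IrisServer(ServerConfig(slide_dir=slide_dir, origin="anonymous")) as srv:
        _, headers, _ = http_get(f"{srv.base_url}/slides/s1/metadata")
        assert headers["Access-Control-Allow-Origin"] == "*"


def test_unknown_verbs_get_405_over_http(server):
    client = RawHttpClient("127.0.0.1", server.port)
    try:
        for verb in ("POST", "DELETE", "PATCH", "BREW"):
            status, _ = client.request("/slides/s1/metadata", method=verb)
            assert status == 405, verb
    finally:
        client.close()


def test_handle_cache_is_shared_and_validating(identity_slide):
    cache = HandleCache()
    h1 = cache.acquire(identity_slide.path)
    h2 = cache.acquire(identity_slide.path)
    assert h1 is h2 and h1.refcount == 2
    cache.release(identity_slide.path)
    assert h1.refcount == 1 and not h1.closed
    cache.release(identity_slide.path)
    assert h1.closed and cache.stats() == {}
    with pytest.raises(FileNotFoundError):
        cache.acquire(identity_slide.path + ".missing")
    assert cache.stats() == {}
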