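# Methods

## The slide model

A whole-slide image is a resolution pyramid. Layer geometry is described by
`scale`, the layer's linear resolution as a fraction of the
highest-resolution plane: layers are stored lowest resolution first, scales
strictly increasing, and the final layer is defined to have scale 1.0 (the
reference plane is the top layer; the alternative — scaling relative to the
base — only relabels the same geometry). A layer of scale *s* over a
*W* × *H* slide spans ⌈*sW*/T⌉ × ⌈*sH*/T⌉ tiles of T = `tile_size` pixels
(default 256). Within a layer, tiles are numbered in raster order,
*t* = *y*·tiles₍ₓ₎ + *x*, which makes a tile address a single integer and
the layer's tile table a flat array.

Edge tiles are stored at full T × T with right/bottom replicate padding, so
every stored tile has identical pixel shape; clients crop against the layer
pixel extent `round(s·W) × round(s·H)`. Uniform geometry keeps the raster
index exact and makes DZI comparison a pure crop. The open question of
which side crops the padding is resolved client-side here: the server never
transcodes, it returns stored bytes verbatim.

## The container

The on-disk format is: 16-byte little-endian header (magic `IRST`, version,
flags, metadata length, tile count), a JSON metadata block, one
`(uint64 offset, uint32 length)` table entry per tile (layers in stored
order, raster order within a layer), the concatenated JPEG payloads, and a
trailing CRC32 over all preceding bytes. Validation runs every check —
magic, version, metadata geometry (including tile-extent/scale
consistency), header count vs. metadata count, table bounds and
non-overlap, checksum — before any tile is served, and each failure is a
distinct error kind with a plain-text narrative. Validation is detection
only; recovery of corrupted containers is out of scope. The explicit header
tile count exists so a metadata/table disagreement is reported as a count
mismatch rather than surfacing indirectly as a bounds error.

## Request handling

Only two GET shapes per dialect are accepted; everything else — wrong verb
(405), malformed or extra segments, non-decimal indices, empty identifiers
(400), any `..`, backslash, or percent-encoded separator (403) — is
rejected by the parser before any file-system access. The WADO-RS mapping
follows the DICOM convention of 1-based instances and frames; frame lists
(multi-frame retrieval) are refused with a narrative naming the
single-frame restriction. Out-of-range layer or tile indices on a valid
grammar are range violations (400). Unknown slides are 404; a container
failing validation is a 500 whose body says so. Error bodies are always
plain text.

The server runs two isolated stacks. Network threads (one per live
connection) accept, parse, and reject; any request needing container bytes
is enqueued on a single FIFO queue drained by `fs_workers` threads (default:
CPU count). The testable contract is FIFO completion order and non-blocking
acceptance — demonstrated with a per-tile delay hook that stalls a worker
while malformed requests keep answering in milliseconds. Every exception in
a job is caught per request, converted to a 500, and the worker proceeds.

A session is one HTTP connection (with keep-alive, the natural analogue of
a TCP socket session). The handle cache maps canonical container paths to
memory-mapped handles; the first request of a session touching a slide
increments its refcount, and the mapping is released exactly when the last
referencing session closes. Small responses are sent with Nagle's algorithm
disabled; headers and body go out as separate writes, and the
delayed-ACK/Nagle interaction otherwise adds ~40 ms to every response.

Static-file mode is opt-in (`-r/--root`) and restricted: resolved paths
must stay inside the document root (symlinks included), only an explicit
extension allow-list (`.html .htm .js .css .json .xml .dzi .png .jpg .jpeg
.ico .svg .wasm`) is served, and `.iris` containers are refused (403) even
when placed inside the root, so slides and viewer assets can share a
directory safely. TLS is off, self-signed (a 2048-bit RSA key and
certificate generated at startup via the `openssl` CLI), or user-supplied
cert/key. CORS headers are emitted only when an origin is configured;
`anonymous` maps to `*`; OPTIONS preflights answer 204 with
`GET, OPTIONS`.

## Synthetic slides

The generator's default is a 1024 × 1024, 3-layer, 2×-downsampled pyramid
of 256-px JPEG tiles at quality 90 — a small but structurally complete
pyramid (layers of 1, 4 and 16 tiles) matching the tile geometry the server
is designed around.

*Identity mode* gives every tile a solid colour encoding its own address
(`R = 8·((t≫5) mod 32)`, `G = 8·(t mod 32)`, `B = 8·(layer mod 32)`).
Multiples of 8 survive JPEG quantisation, so a decoded tile can be traced
back to exactly one (layer, t) after any write → serve → fetch → decode
path; the 5-bit fields cap identity slides at 1024 tiles per layer and 32
layers. This is the oracle used for cross-dialect and cross-format
equivalence.

*Pyramid mode* synthesises a seeded smooth texture (coarse random field
bilinearly upsampled, plus band-limited fine detail at a 4-px grain) and
derives lower layers by block-mean downsampling, which preserves the global
pixel mean across layers to within rounding — the property the tests
assert. The texture is deliberately band-limited, as real scanner optics
are; per-pixel white noise would be unrealistic and unrepresentable by any
JPEG setting. Tiles are encoded 4:4:4 (no chroma subsampling) so colour
detail survives at the configured quality.

What the generator does **not** emulate: real tissue morphology, scanner
illumination artefacts, sparse background/empty-tile statistics, multi-GB
file sizes, and vendor metadata. Passing tests therefore demonstrate the
correctness of addressing, storage, transport and assembly — not
performance or robustness on clinical archives.

*DZI export* re-expresses a 2× container as a DeepZoom tree: descriptor XML
(TileSize, Overlap 0, Format jpg) plus `{x}_{y}.jpg` files per level, where
container layer *l* lands at DeepZoom level ⌈log₂ max(W, H)⌉ − (n−1−l).
Interior tiles are byte-identical copies of the stored payloads; edge tiles
must be cropped to their true size and are re-encoded at quality 95, with
the tests bounding the round-trip error at a mean absolute difference of 2
grey levels.

## Load harness

Virtual users start at a fixed ramp rate; each fetches metadata once, then
loops uniform random in-bounds tile requests with 1–2 ms think time and no
caching. Coordinate streams are per-user seeded, so the sampled sequence is
reproducible; failures (any non-200) are counted, never fatal. The report
aggregates 1-second windows into request count, failures, and 50/75/95th
latency percentiles, mirroring common load-tool CSV output. Absolute
throughput and latency are hardware-bound and are never asserted — the
smoke criterion is zero failures and a well-formed report.

## Numerical and design choices

- Layer indices are 0-based with layer 0 the lowest resolution; `y` grows
  downward (image convention).
- Metadata JSON uses fixed key order and compact separators, so
  serialise → parse → serialise is byte-stable.
- The WADO study segment is accepted and ignored for slide resolution; the
  container has no DICOM hierarchy.
- Identity decoding reads the central pixel and rounds each channel to the
  nearest multiple of 8, rejecting values farther than 3 — safe for JPEG
  quality ≥ 75.
- Scales in the generator are exact powers of the downsample factor, so
  `ceil(scale·extent/T)` and `ceil(round(scale·extent)/T)` agree; the
  client validates the latter, the container the former.
- The acceptance script sizes its runs to finish in about a minute while
  keeping each measurement meaningful: the default 21-tile pyramid for
  equivalence sweeps, 10,000 fuzz targets, a 30-step session schedule, and
  a 30-second 20-user load ramp.

## Known limitations

- HTTP/1.1 only; no range requests, caching headers, or HTTP/2.
- No authentication or authorization; security scope is strict parsing,
  path containment, and the static allow-list.
- The FIFO file-system stack is a single logical queue; per-worker
  lock-free scheduling is treated as an implementation detail, not a
  contract.
- `fetch_region` downloads covering tiles serially; a production viewer
  would schedule and cache.
- Containers are read fully into validation once per open (checksum is
  whole-file), so opening very large slides pays one sequential scan.
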