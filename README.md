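# iris-restful

A RESTful tile server for pyramidal whole-slide images (WSI), with the
client-side tile-source logic a tiled viewer needs to consume it, and
deterministic fixture tooling.

Digital pathology viewers render gigapixel slide scans as multi-resolution
pyramids of small JPEG tiles (here 256 × 256 px). Static HTTP file servers
cannot stream sub-regions of a single large container file, which is why
pyramids are often exploded into DeepZoom (DZI) directory trees holding one
file per tile. This package instead serves tiles directly out of a single
validated binary container over a strict HTTP GET API, so one file on disk
can feed any tiled viewer.

## What it provides

- **A pyramidal slide container** (`.iris`): JPEG tiles per resolution
  layer, a binary tile table, embedded JSON metadata, and a whole-file
  CRC32. Containers are fully validated — magic, version, geometry, table
  bounds, checksum — before a single tile is served.
- **Two API dialects** over HTTP GET:
  - native: `/slides/{id}/metadata` and `/slides/{id}/layers/{l}/tiles/{t}`
  - DICOMweb WADO-RS mapping:
    `/studies/{s}/series/{id}/metadata` and
    `/studies/{s}/series/{id}/instances/{i}/frames/{f}`,
    with 1-based instance *i* → layer *i* − 1 and frame *f* → tile *f* − 1.
- **Raster tile addressing.** Within layer *l*, the tile at column *x*,
  row *y* has index

  *t* = *y* · tiles<sub>l,x</sub> + *x*

  where tiles<sub>l,x</sub> is the number of tile columns of the layer.
- **A two-stack server**: network threads only accept, parse and reject;
  all container access runs on a FIFO file-system worker pool, so a stalled
  slide read never blocks request parsing. Open slides are memory-mapped
  once and shared between client sessions through a reference-counted
  handle cache. Optional restricted static-file mode (allow-listed
  extensions only; container downloads always refused), CORS, and TLS with
  auto-generated self-signed 2048-bit RSA certificates.
- **A client tile source** that configures viewer levels from served
  metadata, builds tile URLs, and stitches exact pixel regions.
- **Fixture tooling**: deterministic synthetic pyramids (identity-encoded
  tiles that name their own address, or procedural textures), DZI export
  for cross-format comparison, and a ramped virtual-user load harness.

## Worked example

```bash
# 1. generate a 3-layer 1024x1024 identity-encoded slide
iris-fixtures generate /data/slides/s1.iris --layers 3
# -> wrote /data/slides/s1.iris: 3 layers, 21 tiles of 256x256

# 2. serve it
iris-restful -d /data/slides -p 8080 -o anonymous
# -> serving /data/slides at http://0.0.0.0:8080

# 3. fetch metadata (either dialect returns the identical document)
curl -s http://127.0.0.1:8080/slides/s1/metadata
```

```json
{"extent":{"width":1024,"height":1024},"tile_size":256,"encoding":"jpeg",
 "layers":[{"x_tiles":1,"y_tiles":1,"scale":0.25},
           {"x_tiles":2,"y_tiles":2,"scale":0.5},
           {"x_tiles":4,"y_tiles":4,"scale":1.0}]}
```

The layer list drives viewer configuration: layer 2 is the full-resolution
1024 × 1024 plane tiled 4 × 4, so its tile (x=3, y=2) is
`GET /slides/s1/layers/2/tiles/11` (t = 2·4 + 3). The same tile via WADO-RS
is `GET /studies/any/series/s1/instances/3/frames/12`.

From Python:

```python
from iris_restful.tilesource import IrisTileSource

src = IrisTileSource("http://127.0.0.1:8080", "s1")
region = src.fetch_region(level=2, x0=100, y0=50, width=400, height=300)
print(region.shape)   # (300, 400, 3) -- exact pixels, edge padding cropped
```

A quick load test against the running instance:

```bash
iris-fixtures loadtest http://127.0.0.1:8080 s1 --users 2 --duration 2 --ramp-rate 5
# 1690 requests, 0 failures, 2 report windows
#   t=  0.0s n=  793 fail=  0 p50=   0.55ms p75=   0.66ms p95=   0.90ms
#   t=  1.0s n=  897 fail=  0 p50=   0.52ms p75=   0.66ms p95=   0.85ms
```

Each report row is one 1-second window: request count, failures, and the
50/75/95th latency percentiles. Absolute numbers are hardware-bound.

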