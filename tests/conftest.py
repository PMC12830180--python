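"""Shared fixtures: synthetic slides and live servers.

The raw-HTTP helpers live in :mod:`iris_restful.testing`; they are re-exported
here for the test modules.
"""

from __future__ import annotations

import os

import pytest

from iris_restful.server import IrisServer, ServerConfig
from iris_restful.synthetic import SyntheticSlideSpec, generate_slide
from iris_restful.testing import (  # noqa: F401  (re-exported for tests)
    RawHttpClient,
    fuzz_targets,
    http_get,
    wait_until,
)


@pytest.fixture(scope="session")
def identity_slide(tmp_path_factory):
    """The default 3-layer identity-encoded slide, written once per session."""
    d = tmp_path_factory.mktemp("slides")
    return generate_slide(SyntheticSlideSpec(seed=7), d / "s1.iris")


@pytest.fixture(scope="session")
def slide_dir(identity_slide):
    return os.path.dirname(identity_slide.path)


@pytest.fixture(scope="session")
def server(slide_dir):
    """A running service over the identity slide, with introspection enabled."""
    config = ServerConfig(slide_dir=slide_dir, fs_workers=2, debug=True)
    with IrisServer(config) as srv:
        yield srv
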