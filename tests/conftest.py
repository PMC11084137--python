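"""Shared fixtures: synthetic datasets and a controlled local HTTP server."""
from __future__ import annotations

import threading
from dataclasses import dataclass, field
from functools import partial
from http.server import SimpleHTTPRequestHandler, ThreadingHTTPServer
from pathlib import Path

import pytest

from omdct.fixtures import FixtureConfig, generate_dataset


@pytest.fixture
def dataset(tmp_path):
    """Default clean dataset (seed 7) under tmp_path/ds."""
    return generate_dataset(FixtureConfig(seed=7), tmp_path / "ds")


@pytest.fixture
def make_dataset(tmp_path):
    """Factory for datasets with custom config fields."""

    def _make(seed=7, name=None, **overrides):
        out = tmp_path / (name or f"ds_{seed}")
        return generate_dataset(FixtureConfig(seed=seed, **overrides), out)

    return _make


@dataclass
class LocalServer:
    """HTTP file server whose failing-path set tests can edit live."""

    root: Path
    url: str = ""
    failing: set = field(default_factory=set)
    _httpd: ThreadingHTTPServer | None = None

    def url_for(self, relpath: str) -> str:
        return f"{self.url}/{relpath}"


class _Handler(SimpleHTTPRequestHandler):
    server_state: LocalServer = None  # set per server instance

    def do_GET(self):
        if self.path.lstrip("/").split("/")[-1] in self.server_state.failing:
            self.send_error(500, "synthetic failure")
            return
        super().do_GET()

    def log_message(self, *args):
        pass


@pytest.fixture
def local_server(tmp_path):
    root = tmp_path / "www"
    root.mkdir(exist_ok=True)
    state = LocalServer(root=root)
    handler = partial(_Handler, directory=str(root))
    httpd = ThreadingHTTPServer(("127.0.0.1", 0), handler)
    _Handler.server_state = state
    state._httpd = httpd
    state.url = f"http://127.0.0.1:{httpd.server_address[1]}"
    thread = threading.Thread(target=httpd.serve_forever, daemon=True)
    thread.start()
    yield state
    httpd.shutdown()
    thread.join(timeout=5)
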