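"""Shared fixtures: worked-example graphs and an in-process SPARQL endpoint.

The endpoint stub serves a real SPARQL 1.1 query interface over an rdflib
graph on localhost, so RemoteSource and federated extraction are exercised
over genuine HTTP without any network dependence.
"""

from __future__ import annotations

import threading
import urllib.parse
from http.server import BaseHTTPRequestHandler, HTTPServer

import pytest
from rdflib import Graph

from schemascout import LocalSource, RemoteSource, worked_example


@pytest.fixture()
def example_data() -> Graph:
    return worked_example()[0]


@pytest.fixture()
def example_vocab() -> Graph:
    return worked_example()[1]


@pytest.fixture()
def example_sources(example_data, example_vocab):
    return LocalSource(graph=example_data), LocalSource(graph=example_vocab)


class _SparqlHandler(BaseHTTPRequestHandler):
    graph: Graph  # set on the subclass by the factory

    def do_POST(self):
        length = int(self.headers.get("Content-Length", 0))
        params = urllib.parse.parse_qs(self.rfile.read(length).decode())
        query = params.get("query", [""])[0]
        try:
            result = self.graph.query(query)
            payload = result.serialize(format="json")
            if isinstance(payload, str):
                payload = payload.encode()
        except Exception as exc:  # malformed query
            self.send_response(400)
            self.end_headers()
            self.wfile.write(str(exc).encode())
            return
        self.send_response(200)
        self.send_header("Content-Type", "application/sparql-results+json")
        self.end_headers()
        self.wfile.write(payload)

    def log_message(self, *args):  # keep test output clean
        pass


@pytest.fixture()
def sparql_endpoint():
    """Factory: serve an rdflib graph as a localhost SPARQL endpoint and
    yield RemoteSource handles; servers are torn down after the test."""
    servers = []

    def make(graph: Graph, **kwargs) -> RemoteSource:
        handler = type("Handler", (_SparqlHandler,), {"graph": graph})
        server = HTTPServer(("127.0.0.1", 0), handler)
        thread = threading.Thread(target=server.serve_forever, daemon=True)
        thread.start()
        servers.append((server, thread))
        url = f"http://127.0.0.1:{server.server_address[1]}/sparql"
        return RemoteSource(url, **kwargs)

    yield make
    for server, thread in servers:
        server.shutdown()
        server.server_close()
        thread.join(timeout=5)
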