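"""Endpoint transports: in-process triple stores and the SPARQL protocol.

Selections and plans are transport-agnostic; they only need an object with
``select(query) -> list[dict]`` and ``ask(query) -> bool``. Two
implementations are provided: an rdflib-Graph-backed in-process store (used
by the tests and the fixture generator) and an HTTP client speaking the
SPARQL 1.1 protocol (``query=`` parameter, JSON results). A minimal
threaded HTTP server exposes any in-process store over the protocol.
"""

from __future__ import annotations

import json
import threading
import urllib.parse
import urllib.request
from dataclasses import dataclass, field
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Optional

from rdflib import Graph, Literal, URIRef

from .rdfizer import TripleDump


class EndpointError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# In-process endpoint
# ---------------------------------------------------------------------------

@dataclass
class InProcessEndpoint:
    """An rdflib Graph answering SELECT and ASK queries."""

    url: str
    graph: Graph = field(default_factory=Graph)

    @classmethod
    def from_dump(cls, url: str, dump: TripleDump) -> "InProcessEndpoint":
        return cls(url=url, graph=dump.to_graph())

    def select(self, query: str) -> list[dict]:
        res = self.graph.query(query)
        rows = []
        for binding in res:
            row = {}
            for var, val in zip(res.vars, binding):
                if val is not None:
                    row[str(var)] = val
            rows.append(row)
        return rows

    def ask(self, query: str) -> bool:
        return bool(self.graph.query(query).askAnswer)

    def __len__(self) -> int:
        return len(self.graph)


# ---------------------------------------------------------------------------
# SPARQL protocol client
# ---------------------------------------------------------------------------

def _term_from_json(obj: dict):
    t = obj.get("type")
    if t == "uri":
        return URIRef(obj["value"])
    if t in ("literal", "typed-literal"):
        dt = obj.get("datatype")
        lang = obj.get("xml:lang")
        if dt:
            return Literal(obj["value"], datatype=URIRef(dt))
        if lang:
            return Literal(obj["value"], lang=lang)
        return Literal(obj["value"])
    if t == "bnode":
        from rdflib import BNode
        return BNode(obj["value"])
    raise EndpointError(f"unknown term type in results: {t!r}")


@dataclass
class HTTPEndpoint:
    """SPARQL 1.1 protocol client (GET, ``query=`` parameter, JSON)."""

    url: str
    timeout: float = 30.0

    def _request(self, query: str) -> dict:
        qs = urllib.parse.urlencode({"query": query})
        req = urllib.request.Request(
            f"{self.url}?{qs}",
            headers={"Accept": "application/sparql-results+json"})
        try:
            with urllib.request.urlopen(req, timeout=self.timeout) as resp:
                return json.loads(resp.read().decode("utf-8"))
        except Exception as exc:
            raise EndpointError(f"endpoint {self.url} failed: {exc}") from exc

    def select(self, query: str) -> list[dict]:
        payload = self._request(query)
        rows = []
        for binding in payload["results"]["bindings"]:
            rows.append({var: _term_from_json(term)
                         for var, term in binding.items()})
        return rows

    def ask(self, query: str) -> bool:
        return bool(self._request(query)["boolean"])


# ---------------------------------------------------------------------------
# Endpoint pool
# ---------------------------------------------------------------------------

@dataclass
class EndpointPool:
    """URL-addressed collection of endpoints; the transport facade."""

    endpoints: dict[str, object] = field(default_factory=dict)

    def add(self, endpoint) -> None:
        self.endpoints[endpoint.url] = endpoint

    def get(self, url: str):
        try:
            return self.endpoints[url]
        except KeyError:
            raise EndpointError(f"no endpoint registered at {url}") from None

    def select(self, url: str, query: str) -> list[dict]:
        return self.get(url).select(query)

    def ask(self, url: str, query: str) -> bool:
        return self.get(url).ask(query)

    def union_graph(self) -> Graph:
        """Centralized view: the union of all in-process endpoint data."""
        g = Graph()
        for ep in self.endpoints.values():
            if not isinstance(ep, InProcessEndpoint):
                raise EndpointError(
                    "union_graph requires in-process endpoints")
            for t in ep.graph:
                g.add(t)
        return g

    def __len__(self) -> int:
        return len(self.endpoints)


# ---------------------------------------------------------------------------
# Minimal SPARQL protocol server (for HTTP-mode testing/deployment demos)
# ---------------------------------------------------------------------------

def _results_json(store: InProcessEndpoint, query: str) -> dict:
    stripped = query.lstrip()
    is_ask = stripped[:20].upper().startswith("ASK") or \
        "\nASK" in stripped[:200].upper()
    if is_ask or stripped.upper().startswith("ASK"):
        return {"head": {}, "boolean": store.ask(query)}
    res = store.graph.query(query)
    vars_ = [str(v) for v in res.vars]
    bindings = []
    for row in res:
        b = {}
        for var, val in zip(res.vars, row):
            if val is None:
                continue
            if isinstance(val, URIRef):
                b[str(var)] = {"type": "uri", "value": str(val)}
            elif isinstance(val, Literal):
                entry = {"type": "literal", "value": str(val)}
                if val.datatype:
                    entry["datatype"] = str(val.datatype)
                b[str(var)] = entry
            else:
                b[str(var)] = {"type": "bnode", "value": str(val)}
        bindings.append(b)
    return {"head": {"vars": vars_}, "results": {"bindings": bindings}}


class _Handler(BaseHTTPRequestHandler):
    store: InProcessEndpoint = None  # set per server subclass

    def do_GET(self):  # noqa: N802 (http.server API)
        parsed = urllib.parse.urlparse(self.path)
        params = urllib.parse.parse_qs(parsed.query)
        query = params.get("query", [None])[0]
        if query is None:
            self.send_error(400, "missing query parameter")
            return
        try:
            payload = json.dumps(_results_json(self.server.store, query))
        except Exception as exc:  # malformed query
            self.send_error(400, str(exc))
            return
        body = payload.encode("utf-8")
        self.send_response(200)
        self.send_header("Content-Type", "application/sparql-results+json")
        self.send_header("Content-Length", str(len(body)))
        self.end_headers()
        self.wfile.write(body)

    def log_message(self, *args):  # keep test output quiet
        pass


class SparqlHTTPServer:
    """Serve one in-process store over the SPARQL protocol on localhost."""

    def __init__(self, store: InProcessEndpoint, port: int = 0):
        self.httpd = ThreadingHTTPServer(("127.0.0.1", port), _Handler)
        self.httpd.store = store
        self.thread = threading.Thread(target=self.httpd.serve_forever,
                                       daemon=True)

    @property
    def url(self) -> str:
        host, port = self.httpd.server_address
        return f"http://{host}:{port}/sparql"

    def start(self) -> "SparqlHTTPServer":
        self.thread.start()
        return self

    def stop(self) -> None:
        self.httpd.shutdown()
        self.httpd.server_close()

    def __enter__(self) -> "SparqlHTTPServer":
        return self.start()

    def __exit__(self, *exc) -> None:
        self.stop()
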