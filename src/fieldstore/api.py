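"""RESTful/JSON access to a store: entities, metadata, data upload and queries.

Every endpoint speaks JSON and delegates to the library; a read endpoint's
body is exactly the library result passed through the serializers below, so
scripted clients and in-process callers see identical documents.  Writes are
serialized through a single lock (one writer at a time); reads are freely
concurrent.

Endpoints
---------
- ``GET  /users``
- ``GET|POST /users/{u}/experiments``
- ``GET|POST /users/{u}/experiments/{e}/nodes``
- ``GET|POST /users/{u}/experiments/{e}/nodes/{n}/streams``
- ``GET|PUT  <any entity path>/metadata``
- ``POST /streams/{sid}/data``   body ``{"points": [[t, v], ...], "duplicate_policy": "replace"}``
- ``GET  /streams/{sid}/data?level=…&from=…&to=…``  (level ``raw`` or a window level)
- ``GET  /streams/{sid}/summary``

Stream ids are hierarchy paths joined with ``~``.  Timestamps in documents
are ISO-8601 UTC; ``from``/``to`` accept ISO-8601 or epoch seconds.
"""

from __future__ import annotations

import json
import re
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from urllib.parse import parse_qs, unquote, urlparse

from .model import DuplicateNameError, NoSuchEntityError, StoreError
from .store import SensorStore, iso, parse_ts
from .windows import WindowLevel, stats_std

__all__ = [
    "to_json",
    "users_doc",
    "children_doc",
    "metadata_doc",
    "window_rows_doc",
    "raw_rows_doc",
    "summary_doc",
    "serve_api",
    "make_server",
]


def to_json(obj) -> bytes:
    """Canonical wire encoding shared by the server and the library."""
    return json.dumps(obj, separators=(",", ":"), ensure_ascii=False).encode("utf-8")


def _entity_doc(e) -> dict:
    doc = {"name": e.name, "kind": e.kind}
    doc.update(e.attrs)
    return doc


def users_doc(store: SensorStore) -> list[dict]:
    return [_entity_doc(u) for u in store.tree.users()]


def children_doc(store: SensorStore, parent) -> list[dict]:
    return [_entity_doc(c) for c in store.tree.children(parent)]


def metadata_doc(store: SensorStore, entity) -> dict:
    return store.tree.get_metadata(entity)


def _stats_doc(level: WindowLevel, start: int, w) -> dict:
    return {
        "level": level.value,
        "start": iso(start),
        "count": w.count,
        "mean": w.mean,
        "std": stats_std(w) if w.count else 0.0,
        "min": w.min_value,
        "min_time": iso(w.min_time),
        "max": w.max_value,
        "max_time": iso(w.max_time),
        "last": w.last_value,
        "last_time": iso(w.last_time),
    }


def window_rows_doc(store, stream, level, t_from: int, t_to: int) -> list[dict]:
    lvl = WindowLevel.parse(level) if isinstance(level, str) else level
    return [
        _stats_doc(lvl, start, w)
        for start, w in store.get_window_stats(stream, lvl, t_from, t_to)
    ]


def raw_rows_doc(store, stream, t_from: int, t_to: int) -> list[dict]:
    return [
        {"t": iso(t), "v": v} for t, v in store.get_raw(stream, t_from, t_to)
    ]


def summary_doc(store, stream) -> dict:
    out = {}
    for label, w in store.stream_summary(stream).items():
        if w.count == 0:
            out[label] = {"count": 0}
        else:
            out[label] = {
                "count": w.count,
                "mean": w.mean,
                "std": stats_std(w),
                "min": w.min_value,
                "min_time": iso(w.min_time),
                "max": w.max_value,
                "max_time": iso(w.max_time),
                "last": w.last_value,
                "last_time": iso(w.last_time),
            }
    return out


_ENTITY_COLLECTIONS = {
    # (regex, parent path groups, child kind)
    "experiments": re.compile(r"^/users/([^/]+)/experiments$"),
    "nodes": re.compile(r"^/users/([^/]+)/experiments/([^/]+)/nodes$"),
    "streams": re.compile(r"^/users/([^/]+)/experiments/([^/]+)/nodes/([^/]+)/streams$"),
}
_KIND_OF = {"experiments": "experiment", "nodes": "node", "streams": "stream"}

_META_RE = re.compile(
    r"^/users/([^/]+)"
    r"(?:/experiments/([^/]+))?"
    r"(?:/nodes/([^/]+))?"
    r"(?:/streams/([^/]+))?"
    r"/metadata$"
)
_STREAM_DATA_RE = re.compile(r"^/streams/([^/]+)/data$")
_STREAM_SUMMARY_RE = re.compile(r"^/streams/([^/]+)/summary$")


class _Handler(BaseHTTPRequestHandler):
    store: SensorStore
    write_lock: threading.Lock
    protocol_version = "HTTP/1.1"

    def log_message(self, fmt, *args):  # quiet by default
        pass

    # -- plumbing ----------------------------------------------------------

    def _send(self, code: int, payload: bytes) -> None:
        self.send_response(code)
        self.send_header("Content-Type", "application/json")
        self.send_header("Content-Length", str(len(payload)))
        self.end_headers()
        self.wfile.write(payload)

    def _ok(self, doc) -> None:
        self._send(200, to_json(doc))

    def _err(self, code: int, message: str) -> None:
        self._send(code, to_json({"error": message}))

    def _body(self) -> dict:
        length = int(self.headers.get("Content-Length") or 0)
        raw = self.rfile.read(length) if length else b"{}"
        doc = json.loads(raw.decode("utf-8"))
        if not isinstance(doc, dict):
            raise ValueError("body must be a JSON object")
        return doc

    def _dispatch(self, method: str) -> None:
        try:
            self._route(method)
        except NoSuchEntityError as e:
            self._err(404, str(e))
        except DuplicateNameError as e:
            self._err(409, str(e))
        except (ValueError, KeyError, StoreError, json.JSONDecodeError) as e:
            self._err(400, str(e))

    do_GET = lambda self: self._dispatch("GET")
    do_POST = lambda self: self._dispatch("POST")
    do_PUT = lambda self: self._dispatch("PUT")

    # -- routing -----------------------------------------------------------

    def _route(self, method: str) -> None:
        url = urlparse(self.path)
        path = unquote(url.path.rstrip("/") or "/")
        store = self.store

        if path == "/users":
            if method == "GET":
                return self._ok(users_doc(store))
            if method == "POST":
                body = self._body()
                with self.write_lock:
                    ent = store.create_entity(
                        "user", body.pop("name"), None, body or None
                    )
                return self._send(201, to_json(_entity_doc(ent)))

        for coll, rx in _ENTITY_COLLECTIONS.items():
            m = rx.match(path)
            if m:
                parent = "~".join(m.groups())
                if method == "GET":
                    return self._ok(children_doc(store, parent))
                if method == "POST":
                    body = self._body()
                    with self.write_lock:
                        ent = store.create_entity(
                            _KIND_OF[coll], body.pop("name"), parent, body or None
                        )
                    return self._send(201, to_json(_entity_doc(ent)))

        m = _META_RE.match(path)
        if m:
            entity = "~".join(g for g in m.groups() if g is not None)
            if method == "GET":
                return self._ok(metadata_doc(store, entity))
            if method == "PUT":
                body = self._body()
                with self.write_lock:
                    for k, v in body.items():
                        store.tree.set_metadata(entity, k, v)
                return self._ok(metadata_doc(store, entity))

        m = _STREAM_DATA_RE.match(path)
        if m:
            sid = m.group(1)
            if method == "POST":
                body = self._body()
                points = [(parse_ts(t), float(v)) for t, v in body.get("points", [])]
                policy = body.get("duplicate_policy", "replace")
                with self.write_lock:
                    rep = store.append_points(sid, points, duplicate_policy=policy)
                doc = {
                    "accepted": rep.accepted,
                    "rejected": rep.rejected,
                    "windows_touched": rep.windows_touched,
                    "errors": rep.errors,
                }
                if policy == "reject" and any(
                    reason == "duplicate timestamp" for _, reason in rep.errors
                ):
                    return self._send(409, to_json(doc))
                return self._ok(doc)
            if method == "GET":
                q = parse_qs(url.query)
                level = q.get("level", ["raw"])[0]
                t_from = parse_ts(q["from"][0]) if "from" in q else 0
                t_to = parse_ts(q["to"][0]) if "to" in q else 2**62
                if t_from > t_to:
                    return self._err(400, "empty range: from must be <= to")
                if level == "raw":
                    return self._ok(raw_rows_doc(store, sid, t_from, t_to))
                return self._ok(window_rows_doc(store, sid, level, t_from, t_to))

        m = _STREAM_SUMMARY_RE.match(path)
        if m and method == "GET":
            return self._ok(summary_doc(store, m.group(1)))

        self._err(404, f"no such resource: {method} {path}")


def make_server(store: SensorStore, host: str = "127.0.0.1", port: int = 0) -> ThreadingHTTPServer:
    """Build (but do not start) the HTTP server bound to *host:port*."""
    handler = type(
        "BoundHandler",
        (_Handler,),
        {"store": store, "write_lock": threading.Lock()},
    )
    return ThreadingHTTPServer((host, port), handler)


def serve_api(store: SensorStore, host: str = "127.0.0.1", port: int = 8630) -> None:
    """Serve the REST API until interrupted."""
    srv = make_server(store, host, port)
    try:
        srv.serve_forever()
    finally:
        srv.server_close()
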