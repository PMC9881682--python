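"""Minimal stateless REST service over a loaded database.

Endpoints
---------
GET  /health   database summary counts
POST /query    QueryRequest as JSON -> candidate rows as JSON records
               (the same columns as the CSV output) plus an optional
               gapped-FASTA alignment string

The database is loaded once at startup; every request is independent, so
concurrent identical queries return identical bodies.  Malformed JSON is a
400; a query that fails validation or parsing is a 422 with a stable error
code (the exception class name).
"""

from __future__ import annotations

import json
import logging
import threading
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer

from .database import EnzymeDatabase
from .errors import EnzSelectError
from .pipeline import QueryRequest, run_query
from .ranking import row_to_record

log = logging.getLogger(__name__)

REQUEST_FIELDS = (
    "host", "smiles", "smirks", "rxn", "ec", "xref",
    "direction", "targets", "weights", "msa",
)


def handle_query(db: EnzymeDatabase, payload: dict) -> tuple[int, dict]:
    """Pure request handler: JSON payload -> (HTTP status, response body)."""
    if not isinstance(payload, dict):
        return 400, {"error": "BadRequest", "message": "JSON object expected"}
    unknown = set(payload) - set(REQUEST_FIELDS)
    if unknown:
        return 422, {"error": "ValidationError", "message": f"unknown fields {sorted(unknown)}"}
    if "host" not in payload:
        return 422, {"error": "ValidationError", "message": "missing required field 'host'"}
    try:
        req = QueryRequest(**payload)
        result = run_query(req, db)
    except EnzSelectError as exc:
        return 422, {"error": type(exc).__name__, "message": str(exc)}
    body = {
        "rows": [row_to_record(r) for r in result.rows],
        "alignment": result.alignment.to_fasta() if result.alignment else None,
    }
    return 200, body


def make_handler(db: EnzymeDatabase):
    class Handler(BaseHTTPRequestHandler):
        def _send(self, status: int, body: dict):
            data = json.dumps(body).encode("utf-8")
            self.send_response(status)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(data)))
            self.end_headers()
            self.wfile.write(data)

        def do_GET(self):
            if self.path == "/health":
                self._send(200, db.summary())
            else:
                self._send(404, {"error": "NotFound", "message": self.path})

        def do_POST(self):
            if self.path != "/query":
                self._send(404, {"error": "NotFound", "message": self.path})
                return
            length = int(self.headers.get("Content-Length", 0))
            raw = self.rfile.read(length)
            try:
                payload = json.loads(raw.decode("utf-8"))
            except (json.JSONDecodeError, UnicodeDecodeError) as exc:
                self._send(400, {"error": "BadRequest", "message": f"invalid JSON: {exc}"})
                return
            status, body = handle_query(db, payload)
            self._send(status, body)

        def log_message(self, fmt, *args):  # route to logging, not stderr prints
            log.info("%s " + fmt, self.address_string(), *args)

    return Handler


def create_server(db: EnzymeDatabase, port: int = 0, host: str = "127.0.0.1") -> ThreadingHTTPServer:
    """Bind (port 0 picks a free port); call .serve_forever() to run."""
    return ThreadingHTTPServer((host, port), make_handler(db))


def serve(db: EnzymeDatabase, port: int, host: str = "127.0.0.1") -> None:
    server = create_server(db, port, host)
    log.info("serving on http://%s:%d", *server.server_address)
    try:
        server.serve_forever()
    except KeyboardInterrupt:
        server.shutdown()


def start_background(db: EnzymeDatabase) -> tuple[ThreadingHTTPServer, threading.Thread]:
    """Start a server on a free port in a daemon thread (used by tests)."""
    server = create_server(db, 0)
    thread = threading.Thread(target=server.serve_forever, daemon=True)
    thread.start()
    return server, thread
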