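"""JSON-RPC 2.0 counting service.

A thin network layer over the counting library: one method,
``count_cells``, takes a Base64-encoded image file (TIFF or PNG) and an
optional red-intensity threshold and returns the total and red-positive
cell counts computed by exactly the same code paths as the local API.
Requests are framed as JSON-RPC 2.0 over HTTP POST to ``/api``; the
dispatcher is a pure function, so it can be exercised without sockets.

Built on the standard library's ``http.server`` — the service is
single-request synchronous by design; batch throughput belongs to the CLI.
"""

from __future__ import annotations

import base64
import binascii
import json
from http.server import BaseHTTPRequestHandler, ThreadingHTTPServer
from typing import Any

from .count_targets import CountMapSpec
from .fluorescence import DEFAULT_RED_THRESHOLD, RedThreshold, count_red
from .image_io import ImageFormatError, luma_grayscale, read_image_bytes
from .tiling import count_frame

PARSE_ERROR = -32700
INVALID_REQUEST = -32600
METHOD_NOT_FOUND = -32601
INVALID_PARAMS = -32602
INTERNAL_ERROR = -32603


class CountingService:
    """Holds one trained model and answers count requests."""

    def __init__(
        self,
        model,
        count_spec: CountMapSpec,
        model_id: str = "fcnn",
        default_threshold: int = DEFAULT_RED_THRESHOLD,
    ) -> None:
        self.model = model
        self.count_spec = count_spec
        self.model_id = model_id
        self.default_threshold = default_threshold

    def count(self, image_bytes: bytes, red_threshold: int) -> dict[str, Any]:
        img = read_image_bytes(image_bytes)
        total = count_frame(self.model, luma_grayscale(img), self.count_spec)
        red: float | None = None
        if img.channels == 3:
            red = count_red(self.model, img, RedThreshold(red_threshold), self.count_spec)
        return {
            "cell_count": total,
            "cell_count_rounded": int(round(total)),
            "red_cell_count": red,
            "red_cell_count_rounded": None if red is None else int(round(red)),
            "red_threshold": red_threshold,
            "model_id": self.model_id,
            "kernel_size": self.count_spec.kernel_size,
        }


def _error(req_id, code: int, message: str) -> dict[str, Any]:
    return {"jsonrpc": "2.0", "id": req_id, "error": {"code": code, "message": message}}


def handle_rpc(service: CountingService | None, request: Any) -> dict[str, Any]:
    """Dispatch one parsed JSON-RPC 2.0 request object to the service."""
    if not isinstance(request, dict) or request.get("jsonrpc") != "2.0":
        return _error(None, INVALID_REQUEST, "not a JSON-RPC 2.0 request")
    req_id = request.get("id")
    method = request.get("method")
    if method != "count_cells":
        return _error(req_id, METHOD_NOT_FOUND, f"unknown method {method!r}")
    if service is None or service.model is None:
        return _error(req_id, INTERNAL_ERROR, "no counting model is loaded")
    params = request.get("params") or {}
    if not isinstance(params, dict):
        return _error(req_id, INVALID_PARAMS, "params must be an object")
    image_b64 = params.get("image")
    if not isinstance(image_b64, str):
        return _error(req_id, INVALID_PARAMS, "missing Base64 'image' parameter")
    threshold = params.get("red_threshold", service.default_threshold)
    if not isinstance(threshold, int) or not (0 <= threshold <= 255):
        return _error(
            req_id, INVALID_PARAMS, f"red_threshold must be an integer in [0, 255], got {threshold!r}"
        )
    try:
        image_bytes = base64.b64decode(image_b64, validate=True)
    except (binascii.Error, ValueError) as exc:
        return _error(req_id, INVALID_PARAMS, f"invalid Base64 image: {exc}")
    try:
        result = service.count(image_bytes, threshold)
    except ImageFormatError as exc:
        return _error(req_id, INVALID_PARAMS, f"undecodable image: {exc}")
    except Exception as exc:  # surface anything else as an internal error
        return _error(req_id, INTERNAL_ERROR, str(exc))
    return {"jsonrpc": "2.0", "id": req_id, "result": result}


def handle_rpc_bytes(service: CountingService | None, body: bytes) -> bytes:
    """Parse a raw request body, dispatch, and serialize the response."""
    try:
        request = json.loads(body.decode("utf-8"))
    except (UnicodeDecodeError, json.JSONDecodeError) as exc:
        return json.dumps(_error(None, PARSE_ERROR, f"parse error: {exc}")).encode()
    return json.dumps(handle_rpc(service, request)).encode()


def make_server(service: CountingService, host: str = "127.0.0.1", port: int = 8080):
    """Build (without starting) an HTTP server exposing POST ``/api``."""

    class Handler(BaseHTTPRequestHandler):
        def do_POST(self) -> None:  # noqa: N802 (stdlib naming)
            if self.path not in ("/api", "/api/"):
                self.send_error(404)
                return
            length = int(self.headers.get("Content-Length", 0))
            body = self.rfile.read(length)
            payload = handle_rpc_bytes(service, body)
            self.send_response(200)
            self.send_header("Content-Type", "application/json")
            self.send_header("Content-Length", str(len(payload)))
            self.end_headers()
            self.wfile.write(payload)

        def log_message(self, *args) -> None:  # keep tests quiet
            pass

    return ThreadingHTTPServer((host, port), Handler)


def serve_forever(service: CountingService, host: str = "0.0.0.0", port: int = 8080) -> None:
    """Blocking entry point used by the CLI ``serve`` subcommand."""
    with make_server(service, host, port) as server:
        server.serve_forever()
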