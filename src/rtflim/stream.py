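"""Acquisition-to-viewer frame transport.

Each frame of the live series is written to its own raw little-endian file
that both sides access by memory mapping, and its availability is announced
with a small JSON datagram over UDP.  Datagram loss is tolerated by design:
a lost announcement is superseded by the next frame's.  On the consumer side
a one-slot queue keeps only the newest unprocessed frame per series, so the
analysis loop always works on the most recent accumulated histogram and
never falls behind acquisition.

Wire format
-----------
* Payload file: C-order (time bin fastest-varying), little-endian, named
  ``series-<id>_frame-<seqno>.raw`` inside a per-series directory.
* Datagram: one UDP packet holding the UTF-8 JSON object
  ``{"series_id", "seqno", "shape", "dtype_code", "bin_width", "file_path"}``
  (unknown extra keys are ignored for forward compatibility).  Must fit in
  1 KB.
* ``dtype_code`` is one of ``uint16 | uint32 | float32 | float64``.
"""

from __future__ import annotations

import json
import logging
import socket
import threading
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Optional

import numpy as np

__all__ = [
    "FrameMessage",
    "FrameQueue",
    "TransportError",
    "CorruptFrameError",
    "DTYPE_CODES",
    "write_frame",
    "notify",
    "map_frame",
    "save_frame",
    "load_frame",
    "Receiver",
    "StreamConsumer",
]

log = logging.getLogger(__name__)

#: dtype_code tag -> little-endian NumPy dtype
DTYPE_CODES = {
    "uint16": np.dtype("<u2"),
    "uint32": np.dtype("<u4"),
    "float32": np.dtype("<f4"),
    "float64": np.dtype("<f8"),
}
_CODE_OF_KIND = {v.str: k for k, v in DTYPE_CODES.items()}

MAX_DATAGRAM = 1024


class TransportError(OSError):
    """I/O or network failure while moving a frame."""


class CorruptFrameError(ValueError):
    """Payload file does not match its announcement; the frame is skipped."""


@dataclass(frozen=True)
class FrameMessage:
    """Announcement of one memory-mappable frame payload."""

    series_id: str
    seqno: int
    shape: tuple[int, int, int]
    dtype_code: str
    bin_width: float
    file_path: str

    def __post_init__(self) -> None:
        if self.seqno < 0:
            raise ValueError("seqno must be >= 0")
        if len(self.shape) != 3 or any(s < 1 for s in self.shape):
            raise ValueError(f"shape components must be >= 1, got {self.shape}")
        object.__setattr__(self, "shape", tuple(int(s) for s in self.shape))

    def to_json(self) -> bytes:
        payload = json.dumps(asdict(self)).encode()
        if len(payload) > MAX_DATAGRAM:
            raise TransportError(f"datagram of {len(payload)} bytes exceeds {MAX_DATAGRAM}")
        return payload

    @classmethod
    def from_json(cls, payload: bytes) -> "FrameMessage":
        obj = json.loads(payload)
        try:
            return cls(
                series_id=str(obj["series_id"]),
                seqno=int(obj["seqno"]),
                shape=tuple(obj["shape"]),
                dtype_code=str(obj["dtype_code"]),
                bin_width=float(obj["bin_width"]),
                file_path=str(obj["file_path"]),
            )
        except KeyError as exc:  # unknown extras are fine, missing keys are not
            raise ValueError(f"datagram missing key {exc}") from exc

    @property
    def n_bytes(self) -> int:
        code = DTYPE_CODES.get(self.dtype_code)
        if code is None:
            raise CorruptFrameError(f"unknown dtype_code {self.dtype_code!r}")
        return int(np.prod(self.shape)) * code.itemsize


def write_frame(
    frames: np.ndarray,
    series_dir: Path | str,
    series_id: str,
    seqno: int,
    bin_width: float,
) -> FrameMessage:
    """Write one frame as a raw little-endian payload and describe it.

    The array is stored C-ordered with the time-bin axis fastest-varying so
    the receiver can memory-map it without any copy or byte swap.
    """
    frames = np.asarray(frames)
    if frames.ndim != 3:
        raise ValueError(f"expected a [rows, cols, bins] array, got ndim={frames.ndim}")
    code = _CODE_OF_KIND.get(np.dtype(frames.dtype).newbyteorder("<").str)
    if code is None:
        raise ValueError(f"unsupported frame dtype {frames.dtype}")
    series_dir = Path(series_dir)
    series_dir.mkdir(parents=True, exist_ok=True)
    path = series_dir / f"series-{series_id}_frame-{seqno}.raw"
    try:
        np.ascontiguousarray(frames, dtype=DTYPE_CODES[code]).tofile(path)
    except OSError as exc:
        raise TransportError(f"failed to write frame payload {path}: {exc}") from exc
    return FrameMessage(
        series_id=series_id, seqno=seqno, shape=frames.shape,
        dtype_code=code, bin_width=bin_width, file_path=str(path),
    )


def notify(message: FrameMessage, endpoint: tuple[str, int]) -> bool:
    """Send one fire-and-forget announcement datagram.

    Loss is tolerated (the next frame supersedes); an unreachable endpoint is
    logged, not fatal.  Returns whether the datagram left the socket.
    """
    payload = message.to_json()
    try:
        with socket.socket(socket.AF_INET, socket.SOCK_DGRAM) as sock:
            sock.sendto(payload, endpoint)
        return True
    except OSError as exc:
        log.warning("notify to %s failed: %s", endpoint, exc)
        return False


def map_frame(message: FrameMessage) -> np.ndarray:
    """Memory-map an announced payload as a read-only [rows, cols, bins] view.

    The file size must match the declared shape and dtype exactly; any
    mismatch raises :class:`CorruptFrameError` so the consumer can skip the
    frame and wait for the next one.
    """
    dtype = DTYPE_CODES.get(message.dtype_code)
    if dtype is None:
        raise CorruptFrameError(f"unknown dtype_code {message.dtype_code!r}")
    path = Path(message.file_path)
    try:
        actual = path.stat().st_size
    except OSError as exc:
        raise CorruptFrameError(f"payload missing: {path}") from exc
    if actual != message.n_bytes:
        raise CorruptFrameError(
            f"payload {path} is {actual} bytes, expected {message.n_bytes}"
        )
    return np.memmap(path, dtype=dtype, mode="r", shape=message.shape)


def save_frame(path_base: Path | str, frames: np.ndarray, bin_width: float) -> Path:
    """Persist a frame as ``<base>.raw`` plus a ``<base>.json`` sidecar.

    The sidecar records shape, dtype code and bin width so ``load_frame`` and
    the CLI can reconstruct the array without guessing.
    """
    path_base = Path(path_base)
    frames = np.asarray(frames)
    code = _CODE_OF_KIND.get(np.dtype(frames.dtype).newbyteorder("<").str)
    if code is None:
        raise ValueError(f"unsupported frame dtype {frames.dtype}")
    path_base.parent.mkdir(parents=True, exist_ok=True)
    np.ascontiguousarray(frames, dtype=DTYPE_CODES[code]).tofile(
        path_base.with_suffix(".raw")
    )
    sidecar = {
        "shape": list(frames.shape),
        "dtype_code": code,
        "bin_width": bin_width,
    }
    path_base.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path_base.with_suffix(".raw")


def load_frame(path_base: Path | str) -> tuple[np.ndarray, float]:
    """Load a frame saved by :func:`save_frame`; returns (array view, bin_width)."""
    path_base = Path(path_base)
    if path_base.suffix in {".raw", ".json"}:
        path_base = path_base.with_suffix("")
    sidecar = json.loads(path_base.with_suffix(".json").read_text())
    dtype = DTYPE_CODES[sidecar["dtype_code"]]
    shape = tuple(sidecar["shape"])
    arr = np.memmap(path_base.with_suffix(".raw"), dtype=dtype, mode="r", shape=shape)
    return arr, float(sidecar["bin_width"])


class FrameQueue:
    """Latest-frame-wins queue between the receiver and the analysis loop.

    Holds at most one pending announcement.  A newer seqno replaces an unread
    older one (the older is counted as superseded); out-of-order or duplicate
    datagrams within the live series are dropped the same way.  A message
    carrying a new ``series_id`` flushes the queue and starts over; stragglers
    from any retired series are discarded as stale.  All methods are
    thread-safe, and ``offer`` never blocks, so receiving a datagram can never
    wait on a slow analysis step.
    """

    def __init__(self) -> None:
        self._lock = threading.Condition()
        self._pending: Optional[FrameMessage] = None
        self._series: Optional[str] = None
        self._retired: set[str] = set()
        self._highest_seqno = -1
        self.n_superseded = 0

    @property
    def current_series(self) -> Optional[str]:
        return self._series

    def offer(self, message: FrameMessage) -> str:
        """Submit an announcement; returns ``accepted | superseded | stale``."""
        with self._lock:
            if message.series_id in self._retired:
                return "stale"
            if message.series_id != self._series:
                # New acquisition: retire the old series and reset.
                if self._series is not None:
                    self._retired.add(self._series)
                if self._pending is not None:
                    self.n_superseded += 1
                self._series = message.series_id
                self._pending = message
                self._highest_seqno = message.seqno
                self._lock.notify_all()
                return "accepted"
            if message.seqno <= self._highest_seqno:
                self.n_superseded += 1
                return "superseded"
            if self._pending is not None:
                self.n_superseded += 1
            self._pending = message
            self._highest_seqno = message.seqno
            self._lock.notify_all()
            return "accepted"

    def take_latest(self, timeout: float | None = 0.0) -> Optional[FrameMessage]:
        """Pop the newest pending announcement, or None if none arrives.

        ``timeout=0`` polls; a positive timeout waits up to that many seconds
        for a frame.
        """
        with self._lock:
            if self._pending is None and timeout:
                self._lock.wait_for(lambda: self._pending is not None, timeout=timeout)
            message, self._pending = self._pending, None
            return message


class Receiver:
    """Background UDP listener feeding a :class:`FrameQueue`.

    Malformed datagrams are logged and dropped; the socket loop never touches
    analysis state, so reception cannot block on processing.
    """

    def __init__(self, queue: FrameQueue, port: int = 5555, bind: str = "127.0.0.1"):
        self.queue = queue
        self._sock = socket.socket(socket.AF_INET, socket.SOCK_DGRAM)
        self._sock.bind((bind, port))
        self._sock.settimeout(0.1)
        self.port = self._sock.getsockname()[1]
        self._stop = threading.Event()
        self._thread = threading.Thread(target=self._run, daemon=True)

    def start(self) -> "Receiver":
        self._thread.start()
        return self

    def _run(self) -> None:
        while not self._stop.is_set():
            try:
                payload, _ = self._sock.recvfrom(MAX_DATAGRAM)
            except socket.timeout:
                continue
            except OSError:
                break
            try:
                message = FrameMessage.from_json(payload)
            except (ValueError, TypeError) as exc:
                log.warning("discarding malformed datagram: %s", exc)
                continue
            self.queue.offer(message)

    def stop(self) -> None:
        self._stop.set()
        self._thread.join(timeout=2.0)
        self._sock.close()


class StreamConsumer:
    """Receive announcements and hand each mapped frame to a callback.

    The receiver thread only enqueues; mapping and the (potentially slow)
    ``on_frame(message, frames)`` callback run in the caller's thread via
    :meth:`run`, always on the most recent accumulated frame.  Frames whose
    payload vanished or mismatched are counted as skipped, not fatal.
    """

    def __init__(
        self,
        on_frame: Callable[[FrameMessage, np.ndarray], None],
        port: int = 5555,
        bind: str = "127.0.0.1",
    ) -> None:
        self.queue = FrameQueue()
        self.on_frame = on_frame
        self._receiver = Receiver(self.queue, port=port, bind=bind)
        self.port = self._receiver.port
        self.n_processed = 0
        self.n_skipped = 0
        self.last_seqno: Optional[int] = None

    def start(self) -> "StreamConsumer":
        self._receiver.start()
        return self

    def run(self, idle_timeout: float = 2.0) -> None:
        """Process frames until none arrives for ``idle_timeout`` seconds."""
        while True:
            message = self.queue.take_latest(timeout=idle_timeout)
            if message is None:
                return
            try:
                frames = map_frame(message)
            except CorruptFrameError as exc:
                log.warning("skipping frame %s: %s", message.seqno, exc)
                self.n_skipped += 1
                continue
            self.on_frame(message, frames)
            self.n_processed += 1
            self.last_seqno = message.seqno

    def stop(self) -> None:
        self._receiver.stop()

    @property
    def n_superseded(self) -> int:
        """Frames discarded unprocessed (bumped from the queue or out of order)."""
        return self.queue.n_superseded + self.n_skipped
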