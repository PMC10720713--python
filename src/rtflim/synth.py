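"""Synthetic TCSPC data: ground-truth phantoms, Poisson frames, pile-up, replay.

This module makes every other part of the engine testable without a
microscope.  A :class:`ScenePhantom` fixes per-pixel ground truth (lifetime
map, photon budget, constant background); :func:`simulate_series` draws
Poisson photon counts frame by frame and accumulates them exactly the way a
live acquisition does; :func:`distort_pileup` applies a first-photon
censoring distortion that leaves the intensity image untouched while skewing
lifetimes short (the classic detector pile-up signature); and
:func:`replay` pushes a simulated or saved series through the real streaming
transport at a chosen frame rate.

One seed drives a whole series; per-frame substreams are spawned
deterministically from it, so a series is bit-reproducible.
"""

from __future__ import annotations

import hashlib
import time
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator, Optional

import numpy as np

from . import stream as _stream

__all__ = [
    "ScenePhantom",
    "two_region_phantom",
    "expected_rates",
    "simulate_series",
    "iter_series",
    "distort_pileup",
    "replay",
    "REPLAY_SCENARIO",
]

#: Replay benchmark scenario: 50 frames of 256 x 256 pixels x 256 time bins
#: streamed at two frames per second.
REPLAY_SCENARIO = {"n_frames": 50, "rows": 256, "cols": 256, "bins": 256, "fps": 2.0}


@dataclass(frozen=True)
class ScenePhantom:
    """Ground truth for a simulated field of view.

    ``amplitude_map`` is the expected number of *decay* photons each pixel
    collects over one full frame; ``background_rate`` is the expected
    uncorrelated background per bin per frame.  ``tau_map`` must be positive
    wherever the amplitude is positive.  Everything downstream is
    deterministic given ``seed``.
    """

    tau_map: np.ndarray
    amplitude_map: np.ndarray
    background_rate: float
    bins: int
    bin_width: float
    seed: int = 0

    def __post_init__(self) -> None:
        tau = np.asarray(self.tau_map, dtype=float)
        amp = np.asarray(self.amplitude_map, dtype=float)
        if tau.shape != amp.shape or tau.ndim != 2:
            raise ValueError("tau_map and amplitude_map must be matching 2-D arrays")
        if np.any(amp < 0) or self.background_rate < 0:
            raise ValueError("photon budgets must be non-negative")
        if np.any((amp > 0) & ~(tau > 0)):
            raise ValueError("tau_map must be positive wherever amplitude_map > 0")
        if self.bins < 3 or not self.bin_width > 0:
            raise ValueError("need >= 3 bins and positive bin_width")
        object.__setattr__(self, "tau_map", tau)
        object.__setattr__(self, "amplitude_map", amp)

    @property
    def shape(self) -> tuple[int, int, int]:
        return (*self.tau_map.shape, self.bins)


def two_region_phantom(
    rows: int = 64,
    cols: int = 64,
    bins: int = 256,
    bin_width: float = 0.05,
    tau_left: float = 1.0,
    tau_right: float = 3.0,
    photons_per_pixel: float = 1e4,
    background_rate: float = 0.0,
    seed: int = 0,
) -> ScenePhantom:
    """Default phantom: two rectangular regions with distinct lifetimes.

    The left half decays with ``tau_left`` (1 ns) and the right half with
    ``tau_right`` (3 ns) — a minimal two-ROI scene whose phasor clusters are
    cleanly separable.
    """
    tau = np.empty((rows, cols), dtype=float)
    tau[:, : cols // 2] = tau_left
    tau[:, cols // 2:] = tau_right
    amp = np.full((rows, cols), float(photons_per_pixel))
    return ScenePhantom(
        tau_map=tau, amplitude_map=amp, background_rate=background_rate,
        bins=bins, bin_width=bin_width, seed=seed,
    )


def expected_rates(phantom: ScenePhantom) -> np.ndarray:
    """Per-bin expected counts for one full frame, shape [rows, cols, bins].

    The per-pixel photon budget ``amplitude_map`` is spread over bins in
    proportion to ``exp(-t_k / tau)`` sampled at bin starts, so the mean
    follows ``Z + A * exp(-t / tau)`` with ``sum_k A * exp(-t_k/tau)`` equal
    to the budget; the constant background adds ``background_rate`` per bin.
    """
    t = np.arange(phantom.bins) * phantom.bin_width
    with np.errstate(divide="ignore", invalid="ignore"):
        decay = np.exp(-t / np.where(phantom.tau_map > 0, phantom.tau_map, np.inf)[..., None])
    norm = decay.sum(axis=-1)
    peak = np.where(norm > 0, phantom.amplitude_map / np.where(norm > 0, norm, 1.0), 0.0)
    return peak[..., None] * decay + phantom.background_rate


def iter_series(
    phantom: ScenePhantom,
    n_frames: int,
    photons_per_frame_fraction: float = 1.0,
    dtype=np.uint16,
) -> Iterator[np.ndarray]:
    """Yield cumulative frames one at a time (constant memory).

    Frame ``f``'s cumulative counts are frame ``f-1``'s plus a fresh Poisson
    draw whose mean is ``photons_per_frame_fraction`` times the full-frame
    expected rates, so cumulative monotonicity holds by construction.  Each
    frame uses an independent substream spawned from the phantom seed.
    """
    if n_frames < 1:
        raise ValueError("need at least one frame")
    if not photons_per_frame_fraction > 0:
        raise ValueError("photons_per_frame_fraction must be positive")
    rates = expected_rates(phantom) * photons_per_frame_fraction
    streams = np.random.SeedSequence(phantom.seed).spawn(n_frames)
    cumulative = np.zeros(phantom.shape, dtype=dtype)
    for child in streams:
        rng = np.random.Generator(np.random.PCG64(child))
        increment = rng.poisson(rates)
        cumulative = cumulative + increment.astype(dtype)
        yield cumulative.copy()


def simulate_series(
    phantom: ScenePhantom,
    n_frames: int,
    photons_per_frame_fraction: float = 1.0,
    dtype=np.uint16,
) -> list[np.ndarray]:
    """Materialize the whole cumulative series (see :func:`iter_series`)."""
    return list(iter_series(phantom, n_frames, photons_per_frame_fraction, dtype))


def distort_pileup(frames: np.ndarray, saturation: float) -> np.ndarray:
    """Apply a first-photon censoring (pile-up) distortion to histograms.

    In TCSPC only the first photon per excitation cycle is timed, so at high
    count rates late photons are censored by earlier ones.  This is modeled
    by multiplying the detection probability at bin ``k`` by
    ``exp(-saturation * C(k) / C_total)`` where ``C(k)`` is the cumulative
    ideal count *before* bin ``k`` — early bins are over-represented and the
    apparent lifetime shortens.  Each pixel's total is then rescaled to its
    original photon count, so the intensity image is unchanged while the
    lifetime and phasor shift early-ward.  ``saturation=0`` is the identity.

    This is a qualitative stand-in for photon-level dead-time physics: its
    only contract is "intensity preserved, tau and phasor skewed early".
    """
    if not 0.0 <= saturation < 1.0:
        raise ValueError(f"saturation must be in [0, 1), got {saturation}")
    counts = np.asarray(frames, dtype=float)
    total = counts.sum(axis=-1, keepdims=True)
    safe_total = np.where(total > 0, total, 1.0)
    if saturation == 0.0:
        return counts.copy()
    before = np.cumsum(counts, axis=-1) - counts  # cumulative strictly before bin k
    censored = counts * np.exp(-saturation * before / safe_total)
    censored_total = censored.sum(axis=-1, keepdims=True)
    scale = np.where(censored_total > 0, total / np.where(censored_total > 0, censored_total, 1.0), 0.0)
    return censored * scale


def replay(
    series: Iterable[np.ndarray],
    endpoint: tuple[str, int],
    series_dir: Path | str,
    bin_width: float,
    fps: Optional[float] = 2.0,
    series_id: Optional[str] = None,
    keep_last: int = 2,
) -> list[dict]:
    """Stream a cumulative series through the live transport.

    Each frame is written as a memory-mappable payload, announced by UDP,
    and paced at ``fps`` frames per second (``None`` means back-to-back).
    The sender deletes payloads older than ``keep_last`` frames to bound disk
    use.  Returns a manifest with one entry per frame — seqno, send
    timestamp, payload path and SHA-256 of the payload bytes — so a consumer
    can verify bit-exact transport and throughput.
    """
    series_dir = Path(series_dir)
    if series_id is None:
        series_id = f"replay-{int(time.time() * 1000) & 0xFFFFFF:06x}"
    interval = None if fps is None or fps <= 0 else 1.0 / fps
    manifest: list[dict] = []
    written: list[Path] = []
    next_due = time.monotonic()
    for seqno, frames in enumerate(series):
        if interval is not None:
            now = time.monotonic()
            if now < next_due:
                time.sleep(next_due - now)
            next_due = max(next_due + interval, time.monotonic())
        message = _stream.write_frame(frames, series_dir, series_id, seqno, bin_width)
        digest = hashlib.sha256(Path(message.file_path).read_bytes()).hexdigest()
        _stream.notify(message, endpoint)
        manifest.append({
            "series_id": series_id,
            "seqno": seqno,
            "t_sent": time.time(),
            "path": message.file_path,
            "sha256": digest,
        })
        written.append(Path(message.file_path))
        while len(written) > keep_last:
            old = written.pop(0)
            old.unlink(missing_ok=True)
    return manifest
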