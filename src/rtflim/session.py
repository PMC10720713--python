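"""Live-series state: snapshots, delta views and settings persistence.

A :class:`Session` tracks the cumulative histogram of the running
acquisition.  Snapshots are immutable copies taken at user-chosen moments;
the live frame acts as the final, implicit slice.  Delta views subtract
consecutive snapshots to slice the photon stream into temporal sub-datasets
that every analysis (RLD, phasor, selections) accepts exactly like a
cumulative stack.  Analysis settings round-trip through a small versioned
JSON document so a live configuration can be reloaded for post-acquisition
work.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np

__all__ = [
    "Snapshot",
    "AnalysisSettings",
    "Session",
    "NoDataError",
    "InconsistentSeriesError",
    "SettingsError",
    "save_settings",
    "load_settings",
]

SETTINGS_SCHEMA_VERSION = 1


class NoDataError(RuntimeError):
    """No live frame has arrived yet."""


class InconsistentSeriesError(ValueError):
    """A delta view came out negative: the series restarted without a reset."""


class SettingsError(ValueError):
    """Settings file could not be parsed."""


@dataclass(frozen=True)
class Snapshot:
    """Immutable copy of the cumulative histogram at capture time."""

    cumulative: np.ndarray
    seqno_at_capture: int
    timestamp: float

    def __post_init__(self) -> None:
        frozen = np.array(self.cumulative, copy=True)
        frozen.setflags(write=False)
        object.__setattr__(self, "cumulative", frozen)


@dataclass
class AnalysisSettings:
    """Every tunable of the analysis pipeline, JSON-persistable.

    ``None`` thresholds mean "no filtering on this quantity"; ``fit_end=None``
    means "to the last histogram bin".  ``chi2_max`` compares against the
    *reduced* chi-square of the RLD estimate.  ``selections`` holds the
    serialized ROI shapes (see :mod:`rtflim.selection`).
    """

    fit_start: int = 0
    fit_end: Optional[int] = None
    bin_width_ns: float = 0.05
    tau_min: Optional[float] = None
    tau_max: Optional[float] = None
    chi2_max: Optional[float] = None
    colormap: str = "turbo"
    display_tau_range: Optional[tuple[float, float]] = None
    harmonic: int = 1
    selections: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.tau_min is not None and self.tau_max is not None:
            if self.tau_min > self.tau_max:
                raise SettingsError(f"tau thresholds out of order: {self.tau_min} > {self.tau_max}")
        if not self.colormap:
            raise SettingsError("colormap name must be non-empty")
        if self.display_tau_range is not None:
            lo, hi = self.display_tau_range
            self.display_tau_range = (float(lo), float(hi))

    def to_dict(self) -> dict[str, Any]:
        doc = asdict(self)
        doc["schema"] = SETTINGS_SCHEMA_VERSION
        if doc["display_tau_range"] is not None:
            doc["display_tau_range"] = list(doc["display_tau_range"])
        return doc

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "AnalysisSettings":
        """Build settings from a JSON object; unknown keys are ignored and
        missing keys take the documented defaults."""
        known = {f for f in cls.__dataclass_fields__}
        kwargs = {k: v for k, v in doc.items() if k in known}
        if kwargs.get("display_tau_range") is not None:
            kwargs["display_tau_range"] = tuple(kwargs["display_tau_range"])
        return cls(**kwargs)


def save_settings(settings: AnalysisSettings, path: Path | str) -> None:
    Path(path).write_text(json.dumps(settings.to_dict(), indent=2) + "\n")


def load_settings(path: Path | str) -> AnalysisSettings:
    """Load settings JSON; malformed files raise with line information."""
    text = Path(path).read_text()
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise SettingsError(
            f"{path}: invalid JSON at line {exc.lineno}, column {exc.colno}: {exc.msg}"
        ) from exc
    if not isinstance(doc, dict):
        raise SettingsError(f"{path}: settings document must be a JSON object")
    return AnalysisSettings.from_dict(doc)


class Session:
    """One live acquisition: the accumulating frame plus its snapshots.

    Slice indices run ``0 .. n_snapshots``; index ``n_snapshots`` is the live
    frame (the slot reserved for live data after the last stored snapshot).
    """

    def __init__(self, settings: Optional[AnalysisSettings] = None) -> None:
        self.settings = settings or AnalysisSettings()
        self.series_id: Optional[str] = None
        self.live: Optional[np.ndarray] = None
        self.live_seqno: int = -1
        self.snapshots: list[Snapshot] = []

    @property
    def n_snapshots(self) -> int:
        return len(self.snapshots)

    def update_live(self, frames: np.ndarray, seqno: int, series_id: str = "default") -> None:
        """Install the newest accumulated frame; a new series clears snapshots."""
        if series_id != self.series_id:
            self.series_id = series_id
            self.snapshots.clear()
        self.live = np.asarray(frames)
        self.live_seqno = seqno

    def take_snapshot(self) -> Snapshot:
        """Freeze the current cumulative histogram as a new snapshot."""
        if self.live is None:
            raise NoDataError("no live frame has arrived yet")
        snap = Snapshot(
            cumulative=self.live, seqno_at_capture=self.live_seqno,
            timestamp=time.time(),
        )
        self.snapshots.append(snap)
        return snap

    def _cumulative_at(self, index: int) -> np.ndarray:
        if index < self.n_snapshots:
            return self.snapshots[index].cumulative
        if self.live is None:
            raise NoDataError("no live frame has arrived yet")
        return self.live

    def delta_view(self, index: int) -> np.ndarray:
        """Photons that arrived between slice ``index-1`` and slice ``index``.

        Slice 0 is everything up to the first snapshot; slice ``n_snapshots``
        is live-minus-last-snapshot.  Deltas are computed lazily from the
        stored cumulative arrays (never stored themselves), and a negative
        delta — which can only happen if the acquisition restarted without a
        series reset — raises :class:`InconsistentSeriesError`.
        """
        if not 0 <= index <= self.n_snapshots:
            raise IndexError(
                f"slice index {index} out of range 0..{self.n_snapshots}"
            )
        def signed(a: np.ndarray) -> np.ndarray:
            # unsigned counts would wrap on subtraction; floats pass through
            kind = np.int64 if np.issubdtype(a.dtype, np.integer) else np.float64
            return a.astype(kind, copy=False)

        current = signed(self._cumulative_at(index))
        if index == 0:
            return np.array(current, copy=True)
        previous = signed(self._cumulative_at(index - 1))
        delta = current - previous
        if (delta < 0).any():
            raise InconsistentSeriesError(
                "cumulative counts decreased between snapshots; "
                "the series restarted without a reset"
            )
        return delta
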