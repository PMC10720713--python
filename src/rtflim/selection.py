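"""ROI selection in image and phasor space, co-selection, and ROI fitting.

A :class:`Selection` is an ellipse, rectangle or polygon living either in
image coordinates (row, col pixels) or in phasor coordinates (g, s).  Both
kinds resolve to the same thing — a boolean pixel mask over the frame — which
is the single source of truth behind bidirectional highlighting: pixels
chosen in the lifetime image light up in the phasor plot and vice versa.

Averaging the histograms inside a selection reduces the whole ROI to one
decay, cheap enough to refit with the gold-standard Levenberg-Marquardt
optimizer alongside the closed-form RLD estimate.

Hit-testing rules (deterministic by construction):

* a pixel ``(r, c)`` belongs to an image-space shape iff its center
  ``(r + 1/2, c + 1/2)`` lies inside;
* a pixel belongs to a phasor-space shape iff its ``(g, s)`` point lies
  inside; pixels with an undefined phasor are never selected;
* points exactly on a shape boundary count as inside;
* polygons use the even-odd (ray-crossing parity) rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np

from .fitcore import (
    Decay,
    FitWindow,
    LMAResult,
    NoiseModel,
    RLDResult,
    fit_lma,
    fit_rld,
    PhasorField,
)

__all__ = [
    "Selection",
    "CoSelection",
    "EmptySelectionError",
    "shape_mask",
    "coselect",
    "roi_decay",
    "roi_fit",
    "ROIFitReport",
]


class EmptySelectionError(ValueError):
    """The selection contains no pixels."""


@dataclass(frozen=True)
class Selection:
    """A colored shape in image space or phasor space.

    ``params`` by kind:

    * ``rectangle`` — ``{"lo": (y0, x0), "hi": (y1, x1)}`` corner pair;
    * ``ellipse``   — ``{"center": (cy, cx), "radii": (ry, rx)}``;
    * ``polygon``   — ``{"vertices": [(y, x), ...]}`` with >= 3 vertices.

    In image space the coordinate pair is (row, col); in phasor space it is
    read as (g, s).  Degenerate shapes (zero extent) give empty masks rather
    than errors.
    """

    kind: Literal["ellipse", "rectangle", "polygon"]
    params: dict
    space: Literal["image", "phasor"] = "image"
    color_id: int = 0
    visible: bool = True

    def __post_init__(self) -> None:
        if self.kind == "polygon":
            verts = np.asarray(self.params["vertices"], dtype=float)
            if verts.ndim != 2 or verts.shape[0] < 3 or verts.shape[1] != 2:
                raise ValueError("polygon needs >= 3 (y, x) vertices")
        elif self.kind == "ellipse":
            ry, rx = self.params["radii"]
            if ry < 0 or rx < 0:
                raise ValueError("ellipse radii must be non-negative")
        elif self.kind == "rectangle":
            lo = np.asarray(self.params["lo"], float)
            hi = np.asarray(self.params["hi"], float)
            if lo.shape != (2,) or hi.shape != (2,):
                raise ValueError("rectangle corners must be (y, x) pairs")
        else:
            raise ValueError(f"unknown selection kind {self.kind!r}")

    # --- GeoJSON-like serialization (round-trips inside the settings file) ---

    def to_dict(self) -> dict:
        doc: dict = {"space": self.space, "color_id": self.color_id, "visible": self.visible}
        if self.kind == "polygon":
            doc["type"] = "Polygon"
            doc["coordinates"] = np.asarray(self.params["vertices"], float).tolist()
        elif self.kind == "ellipse":
            doc["type"] = "Ellipse"
            doc["center"] = list(map(float, self.params["center"]))
            doc["radii"] = list(map(float, self.params["radii"]))
        else:
            doc["type"] = "Rectangle"
            doc["bounds"] = [
                list(map(float, self.params["lo"])),
                list(map(float, self.params["hi"])),
            ]
        return doc

    @classmethod
    def from_dict(cls, doc: dict) -> "Selection":
        kind = doc["type"].lower()
        common = dict(
            space=doc.get("space", "image"),
            color_id=int(doc.get("color_id", 0)),
            visible=bool(doc.get("visible", True)),
        )
        if kind == "polygon":
            return cls("polygon", {"vertices": doc["coordinates"]}, **common)
        if kind == "ellipse":
            return cls("ellipse", {"center": tuple(doc["center"]),
                                   "radii": tuple(doc["radii"])}, **common)
        if kind == "rectangle":
            lo, hi = doc["bounds"]
            return cls("rectangle", {"lo": tuple(lo), "hi": tuple(hi)}, **common)
        raise ValueError(f"unknown selection type {doc['type']!r}")


def _contains(selection: Selection, y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Vectorized point-in-shape test; boundary points count as inside."""
    if selection.kind == "rectangle":
        (y0, x0), (y1, x1) = selection.params["lo"], selection.params["hi"]
        ylo, yhi = min(y0, y1), max(y0, y1)
        xlo, xhi = min(x0, x1), max(x0, x1)
        return (y >= ylo) & (y <= yhi) & (x >= xlo) & (x <= xhi)
    if selection.kind == "ellipse":
        (cy, cx), (ry, rx) = selection.params["center"], selection.params["radii"]
        if ry == 0 or rx == 0:
            return np.zeros_like(y, dtype=bool)
        return ((y - cy) / ry) ** 2 + ((x - cx) / rx) ** 2 <= 1.0
    # polygon: even-odd rule plus explicit on-edge inclusion
    verts = np.asarray(selection.params["vertices"], dtype=float)
    inside = np.zeros_like(y, dtype=bool)
    on_edge = np.zeros_like(y, dtype=bool)
    n = len(verts)
    for i in range(n):
        y1, x1 = verts[i]
        y2, x2 = verts[(i + 1) % n]
        # parity flip when the horizontal ray from (y, x) crosses edge i
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            x_at = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < np.where(crosses, x_at, np.inf))
        # on-segment: zero cross product and inside the bounding box
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        in_box = (
            (y >= min(y1, y2)) & (y <= max(y1, y2))
            & (x >= min(x1, x2)) & (x <= max(x1, x2))
        )
        on_edge |= (cross == 0) & in_box
    return inside | on_edge


def shape_mask(
    selection: Selection,
    frame_shape: Optional[tuple[int, int]] = None,
    phasor_field: Optional[PhasorField] = None,
) -> np.ndarray:
    """Resolve a selection to a boolean pixel mask.

    Image-space selections need ``frame_shape``; phasor-space selections need
    the ``phasor_field`` of the frame being displayed (its shape defines the
    mask shape, and invalid-phasor pixels are never selected).
    """
    if selection.space == "image":
        if frame_shape is None:
            raise ValueError("image-space selection needs frame_shape")
        rows, cols = frame_shape
        yy, xx = np.meshgrid(
            np.arange(rows) + 0.5, np.arange(cols) + 0.5, indexing="ij"
        )
        return _contains(selection, yy, xx)
    if phasor_field is None:
        raise ValueError("phasor-space selection needs a phasor field")
    g = np.asarray(phasor_field.g, dtype=float)
    s = np.asarray(phasor_field.s, dtype=float)
    valid = np.asarray(phasor_field.valid, dtype=bool)
    # coordinates in phasor space are (g, s); NaNs compare False everywhere
    with np.errstate(invalid="ignore"):
        return _contains(selection, g, s) & valid


@dataclass(frozen=True)
class CoSelection:
    """One pixel set rendered in two views.

    Both highlights are the *same* mask by construction, which is the whole
    point: selecting in either view selects in both.
    """

    selection: Selection
    pixel_mask: np.ndarray

    @property
    def image_highlight(self) -> np.ndarray:
        return self.pixel_mask

    @property
    def phasor_highlight(self) -> np.ndarray:
        return self.pixel_mask


def coselect(
    selection: Selection,
    phasor_field: PhasorField,
    frame_shape: Optional[tuple[int, int]] = None,
) -> CoSelection:
    """Resolve a selection and link its image and phasor highlights.

    The round trip image -> phasor -> image is the identity on the mask
    because there is only one mask.
    """
    shape = frame_shape if frame_shape is not None else phasor_field.shape
    mask = shape_mask(selection, frame_shape=shape, phasor_field=phasor_field)
    return CoSelection(selection=selection, pixel_mask=mask)


def roi_decay(frames: np.ndarray, mask: np.ndarray, bin_width: float) -> Decay:
    """Average the histograms of the selected pixels into one decay."""
    frames = np.asarray(frames)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != frames.shape[:-1]:
        raise ValueError(f"mask shape {mask.shape} != frame shape {frames.shape[:-1]}")
    if not mask.any():
        raise EmptySelectionError("selection contains no pixels")
    mean = frames[mask].astype(float).mean(axis=0)
    return Decay(mean, bin_width)


@dataclass
class ROIFitReport:
    """Everything the decay-plot panel needs for one ROI.

    Raw points, the RLD and LMA model curves sampled over the fit window, the
    numeric parameter estimates for both methods, and the window boundary
    times (the two vertical fit-range markers).  ``status`` is ``"ok"`` when
    both fits ran, ``"rld-invalid"`` when the ROI carried no decay signal (in
    which case the LMA is not attempted and the curves are None).
    """

    decay: Decay
    window: FitWindow
    times: np.ndarray
    raw_counts: np.ndarray
    rld: RLDResult
    lma: Optional[LMAResult]
    rld_curve: Optional[np.ndarray]
    lma_curve: Optional[np.ndarray]
    fit_range_ns: tuple[float, float]
    status: str = "ok"


def roi_fit(
    decay: Decay,
    window: FitWindow,
    noise_model: NoiseModel = "poisson",
) -> ROIFitReport:
    """Fit an ROI-averaged decay with RLD and then refine with LMA.

    The RLD estimate seeds the Levenberg-Marquardt fit, which by construction
    can only lower the chi-square.  If RLD finds no decay signal (flat or
    rising histogram) the report says so explicitly instead of guessing an
    LMA starting point.
    """
    window.validate_for(len(decay))
    t_start = window.start_bin * window.bin_width
    t_end = window.end_bin * window.bin_width
    times = t_start + window.times()
    raw = decay.counts[window.start_bin:window.end_bin]

    rld = fit_rld(decay, window, noise_model=noise_model).single()
    if not rld.valid:
        return ROIFitReport(
            decay=decay, window=window, times=times, raw_counts=raw,
            rld=rld, lma=None, rld_curve=None, lma_curve=None,
            fit_range_ns=(t_start, t_end), status="rld-invalid",
        )
    lma = fit_lma(decay, window, init=rld, noise_model=noise_model)
    # sample both model curves directly: a fitted background may dip below
    # zero, which Decay (a measured histogram) would rightly reject
    t = window.times()
    rld_curve = rld.Z + rld.A * np.exp(-t / rld.tau)
    lma_curve = lma.Z + lma.A * np.exp(-t / lma.tau)
    return ROIFitReport(
        decay=decay, window=window, times=times, raw_counts=raw,
        rld=rld, lma=lma, rld_curve=rld_curve, lma_curve=lma_curve,
        fit_range_ns=(t_start, t_end), status="ok",
    )
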