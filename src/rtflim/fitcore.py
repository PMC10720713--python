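"""Per-decay and per-pixel TCSPC numerics.

This module holds every estimator the engine runs on photon-arrival
histograms: the mono-exponential decay model, closed-form rapid lifetime
determination (RLD) from three contiguous time gates, the phasor (Fourier)
transform, Levenberg-Marquardt (LMA) least-squares refinement, and the
chi-square goodness-of-fit statistic.  All estimators are vectorized over
arbitrary leading axes so that a full ``[rows, cols, bins]`` frame is fitted
in a handful of NumPy array operations rather than a Python loop over pixels.

Conventions
-----------
* Time bins are 0-based; fit windows are half-open ``[start_bin, end_bin)``.
* Within a window, bin ``k`` is evaluated at its *start* time ``k * bin_width``
  relative to the window start (the decay model and RLD), while the phasor
  transform uses bin *centers* ``(k + 1/2) * bin_width`` so that a uniform
  histogram maps exactly to the phasor origin.
* Pixels that cannot be fitted (no photons, no net decay) are flagged in a
  boolean ``valid`` mask and carry NaN in the numeric fields; they are never
  raised as errors because real frames routinely contain dark pixels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence, Union

import numpy as np

__all__ = [
    "FitWindow",
    "Decay",
    "RLDResult",
    "RLDField",
    "LMAResult",
    "PhasorPoint",
    "PhasorField",
    "InvalidParameterError",
    "InvalidWindowError",
    "decay_model",
    "fit_rld",
    "fit_lma",
    "phasor",
    "chi_square",
    "ChiSquare",
]

NoiseModel = Literal["poisson", "gaussian"]


class InvalidParameterError(ValueError):
    """A model or fit parameter violates its domain (e.g. tau <= 0)."""


class InvalidWindowError(ValueError):
    """A fit window is unusable for the given histogram."""


@dataclass(frozen=True)
class FitWindow:
    """Half-open range of histogram bins used for analysis.

    Parameters
    ----------
    start_bin, end_bin
        0-based bin indices; the window covers ``[start_bin, end_bin)``.
        At least three bins are required (RLD needs three gates).
    bin_width
        Time per histogram bin in nanoseconds.
    """

    start_bin: int
    end_bin: int
    bin_width: float

    def __post_init__(self) -> None:
        if not (0 <= self.start_bin < self.end_bin):
            raise InvalidWindowError(
                f"need 0 <= start_bin < end_bin, got [{self.start_bin}, {self.end_bin})"
            )
        if self.n_bins < 3:
            raise InvalidWindowError(
                f"window [{self.start_bin}, {self.end_bin}) has {self.n_bins} bins; "
                "at least 3 are required"
            )
        if not self.bin_width > 0:
            raise InvalidWindowError(f"bin_width must be positive, got {self.bin_width}")

    @property
    def n_bins(self) -> int:
        return self.end_bin - self.start_bin

    @property
    def duration(self) -> float:
        """Window span in nanoseconds."""
        return self.n_bins * self.bin_width

    def validate_for(self, total_bins: int) -> None:
        """Raise if the window does not fit inside a histogram of ``total_bins``."""
        if self.end_bin > total_bins:
            raise InvalidWindowError(
                f"window end {self.end_bin} exceeds histogram length {total_bins}"
            )

    def times(self, offset: float = 0.0) -> np.ndarray:
        """Bin evaluation times relative to the window start (ns)."""
        return (np.arange(self.n_bins) + offset) * self.bin_width


@dataclass(frozen=True)
class Decay:
    """A single photon-arrival histogram with its time calibration."""

    counts: np.ndarray
    bin_width: float

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 1 or counts.size < 3:
            raise ValueError("decay needs a 1-D histogram of at least 3 bins")
        if np.any(counts < 0):
            raise ValueError("photon counts must be non-negative")
        if not self.bin_width > 0:
            raise ValueError("bin_width must be positive")
        object.__setattr__(self, "counts", counts)

    def __len__(self) -> int:
        return self.counts.size


@dataclass(frozen=True)
class RLDResult:
    """Closed-form triple-gate fit of one decay: Z + A*exp(-t/tau)."""

    Z: float
    A: float
    tau: float
    chi2: float
    chi2_reduced: float
    valid: bool


@dataclass
class RLDField:
    """Per-pixel RLD maps over a frame (or any stack of decays).

    All arrays share the shape of the input's leading axes; invalid pixels
    hold NaN and ``valid`` is False there.
    """

    Z: np.ndarray
    A: np.ndarray
    tau: np.ndarray
    chi2: np.ndarray
    chi2_reduced: np.ndarray
    valid: np.ndarray
    window: FitWindow = field(repr=False)

    @property
    def shape(self) -> tuple:
        return self.tau.shape

    def single(self) -> RLDResult:
        """Collapse a scalar field (fit of one decay) to an ``RLDResult``."""
        if self.tau.shape != ():
            raise ValueError(f"field has shape {self.tau.shape}, not scalar")
        return RLDResult(
            Z=float(self.Z),
            A=float(self.A),
            tau=float(self.tau),
            chi2=float(self.chi2),
            chi2_reduced=float(self.chi2_reduced),
            valid=bool(self.valid),
        )


@dataclass(frozen=True)
class LMAResult:
    """Levenberg-Marquardt refinement of (Z, A, tau) for one decay."""

    Z: float
    A: float
    tau: float
    chi2: float
    chi2_reduced: float
    n_iterations: int
    converged: bool


@dataclass(frozen=True)
class PhasorPoint:
    """Fourier coordinates of one decay at a given harmonic."""

    g: float
    s: float
    harmonic: int
    omega: float
    valid: bool


@dataclass
class PhasorField:
    """Per-pixel phasor coordinates; ``omega`` is shared by all pixels."""

    g: np.ndarray
    s: np.ndarray
    harmonic: int
    omega: float
    valid: np.ndarray

    @property
    def shape(self) -> tuple:
        return self.g.shape

    def single(self) -> PhasorPoint:
        if self.g.shape != ():
            raise ValueError(f"field has shape {self.g.shape}, not scalar")
        return PhasorPoint(
            g=float(self.g), s=float(self.s), harmonic=self.harmonic,
            omega=self.omega, valid=bool(self.valid),
        )


def _counts_array(data: Union[Decay, np.ndarray]) -> tuple[np.ndarray, float | None]:
    if isinstance(data, Decay):
        return data.counts, data.bin_width
    return np.asarray(data, dtype=float), None


def decay_model(Z: float, A: float, tau: float, window: FitWindow) -> Decay:
    """Mono-exponential model histogram over a fit window.

    ``counts[k] = Z + A * exp(-k * bin_width / tau)`` for ``k`` in
    ``0 .. n_bins-1``, evaluated at bin start times relative to the window
    start.  ``tau`` must be positive.
    """
    if not tau > 0:
        raise InvalidParameterError(f"tau must be positive, got {tau}")
    t = window.times()
    return Decay(Z + A * np.exp(-t / tau), window.bin_width)


def _sigma2(observed: np.ndarray, noise_model: NoiseModel) -> np.ndarray:
    """Per-bin variance under the chosen noise model."""
    if noise_model == "poisson":
        return np.maximum(observed, 1.0)
    if noise_model == "gaussian":
        return np.ones_like(observed)
    raise ValueError(f"unknown noise model {noise_model!r}")


@dataclass(frozen=True)
class ChiSquare:
    value: float
    reduced: float
    dof: int


def chi_square(
    observed: Union[Decay, np.ndarray],
    model: Union[Decay, np.ndarray],
    window: FitWindow | None = None,
    noise_model: NoiseModel = "poisson",
) -> ChiSquare:
    """Weighted sum of squared residuals between data and model.

    ``chi2 = sum_k (obs_k - model_k)^2 / sigma2_k`` with the Poisson variance
    ``sigma2_k = max(obs_k, 1)`` by default (Gaussian-constant: ``sigma2 = 1``).
    The reduced form divides by ``N - 3`` degrees of freedom (three fitted
    parameters).  If ``window`` is given, both histograms are first sliced to
    it; otherwise they are compared full-length (then they must already be the
    window-restricted vectors).
    """
    obs, _ = _counts_array(observed)
    mod, _ = _counts_array(model)
    if window is not None:
        if obs.shape[-1] != mod.shape[-1]:
            raise ValueError("observed and model have different lengths")
        # Slice only if the arrays still span the full histogram.
        if obs.shape[-1] > window.n_bins:
            obs = obs[..., window.start_bin:window.end_bin]
            mod = mod[..., window.start_bin:window.end_bin]
    if obs.shape != mod.shape:
        raise ValueError(f"length mismatch: {obs.shape} vs {mod.shape}")
    resid2 = (obs - mod) ** 2 / _sigma2(obs, noise_model)
    value = float(resid2.sum())
    dof = max(obs.shape[-1] - 3, 1)
    return ChiSquare(value=value, reduced=value / dof, dof=dof)


def fit_rld(
    frames: Union[Decay, np.ndarray],
    window: FitWindow,
    noise_model: NoiseModel = "poisson",
) -> RLDField:
    """Triple-integral rapid lifetime determination, vectorized over pixels.

    The window is split into three equal contiguous gates of
    ``m = floor(n_bins / 3)`` bins (trailing remainder bins are ignored).
    With gate sums ``S1, S2, S3`` of the model ``Z + A * x**k``
    (``x = exp(-bin_width / tau)``) the gate differences cancel the constant
    background, giving the exact closed form::

        R   = (S1 - S2) / (S2 - S3) = x**(-m)
        tau = m * bin_width / ln(R)
        G   = (1 - x**m) / (1 - x)          # geometric sum over one gate
        A   = (S1 - S2) / (G * (1 - x**m))
        Z   = (S1 - A * G) / m

    Pixels where ``S1 - S2 <= 0``, ``S2 - S3 <= 0`` or ``R <= 1`` carry no
    usable decay signal and are flagged invalid (NaN parameters), not raised.
    ``chi2`` is evaluated against the fitted model over the *full* window.

    Parameters
    ----------
    frames
        A single :class:`Decay` or an array whose last axis is time bins —
        e.g. a ``[rows, cols, bins]`` frame.  The result's arrays have the
        shape of the leading axes (scalar for a single decay).
    """
    counts, _ = _counts_array(frames)
    window.validate_for(counts.shape[-1])
    delta = window.bin_width
    n = window.n_bins
    m = n // 3

    w = counts[..., window.start_bin:window.end_bin]
    S1 = w[..., :m].sum(axis=-1)
    S2 = w[..., m:2 * m].sum(axis=-1)
    S3 = w[..., 2 * m:3 * m].sum(axis=-1)

    d12 = S1 - S2
    d23 = S2 - S3
    with np.errstate(divide="ignore", invalid="ignore"):
        R = d12 / d23
        valid = (d12 > 0) & (d23 > 0) & (R > 1)
        logR = np.log(np.where(valid, R, 2.0))
        tau = np.where(valid, m * delta / logR, np.nan)
        x = np.exp(-delta / tau)
        xm = np.where(valid, 1.0 / R, np.nan)  # x**m, exact from the gate ratio
        G = (1.0 - xm) / (1.0 - x)
        A = d12 / (G * (1.0 - xm))
        Z = (S1 - A * G) / m

    nan = np.full_like(tau, np.nan)
    tau = np.where(valid, tau, nan)
    A = np.where(valid, A, nan)
    Z = np.where(valid, Z, nan)

    # Goodness of fit over the full window against the fitted model.
    t = window.times()
    with np.errstate(invalid="ignore", over="ignore"):
        model = Z[..., None] + A[..., None] * np.exp(-t / tau[..., None])
        resid2 = (w - model) ** 2 / _sigma2(w, noise_model)
        chi2 = np.where(valid, resid2.sum(axis=-1), np.nan)
    dof = max(n - 3, 1)
    return RLDField(
        Z=Z, A=A, tau=tau, chi2=chi2, chi2_reduced=chi2 / dof,
        valid=valid, window=window,
    )


def phasor(
    frames: Union[Decay, np.ndarray],
    window: FitWindow,
    harmonic: int = 1,
) -> PhasorField:
    """Phasor (discrete Fourier) transform of decays over a fit window.

    Over window bins ``k = 0 .. N-1`` with bin-center times
    ``t_k = (k + 1/2) * bin_width`` and angular frequency
    ``omega = 2*pi*harmonic / (N * bin_width)``::

        g = sum_k c_k cos(omega t_k) / sum_k c_k
        s = sum_k c_k sin(omega t_k) / sum_k c_k

    For non-negative counts with positive total, (g, s) lies in the closed
    unit disc; mono-exponential decays fall on the universal semicircle
    ``(g - 1/2)**2 + s**2 = 1/4`` in the fine-binning limit.  Pixels with zero
    total counts in the window are flagged invalid.
    """
    if harmonic < 1:
        raise InvalidParameterError(f"harmonic must be >= 1, got {harmonic}")
    counts, _ = _counts_array(frames)
    window.validate_for(counts.shape[-1])
    N = window.n_bins
    t = window.times(offset=0.5)
    omega = 2.0 * np.pi * harmonic / (N * window.bin_width)

    w = counts[..., window.start_bin:window.end_bin]
    total = w.sum(axis=-1)
    valid = total > 0
    safe_total = np.where(valid, total, 1.0)
    with np.errstate(invalid="ignore"):
        g = (w * np.cos(omega * t)).sum(axis=-1) / safe_total
        s = (w * np.sin(omega * t)).sum(axis=-1) / safe_total
    nan = np.full_like(g, np.nan)
    g = np.where(valid, g, nan)
    s = np.where(valid, s, nan)
    return PhasorField(g=g, s=s, harmonic=harmonic, omega=float(omega), valid=valid)


def _as_init(init) -> tuple[float, float, float]:
    if isinstance(init, RLDResult):
        if not init.valid:
            raise InvalidParameterError("RLD initialization is invalid (no decay signal)")
        triple = (init.Z, init.A, init.tau)
    else:
        triple = tuple(float(v) for v in init)
        if len(triple) != 3:
            raise InvalidParameterError("explicit init must be a (Z, A, tau) triple")
    if not all(np.isfinite(triple)):
        raise InvalidParameterError(f"non-finite initialization {triple}")
    if not triple[2] > 0:
        raise InvalidParameterError(f"initial tau must be positive, got {triple[2]}")
    return triple


def fit_lma(
    decay: Union[Decay, np.ndarray],
    window: FitWindow,
    init: Union[RLDResult, Sequence[float]],
    noise_model: NoiseModel = "poisson",
    max_iterations: int = 100,
    rtol: float = 1e-6,
) -> LMAResult:
    """Levenberg-Marquardt mono-exponential fit of one decay.

    Minimizes ``chi2 = sum_k (c_k - Z - A*exp(-t_k/tau))**2 / sigma2_k`` over
    ``(Z, A, tau)`` with fixed per-bin variances taken from the observed
    counts (Poisson: ``max(c_k, 1)``).  Classic Marquardt damping: the normal
    equations are solved with the diagonal scaled by ``(1 + lam)``, ``lam``
    starting at 1e-3, divided by 10 after an accepted step and multiplied by
    10 after a rejected one.  Iteration stops when the relative chi2
    improvement of an accepted step falls below ``rtol`` (converged) or after
    ``max_iterations`` (not converged; best-so-far parameters are returned).
    Steps that would drive ``tau`` non-positive are rejected.

    Because only improving steps are ever accepted, the returned ``chi2``
    never exceeds that of the initialization.
    """
    counts, _ = _counts_array(decay)
    if counts.ndim != 1:
        raise ValueError("fit_lma fits a single decay; use fit_rld for frames")
    window.validate_for(counts.shape[-1])
    Z, A, tau = _as_init(init)

    obs = counts[window.start_bin:window.end_bin]
    t = window.times()
    weights = 1.0 / _sigma2(obs, noise_model)
    dof = max(obs.size - 3, 1)

    def model_of(p):
        return p[0] + p[1] * np.exp(-t / p[2])

    def chi2_of(p):
        r = obs - model_of(p)
        return float((weights * r * r).sum())

    p = np.array([Z, A, tau], dtype=float)
    chi2 = chi2_of(p)
    lam = 1e-3
    converged = False
    n_iter = 0
    for n_iter in range(1, max_iterations + 1):
        e = np.exp(-t / p[2])
        J = np.stack([np.ones_like(t), e, p[1] * e * t / p[2] ** 2], axis=-1)
        r = obs - model_of(p)
        JW = J * weights[:, None]
        H = JW.T @ J
        grad = JW.T @ r
        try:
            step = np.linalg.solve(H + lam * np.diag(np.diag(H)), grad)
        except np.linalg.LinAlgError:
            lam *= 10.0
            continue
        cand = p + step
        if not cand[2] > 0 or not np.all(np.isfinite(cand)):
            lam *= 10.0
            continue
        chi2_new = chi2_of(cand)
        if chi2_new <= chi2:
            improvement = chi2 - chi2_new
            p, chi2 = cand, chi2_new
            lam = max(lam / 10.0, 1e-12)
            if improvement <= rtol * max(chi2, np.finfo(float).tiny):
                converged = True
                break
        else:
            lam *= 10.0
            if lam > 1e12:
                break  # damping saturated: report best-so-far, not converged
    return LMAResult(
        Z=float(p[0]), A=float(p[1]), tau=float(p[2]),
        chi2=chi2, chi2_reduced=chi2 / dof,
        n_iterations=n_iter, converged=converged,
    )
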