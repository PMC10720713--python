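# Methods

This note records the models, conventions, parameter choices and known
limitations behind `rtflim`.

## Decay model and fit window

All estimators assume a mono-exponential decay with constant background,

    c(t) = Z + A · exp(−t / τ),

sampled on histogram bins of width δ (ns). Fit windows are half-open bin
ranges `[start, end)`, 0-based, at least three bins long. Within a window,
bin *k* is evaluated at its start time `k·δ` for the decay model, RLD and
LMA; the phasor transform uses bin centers `(k+½)·δ`. The center convention
makes the phasor of a uniform histogram exactly (0, 0) — the full-period
cosine and sine sums vanish at bin centers — while the start convention keeps
the RLD gate algebra exact on sampled model decays.

Instrument-response convolution, multi-exponential models, global analysis
and IRF deconvolution are out of scope throughout.

## Rapid lifetime determination

The triple-gate (three equal contiguous integrals) scheme is used: with
`m = ⌊n/3⌋` bins per gate (trailing remainder ignored) and gate sums
S₁, S₂, S₃,

    R = (S₁−S₂)/(S₂−S₃) = e^{mδ/τ},   τ = mδ / ln R,
    G = (1−x^m)/(1−x),  x = e^{−δ/τ},
    A = (S₁−S₂)/(G(1−x^m)),   Z = (S₁ − A·G)/m.

The gate differences cancel any constant background, so the estimator is
exact (to float rounding) on noiseless sampled decays, which the test suite
verifies at 1e−9 relative tolerance over τ ∈ {0.5, 1, 2, 5} ns and
Z ∈ {0, 10}. Pixels with `S₁−S₂ ≤ 0`, `S₂−S₃ ≤ 0` or `R ≤ 1` carry no
fittable decay; they get NaN parameters and a False entry in the validity
mask rather than raising, because dark pixels are a normal feature of real
frames.

## Phasor transform

`g` and `s` are the cosine and sine Fourier coefficients at
`ω = 2π·h/(N·δ)` — the frequency is defined from the *fit window span*, not
from the laser repetition period, because the engine receives no hardware
metadata. (If the window spans exactly one repetition period the two
definitions coincide.) With bin-center sampling the discrete transform
converges to the continuous closed form
`(g, s) = (1/(1+(ωτ)²), ωτ/(1+(ωτ)²))` at O((δ/τ)²); at 1024 bins the
residual from the universal semicircle is below 1e−5, comfortably inside the
1e−3 bound the tests assert. The transform is linear in the counts, so the
phasor of any mixture is the photon-weighted convex combination of the
component phasors — asserted exactly.

## Chi-square and noise models

χ² = Σ (c_k − model_k)²/σ²_k. The default noise model is Poisson counting
statistics with the observed-count (Neyman) variance estimate
σ²_k = max(c_k, 1); a Gaussian-constant option (σ² = 1) exists for
non-counting data. The reduced form divides by N − 3 (three fitted
parameters). Neyman weighting biases E[χ²_red] upward by roughly 2/μ per
bin, noticeable below ~20 counts/bin; the Monte-Carlo calibration tests
therefore use histograms bright enough for the bias to stay within their
asserted bands. Thresholding in the render stage compares the *reduced*
χ² against the user's bound, since a raw χ² bound would depend on window
length.

## Levenberg–Marquardt refit

Classic Marquardt damping on the normal equations: solve
`(JᵀWJ + λ·diag(JᵀWJ)) Δ = JᵀW r`, with λ starting at 1e−3, ÷10 after an
accepted (χ²-decreasing) step and ×10 after a rejected one; steps driving
τ ≤ 0 are rejected. Iteration stops when the relative χ² improvement of an
accepted step drops below 1e−6 (converged) or after 100 iterations
(best-so-far returned, `converged=False`). Weights are held fixed at the
observed-count estimate during the fit, making the objective an ordinary
weighted least squares whose optimum is cross-checked in the tests against
SciPy's independent trust-region LM implementation. Because only improving
steps are accepted, the final χ² can never exceed the RLD seed's — an
invariant asserted on every fit the suite runs. The LMA path is intended for
ROI-averaged decays (one fit per selection), not per-pixel use.

## Streaming transport and queue policy

Each frame is written to its own raw little-endian C-ordered file (time bin
fastest-varying) and announced with a ≤1 KB JSON datagram over UDP; both
sides memory-map the payload, so no copy is made before the analysis slices
its fit window. UDP loss needs no recovery protocol: a lost announcement is
simply superseded by the next frame's. The consumer keeps at most one
pending announcement per series — a newer seqno replaces an unread older
one, out-of-order or duplicate datagrams are dropped by seqno monotonicity,
and a new series id flushes the queue and retires the old id (stragglers
from retired series are discarded as stale). Reception and analysis run on
separate threads and the receive path never blocks on analysis. The
accounting identity `processed + superseded = sent`, the strict monotonicity
of processed seqnos, and the guarantee that the final frame of an idle
stream is always processed are asserted under the benchmark replay scenario
(50 cumulative frames of 256×256×256 uint16 at 2 frames per second). The
sender deletes payload files older than two frames to bound disk use;
frames are assumed cumulative (monotone non-decreasing counts), matching an
accumulating TCSPC acquisition.

## Snapshots and delta views

Snapshots store immutable *cumulative* copies; deltas are computed lazily as
differences of consecutive cumulative arrays (index n = live minus last
snapshot). Storing cumulative data makes the telescoping identity
`Σ deltas = live` exact by construction in integer arithmetic, which the
tests assert bit-exactly. A negative delta can only arise from an
acquisition restart without a series reset and raises an explicit
inconsistency error; a new series id clears all snapshots. Settings persist
as a versioned JSON document (`"schema": 1`); unknown keys are ignored on
load and missing keys take the documented defaults, so older and newer
files interoperate.

## Selections and co-selection

Shapes are ellipses, axis-aligned rectangles, and simple polygons, in image
coordinates (pixel centers at (r+½, c+½)) or phasor coordinates (g, s).
Boundary points count as inside, and polygons use the even-odd rule —
deterministic tie-breaks chosen for reproducibility; the polygon test is
property-checked against an independent computational-geometry oracle.
Phasor-space hit-testing evaluates each pixel's actual (g, s) value rather
than a rasterized 2-D histogram: exact at the frame sizes the engine
targets. Both views of a selection share one pixel mask, so image↔phasor
round trips are identities by construction rather than by reconciliation.

## Synthetic data generator

A `ScenePhantom` fixes a per-pixel lifetime map, a per-pixel expected photon
budget per full frame (spread across bins proportional to `e^{−t/τ}`), and a
constant per-bin background. Frames are independent Poisson draws
accumulated cumulatively; one seed drives a series through per-frame
spawned substreams, so a series is bit-reproducible. The default phantom is
two rectangular regions at τ = 1 ns and 3 ns — the minimal scene with two
separable phasor clusters. Default study conditions used by the tests and
the acceptance script: 128 bins of 0.1 ns (a 12.8 ns window, matching a
~78 MHz pulsed laser) for statistical checks, 10⁴ photons/pixel as the
"well-exposed" budget, and the 50-frame 256×256×256 @ 2 fps shape for the
streaming scenario. The generator emulates Poisson shot noise and cumulative
accumulation only — no IRF convolution, detector afterpulsing, dark noise
structure, scanner distortion or photobleaching — so passing tests
demonstrate estimator and pipeline correctness under ideal counting
statistics, not robustness to every real-detector artifact.

The pile-up mode multiplies the detection probability at bin *k* by
`exp(−saturation·C(k)/C_total)` (C(k) = cumulative ideal counts before *k*)
and rescales each pixel to its original total — a first-photon censoring
approximation, not photon-level dead-time Monte-Carlo. Its contract is
qualitative and matches what matters for the artifact's signature: the
intensity image is preserved exactly while lifetimes shorten and phasor
clusters move along/inside the semicircle toward (1, 0).

## Numerical and design choices

- Invalid pixels: NaN sentinels plus a boolean mask, never exceptions.
- Bin indexing 0-based, windows half-open; little-endian C-order on disk.
- Default colormap turbo; brightness normalized by the 99th-percentile
  intensity (robust to hot pixels), optionally pinned via `intensity_norm`
  for cross-frame comparability; display τ range defaults to the
  [1st, 99th] percentile of passing lifetimes.
- The χ² threshold applies to the reduced statistic (documented above).
- The ROI-averaged decay keeps fractional counts; Poisson weights apply
  unchanged since only relative weights matter to the optimizer.

## Known limitations

- Mono-exponential only; multi-component mixtures appear as intermediate
  lifetimes in RLD/LMA (the phasor view resolves them geometrically).
- The Neyman χ² weighting degrades below a few counts per bin; rebin or
  restrict the window for very dim data.
- The transport is single-consumer, same-host, unencrypted by design.
- uint16 frame payloads saturate at 65535 counts/bin/pixel; choose uint32
  sidecars for very long accumulations.
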