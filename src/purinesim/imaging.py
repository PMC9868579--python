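"""Ca2+-imaging trace extraction from (T, M, N) fluorescence stacks.

The pipeline mirrors a standard widefield Fluo-4 workflow: sum the stack
along time, log-transform and min-max normalize the total image, threshold
it (Otsu by default, manual override supported), label connected components
as cells, then read each cell's mean gray-scale intensity per frame from
the original stack.  Traces are normalized against a pre-stimulus control
window either by division (default) or subtraction.  A displacement helper
converts pixel vectors to micrometers (1.6 um/px brightfield scale).

A seeded synthetic-stack generator (Gaussian-blob cells, injected Ca2+
transients, Poisson/Gaussian noise) provides ground truth so the whole
pipeline is testable without microscope data.  Touching cells are merged by
the connected-component step -- there is no watershed splitting -- and
motion/photobleaching correction is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label

MICRONS_PER_PIXEL = 1.6   # brightfield displacement scale


@dataclass
class ImageStack:
    """16-bit grayscale stack shaped (T, M, N) with a frame interval (s)."""

    data: np.ndarray
    frame_interval: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or self.data.shape[0] < 2:
            raise ValueError("stack must be (T, M, N) with T >= 2")
        if np.any(self.data < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval


@dataclass
class TraceSet:
    """Per-cell raw and normalized traces plus the label map they came from."""

    labels: np.ndarray            # (M, N) int, 0 = background
    raw: np.ndarray               # (K, T)
    normalized: np.ndarray        # (K, T)
    mode: str                     # "divide" | "subtract"
    control_frames: tuple[int, int]
    frame_interval: float = 2.0

    @property
    def n_cells(self) -> int:
        return self.raw.shape[0]

    def to_frame(self) -> pd.DataFrame:
        t = np.arange(self.raw.shape[1]) * self.frame_interval
        df = pd.DataFrame({"time_s": t})
        for k in range(self.n_cells):
            df[f"cell_{k + 1}"] = self.normalized[k]
        return df


def detect_cells(stack: ImageStack, threshold: float | str = "auto") -> np.ndarray:
    """Segment cell bodies from the time-summed image.

    Pipeline: time-sum -> log transform -> min-max normalization ->
    binarize at ``threshold`` (fraction in [0, 1], or "auto" for Otsu on
    the normalized image) -> connected-component labeling.  Returns the
    (M, N) integer label map; an all-background result is returned empty
    with a warning rather than raised.
    """
    total = stack.data.astype(np.float64).sum(axis=0)
    logged = np.log1p(total)
    lo, hi = logged.min(), logged.max()
    if hi <= lo:
        warnings.warn("uniform stack: no cells detected", stacklevel=2)
        return np.zeros(total.shape, dtype=np.int32)
    norm = (logged - lo) / (hi - lo)
    thr = threshold_otsu(norm) if threshold == "auto" else float(threshold)
    binary = norm > thr
    if not binary.any():
        warnings.warn("threshold left no foreground pixels", stacklevel=2)
        return np.zeros(total.shape, dtype=np.int32)
    return cc_label(binary, connectivity=2).astype(np.int32)


def extract_traces(
    stack: ImageStack,
    labels: np.ndarray,
    control_window: tuple[float, float],
    mode: str = "divide",
) -> TraceSet:
    """Mean per-cell intensity per frame, normalized to the control phase.

    ``control_window`` is (start_s, end_s) of the pre-stimulus phase;
    ``mode="divide"`` divides each trace by its control-phase mean (F/F0),
    ``mode="subtract"`` subtracts it (delta-F).
    """
    if mode not in ("divide", "subtract"):
        raise ValueError("mode must be 'divide' or 'subtract'")
    t0, t1 = control_window
    f0 = int(np.floor(t0 / stack.frame_interval))
    f1 = int(np.ceil(t1 / stack.frame_interval))
    f0, f1 = max(f0, 0), min(f1, stack.n_frames)
    if f1 <= f0:
        raise ValueError("control window is empty")
    ks = [k for k in np.unique(labels) if k != 0]
    raw = np.empty((len(ks), stack.n_frames))
    flat = stack.data.reshape(stack.n_frames, -1).astype(np.float64)
    lab_flat = np.asarray(labels).ravel()
    for row, k in enumerate(ks):
        raw[row] = flat[:, lab_flat == k].mean(axis=1)
    ctrl = raw[:, f0:f1].mean(axis=1, keepdims=True)
    if mode == "divide":
        if np.any(ctrl == 0):
            raise ValueError("zero control-phase intensity; cannot divide")
        normalized = raw / ctrl
    else:
        normalized = raw - ctrl
    return TraceSet(
        labels=np.asarray(labels),
        raw=raw,
        normalized=normalized,
        mode=mode,
        control_frames=(f0, f1),
        frame_interval=stack.frame_interval,
    )


def moving_stats(trace: np.ndarray, window: int) -> tuple[np.ndarray, np.ndarray]:
    """Centered moving average and running variance, edges truncated."""
    trace = np.asarray(trace, float)
    if window < 1:
        raise ValueError("window must be >= 1")
    if window > trace.size:
        raise ValueError("window longer than trace")
    s = pd.Series(trace).rolling(window, center=True, min_periods=1)
    return s.mean().to_numpy(), s.var(ddof=0).fillna(0.0).to_numpy()


def ensemble_summary(traces: np.ndarray, window: int = 8):
    """Smoothed ensemble mean trace and variance band (window-8 moving
    average, matching the figure processing convention)."""
    mean_trace = np.asarray(traces, float).mean(axis=0)
    return moving_stats(mean_trace, window)


def measure_displacement(
    p_start: tuple[float, float],
    p_end: tuple[float, float],
    scale: float = MICRONS_PER_PIXEL,
) -> float:
    """Euclidean pixel displacement converted to micrometers."""
    d = np.hypot(p_end[0] - p_start[0], p_end[1] - p_start[1])
    return float(d * scale)


@dataclass
class SynthSpec:
    """Recipe for a synthetic stack with known ground truth."""

    n_cells: int = 12
    shape: tuple[int, int] = (128, 128)
    n_frames: int = 120
    frame_interval: float = 2.0
    radius: float = 6.0            # px cell radius
    baseline: float = 400.0        # counts
    background: float = 40.0       # counts
    transient_amplitude: float = 600.0
    transient_onset_frame: int = 40
    transient_decay_frames: float = 20.0
    gaussian_sigma: float = 0.0    # additive read noise (counts)
    poisson: bool = False          # shot noise
    seed: int = 0
    centers: list[tuple[int, int]] | None = None


@dataclass
class SynthTruth:
    labels: np.ndarray
    centers: np.ndarray            # (K, 2) row, col
    traces: np.ndarray             # (K, T) clean mean cell intensity


def synth_stack(spec: SynthSpec) -> tuple[ImageStack, SynthTruth]:
    """Generate a reproducible stack of Gaussian-blob cells with injected
    transients; returns the stack and its ground truth (labels + clean
    traces).  Cells whose footprint would leave the frame are rejected.
    """
    rng = np.random.default_rng(spec.seed)
    m, n = spec.shape
    r = spec.radius
    if spec.centers is not None:
        centers = np.asarray(spec.centers, float)
        if len(centers) != spec.n_cells:
            raise ValueError("centers length must equal n_cells")
    else:
        # jittered grid placement keeps blobs disjoint
        per_side = int(np.ceil(np.sqrt(spec.n_cells)))
        gy = np.linspace(2.5 * r, m - 2.5 * r, per_side)
        gx = np.linspace(2.5 * r, n - 2.5 * r, per_side)
        grid = [(y, x) for y in gy for x in gx][: spec.n_cells]
        jitter = rng.uniform(-0.5 * r, 0.5 * r, size=(spec.n_cells, 2))
        centers = np.asarray(grid) + jitter
    if np.any(centers[:, 0] < r) or np.any(centers[:, 0] > m - r) or \
       np.any(centers[:, 1] < r) or np.any(centers[:, 1] > n - r):
        raise ValueError("cell footprint extends beyond the frame")

    yy, xx = np.mgrid[0:m, 0:n]
    labels = np.zeros((m, n), np.int32)
    profiles = np.zeros((spec.n_cells, m, n))
    sigma = r / 2.0
    for k, (cy, cx) in enumerate(centers):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        profiles[k] = np.exp(-d2 / (2 * sigma**2))
        labels[d2 <= r**2] = k + 1

    t = np.arange(spec.n_frames)
    amp = np.where(
        t >= spec.transient_onset_frame,
        spec.transient_amplitude
        * np.exp(-(t - spec.transient_onset_frame) / spec.transient_decay_frames),
        0.0,
    )
    cell_signal = spec.baseline + amp              # (T,)
    clean = spec.background + np.einsum(
        "t,kmn->tmn", cell_signal, profiles
    )
    data = clean.copy()
    if spec.poisson:
        data = rng.poisson(np.maximum(data, 0.0)).astype(np.float64)
    if spec.gaussian_sigma > 0:
        data = data + rng.normal(0.0, spec.gaussian_sigma, data.shape)
    data = np.clip(np.round(data), 0, 65535).astype(np.uint16)

    # ground-truth clean mean trace per cell over its label footprint
    traces = np.empty((spec.n_cells, spec.n_frames))
    for k in range(spec.n_cells):
        mask = labels == k + 1
        traces[k] = clean[:, mask].mean(axis=1)

    stack = ImageStack(data, frame_interval=spec.frame_interval)
    return stack, SynthTruth(labels=labels, centers=centers, traces=traces)
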