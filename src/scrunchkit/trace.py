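"""Length-vs-time extraction from image stacks.

The measurement chain follows the standard workflow for single-animal
contrast imaging: background subtraction, thresholding, largest connected
component, then the major axis of the intensity-equivalent ellipse of the
binary silhouette as the worm length.  The equivalent-ellipse length is
``4 * sqrt(largest eigenvalue of the pixel-coordinate covariance)`` — the
same convention common image-analysis software uses for "fit ellipse"
measurements — and has an exact closed form for simple shapes, which the
tests exploit.

Pixel centers sit at integer coordinates; frame ``i`` is at time
``i / fps`` with the first frame at t = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from skimage.filters import threshold_otsu
from skimage.measure import label as cc_label, regionprops

from .simulate import ImageStack

__all__ = [
    "LengthTrace",
    "BinaryMask",
    "EllipseFit",
    "subtract_background",
    "segment_worm",
    "fit_ellipse_major_axis",
    "extract_length_trace",
    "normalize_by_gliding",
]


@dataclass
class LengthTrace:
    """Worm length sampled on a uniform time grid.

    ``lengths`` is in pixels, or dimensionless body-length units once
    ``normalized`` is set (in which case ``gliding_baseline`` records the
    pixel baseline that was divided out).
    """

    times: np.ndarray
    lengths: np.ndarray
    fps: float
    normalized: bool = False
    gliding_baseline: float | None = None
    interpolated: np.ndarray | None = None  # bool per sample
    bend_flags: np.ndarray | None = None    # bool per sample
    trace_id: str | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.lengths = np.asarray(self.lengths, dtype=float)
        if self.times.shape != self.lengths.shape:
            raise ValueError("times and lengths must have equal length")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if len(self.times) >= 2:
            steps = np.diff(self.times)
            if np.any(steps <= 0) or not np.allclose(steps, 1.0 / self.fps, atol=1e-6):
                raise ValueError("times must increase uniformly with step 1/fps")
        if np.any(self.lengths <= 0):
            raise ValueError("lengths must be strictly positive")

    @property
    def n_samples(self) -> int:
        return len(self.times)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])

    def bend_spans(self) -> list[tuple[float, float]]:
        """Contiguous time intervals flagged as bent, as (t0, t1) pairs."""
        if self.bend_flags is None or not np.any(self.bend_flags):
            return []
        flags = np.asarray(self.bend_flags, bool)
        edges = np.flatnonzero(np.diff(np.concatenate(([False], flags, [False]))))
        return [(float(self.times[a]), float(self.times[b - 1]))
                for a, b in zip(edges[::2], edges[1::2])]


@dataclass
class BinaryMask:
    """Single-frame segmentation result; ``valid`` is False when no
    component of at least ``min_area`` pixels was found."""

    mask: np.ndarray | None
    frame_index: int = 0
    valid: bool = True


@dataclass(frozen=True)
class EllipseFit:
    length: float          # equivalent-ellipse major axis, pixels
    minor: float
    eccentricity: float
    axis_ratio: float      # minor / major, 0 for degenerate masks
    degenerate: bool = False


def subtract_background(stack: ImageStack, background="auto") -> ImageStack:
    """Absolute difference of every frame from a background image.

    ``"auto"`` uses the per-pixel temporal median of the stack, which is
    appropriate when the worm moves enough that each pixel is background
    in most frames.  Output preserves the input bit depth by clipping.
    """
    frames = stack.frames
    if isinstance(background, str):
        if background != "auto":
            raise ValueError("background must be an array or 'auto'")
        bg = np.median(frames.astype(float), axis=0)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != frames.shape[1:]:
            raise ValueError("background shape does not match the frames")
    diff = np.abs(frames.astype(float) - bg[None, :, :])
    if np.issubdtype(frames.dtype, np.integer):
        info = np.iinfo(frames.dtype)
        diff = np.clip(np.round(diff), info.min, info.max).astype(frames.dtype)
    return ImageStack(frames=diff, fps=stack.fps, source=stack.source)


def segment_worm(frame: np.ndarray, method: str = "otsu", threshold: float | None = None,
                 min_area: int = 50, frame_index: int = 0) -> BinaryMask:
    """Threshold a (background-subtracted) frame and keep the largest
    8-connected component.  Frames with no component of at least
    ``min_area`` pixels come back flagged invalid rather than raising."""
    frame = np.asarray(frame)
    if method == "otsu":
        if frame.min() == frame.max():
            return BinaryMask(mask=None, frame_index=frame_index, valid=False)
        thr = threshold_otsu(frame)
    elif method == "fixed":
        if threshold is None:
            raise ValueError("fixed method requires a threshold")
        thr = threshold
    else:
        raise ValueError(f"unknown segmentation method {method!r}")

    binary = frame > thr
    labels = cc_label(binary, connectivity=2)
    if labels.max() == 0:
        return BinaryMask(mask=None, frame_index=frame_index, valid=False)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    biggest = int(np.argmax(counts))
    if counts[biggest] < min_area:
        return BinaryMask(mask=None, frame_index=frame_index, valid=False)
    return BinaryMask(mask=labels == biggest, frame_index=frame_index, valid=True)


def fit_ellipse_major_axis(mask) -> EllipseFit:
    """Major axis of the intensity-equivalent ellipse of a binary mask.

    Equals ``4 * sqrt(largest eigenvalue of the pixel coordinate
    covariance matrix)``; for a filled digitized ellipse this recovers the
    full major-axis length.  A single-pixel mask yields length 0 with the
    degenerate flag set; an empty mask is an error.
    """
    arr = mask.mask if isinstance(mask, BinaryMask) else np.asarray(mask)
    if arr is None or not np.any(arr):
        raise ValueError("cannot fit an ellipse to an empty mask")
    props = regionprops(arr.astype(np.uint8))[0]
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    if major <= 0:
        return EllipseFit(length=0.0, minor=0.0, eccentricity=0.0,
                          axis_ratio=0.0, degenerate=True)
    return EllipseFit(length=major, minor=minor,
                      eccentricity=float(props.eccentricity),
                      axis_ratio=minor / major)


def extract_length_trace(stack: ImageStack, background="auto",
                         method: str = "otsu", threshold: float | None = None,
                         min_area: int = 50, bend_ratio_max: float = 0.35,
                         max_invalid_fraction: float = 0.2,
                         trace_id: str | None = None) -> LengthTrace:
    """Per-frame worm length for a whole stack.

    ``background`` may be ``"auto"``, an explicit raster (the stack's own
    ``background`` attribute is used when ``background is None`` and one
    is attached), or ``False`` to skip subtraction.  Isolated invalid
    frames are filled by linear interpolation so the time grid stays
    uniform; leading/trailing invalid frames are dropped.  Frames whose
    minor/major axis ratio exceeds ``bend_ratio_max`` are flagged as bent.
    """
    if stack.n_frames < 2:
        raise ValueError("need at least 2 frames to extract a trace")
    if background is None:
        background = stack.background if stack.background is not None else "auto"
    work = stack if background is False else subtract_background(stack, background)

    n = work.n_frames
    lengths = np.full(n, np.nan)
    bend = np.zeros(n, dtype=bool)
    for i in range(n):
        seg = segment_worm(work.frames[i], method=method, threshold=threshold,
                           min_area=min_area, frame_index=i)
        if not seg.valid:
            continue
        fit = fit_ellipse_major_axis(seg)
        if fit.degenerate:
            continue
        lengths[i] = fit.length
        bend[i] = fit.axis_ratio > bend_ratio_max

    valid = np.isfinite(lengths)
    if not np.any(valid):
        raise ValueError("no frame produced a valid segmentation")
    first, last = np.flatnonzero(valid)[[0, -1]]
    lengths, bend, valid = lengths[first:last + 1], bend[first:last + 1], valid[first:last + 1]

    invalid_fraction = 1.0 - valid.mean()
    if invalid_fraction > max_invalid_fraction:
        raise ValueError(
            f"{invalid_fraction:.0%} of frames failed segmentation "
            f"(limit {max_invalid_fraction:.0%})")
    idx = np.arange(len(lengths))
    lengths[~valid] = np.interp(idx[~valid], idx[valid], lengths[valid])

    times = idx / stack.fps
    return LengthTrace(times=times, lengths=lengths, fps=stack.fps,
                       interpolated=~valid, bend_flags=bend, trace_id=trace_id)


def normalize_by_gliding(trace: LengthTrace, gliding_window="auto",
                         window_s: float = 3.0) -> LengthTrace:
    """Divide a trace by its average gliding length.

    ``gliding_window`` is a ``(t0, t1)`` interval known to contain
    gliding, or ``"auto"`` to pick the lowest-variance sliding window of
    width ``window_s`` (gliding is the flattest stretch of the trace).
    The window must span at least one second of samples.
    """
    k_min = max(2, int(round(trace.fps)))
    if isinstance(gliding_window, str):
        if gliding_window != "auto":
            raise ValueError("gliding_window must be a (t0, t1) pair or 'auto'")
        k = max(k_min, int(round(window_s * trace.fps)))
        if k > trace.n_samples:
            raise ValueError("trace shorter than the baseline window")
        c1 = np.concatenate(([0.0], np.cumsum(trace.lengths)))
        c2 = np.concatenate(([0.0], np.cumsum(trace.lengths ** 2)))
        means = (c1[k:] - c1[:-k]) / k
        variances = (c2[k:] - c2[:-k]) / k - means ** 2
        start = int(np.argmin(variances))
        baseline = float(means[start])
    else:
        t0, t1 = gliding_window
        sel = (trace.times >= t0) & (trace.times <= t1)
        if sel.sum() < k_min:
            raise ValueError("gliding window must cover at least 1 s of samples")
        baseline = float(trace.lengths[sel].mean())

    if trace.normalized:
        raise ValueError("trace is already normalized")
    return _dc_replace(trace, lengths=trace.lengths / baseline,
                       normalized=True, gliding_baseline=baseline)
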