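"""Synthetic single-worm recordings with known ground truth.

Planarians move with three distinct gaits: cilia-driven *gliding* at
approximately constant body length, low-amplitude near-symmetric
*peristalsis*, and the large-amplitude, asymmetric escape gait
*scrunching* (elongation occupies more than half of each cycle).  This
module generates length-vs-time traces and rendered image stacks for all
three gaits, with the generating parameters and per-frame truth attached,
so that the extraction and quantification stages can be validated without
real video.

The oscillation waveform is a piecewise cosine-eased ramp between a trough
and a peak length: smooth at the extrema (as in real traces) while keeping
the ground-truth cycle boundaries, amplitude and phase split exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "GaitParams",
    "RenderParams",
    "GroundTruth",
    "ImageStack",
    "generate_length_trace",
    "render_worm_stack",
    "generate_score_table",
    "generate_ct_records",
    "PRESETS",
]

GAIT_KINDS = ("gliding", "peristalsis", "scrunching")


@dataclass(frozen=True)
class GaitParams:
    """Generating parameters for one synthetic recording.

    frequency_hz, max_elongation and asymmetry are ignored for gliding.
    ``gliding_prelude_s`` prepends a constant-length gliding segment
    followed by a single contraction ramp down to the first trough,
    mimicking the immediate contraction that precedes a scrunching bout.
    """

    gait_kind: str
    frequency_hz: float = 0.72
    max_elongation: float = 0.52
    asymmetry: float = 0.59
    gliding_length: float = 100.0
    peak_factor: float = 1.2
    noise_sd: float = 0.0
    duration_s: float = 30.0
    fps: float = 10.0
    seed: int = 0
    gliding_prelude_s: float = 0.0

    def __post_init__(self) -> None:
        if self.gait_kind not in GAIT_KINDS:
            raise ValueError(f"unknown gait_kind {self.gait_kind!r}; expected one of {GAIT_KINDS}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")
        if self.gliding_length <= 0:
            raise ValueError("gliding_length must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.gliding_prelude_s < 0:
            raise ValueError("gliding_prelude_s must be >= 0")
        if self.gait_kind != "gliding":
            if self.frequency_hz <= 0:
                raise ValueError("frequency_hz must be > 0 for oscillatory gaits")
            if not 0 < self.max_elongation < 1:
                raise ValueError("max_elongation must lie in (0, 1)")
            if not 0 < self.asymmetry < 1:
                raise ValueError("asymmetry must lie in (0, 1)")
            if self.peak_factor * (1 - self.max_elongation) <= 0:
                raise ValueError("trough length peak_factor*(1-max_elongation) must be > 0")

    @property
    def peak_length(self) -> float:
        return self.peak_factor * self.gliding_length

    @property
    def trough_length(self) -> float:
        return self.peak_length * (1 - self.max_elongation)


@dataclass(frozen=True)
class RenderParams:
    """Geometry and photometry of the rendered frames.

    The worm silhouette is an elliptical body (tapered at both ends, like
    a planarian seen from above) drawn dark on a light background; an
    optional sinusoidal bend shears the body laterally while preserving
    the end-to-end spine chord.
    """

    frame_height: int = 48
    frame_width: int = 160
    worm_width: float = 6.0
    bend_amplitude: float = 0.0
    worm_intensity: int = 60
    background_intensity: int = 200
    background_noise_sd: float = 0.0
    drift_px_per_s: float = 0.0

    def __post_init__(self) -> None:
        if self.worm_width <= 0:
            raise ValueError("worm_width must be > 0")
        if self.bend_amplitude < 0:
            raise ValueError("bend_amplitude must be >= 0")
        if not 0 <= self.worm_intensity <= 255 or not 0 <= self.background_intensity <= 255:
            raise ValueError("intensities must be 8-bit gray levels (0-255)")
        if self.worm_intensity >= self.background_intensity:
            raise ValueError("worm must be darker than the background")


@dataclass
class GroundTruth:
    """Per-frame truth attached to every synthetic recording."""

    params: GaitParams
    true_length_per_frame: np.ndarray
    true_cycle_boundaries: np.ndarray  # trough times, seconds
    true_mask_per_frame: np.ndarray | None = None  # (n, H, W) bool, set when rendered

    @property
    def true_frequency(self) -> float:
        return 0.0 if self.params.gait_kind == "gliding" else self.params.frequency_hz

    @property
    def true_max_elongation(self) -> float:
        return 0.0 if self.params.gait_kind == "gliding" else self.params.max_elongation

    @property
    def true_speed(self) -> float:
        return self.true_frequency * self.true_max_elongation

    @property
    def true_asymmetry(self) -> float:
        return 0.5 if self.params.gait_kind == "gliding" else self.params.asymmetry

    def normalized_true_lengths(self) -> np.ndarray:
        return self.true_length_per_frame / self.params.gliding_length


@dataclass
class ImageStack:
    """A time-ordered sequence of equally shaped grayscale frames."""

    frames: np.ndarray  # (n, H, W)
    fps: float
    source: str | None = None
    background: np.ndarray | None = None  # clean background, if known

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, H, W) array")
        if self.fps <= 0:
            raise ValueError("fps must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.fps


def _eased(x: np.ndarray) -> np.ndarray:
    """Cosine smooth-step from 0 at x=0 to 1 at x=1."""
    return 0.5 * (1.0 - np.cos(np.pi * np.clip(x, 0.0, 1.0)))


def _waveform(params: GaitParams, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Noise-free lengths and trough times for oscillatory gaits."""
    peak, trough = params.peak_length, params.trough_length
    period = 1.0 / params.frequency_hz
    t_elong = params.asymmetry * period

    # Optional gliding prelude, then one contraction ramp into the first trough.
    ramp = (1 - params.asymmetry) * period if params.gliding_prelude_s > 0 else 0.0
    t0 = params.gliding_prelude_s + ramp  # time of the first trough
    lengths = np.full_like(t, params.gliding_length, dtype=float)

    in_ramp = (t >= params.gliding_prelude_s) & (t < t0)
    if ramp > 0:
        frac = (t[in_ramp] - params.gliding_prelude_s) / ramp
        lengths[in_ramp] = params.gliding_length - (params.gliding_length - trough) * _eased(frac)

    osc = t >= t0
    tau = np.mod(t[osc] - t0, period)
    up = tau < t_elong
    y = np.empty(tau.shape)
    y[up] = trough + (peak - trough) * _eased(tau[up] / t_elong)
    y[~up] = peak - (peak - trough) * _eased((tau[~up] - t_elong) / (period - t_elong))
    lengths[osc] = y

    t_end = t[-1]
    n_troughs = int(math.floor((t_end - t0) / period + 1e-9)) + 1
    boundaries = t0 + period * np.arange(max(n_troughs, 0))
    return lengths, boundaries


def generate_length_trace(params: GaitParams):
    """Generate a synthetic length-vs-time trace with its ground truth.

    Returns ``(trace, truth)`` where ``trace`` is a
    :class:`scrunchkit.trace.LengthTrace` in pixels and ``truth`` a
    :class:`GroundTruth`.  Deterministic for a given seed; noise is
    additive i.i.d. Gaussian applied after the waveform is built.
    """
    from .trace import LengthTrace  # local import to avoid a cycle

    total = params.duration_s + params.gliding_prelude_s
    n = int(math.floor(total * params.fps + 1e-9)) + 1
    t = np.arange(n) / params.fps

    if params.gait_kind == "gliding":
        lengths = np.full(n, params.gliding_length, dtype=float)
        boundaries = np.array([])
    else:
        lengths, boundaries = _waveform(params, t)

    true_lengths = lengths.copy()
    if params.noise_sd > 0:
        rng = np.random.default_rng(params.seed)
        lengths = lengths + rng.normal(0.0, params.noise_sd * params.gliding_length, n)
    lengths = np.maximum(lengths, 1e-3 * params.gliding_length)

    trace = LengthTrace(times=t, lengths=lengths, fps=params.fps)
    truth = GroundTruth(params=params, true_length_per_frame=true_lengths,
                        true_cycle_boundaries=boundaries)
    return trace, truth


def _render_frame(length: float, t: float, render: RenderParams) -> np.ndarray:
    """Boolean silhouette of the worm at the given spine chord length."""
    H, W = render.frame_height, render.frame_width
    cx = (W - 1) / 2.0 + render.drift_px_per_s * t
    cy = (H - 1) / 2.0
    yy, xx = np.mgrid[0:H, 0:W].astype(float)
    a = length / 2.0
    b = render.worm_width / 2.0
    if render.bend_amplitude > 0:
        # vertical shear preserving the end-to-end chord (zero deflection at the tips)
        u = np.clip((xx - (cx - a)) / max(length, 1e-9), 0.0, 1.0)
        shift = render.bend_amplitude * length * np.sin(np.pi * u)
    else:
        shift = 0.0
    return ((xx - cx) / a) ** 2 + ((yy - cy - shift) / b) ** 2 <= 1.0


def render_worm_stack(trace, truth: GroundTruth, render: RenderParams) -> tuple[ImageStack, GroundTruth]:
    """Render an 8-bit image stack for a trace, returning masks as truth.

    Each frame contains a single connected worm silhouette whose straight
    end-to-end spine length equals that frame's true length.  Rendering is
    deterministic given the generator seed.
    """
    lengths = truth.true_length_per_frame
    n = len(lengths)
    times = np.arange(n) / trace.fps
    H, W = render.frame_height, render.frame_width

    max_len = float(np.max(lengths))
    for t_ in (times[0], times[-1]):
        cx = (W - 1) / 2.0 + render.drift_px_per_s * t_
        if cx - max_len / 2.0 < 0.5 or cx + max_len / 2.0 > W - 1.5:
            raise ValueError("worm does not fit inside the frame at peak length")
    if render.worm_width > H - 2:
        raise ValueError("worm width exceeds the frame height")

    rng = np.random.default_rng([truth.params.seed, 0x5EED])
    frames = np.empty((n, H, W), dtype=np.uint8)
    masks = np.empty((n, H, W), dtype=bool)
    for i in range(n):
        mask = _render_frame(float(lengths[i]), float(times[i]), render)
        img = np.full((H, W), float(render.background_intensity))
        img[mask] = render.worm_intensity
        if render.background_noise_sd > 0:
            img = img + rng.normal(0.0, render.background_noise_sd, (H, W))
        frames[i] = np.clip(np.round(img), 0, 255).astype(np.uint8)
        masks[i] = mask

    background = np.full((H, W), render.background_intensity, dtype=np.uint8)
    stack = ImageStack(frames=frames, fps=trace.fps, background=background)
    truth_out = replace_masks(truth, masks)
    return stack, truth_out


def replace_masks(truth: GroundTruth, masks: np.ndarray) -> GroundTruth:
    return GroundTruth(params=truth.params,
                       true_length_per_frame=truth.true_length_per_frame,
                       true_cycle_boundaries=truth.true_cycle_boundaries,
                       true_mask_per_frame=masks)


# ---------------------------------------------------------------------------
# Behavior-score and qPCR record generators


SCORE_LABELS = ("S", "R", "N")  # scrunching, non-scrunching reaction, no reaction
N_INTERVALS = 6  # 15-s bins covering the first 90 s


def generate_score_table(n_worms: int, n_replicates: int, interval_probs,
                         seed: int = 0, agreement: float = 0.9,
                         condition: str = "condition") -> pd.DataFrame:
    """Synthetic two-reviewer behavior score table.

    ``interval_probs`` is either a single (pS, pR, pN) triple applied to
    all six 15-s intervals or a (6, 3) array of per-interval label
    probabilities.  The second reviewer repeats the first reviewer's label
    with probability ``agreement`` and otherwise redraws from the interval
    distribution.
    """
    probs = np.asarray(interval_probs, dtype=float)
    if probs.ndim == 1:
        probs = np.tile(probs, (N_INTERVALS, 1))
    if probs.shape != (N_INTERVALS, 3):
        raise ValueError("interval_probs must be a (pS,pR,pN) triple or a (6,3) array")
    if np.any(probs < 0) or not np.allclose(probs.sum(axis=1), 1.0):
        raise ValueError("label probabilities must be non-negative and sum to 1 per interval")
    if not 0 <= agreement <= 1:
        raise ValueError("agreement must lie in [0, 1]")

    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(1, n_replicates + 1):
        for worm in range(1, n_worms + 1):
            for k in range(N_INTERVALS):
                first = SCORE_LABELS[rng.choice(3, p=probs[k])]
                if rng.random() < agreement:
                    second = first
                else:
                    second = SCORE_LABELS[rng.choice(3, p=probs[k])]
                rows.append((condition, rep, 1, worm, k + 1, first))
                rows.append((condition, rep, 2, worm, k + 1, second))
    return pd.DataFrame(rows, columns=["condition", "replicate", "reviewer",
                                       "worm", "interval", "label"])


def generate_ct_records(true_relative_expression: float,
                        target_gene: str = "target", housekeeping_gene: str = "GAPDH",
                        control_sample: str = "control", rnai_sample: str = "rnai",
                        n_bio: int = 2, n_tech: int = 3,
                        ct_noise_sd: float = 0.1,
                        base_target_ct: float = 24.0, base_housekeeping_ct: float = 18.0,
                        seed: int = 0) -> pd.DataFrame:
    """Synthetic qPCR Ct table with a known true relative expression.

    Knockdown shifts the target Ct of the RNAi sample up by
    ``-log2(true_relative_expression)`` cycles relative to control.  Each
    (sample, bio replicate) gets a random plate offset applied to all its
    Cts, and each well gets i.i.d. Gaussian Ct noise.
    """
    if true_relative_expression <= 0:
        raise ValueError("true_relative_expression must be > 0")
    rng = np.random.default_rng(seed)
    ddct = -math.log2(true_relative_expression)
    rows = []
    for bio in range(1, n_bio + 1):
        for sample in (control_sample, rnai_sample):
            offset = rng.normal(0.0, 0.5)  # plate-to-plate shift
            for gene in (target_gene, housekeeping_gene):
                base = base_housekeeping_ct if gene == housekeeping_gene else base_target_ct
                if gene == target_gene and sample == rnai_sample:
                    base = base + ddct
                for tech in range(1, n_tech + 1):
                    ct = base + offset + rng.normal(0.0, ct_noise_sd)
                    rows.append((sample, gene, bio, tech, ct))
    return pd.DataFrame(rows, columns=["sample", "gene", "bio_rep", "tech_rep", "ct"])


#: Canonical parameter regimes: the D. japonica AITC scrunch, the
#: S. mediterranea peristalsis reference, and plain gliding.
PRESETS: dict[str, GaitParams] = {
    "scrunching": GaitParams(gait_kind="scrunching", frequency_hz=0.72,
                             max_elongation=0.52, asymmetry=0.59),
    "peristalsis": GaitParams(gait_kind="peristalsis", frequency_hz=0.26,
                              max_elongation=0.23, asymmetry=0.50),
    "gliding": GaitParams(gait_kind="gliding"),
}
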