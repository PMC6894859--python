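"""Cycle detection and the four scrunching parameters.

A scrunching or peristalsis bout is a train of body-length oscillations.
Each cycle runs trough → peak → trough; from a window of at least
``min_cycles`` consecutive cycles we compute

* frequency — cycles per second over the trough-to-trough span,
* maximum elongation — per-cycle (peak − trough) / peak averaged over
  cycles, the trough being the mean of the two bounding troughs,
* relative speed — frequency × maximum elongation (an exact identity),
* asymmetry — summed elongation time over summed cycle time; values
  above ~0.55 are the scrunching hallmark.

Peak detection runs on a lightly smoothed copy of the trace, but every
quantity entering the parameters is measured on the raw samples:
extremum times/amplitudes by local parabola fits and phase durations by
amplitude-band transit times, so neither smoothing lag nor frame
quantization biases the estimates (see detect_cycles).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd
from scipy.signal import find_peaks

from .trace import LengthTrace

__all__ = [
    "Cycle",
    "GaitSummary",
    "InsufficientOscillation",
    "smooth",
    "detect_cycles",
    "select_window",
    "summarize",
    "count_scrunches",
    "batch_summarize",
    "quantify_trace",
    "round_half_up",
]


@dataclass(frozen=True)
class Cycle:
    """One trough → peak → trough oscillation.

    ``L_trough_low``/``L_trough_mean`` are the lower and the mean of the
    two bounding trough lengths (identical on clean periodic data).
    ``elong_time_s``/``contract_time_s`` hold sub-sample rise/fall
    durations measured between fixed amplitude fractions when available;
    otherwise the extremum times are used.
    """

    t_start: float
    t_peak: float
    t_end: float
    L_peak: float
    L_trough_low: float
    i_start: int
    i_peak: int
    i_end: int
    L_trough_mean: float | None = None
    elong_time_s: float | None = None
    contract_time_s: float | None = None

    def __post_init__(self) -> None:
        if not self.t_start < self.t_peak < self.t_end:
            raise ValueError("cycle must satisfy t_start < t_peak < t_end")
        if self.L_peak <= self.L_trough_low:
            raise ValueError("cycle peak must exceed its bounding trough")

    @property
    def trough(self) -> float:
        return self.L_trough_mean if self.L_trough_mean is not None else self.L_trough_low

    @property
    def elongation(self) -> float:
        return (self.L_peak - self.trough) / self.L_peak

    @property
    def rise_s(self) -> float:
        return self.elong_time_s if self.elong_time_s is not None else self.t_peak - self.t_start

    @property
    def fall_s(self) -> float:
        return (self.contract_time_s if self.contract_time_s is not None
                else self.t_end - self.t_peak)


@dataclass(frozen=True)
class GaitSummary:
    frequency: float        # cycles / s
    max_elongation: float   # dimensionless fraction
    speed: float            # body lengths / s, = frequency * max_elongation
    asymmetry: float        # fraction of cycle time spent elongating
    n_cycles: int
    window: tuple[float, float]
    trace_id: str | None = None


@dataclass(frozen=True)
class InsufficientOscillation:
    """Returned when no run of ``min_cycles`` consecutive clean cycles
    exists — downstream this drives a gliding call."""

    n_cycles_found: int = 0
    reason: str = "insufficient oscillation"


def round_half_up(x: float, decimals: int = 2) -> float:
    """Round with ties away from zero, as in printed summary tables."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def smooth(trace: LengthTrace, window_s: float = 0.3) -> LengthTrace:
    """Centered moving average with truncated windows at the edges."""
    if window_s < 2.0 / trace.fps:
        raise ValueError("smoothing window must cover at least 2 samples")
    half = int(round(window_s * trace.fps)) // 2
    kernel = np.ones(2 * half + 1)
    sums = np.convolve(trace.lengths, kernel, mode="same")
    counts = np.convolve(np.ones_like(trace.lengths), kernel, mode="same")
    from dataclasses import replace
    return replace(trace, lengths=sums / counts)


def _alternating_extrema(y: np.ndarray, peaks: np.ndarray, troughs: np.ndarray):
    """Merge peak/trough indices into a strictly alternating sequence,
    resolving runs of same-type extrema by keeping the most extreme."""
    events = sorted([(i, +1) for i in peaks] + [(i, -1) for i in troughs])
    out: list[tuple[int, int]] = []
    for i, kind in events:
        if out and out[-1][1] == kind:
            prev = out[-1][0]
            better = y[i] > y[prev] if kind == +1 else y[i] < y[prev]
            if better:
                out[-1] = (i, kind)
        else:
            out.append((i, kind))
    return out


def _parabola_vertex(raw: np.ndarray, i: int, kind: int, r: int, fps: float):
    """Sub-sample extremum (time, value) from a least-squares parabola on
    the raw samples within ± r frames of index i.  Falls back to the
    sample itself when the fitted curvature has the wrong sign."""
    lo, hi = max(0, i - r), min(len(raw), i + r + 1)
    xs = (np.arange(lo, hi) - i) / fps
    design = np.vstack([np.ones_like(xs), xs, xs * xs]).T
    c0, c1, c2 = np.linalg.lstsq(design, raw[lo:hi], rcond=None)[0]
    if abs(c2) < 1e-12 or (kind == +1) != (c2 < 0):
        return i / fps, float(raw[i])
    tv = float(np.clip(-c1 / (2 * c2), xs[0], xs[-1]))
    return i / fps + tv, float(c0 + c1 * tv + c2 * tv * tv)


def _band_transit(times: np.ndarray, ys: np.ndarray, lo: float, hi: float,
                  rising: bool) -> float | None:
    """Duration the signal takes to traverse [lo, hi] in the given
    direction, from the median of sub-sample linear-interpolated
    crossings of each level (the median absorbs noise re-crossings)."""
    def crossings(level):
        out = []
        for j in range(len(ys) - 1):
            y0, y1 = ys[j], ys[j + 1]
            if (y0 < level <= y1) or (y0 > level >= y1):
                out.append(times[j] + (level - y0) / (y1 - y0) * (times[j + 1] - times[j]))
        return out
    c_lo, c_hi = crossings(lo), crossings(hi)
    if not c_lo or not c_hi:
        return None
    t0, t1 = ((np.median(c_lo), np.median(c_hi)) if rising
              else (np.median(c_hi), np.median(c_lo)))
    return float(t1 - t0) if t1 > t0 else None


def detect_cycles(trace: LengthTrace, prominence_frac: float = 0.10,
                  min_period_s: float = 0.5,
                  smooth_window_s: float | None = 0.3,
                  band: tuple[float, float] = (0.25, 0.75)) -> list[Cycle]:
    """Detect trough→peak→trough cycles in a length trace.

    Extrema need prominence of at least ``prominence_frac`` times the
    median length and same-type spacing of at least ``min_period_s``;
    detection runs on a smoothed copy, then each extremum is refined to
    sub-sample precision with a local parabola fit on the raw samples
    (smoothing drags the extremum of an asymmetric waveform toward its
    flatter side, so amplitudes and times come from the raw data).
    Rise/fall durations between the ``band`` amplitude fractions are
    attached to each cycle for quantization-robust asymmetry estimation.
    Returns an empty list for non-oscillating traces.
    """
    if not 0 < prominence_frac < 1:
        raise ValueError("prominence_frac must lie in (0, 1)")
    y = trace.lengths
    if smooth_window_s is not None and smooth_window_s >= 2.0 / trace.fps:
        y = smooth(trace, smooth_window_s).lengths
    prom = prominence_frac * float(np.median(trace.lengths))
    distance = max(1, int(round(min_period_s * trace.fps)))
    peaks, _ = find_peaks(y, prominence=prom, distance=distance)
    troughs, _ = find_peaks(-y, prominence=prom, distance=distance)
    seq = _alternating_extrema(y, peaks, troughs)

    # find_peaks cannot see extrema at the trace boundaries; a bout that
    # starts or ends on a trough would otherwise lose its first/last cycle
    if seq and seq[0][1] == +1:
        i0 = int(np.argmin(y[: seq[0][0]])) if seq[0][0] > 0 else 0
        if i0 < seq[0][0] and y[seq[0][0]] - y[i0] >= prom:
            seq.insert(0, (i0, -1))
    if seq and seq[-1][1] == +1:
        tail = seq[-1][0]
        i1 = tail + int(np.argmin(y[tail:]))
        if i1 > tail and y[tail] - y[i1] >= prom:
            seq.append((i1, -1))

    raw = trace.lengths
    troughs_idx = [i for i, k in seq if k == -1]
    period_est = (float(np.median(np.diff(troughs_idx))) / trace.fps
                  if len(troughs_idx) > 2 else 1.0)
    r = int(np.clip(round(0.1 * period_est * trace.fps), 2, 6))
    t_off = float(trace.times[0])
    refined = [(i, kind, *_parabola_vertex(raw, i, kind, r, trace.fps)) for i, kind in seq]

    cycles: list[Cycle] = []
    for (i0, k0, t0, v0), (i1, k1, t1, v1), (i2, k2, t2, v2) in zip(
            refined, refined[1:], refined[2:]):
        if (k0, k1, k2) != (-1, +1, -1):
            continue
        if v1 <= min(v0, v2) or not t0 < t1 < t2:
            continue  # noise artifact: refinement contradicts the smoothed shape
        trough_mean = 0.5 * (v0 + v2)
        lo_level = trough_mean + band[0] * (v1 - trough_mean)
        hi_level = trough_mean + band[1] * (v1 - trough_mean)
        rise = _band_transit(trace.times[i0:i1 + 1], raw[i0:i1 + 1],
                             lo_level, hi_level, rising=True)
        fall = _band_transit(trace.times[i1:i2 + 1], raw[i1:i2 + 1],
                             lo_level, hi_level, rising=False)
        if rise is None or fall is None:
            rise = fall = None  # fall back to extremum times for both phases
        cycles.append(Cycle(t_start=t_off + t0, t_peak=t_off + t1, t_end=t_off + t2,
                            L_peak=v1, L_trough_low=float(min(v0, v2)),
                            i_start=int(i0), i_peak=int(i1), i_end=int(i2),
                            L_trough_mean=trough_mean,
                            elong_time_s=rise, contract_time_s=fall))
    return cycles


def select_window(cycles: list[Cycle], min_cycles: int = 4,
                  bend_spans: list[tuple[float, float]] | None = None):
    """Earliest run of at least ``min_cycles`` consecutive clean cycles.

    Consecutive means sharing a trough; clean means not overlapping any
    bend-flagged time span.  Returns ``(window, cycles_in_window)`` or an
    :class:`InsufficientOscillation` result.
    """
    bend_spans = bend_spans or []

    def clean(c: Cycle) -> bool:
        return all(c.t_end < a or c.t_start > b for a, b in bend_spans)

    run: list[Cycle] = []
    for c in cycles:
        if not clean(c):
            if len(run) >= min_cycles:
                break
            run = []
            continue
        if run and c.i_start != run[-1].i_end:
            if len(run) >= min_cycles:
                break
            run = [c]
        else:
            run.append(c)
    if len(run) < min_cycles:
        return InsufficientOscillation(n_cycles_found=len(cycles))
    return (run[0].t_start, run[-1].t_end), run


def summarize(trace: LengthTrace, cycles: list[Cycle],
              trace_id: str | None = None) -> GaitSummary:
    """The four gait parameters over a set of consecutive cycles."""
    if not cycles:
        raise ValueError("cannot summarize an empty cycle set")
    t0, t1 = cycles[0].t_start, cycles[-1].t_end
    frequency = len(cycles) / (t1 - t0)
    max_elongation = float(np.mean([c.elongation for c in cycles]))
    asymmetry = (sum(c.rise_s for c in cycles)
                 / sum(c.rise_s + c.fall_s for c in cycles))
    return GaitSummary(frequency=frequency, max_elongation=max_elongation,
                       speed=frequency * max_elongation, asymmetry=asymmetry,
                       n_cycles=len(cycles), window=(t0, t1),
                       trace_id=trace_id or trace.trace_id)


def count_scrunches(trace: LengthTrace, prominence_frac: float = 0.10,
                    min_period_s: float = 0.5,
                    smooth_window_s: float | None = 0.3) -> int:
    """Number of oscillation cycles after the initial contraction.

    Mirrors scrunch counting after amputation: the bout is taken to begin
    after the first immediate contraction, so any cycle whose peak falls
    before the end of the initial monotone contraction from t = 0 is
    discarded.
    """
    cycles = detect_cycles(trace, prominence_frac=prominence_frac,
                           min_period_s=min_period_s, smooth_window_s=smooth_window_s)
    if not cycles:
        return 0
    y = trace.lengths
    if smooth_window_s is not None and smooth_window_s >= 2.0 / trace.fps:
        y = smooth(trace, smooth_window_s).lengths
    tol = 1e-6 * float(np.median(trace.lengths))
    rising = np.flatnonzero(np.diff(y) > tol)
    t_contracted = trace.times[rising[0]] if len(rising) else trace.times[-1]
    return sum(1 for c in cycles if c.t_peak > t_contracted)


def quantify_trace(trace: LengthTrace, min_cycles: int = 4,
                   prominence_frac: float = 0.10, min_period_s: float = 0.5,
                   smooth_window_s: float | None = 0.3,
                   trace_id: str | None = None):
    """Detect cycles, select the analysis window and summarize.

    Returns a :class:`GaitSummary`, or :class:`InsufficientOscillation`
    when the trace does not contain the required run of clean cycles.
    """
    cycles = detect_cycles(trace, prominence_frac=prominence_frac,
                           min_period_s=min_period_s, smooth_window_s=smooth_window_s)
    picked = select_window(cycles, min_cycles=min_cycles,
                           bend_spans=trace.bend_spans())
    if isinstance(picked, InsufficientOscillation):
        return picked
    _, in_window = picked
    return summarize(trace, in_window, trace_id=trace_id)


def batch_summarize(summaries: list[GaitSummary]) -> pd.DataFrame:
    """Population mean ± SD per parameter across worms.

    The population speed is the mean of per-worm speeds (each of which is
    its worm's frequency × elongation), not the product of the population
    means.  With a single worm the SD is reported as 0 and flagged.
    """
    if not summaries:
        raise ValueError("need at least one summary")
    cols = {"frequency": [s.frequency for s in summaries],
            "max_elongation": [s.max_elongation for s in summaries],
            "speed": [s.speed for s in summaries],
            "asymmetry": [s.asymmetry for s in summaries]}
    n = len(summaries)
    rows = []
    for name, values in cols.items():
        arr = np.asarray(values)
        sd = float(arr.std(ddof=1)) if n > 1 else 0.0
        rows.append({"parameter": name, "mean": float(arr.mean()), "sd": sd,
                     "n": n, "sd_defined": n > 1})
    return pd.DataFrame(rows)
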