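"""Readers/writers for the pipeline's plain-text and image formats.

CSV dialect: comma-separated, UTF-8, "." decimal, mandatory header row.
Image stacks are multi-page 8-bit TIFF (preferred) or a glob of numbered
TIFF/PNG frames sorted numerically.  Every run directory gets a
machine-readable provenance JSON sufficient to re-run the command.
"""

from __future__ import annotations

import glob as _glob
import json
import re
from dataclasses import asdict, is_dataclass
from datetime import datetime, timezone
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .simulate import ImageStack
from .trace import LengthTrace

__all__ = [
    "read_trace_csv", "write_trace_csv",
    "read_score_csv", "write_score_csv",
    "read_ct_csv", "read_refs_csv",
    "read_stack", "write_stack",
    "write_ground_truth", "write_provenance",
]

TRACE_COLUMNS = ["frame", "time_s", "length_px", "length_norm", "interpolated", "bend_flag"]


def _require(df: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{what} is missing required column(s): {missing}")


def write_trace_csv(trace: LengthTrace, path) -> Path:
    path = Path(path)
    n = trace.n_samples
    if trace.normalized:
        norm = trace.lengths
        px = trace.lengths * trace.gliding_baseline
    else:
        norm = np.full(n, np.nan)
        px = trace.lengths
    df = pd.DataFrame({
        "frame": np.arange(n),
        "time_s": trace.times,
        "length_px": px,
        "length_norm": norm,
        "interpolated": (trace.interpolated if trace.interpolated is not None
                         else np.zeros(n, bool)).astype(int),
        "bend_flag": (trace.bend_flags if trace.bend_flags is not None
                      else np.zeros(n, bool)).astype(int),
    })
    df.to_csv(path, index=False, float_format="%.6g")
    return path


def read_trace_csv(path) -> LengthTrace:
    df = pd.read_csv(path)
    _require(df, TRACE_COLUMNS[:3], f"trace CSV {path}")
    times = df["time_s"].to_numpy(float)
    if len(times) < 2:
        raise ValueError("trace CSV must contain at least 2 samples")
    fps = 1.0 / float(np.median(np.diff(times)))
    normalized = "length_norm" in df.columns and df["length_norm"].notna().all()
    if normalized:
        lengths = df["length_norm"].to_numpy(float)
        baseline = float(df["length_px"].iloc[0] / lengths[0]) if lengths[0] else None
    else:
        lengths, baseline = df["length_px"].to_numpy(float), None
    interp = df["interpolated"].astype(bool).to_numpy() if "interpolated" in df.columns else None
    bend = df["bend_flag"].astype(bool).to_numpy() if "bend_flag" in df.columns else None
    return LengthTrace(times=times - times[0], lengths=lengths, fps=fps,
                       normalized=normalized, gliding_baseline=baseline,
                       interpolated=interp, bend_flags=bend, trace_id=str(path))


def write_score_csv(df: pd.DataFrame, path) -> Path:
    from .scoring import validate_score_table
    validate_score_table(df)
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_score_csv(path) -> pd.DataFrame:
    from .scoring import validate_score_table
    df = pd.read_csv(path)
    return validate_score_table(df)


def read_ct_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["sample", "gene", "bio_rep", "tech_rep", "ct"], f"Ct CSV {path}")
    return df


def read_refs_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require(df, ["species", "gait", "parameter", "mean", "sd", "n"],
             f"reference CSV {path}")
    return df


def _numeric_sort(paths):
    def key(p):
        nums = re.findall(r"\d+", Path(p).stem)
        return (int(nums[-1]) if nums else 0, str(p))
    return sorted(paths, key=key)


def read_stack(path, fps: float) -> ImageStack:
    """Read a multi-page TIFF, or a glob of numbered TIFF/PNG frames."""
    text = str(path)
    if any(ch in text for ch in "*?["):
        files = _numeric_sort(_glob.glob(text))
        if not files:
            raise FileNotFoundError(f"no frames match {text!r}")
        frames = np.stack([iio.imread(f) for f in files])
        return ImageStack(frames=frames, fps=fps, source=text)
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(str(p))
    if p.suffix.lower() in (".tif", ".tiff"):
        frames = tifffile.imread(p)
    else:
        frames = iio.imread(p)
    frames = np.asarray(frames)
    if frames.ndim == 2:
        frames = frames[None]
    return ImageStack(frames=frames, fps=fps, source=str(p))


def write_stack(stack: ImageStack, path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.uint8))
    return path


def write_ground_truth(truth, directory, stem: str = "truth") -> tuple[Path, Path]:
    """Ground truth as CSV (frame, time_s, true_length_px) plus a JSON
    sidecar of the generating parameters."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    n = len(truth.true_length_per_frame)
    csv_path = directory / f"{stem}.csv"
    pd.DataFrame({
        "frame": np.arange(n),
        "time_s": np.arange(n) / truth.params.fps,
        "true_length_px": truth.true_length_per_frame,
    }).to_csv(csv_path, index=False, float_format="%.6g")
    json_path = directory / f"{stem}_params.json"
    json_path.write_text(json.dumps(asdict(truth.params), indent=2) + "\n")
    return csv_path, json_path


def write_provenance(directory, command: str, params: dict) -> Path:
    """Resolved run configuration written next to the outputs."""
    from . import __version__
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "tool": "scrunchkit",
        "version": __version__,
        "command": command,
        "timestamp": datetime.now(timezone.utc).isoformat(),
        "parameters": {k: (asdict(v) if is_dataclass(v) else v) for k, v in params.items()},
    }
    path = directory / f"{command}_provenance.json"
    path.write_text(json.dumps(payload, indent=2, default=str) + "\n")
    return path
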