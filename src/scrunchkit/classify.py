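"""Gait classification against published reference values.

Scrunching and peristalsis can be hard to tell apart by eye; they are
separated quantitatively by comparing the four gait parameters with
per-species published reference values (amputation-induced scrunching for
each species, plus the S. mediterranea peristalsis reference).  The
classifier is a nearest-centroid rule on the standardized Euclidean
distance

    d_g = sqrt( sum_k ((x_k - mu_k,g) / sigma_k,g)^2 )

over the four parameters, with two guard rails: traces without a
qualifying oscillation run, or with amplitude below a floor, are called
gliding; near-ties are broken by the asymmetry hallmark (> 0.55 means
scrunching).  Welch or pooled two-sample t-tests against a reference are
available as a report alongside the label.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import GaitSummary, InsufficientOscillation

__all__ = [
    "ReferenceEntry",
    "ReferenceTable",
    "Classification",
    "load_reference_table",
    "load_published_parameters",
    "classify",
    "classify_batch",
    "t_test_vs_reference",
    "ttest_from_stats",
    "PARAMETERS",
]

PARAMETERS = ("frequency", "max_elongation", "speed", "asymmetry")
SPECIES = ("D_japonica", "S_mediterranea")


@dataclass(frozen=True)
class ReferenceEntry:
    species: str
    gait: str  # "scrunching" or "peristalsis"
    means: dict
    sds: dict
    n: int

    def __post_init__(self) -> None:
        for p in PARAMETERS:
            if p not in self.means or p not in self.sds:
                raise ValueError(f"reference entry missing parameter {p!r}")
            if self.sds[p] <= 0:
                raise ValueError("reference SDs must be > 0")
        if self.n < 2:
            raise ValueError("reference n must be >= 2")

    def distance(self, values: dict) -> float:
        return float(np.sqrt(sum(
            ((values[p] - self.means[p]) / self.sds[p]) ** 2 for p in PARAMETERS)))


class ReferenceTable:
    """Per-species, per-gait reference parameter means ± SD."""

    def __init__(self, entries: list[ReferenceEntry]):
        self._entries = {(e.species, e.gait): e for e in entries}

    def get(self, species: str, gait: str) -> ReferenceEntry | None:
        return self._entries.get((species, gait))

    def entries(self) -> list[ReferenceEntry]:
        return list(self._entries.values())

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ReferenceTable":
        required = {"species", "gait", "parameter", "mean", "sd", "n"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"reference table missing columns: {sorted(missing)}")
        entries = []
        for (species, gait), grp in df.groupby(["species", "gait"]):
            means = dict(zip(grp["parameter"], grp["mean"].astype(float)))
            sds = dict(zip(grp["parameter"], grp["sd"].astype(float)))
            entries.append(ReferenceEntry(species=species, gait=gait, means=means,
                                          sds=sds, n=int(grp["n"].iloc[0])))
        return cls(entries)


def load_reference_table(path=None) -> ReferenceTable:
    """The packaged reference table, or one read from ``path``."""
    if path is not None:
        return ReferenceTable.from_frame(pd.read_csv(path))
    with resources.files("scrunchkit").joinpath("data/gait_references.csv").open() as fh:
        return ReferenceTable.from_frame(pd.read_csv(fh))


def load_published_parameters() -> pd.DataFrame:
    """Published per-condition gait parameters (mean, SD, gait call, N)
    for both species, including the reference rows."""
    with resources.files("scrunchkit").joinpath(
            "data/published_gait_parameters.csv").open() as fh:
        return pd.read_csv(fh)


@dataclass
class Classification:
    label: str  # gliding | peristalsis | scrunching
    z_distances: dict = field(default_factory=dict)
    flags: list = field(default_factory=list)
    t_tests: pd.DataFrame | None = None
    trace_id: str | None = None


def classify(summary, refs: ReferenceTable, species: str,
             amplitude_floor: float = 0.10, asym_threshold: float = 0.55,
             tie_margin: float = 0.05) -> Classification:
    """Label one trace as gliding, peristalsis or scrunching.

    ``summary`` is a :class:`GaitSummary` or an
    :class:`InsufficientOscillation` result (which maps to gliding, as
    does any amplitude below ``amplitude_floor``).  A species lacking its
    own peristalsis reference borrows the other species' entry for that
    centroid.  Near-ties (distance difference under ``tie_margin``) fall
    back on the asymmetry hallmark.
    """
    scrunch_ref = refs.get(species, "scrunching")
    if scrunch_ref is None:
        raise ValueError(f"reference table has no scrunching entry for {species}")

    if summary is None or isinstance(summary, InsufficientOscillation):
        return Classification(label="gliding", flags=["insufficient_oscillation"])
    if summary.max_elongation < amplitude_floor:
        return Classification(label="gliding", flags=["amplitude_floor"],
                              trace_id=summary.trace_id)

    peri_ref = refs.get(species, "peristalsis")
    if peri_ref is None:
        others = [e for e in refs.entries() if e.gait == "peristalsis"]
        peri_ref = others[0] if others else None

    values = {"frequency": summary.frequency, "max_elongation": summary.max_elongation,
              "speed": summary.speed, "asymmetry": summary.asymmetry}
    distances = {"scrunching": scrunch_ref.distance(values)}
    if peri_ref is not None:
        distances["peristalsis"] = peri_ref.distance(values)

    label = min(distances, key=distances.get)
    flags = []
    if len(distances) == 2:
        d_s, d_p = distances["scrunching"], distances["peristalsis"]
        if abs(d_s - d_p) < tie_margin:
            label = "scrunching" if summary.asymmetry > asym_threshold else "peristalsis"
            flags.append("tie_broken_by_asymmetry")
    return Classification(label=label, z_distances=distances, flags=flags,
                          trace_id=summary.trace_id)


def ttest_from_stats(mean1: float, sd1: float, n1: int,
                     mean2: float, sd2: float, n2: int,
                     variant: str = "welch", sides: int = 2):
    """Two-sample t-test from summary statistics.

    Welch uses the Welch–Satterthwaite degrees of freedom; the pooled
    variant is the classical equal-variance student's t.  Returns
    ``(t, df, p)``.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("both groups need n >= 2")
    if sides not in (1, 2):
        raise ValueError("sides must be 1 or 2")
    v1, v2 = sd1 ** 2 / n1, sd2 ** 2 / n2
    if variant == "welch":
        se = np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1 ** 2 / (n1 - 1) + v2 ** 2 / (n2 - 1))
    elif variant == "pooled":
        sp2 = ((n1 - 1) * sd1 ** 2 + (n2 - 1) * sd2 ** 2) / (n1 + n2 - 2)
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = n1 + n2 - 2
    else:
        raise ValueError(f"unknown t-test variant {variant!r}")
    if se == 0:
        t = 0.0
    else:
        t = (mean1 - mean2) / se
    p = sides * float(stats.t.sf(abs(t), df))
    return float(t), float(df), min(p, 1.0)


def t_test_vs_reference(sample_stats: dict, ref: ReferenceEntry,
                        variant: str = "welch", sides: int = 2) -> pd.DataFrame:
    """Per-parameter t-tests of a sample against a reference entry.

    ``sample_stats`` maps parameter name to ``(mean, sd, n)``.
    """
    rows = []
    for p in PARAMETERS:
        if p not in sample_stats:
            continue
        mean, sd, n = sample_stats[p]
        t, df, pval = ttest_from_stats(mean, sd, n, ref.means[p], ref.sds[p], ref.n,
                                       variant=variant, sides=sides)
        rows.append({"parameter": p, "t": t, "df": df, "p": pval})
    return pd.DataFrame(rows)


def classify_batch(summaries, refs: ReferenceTable, species,
                   conditions=None, **kwargs) -> pd.DataFrame:
    """Classify a batch of traces; returns one labeled row per trace.

    ``species`` may be a single name or a per-trace sequence;
    ``conditions`` optionally tags rows for per-condition label counts
    (exposed via ``df.attrs['label_counts']``).
    """
    n = len(summaries)
    if isinstance(species, str):
        species = [species] * n
    if conditions is None:
        conditions = [""] * n
    rows = []
    for i, (s, sp, cond) in enumerate(zip(summaries, species, conditions)):
        c = classify(s, refs, sp, **kwargs)
        rows.append({"index": i, "condition": cond, "species": sp, "label": c.label,
                     "d_scrunching": c.z_distances.get("scrunching", np.nan),
                     "d_peristalsis": c.z_distances.get("peristalsis", np.nan),
                     "flags": ";".join(c.flags)})
    df = pd.DataFrame(rows)
    df.attrs["label_counts"] = (df.groupby(["condition", "label"]).size()
                                .rename("count").reset_index())
    return df
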