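"""qPCR support: standard-curve primer efficiency and ΔΔCt knockdown.

Primer efficiency comes from the slope of the standard curve (mean Ct
versus log10 dilution): efficiency% = (10^(−1/slope) − 1) × 100, so a
perfect doubling per cycle (slope −1/log10(2) ≈ −3.3219) gives 100%.

Knockdown uses the ΔΔCt method with technical replicates averaged on the
Ct scale: per biological replicate, ΔCt = Ct(target) − Ct(housekeeping);
ΔΔCt = ΔCt(RNAi) − ΔCt(control); relative expression = 2^(−ΔΔCt);
knockdown% = (1 − relative expression) × 100.  Reported knockdown is the
mean of per-bio-replicate relative expressions (averaging on the ΔΔCt
scale is available via ``average="ddct"``).  Efficiency is used only as a
QC range; no Pfaffl correction is applied to knockdown values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["KnockdownResult", "primer_efficiency", "ddct_knockdown"]

CT_COLUMNS = ["sample", "gene", "bio_rep", "tech_rep", "ct"]


def primer_efficiency(points) -> tuple[float, float]:
    """Slope and amplification efficiency from a dilution series.

    ``points`` is an iterable of ``(log10_dilution, mean_ct)`` pairs (at
    least three, with non-constant dilutions).  Returns
    ``(slope, efficiency_percent)``.
    """
    arr = np.asarray(list(points), dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (log10_dilution, ct) points")
    x, y = arr[:, 0], arr[:, 1]
    if np.ptp(x) == 0:
        raise ValueError("dilutions are constant; cannot fit a slope")
    fit = stats.linregress(x, y)
    slope = float(fit.slope)
    if slope == 0:
        raise ValueError("zero slope; efficiency undefined")
    efficiency = (10.0 ** (-1.0 / slope) - 1.0) * 100.0
    return slope, float(efficiency)


@dataclass
class KnockdownResult:
    target_gene: str
    housekeeping_gene: str
    control_sample: str
    rnai_sample: str
    per_replicate: pd.DataFrame  # bio_rep, dct_control, dct_rnai, ddct, relative_expression
    relative_expression: float   # mean across bio replicates
    knockdown_percent: float     # (1 - relative_expression) * 100
    average: str = "expression"


def _mean_ct(df: pd.DataFrame, sample: str, gene: str, bio: int) -> float:
    sel = df[(df["sample"] == sample) & (df["gene"] == gene) & (df["bio_rep"] == bio)]
    if sel.empty:
        raise ValueError(f"no Ct records for sample={sample!r} gene={gene!r} bio_rep={bio}")
    return float(sel["ct"].mean())


def ddct_knockdown(records: pd.DataFrame, target_gene: str, housekeeping_gene: str,
                   control_sample: str, rnai_sample: str,
                   average: str = "expression") -> KnockdownResult:
    """ΔΔCt relative expression of ``target_gene`` in the RNAi sample.

    Requires both genes in both samples and a matching set of biological
    replicates; technical replicates are averaged on the Ct scale.
    """
    missing = set(CT_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if np.any(records["ct"] <= 0):
        raise ValueError("Ct values must be > 0")
    for sample in (control_sample, rnai_sample):
        genes = set(records.loc[records["sample"] == sample, "gene"])
        if target_gene not in genes:
            raise ValueError(f"target gene {target_gene!r} absent from sample {sample!r}")
        if housekeeping_gene not in genes:
            raise ValueError(f"housekeeping gene {housekeeping_gene!r} absent "
                             f"from sample {sample!r}")
    if average not in ("expression", "ddct"):
        raise ValueError("average must be 'expression' or 'ddct'")

    bios_ctrl = set(records.loc[records["sample"] == control_sample, "bio_rep"])
    bios_rnai = set(records.loc[records["sample"] == rnai_sample, "bio_rep"])
    if bios_ctrl != bios_rnai:
        raise ValueError("control and RNAi samples have mismatched biological replicates")

    rows = []
    for bio in sorted(bios_ctrl):
        dct_ctrl = (_mean_ct(records, control_sample, target_gene, bio)
                    - _mean_ct(records, control_sample, housekeeping_gene, bio))
        dct_rnai = (_mean_ct(records, rnai_sample, target_gene, bio)
                    - _mean_ct(records, rnai_sample, housekeeping_gene, bio))
        ddct = dct_rnai - dct_ctrl
        rows.append({"bio_rep": bio, "dct_control": dct_ctrl, "dct_rnai": dct_rnai,
                     "ddct": ddct, "relative_expression": 2.0 ** (-ddct)})
    per_rep = pd.DataFrame(rows)

    if average == "expression":
        rel = float(per_rep["relative_expression"].mean())
    else:
        rel = float(2.0 ** (-per_rep["ddct"].mean()))
    return KnockdownResult(target_gene=target_gene, housekeeping_gene=housekeeping_gene,
                           control_sample=control_sample, rnai_sample=rnai_sample,
                           per_replicate=per_rep, relative_expression=rel,
                           knockdown_percent=(1.0 - rel) * 100.0, average=average)
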