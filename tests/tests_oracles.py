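"""Independent oracles shared by the test modules: deliberately naive
implementations kept separate from the package code paths they check."""

from math import comb

import numpy as np


def brute_force_major_axis(mask: np.ndarray) -> float:
    """4 * sqrt(largest eigenvalue of the pixel-coordinate covariance),
    from enumerated coordinates."""
    coords = np.argwhere(mask).astype(float)
    cov = np.cov(coords.T, bias=True)
    return 4.0 * np.sqrt(np.linalg.eigvalsh(cov).max())


def fisher_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Two-sided Fisher p by exhaustive hypergeometric enumeration of all
    tables sharing the observed margins."""
    r1, r2, c1 = a + b, c + d, a + c
    denom = comb(r1 + r2, c1)
    probs = [comb(r1, x) * comb(r2, c1 - x) / denom
             for x in range(max(0, c1 - r2), min(r1, c1) + 1)]
    p_obs = comb(r1, a) * comb(r2, c1 - a) / denom
    return sum(p for p in probs if p <= p_obs * (1 + 1e-9))
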