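"""Weighted delete-m (block) jackknife for ratio statistics over genomic windows.

Blocks are genomic windows as produced upstream (5 Mb whole-genome,
10 Mb genic-only); they are never re-chunked here.  Unequal block sizes
(numbers of informative sites) are handled by the weighted delete-m
estimator of Busing, Meijer & van der Leeden (1999): with g blocks,
block weights m_j summing to n, h_j = n / m_j, full-sample estimate
theta-hat and leave-block-out estimates theta-hat_(-j),

    theta-tilde = g * theta-hat - sum_j (1 - m_j / n) * theta-hat_(-j)
    SE^2 = (1/g) * sum_j (h_j * theta-hat - (h_j - 1) * theta-hat_(-j)
                          - theta-tilde)^2 / (h_j - 1)

With equal weights this reduces exactly to the classical delete-1
jackknife.  The 95% CI uses the normal approximation estimate +/- 1.96 SE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["JackknifeResult", "jackknife_se", "variance_from_se"]


@dataclass
class JackknifeResult:
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_blocks: int


def jackknife_se(
    numerators: np.ndarray,
    denominators: np.ndarray,
    weights: np.ndarray | None = None,
    ci_z: float = 1.96,
) -> JackknifeResult:
    """Weighted delete-m jackknife SE of the ratio sum(num)/sum(den).

    Parameters
    ----------
    numerators, denominators : array of per-block contributions.
        For Patterson's D these are (n_abba - n_baba) and
        (n_abba + n_baba) per window.
    weights : per-block jackknife weights m_j; defaults to the
        denominator contributions (block information content).
    """
    num = np.asarray(numerators, dtype=float)
    den = np.asarray(denominators, dtype=float)
    if num.shape != den.shape or num.ndim != 1:
        raise ValueError("numerators and denominators must be equal-length 1-D arrays")
    g = len(num)
    if g < 2:
        raise ValueError(f"need >= 2 blocks for a jackknife SE, got {g}")
    m = den.copy() if weights is None else np.asarray(weights, dtype=float)
    if np.any(m < 0) or m.sum() <= 0:
        raise ValueError("block weights must be non-negative with positive sum")
    tot_den = den.sum()
    if tot_den <= 0:
        raise ValueError("zero total denominator")

    theta = num.sum() / tot_den
    loo = (num.sum() - num) / (tot_den - den)  # theta-hat_(-j)
    n = m.sum()
    h = n / m
    theta_tilde = g * theta - ((1.0 - m / n) * loo).sum()
    pseudo = h * theta - (h - 1.0) * loo
    se2 = ((pseudo - theta_tilde) ** 2 / (h - 1.0)).sum() / g
    se = float(np.sqrt(se2))
    return JackknifeResult(
        estimate=float(theta),
        se=se,
        ci_low=float(theta - ci_z * se),
        ci_high=float(theta + ci_z * se),
        n_blocks=g,
    )


def variance_from_se(se: float, n_blocks: int) -> float:
    """Within-partition variance of per-window D: SE^2 times block count.

    The jackknife SE describes the genome-wide estimate; multiplying the
    squared SE by the number of blocks recovers the variance of D across
    windows, the scale on which the subgenome contrast is pooled.
    """
    if se < 0:
        raise ValueError("se must be non-negative")
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    return float(se * se * n_blocks)
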