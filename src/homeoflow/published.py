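"""Published genome-wide ABBA/BABA site totals for X. laevis.

Reported per-subgenome totals of ABBA and BABA sites for the five
population comparisons of the South African X. laevis radiation
(populations grouped by rainfall zone, with an X. victorianus +
X. poweri outgroup, plus a focused comparison around the admixed
Laingsburg population).  These printed totals serve as fixed inputs for
recomputing the genome-wide D statistics and the comparison-level
contrast columns; the per-window data behind the confidence intervals
and permutation p-values are not part of the publication record.
"""

from __future__ import annotations

#: comparison -> subgenome -> (n_abba, n_baba)
SITE_TOTALS: dict[str, dict[str, tuple[int, int]]] = {
    "comparison1": {"L": (38_408, 20_603), "S": (25_342, 19_882)},
    "comparison2": {"L": (33_283, 25_295), "S": (28_799, 21_628)},
    "comparison3": {"L": (27_614, 38_789), "S": (23_752, 32_632)},
    "comparison4": {"L": (2_994, 5_762), "S": (2_793, 5_366)},
    "laingsburg_focus": {"L": (20_320, 38_782), "S": (17_910, 32_609)},
}

#: P1, P2, P3, O population grouping of each comparison
ROLE_LABELS: dict[str, tuple[str, str, str, str]] = {
    "comparison1": ("winter", "SE transition", "summer", "outgroup"),
    "comparison2": ("winter", "NW transition", "summer", "outgroup"),
    "comparison3": ("SE transition", "NW transition", "summer", "outgroup"),
    "comparison4": ("winter", "SE transition", "NW transition", "summer"),
    "laingsburg_focus": (
        "Laingsburg", "Beaufort West", "De Doorns", "Victoria West + Kimberly"
    ),
}

#: reported pooled SE of the contrast statistic per comparison (the
#: column feeding both the 80%-power threshold and the printed effect size)
POOLED_SE: dict[str, float] = {
    "comparison1": 0.074,
    "comparison2": 0.081,
    "comparison3": 0.077,
    "comparison4": 0.160,
    "laingsburg_focus": 0.116,
}


def d_from_totals(n_abba: float, n_baba: float) -> float:
    """D from partition-level count totals."""
    return (n_abba - n_baba) / (n_abba + n_baba)
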