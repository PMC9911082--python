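"""Tabular (TSV) views of window counts and comparison results.

The per-window schema (chrom, start, end, subgenome, n_abba, n_baba,
n_sites, d) mirrors the window output of the frequency-based D
implementations in common use, so third-party window files can be fed
to the contrast stage directly.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .contrast import SubgenomePartition, SubgenomeTestResult
from .dstat import WindowCounts
from .io import GenomicWindow

__all__ = [
    "windows_to_frame",
    "frame_to_windows",
    "comparison_to_frame",
]

WINDOW_COLUMNS = ["chrom", "start", "end", "subgenome", "n_abba", "n_baba", "n_sites", "d"]


def windows_to_frame(counts: list[WindowCounts]) -> pd.DataFrame:
    rows = [
        {
            "chrom": c.window.chrom,
            "start": c.window.start,
            "end": c.window.end,
            "subgenome": c.window.subgenome,
            "n_abba": c.n_abba,
            "n_baba": c.n_baba,
            "n_sites": c.n_sites,
            "d": c.d,
        }
        for c in counts
    ]
    return pd.DataFrame(rows, columns=WINDOW_COLUMNS)


def frame_to_windows(df: pd.DataFrame) -> list[WindowCounts]:
    """Rebuild window counts from a TSV frame (inverse of windows_to_frame)."""
    out = []
    for row in df.itertuples(index=False):
        out.append(
            WindowCounts(
                window=GenomicWindow(
                    str(row.chrom), int(row.start), int(row.end), str(row.subgenome)
                ),
                n_abba=float(row.n_abba),
                n_baba=float(row.n_baba),
                n_sites=int(row.n_sites),
            )
        )
    return out


def comparison_to_frame(
    label: str, result: SubgenomeTestResult, decimals: int = 3
) -> pd.DataFrame:
    """Two-row report for one comparison, one row per subgenome.

    Comparison-level columns (test statistic, pooled SE, power
    threshold, p, effect size) appear on the L row only, matching the
    conventional table layout; a suppressed effect size (non-positive
    contrast) is printed as "-".
    """

    def _fmt(x: float) -> float:
        return float(np.round(x, decimals))

    rows = []
    for sg, dres in (("L", result.d_l), ("S", result.d_s)):
        row = {
            "comparison": label,
            "subgenome": sg,
            "n_abba": dres.n_abba,
            "n_baba": dres.n_baba,
            "d": _fmt(dres.d),
            "ci_low": _fmt(dres.ci_low),
            "ci_high": _fmt(dres.ci_high),
            "n_windows": dres.n_windows,
            "test_statistic": "",
            "pooled_se": "",
            "power80_threshold": "",
            "p_value": "",
            "effect_size": "",
        }
        if sg == "L":
            row.update(
                test_statistic=_fmt(result.t_obs),
                pooled_se=_fmt(result.pooled_se),
                power80_threshold=_fmt(result.power80_threshold),
                p_value=_fmt(result.p_value),
                effect_size="-" if result.cohen_d is None else _fmt(result.cohen_d),
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_window_tsv(path: str | Path) -> list[WindowCounts]:
    return frame_to_windows(pd.read_csv(path, sep="\t"))
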