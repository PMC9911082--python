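"""ABBA/BABA pattern weights and Patterson's D.

For four populations related as (((P1, P2), P3), O), Patterson's D
contrasts the two discordant site patterns

    ABBA:  derived allele shared by P2 and P3
    BABA:  derived allele shared by P1 and P3

    D = (sum ABBA - sum BABA) / (sum ABBA + sum BABA)

Positive D indicates an excess of allele sharing between P2 and P3.
Per-site weights use the population-frequency form

    abba = (1 - p1) * p2 * p3 * (1 - p4)
    baba = p1 * (1 - p2) * p3 * (1 - p4)

where p_i is the alternate-allele frequency in each role.  No explicit
ancestral polarization is performed: the (1 - p4) factor down-weights
sites where the outgroup carries the allele, which is the standard
frequency-based estimator.  "count" mode binarizes each frequency at
0.5 first (strict majority; ties to 0), yielding integer site tallies.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .io import GenomicWindow, GenotypeMatrix, PopulationMap, MISSING, ROLES

logger = logging.getLogger(__name__)

__all__ = [
    "SiteFrequencies",
    "WindowCounts",
    "DResult",
    "site_frequencies",
    "pattern_weights",
    "aggregate_windows",
    "patterson_d",
]


@dataclass
class SiteFrequencies:
    """Per-site alt-allele frequencies for the four roles.

    ``chrom``/``pos`` identify the retained sites (those passing the
    per-role minimum of called allele copies); ``p1..p4`` are frequency
    arrays over those sites; ``n_called[role]`` the allele-copy counts.
    """

    chrom: np.ndarray
    pos: np.ndarray
    p1: np.ndarray
    p2: np.ndarray
    p3: np.ndarray
    p4: np.ndarray
    n_called: dict[str, np.ndarray]


@dataclass
class WindowCounts:
    """Summed ABBA/BABA weights for one genomic window."""

    window: GenomicWindow
    n_abba: float
    n_baba: float
    n_sites: int
    low_count: bool = False  # flagged when n_abba + n_baba < minimum

    @property
    def weight(self) -> float:
        return self.n_abba + self.n_baba

    @property
    def d(self) -> float:
        w = self.weight
        return (self.n_abba - self.n_baba) / w if w > 0 else np.nan


@dataclass
class DResult:
    """Patterson's D with block-jackknife standard error and 95% CI."""

    d: float
    n_abba: float
    n_baba: float
    se: float
    ci_low: float
    ci_high: float
    n_windows: int


def site_frequencies(
    matrix: GenotypeMatrix,
    popmap: PopulationMap,
    min_called: int = 2,
) -> SiteFrequencies:
    """Alt-allele frequency per role, dropping under-called sites.

    ``min_called`` is the minimum number of called allele copies per
    role (default 2, i.e. at least one called diploid genotype).
    """
    idx = popmap.role_indices(matrix.samples)
    freqs: dict[str, np.ndarray] = {}
    called_counts: dict[str, np.ndarray] = {}
    keep = np.ones(matrix.n_sites, dtype=bool)
    for role in ROLES:
        sub = matrix.doses[:, idx[role]]
        called = sub != MISSING
        n_copies = 2 * called.sum(axis=1)
        alt_copies = np.where(called, sub, 0).sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            freqs[role] = np.where(n_copies > 0, alt_copies / np.maximum(n_copies, 1), np.nan)
        called_counts[role] = n_copies
        keep &= n_copies >= min_called
    kept = np.flatnonzero(keep)
    return SiteFrequencies(
        chrom=matrix.chrom[kept],
        pos=matrix.pos[kept],
        p1=freqs["P1"][kept],
        p2=freqs["P2"][kept],
        p3=freqs["P3"][kept],
        p4=freqs["O"][kept],
        n_called={r: called_counts[r][kept] for r in ROLES},
    )


def pattern_weights(
    freqs: SiteFrequencies, mode: str = "frequency"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site (abba, baba) weights.

    mode="frequency" uses the population frequencies directly;
    mode="count" binarizes each frequency at 0.5 (strict majority)
    first, so each site contributes 0 or 1 to each tally.
    """
    if mode not in ("frequency", "count"):
        raise ValueError(f"mode must be 'frequency' or 'count', got {mode!r}")
    p1, p2, p3, p4 = freqs.p1, freqs.p2, freqs.p3, freqs.p4
    if mode == "count":
        p1, p2, p3, p4 = ((p > 0.5).astype(float) for p in (p1, p2, p3, p4))
    abba = (1.0 - p1) * p2 * p3 * (1.0 - p4)
    baba = p1 * (1.0 - p2) * p3 * (1.0 - p4)
    return abba, baba


def aggregate_windows(
    freqs: SiteFrequencies,
    abba: np.ndarray,
    baba: np.ndarray,
    windows: list[GenomicWindow],
    min_pattern_sum: float = 0.0,
) -> list[WindowCounts]:
    """Sum per-site weights into their windows.

    Windows must tile the chromosomes of the sites; a site falling
    outside every window of its chromosome raises.  Windows whose
    n_abba + n_baba falls below ``min_pattern_sum`` are flagged
    (``low_count=True``) but kept.
    """
    by_chrom: dict[str, list[int]] = {}
    for i, w in enumerate(windows):
        by_chrom.setdefault(w.chrom, []).append(i)

    n_abba = np.zeros(len(windows))
    n_baba = np.zeros(len(windows))
    n_sites = np.zeros(len(windows), dtype=np.int64)

    for chrom in np.unique(freqs.chrom):
        sel = np.flatnonzero(freqs.chrom == chrom)
        widx = by_chrom.get(str(chrom))
        if not widx:
            raise ValueError(f"sites on {chrom} but no windows cover it")
        widx_sorted = sorted(widx, key=lambda i: windows[i].start)
        starts = np.array([windows[i].start for i in widx_sorted])
        ends = np.array([windows[i].end for i in widx_sorted])
        pos0 = freqs.pos[sel] - 1
        j = np.searchsorted(starts, pos0, side="right") - 1
        bad = (j < 0) | (pos0 >= ends[np.clip(j, 0, len(ends) - 1)])
        if np.any(bad):
            p = freqs.pos[sel][np.flatnonzero(bad)[0]]
            raise ValueError(f"site {chrom}:{p} outside all windows (tiling violated)")
        tgt = np.asarray(widx_sorted)[j]
        np.add.at(n_abba, tgt, abba[sel])
        np.add.at(n_baba, tgt, baba[sel])
        np.add.at(n_sites, tgt, 1)

    out = [
        WindowCounts(
            window=w,
            n_abba=float(n_abba[i]),
            n_baba=float(n_baba[i]),
            n_sites=int(n_sites[i]),
            low_count=(n_abba[i] + n_baba[i]) < min_pattern_sum,
        )
        for i, w in enumerate(windows)
    ]
    n_low = sum(wc.low_count for wc in out)
    if n_low and min_pattern_sum > 0:
        logger.info(
            "aggregate_windows: %d/%d windows below pattern sum %g",
            n_low, len(out), min_pattern_sum,
        )
    return out


def patterson_d(counts: list[WindowCounts], ci_z: float = 1.96) -> DResult:
    """Genome- or partition-level D with block-jackknife SE over windows.

    Windows with zero pattern sum carry no information about the ratio
    and are excluded from the jackknife (their count is logged).  With
    fewer than two usable windows the SE and CI are NaN.
    """
    from .jackknife import jackknife_se

    tot_abba = float(sum(c.n_abba for c in counts))
    tot_baba = float(sum(c.n_baba for c in counts))
    denom = tot_abba + tot_baba
    if denom <= 0:
        raise ValueError("no informative sites: sum of ABBA and BABA weights is zero")
    d = (tot_abba - tot_baba) / denom

    usable = [c for c in counts if c.weight > 0]
    n_dropped = len(counts) - len(usable)
    if n_dropped:
        logger.info("patterson_d: %d empty windows excluded from jackknife", n_dropped)
    if len(usable) >= 2:
        num = np.array([c.n_abba - c.n_baba for c in usable])
        den = np.array([c.weight for c in usable])
        jk = jackknife_se(num, den)
        se, ci_low, ci_high = jk.se, d - ci_z * jk.se, d + ci_z * jk.se
    else:
        warnings.warn(
            "fewer than 2 informative windows: jackknife SE undefined",
            stacklevel=2,
        )
        se = ci_low = ci_high = np.nan
    return DResult(
        d=d,
        n_abba=tot_abba,
        n_baba=tot_baba,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        n_windows=len(usable),
    )
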