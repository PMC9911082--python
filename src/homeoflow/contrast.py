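"""Subgenome contrast of Patterson's D: test statistic, permutation null, power.

An allotetraploid carries two coresident subgenomes (L and S).  If gene
flow differed between them — e.g. restorative gene flow counteracting a
polyploid ratchet in the less stable subgenome — windowed D should be
systematically more extreme in one subgenome.  The contrast statistic is

    T = | weighted mean D over S windows | - | weighted mean D over L windows |

with window weights w_i = n_abba_i + n_baba_i.  Because D is a ratio of
sums, the w-weighted mean of window D equals the D computed from global
count totals, so T = |D_S| - |D_L| exactly.

The null distribution is obtained by permuting the L/S labels of the
windows (preserving the observed label counts) and recomputing T; the
one-sided p-value uses the add-one convention p = (1 + #{T* >= T_obs})
/ (1 + n_perm), so p is never zero and a maximally negative T gives
p ~= 1.  The a priori alternative is one-sided: S more extreme than L.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dstat import DResult, WindowCounts, patterson_d
from .jackknife import variance_from_se

__all__ = [
    "SubgenomePartition",
    "PermutationConfig",
    "SubgenomeTestResult",
    "test_statistic",
    "permutation_test",
    "pooled_se",
    "power80_threshold",
    "cohen_d",
    "evaluate_partition",
    "run_comparison",
]

#: z_{0.975} + z_{0.80}: multiplier turning a SE into the effect giving
#: 80% power in a two-sided 5% test under the normal approximation.
POWER80_MULTIPLIER = 2.8

#: Below this |d| the conventional reading is a weak effect.
WEAK_EFFECT = 0.2


@dataclass
class SubgenomePartition:
    """Window counts split by subgenome, with per-window weights."""

    l_windows: list[WindowCounts]
    s_windows: list[WindowCounts]

    def __post_init__(self) -> None:
        for wc in self.l_windows:
            if wc.window.subgenome != "L":
                raise ValueError(f"window {wc.window} in L list but labeled {wc.window.subgenome}")
        for wc in self.s_windows:
            if wc.window.subgenome != "S":
                raise ValueError(f"window {wc.window} in S list but labeled {wc.window.subgenome}")

    @classmethod
    def from_counts(cls, counts: list[WindowCounts], drop_empty: bool = True) -> "SubgenomePartition":
        """Split window counts by subgenome label.

        Zero-weight windows carry no ratio information and are dropped
        (the same filtered set then feeds the jackknife and the
        permutation, keeping the two consistent).
        """
        kept = [c for c in counts if (c.weight > 0 or not drop_empty)]
        return cls(
            l_windows=[c for c in kept if c.window.subgenome == "L"],
            s_windows=[c for c in kept if c.window.subgenome == "S"],
        )


@dataclass
class PermutationConfig:
    n_permutations: int = 1000
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")


@dataclass
class SubgenomeTestResult:
    t_obs: float
    p_value: float
    pooled_se: float
    power80_threshold: float
    cohen_d: float | None  # None when t_obs <= 0 (suppressed in reports)
    d_l: DResult
    d_s: DResult


def _weighted_d(windows: list[WindowCounts]) -> float:
    num = sum(c.n_abba - c.n_baba for c in windows)
    den = sum(c.weight for c in windows)
    if den <= 0:
        raise ValueError("subgenome has no windows with positive weight")
    return num / den


def test_statistic(partition: SubgenomePartition) -> float:
    """T = |weighted mean D over S| - |weighted mean D over L|."""
    if not partition.l_windows or not partition.s_windows:
        raise ValueError("both subgenomes need >= 1 window with positive weight")
    return abs(_weighted_d(partition.s_windows)) - abs(_weighted_d(partition.l_windows))


test_statistic.__test__ = False  # keep pytest from collecting the library function


def permutation_test(
    partition: SubgenomePartition, config: PermutationConfig
) -> tuple[float, np.ndarray]:
    """One-sided permutation p-value for T under label exchangeability.

    Each permutation reassigns L/S labels across the pooled windows,
    preserving the observed number of windows per subgenome.  Returns
    (p_value, permuted statistics); deterministic given config.seed.
    """
    t_obs = test_statistic(partition)
    # canonical genomic order makes the p-value invariant to how the
    # caller happened to order the windows
    pooled = sorted(
        partition.l_windows + partition.s_windows,
        key=lambda c: (c.window.chrom, c.window.start, c.window.subgenome),
    )
    num = np.array([c.n_abba - c.n_baba for c in pooled])
    den = np.array([c.weight for c in pooled])
    n_l = len(partition.l_windows)
    n_tot = len(pooled)

    rng = np.random.default_rng(config.seed)
    t_perm = np.empty(config.n_permutations)
    for k in range(config.n_permutations):
        perm = rng.permutation(n_tot)
        l_idx, s_idx = perm[:n_l], perm[n_l:]
        d_l = num[l_idx].sum() / den[l_idx].sum()
        d_s = num[s_idx].sum() / den[s_idx].sum()
        t_perm[k] = abs(d_s) - abs(d_l)
    p = (1.0 + np.count_nonzero(t_perm >= t_obs)) / (1.0 + config.n_permutations)
    return float(p), t_perm


def pooled_se(var_l: float, n_l: int, var_s: float, n_s: int) -> float:
    """SE of T: sqrt of summed within-subgenome variances over window counts."""
    if var_l < 0 or var_s < 0:
        raise ValueError("variances must be non-negative")
    if n_l < 1 or n_s < 1:
        raise ValueError("window counts must be >= 1")
    return float(np.sqrt(var_l / n_l + var_s / n_s))


def power80_threshold(pooled: float) -> float:
    """Value of T detectable with 80% power: 2.8 x pooled SE."""
    if pooled < 0:
        raise ValueError("pooled SE must be non-negative")
    return POWER80_MULTIPLIER * pooled


def cohen_d(t_obs: float, var_l: float, var_s: float) -> float:
    """Cohen's d: T over the pooled SD, sqrt of the mean subgenome variance."""
    if var_l < 0 or var_s < 0:
        raise ValueError("variances must be non-negative")
    if var_l == 0 and var_s == 0:
        raise ValueError("both variances are zero: effect size undefined")
    return float(t_obs / np.sqrt((var_l + var_s) / 2.0))


def evaluate_partition(
    partition: SubgenomePartition, config: PermutationConfig
) -> SubgenomeTestResult:
    """Full contrast on a window partition: D per subgenome, T, p, power, effect.

    Cohen's d is reported only for positive T, matching the convention
    of suppressing effect sizes when the observed contrast runs against
    the one-sided alternative.
    """
    d_l = patterson_d(partition.l_windows)
    d_s = patterson_d(partition.s_windows)
    t_obs = test_statistic(partition)
    p, _ = permutation_test(partition, config)
    var_l = variance_from_se(d_l.se, d_l.n_windows) if np.isfinite(d_l.se) else np.nan
    var_s = variance_from_se(d_s.se, d_s.n_windows) if np.isfinite(d_s.se) else np.nan
    se_t = (
        pooled_se(var_l, d_l.n_windows, var_s, d_s.n_windows)
        if np.isfinite(var_l) and np.isfinite(var_s)
        else np.nan
    )
    power = power80_threshold(se_t) if np.isfinite(se_t) else np.nan
    effect = (
        cohen_d(t_obs, var_l, var_s)
        if t_obs > 0 and np.isfinite(var_l) and np.isfinite(var_s) and (var_l + var_s) > 0
        else None
    )
    return SubgenomeTestResult(
        t_obs=t_obs,
        p_value=p,
        pooled_se=se_t,
        power80_threshold=power,
        cohen_d=effect,
        d_l=d_l,
        d_s=d_s,
    )


def run_comparison(
    matrix,
    popmap,
    windows,
    regions=None,
    mode: str = "frequency",
    min_called: int = 2,
    min_pattern_sum: float = 0.0,
    n_permutations: int = 1000,
    seed: int | None = None,
) -> tuple[SubgenomeTestResult, list[WindowCounts]]:
    """Run one comparison end to end: genotypes -> windowed D -> contrast.

    Parameters
    ----------
    matrix : GenotypeMatrix
        Biallelic genotypes, optionally pre-restricted to genic regions.
    popmap : PopulationMap
        Sample->population assignments with the P1/P2/P3/O role grouping.
    windows : list of GenomicWindow
        Subgenome-labeled tiling windows (5 Mb whole-genome convention,
        10 Mb when restricting to genic regions).
    regions : RegionSet, optional
        If given, sites are restricted to these intervals first.

    Returns the contrast result and the per-window counts that fed it.
    """
    from .dstat import aggregate_windows, pattern_weights, site_frequencies
    from .io import restrict_to_regions

    if regions is not None:
        matrix = restrict_to_regions(matrix, regions)
    freqs = site_frequencies(matrix, popmap, min_called=min_called)
    abba, baba = pattern_weights(freqs, mode=mode)
    counts = aggregate_windows(freqs, abba, baba, windows, min_pattern_sum=min_pattern_sum)
    partition = SubgenomePartition.from_counts(counts)
    config = PermutationConfig(n_permutations=n_permutations, seed=seed)
    return evaluate_partition(partition, config), counts
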