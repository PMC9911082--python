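# Methods

## Statistical model

### Pattern weights and Patterson's D

Genotypes are biallelic alternate-allele doses (0/1/2, −1 missing) per
sample. For each site passing a per-role minimum of called allele copies
(default 2, i.e. one called diploid genotype per role, configurable), the
alternate-allele frequency p_i is estimated in each of the four roles
P1, P2, P3, O by direct counting. The per-site weights are the standard
frequency-based forms

    abba = (1 − p1) p2 p3 (1 − p4)
    baba = p1 (1 − p2) p3 (1 − p4)

No explicit ancestral polarization is applied: frequencies refer to the VCF
alternate allele, and the (1 − p4) factor suppresses sites where the
outgroup carries it. A second, "count" mode binarizes each frequency at 0.5
before applying the same formula, yielding integer tallies; ties (p exactly
0.5) map to 0, a strict-majority rule. Frequency mode is the default; the
two modes agree on the partition-level D whenever populations are near
fixation.

D is the ratio of summed weights, D = (Σabba − Σbaba)/(Σabba + Σbaba), over
any collection of windows. Because D is a ratio of sums, the weighted mean
of window-level D values with weights w_i = abba_i + baba_i equals the D
from global totals exactly; this identity is what lets the subgenome
contrast operate interchangeably on window tables or count totals, and it
is enforced by tests at 1e−12.

### Block jackknife

Standard errors use the weighted delete-m jackknife (Busing, Meijer &
van der Leeden 1999) over genomic windows, with block weights equal to each
window's ABBA+BABA sum. With equal weights the estimator reduces exactly to
the classical delete-1 jackknife (tested to 1e−10 against an independent
implementation). The 95% CI is the normal approximation estimate ± 1.96 SE;
per-window D values are approximately normal in the regimes exercised here.
Windows with zero pattern sum carry no information about the ratio and are
excluded from the jackknife (and from the permutation pool, keeping the two
consistent); their count is logged. With fewer than two usable windows the
SE and CI are reported as NaN with a warning rather than an exception, so
degenerate partitions still produce a D estimate.

The variance of per-window D within a subgenome is recovered from the
jackknife SE as var = SE² × n_windows; this is the scale on which the
subgenome contrast is pooled.

### Subgenome contrast, permutation null, power

The contrast statistic is T = |D_S| − |D_L|, each side the weighted mean of
window D (equivalently the global-total D) for that subgenome. The null
distribution is built by permuting the L/S window labels — each permutation
draws a uniformly random assignment preserving the observed number of L and
S windows — and recomputing T; 1,000 permutations by default. The one-sided
p-value uses the add-one convention p = (1 + #{T* ≥ T_obs})/(1 + n_perm),
so p is never 0 and a strongly negative T gives p ≈ 1. The alternative is
fixed a priori as S more extreme than L (the direction restorative gene
flow would take). Before drawing labelings the pooled windows are sorted
into canonical genomic order, which makes the p-value exactly invariant to
how the caller ordered the windows, not merely invariant in distribution.

The pooled SE of T is sqrt(var_L/n_L + var_S/n_S) (= sqrt(SE_L² + SE_S²)),
and the contrast detectable with 80% power in a two-sided 5% test is
2.8 × pooled SE (2.8 ≈ z₀.₉₇₅ + z₀.₈₀). Cohen's d is T divided by the
pooled SD, taken as sqrt((var_L + var_S)/2); values below 0.2 read as a
weak effect. The two denominators — pooled SE of T and pooled SD of window
D — are different quantities and both are reported. Effect sizes are
suppressed (printed "-") when T ≤ 0, since a contrast running against the
one-sided alternative has no interpretable magnitude under it. On simulated
replicates the pooled SE tracks the empirical SD of T within ~10%
(tested at a 25% tolerance over 500 replicates).

## Synthetic data generator

Each site draws an ancestral frequency π from Beta(0.8, 0.8) rescaled into
(0.05, 0.95) — a U-shaped spectrum that guarantees polymorphism — and
evolves along (((P1, P2), P3), O) under the Balding–Nichols model: on a
branch with drift parameter F, p_child ~ Beta(p(1−F)/F, (1−p)(1−F)/F),
mean p and variance F·p(1−p). Exact fixation is absorbing (a fixed
frequency passes through unchanged). Gene flow from P3 into P2 is a
frequency-level pulse p2' = γ·p3 + (1−γ)·p2 with separate γ_L and γ_S per
subgenome; diploid genotypes are Binomial(2, p) draws. Site positions are
uniform with no linkage, so windows are i.i.d. — deliberately, since that
is the regime where jackknife SEs and permutation calibration can be
checked against theory.

Defaults (units in parentheses) and why:

- `n_chroms_per_subgenome = 2`, `chrom_length = 5e7` (bp), `window_size
  = 5e6` (bp): 20 windows of 5 Mb per subgenome — enough blocks for a
  stable jackknife and a rich permutation space (C(40,20) labelings) at
  desk scale.
- `sites_per_window_mean = 300`: several hundred informative sites per
  window, comfortably above the >100-per-pattern regime where window D is
  well behaved.
- `samples_per_population = {P1: 8, P2: 8, P3: 8, O: 4}`: small
  population panels with a smaller pooled outgroup, the typical shape of a
  reduced-representation population survey with a few individuals of
  sister species as outgroup.
- `drift_f`: terminal P1/P2 branches 0.05 (sister populations within a
  region), P3 terminal 0.2 (a population across a strong biogeographic
  divide — under this model E[D] scales with γ·F_P3, and this value puts
  |D| under moderate admixture in the 0.1–0.3 range typical of strongly
  structured amphibian populations), internal branches 0.1, outgroup 0.5
  (deeply diverged sister species, frequently fixed, which concentrates
  the (1−p4) weight on ingroup-informative sites).
- `gamma_l = gamma_s = 0`: no admixture unless asked for.

What the generator does **not** emulate: linkage (windows are exchangeable
by construction, so calibration results transfer to real data only to the
extent that 5 Mb blocks absorb local LD), selection against hybrids beyond
the net admixture proportion, missing genotypes, sequencing error, and
reference bias. Passing calibration and power tests therefore validates the
statistical machinery, not robustness to those real-data features.

## Numerical and interface choices

- Coordinates: VCF is 1-based; windows and BED intervals are 0-based
  half-open; all conversion happens at the I/O boundary.
- Multiallelic and non-SNP records are dropped on read (logged), since the
  pattern weights are defined for biallelic sites.
- Chromosome→subgenome assignment comes from the trailing L/S of the
  chromosome name (the *X. laevis* v9.2 convention); names without the
  suffix (unplaced scaffolds) raise, which excludes them explicitly.
- Upstream genotype filtering (caller-level hard filters, LD pruning) is
  out of scope; the pipeline consumes already-filtered VCFs.
- Windows tile each chromosome from 0 with the last window truncated;
  a site falling outside every window is a hard error (tiling violation),
  not a silent drop.
- Reported tables round to 3 decimals; internal computation is full
  precision.
- The permutation preserves observed label counts (a permutation of
  assignments) rather than relabeling windows independently; with equal
  counts per subgenome the two schemes coincide asymptotically, and the
  count-preserving scheme is the natural reading of "permuting the
  assignments".

## Problem sizes

The test suite and the acceptance script use the generator's default scale
(20 windows per subgenome, ~12,000 sites, 28 samples): 200 replicates for
null calibration, 50 for power, 500 for the pooled-SE consistency check,
1,000 permutations per test. These sizes give binomial/Monte-Carlo error
well inside the asserted tolerances while keeping a full run to a few
minutes on one core.

## Known limitations

- The frequency estimator ignores uncertainty in p_i from small panels;
  with very few called genotypes per role, D is noisy and min_called
  should be raised.
- The jackknife CI relies on approximate normality of window D; with <10
  windows per subgenome the CI is anticonservative.
- The permutation test assumes windows are exchangeable between subgenomes
  under the null up to their weights; strong L/S differences in window
  information content would violate this in ways the label shuffle cannot
  detect.
- Cohen's d is reported against the pooled per-window SD of D, which is an
  estimate of spread across windows, not of estimation error; it is a
  descriptive effect size, not a test.
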