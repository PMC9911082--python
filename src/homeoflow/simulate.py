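"""Synthetic allotetraploid genotype data for a four-population topology.

Generative model
----------------
Each informative site evolves on the tree (((P1, P2), P3), O).  An
ancestral alternate-allele frequency pi is drawn from a truncated
Beta(0.8, 0.8) on (0.05, 0.95) — a U-shaped spectrum guaranteeing
polymorphism.  Along each branch with drift parameter F in (0, 1) the
frequency moves under the Balding–Nichols model:

    p_child ~ Beta(p_parent * (1 - F) / F, (1 - p_parent) * (1 - F) / F)

which has mean p_parent and variance F * p_parent * (1 - p_parent).
Gene flow from P3 into P2 is a frequency-level pulse,

    p2' = gamma * p3 + (1 - gamma) * p2

with a separate admixture proportion gamma per subgenome (gamma_l,
gamma_s), realizing the differential-introgression scenario the
contrast test is designed to detect.  Diploid genotypes are then drawn
binomially from each population frequency — the correct sampling model
for a disomic allotetraploid scored per subgenome locus.

Sites are placed uniformly at random (no linkage), so genomic windows
are i.i.d. — the regime in which the block jackknife and the
permutation calibration can be checked against theory.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .io import GenotypeMatrix, GenomicWindow, PopulationMap, ROLES

__all__ = ["SimulationConfig", "SimulatedDataset", "simulate", "write_vcf",
           "write_dataset", "make_genic_bed"]

_NUCS = np.array(list("ACGT"))


def _default_samples() -> dict[str, int]:
    # three ingroup populations of 8 diploids; a small pooled outgroup
    # (the field-typical situation: few individuals of sister species)
    return {"P1": 8, "P2": 8, "P3": 8, "O": 4}


def _default_drift() -> dict[str, float]:
    # P1/P2 are sister populations within a region (mild terminal drift);
    # P3 sits across a strong biogeographic divide (heavier drift, the
    # regime where |D| reaches the 0.1-0.3 range typical of structured
    # amphibian populations); the outgroup is a deeply diverged sister
    # species pool
    return {"P123": 0.1, "P12": 0.1, "P1": 0.05, "P2": 0.05, "P3": 0.2, "O": 0.5}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic four-population allotetraploid model.

    Defaults give 2 chromosomes per subgenome of 50 Mb — 10 windows of
    5 Mb each, i.e. 20 windows per subgenome — with ~300 informative
    sites expected per window.
    """

    n_chroms_per_subgenome: int = 2
    chrom_length: int = 50_000_000
    window_size: int = 5_000_000
    sites_per_window_mean: float = 300.0
    samples_per_population: dict[str, int] = field(default_factory=_default_samples)
    drift_f: dict[str, float] = field(default_factory=_default_drift)
    gamma_l: float = 0.0
    gamma_s: float = 0.0
    ancestral_beta: tuple[float, float] = (0.8, 0.8)
    ancestral_trunc: tuple[float, float] = (0.05, 0.95)
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n_chroms_per_subgenome < 1:
            raise ValueError("n_chroms_per_subgenome must be >= 1")
        if self.chrom_length < 1 or self.window_size < 1:
            raise ValueError("chrom_length and window_size must be positive")
        if self.sites_per_window_mean <= 0:
            raise ValueError("sites_per_window_mean must be positive")
        for role in ROLES:
            if self.samples_per_population.get(role, 0) < 1:
                raise ValueError(f"samples_per_population[{role!r}] must be >= 1")
        for branch, f in self.drift_f.items():
            if not (0.0 < f < 1.0):
                raise ValueError(f"drift_f[{branch!r}] must be in (0, 1), got {f}")
        for name in ("gamma_l", "gamma_s"):
            g = getattr(self, name)
            if not (0.0 <= g <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {g}")
        lo, hi = self.ancestral_trunc
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"ancestral_trunc must satisfy 0 <= lo < hi <= 1")

    def chrom_lengths(self) -> dict[str, int]:
        return {
            f"chr{i + 1}{sg}": self.chrom_length
            for sg in ("L", "S")
            for i in range(self.n_chroms_per_subgenome)
        }

    def subgenome_map(self) -> dict[str, str]:
        return {name: name[-1] for name in self.chrom_lengths()}


@dataclass
class SimulatedDataset:
    matrix: GenotypeMatrix
    popmap: PopulationMap
    subgenome_map: dict[str, str]
    chrom_lengths: dict[str, int]
    truth: SimulationConfig


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    # fixation (p = 0 or 1) is absorbing under pure drift: carry it through
    out = np.asarray(p, dtype=float).copy()
    seg = (out > 0.0) & (out < 1.0)
    a = out[seg] * (1.0 - f) / f
    b = (1.0 - out[seg]) * (1.0 - f) / f
    out[seg] = rng.beta(a, b)
    return out


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Draw a complete dataset from the configured generative model."""
    rng = np.random.default_rng(config.seed)
    lengths = config.chrom_lengths()
    sg_map = config.subgenome_map()

    # site positions per chromosome: Poisson count, uniform placement
    chroms: list[str] = []
    positions: list[np.ndarray] = []
    mean_sites = config.sites_per_window_mean * config.chrom_length / config.window_size
    for chrom in sorted(lengths):
        n = rng.poisson(mean_sites)
        pos = np.unique(rng.integers(1, lengths[chrom] + 1, size=n))
        chroms.append(chrom)
        positions.append(pos)
    n_sites = int(sum(len(p) for p in positions))
    chrom_arr = np.concatenate(
        [np.full(len(p), c, dtype=object) for c, p in zip(chroms, positions)]
    )
    pos_arr = np.concatenate(positions).astype(np.int64)
    is_s = np.array([sg_map[c] == "S" for c in chrom_arr])

    # frequencies down the tree (((P1,P2),P3),O)
    lo, hi = config.ancestral_trunc
    a0, b0 = config.ancestral_beta
    pi = rng.beta(a0, b0, size=n_sites)
    pi = lo + pi * (hi - lo)  # rescale into the truncation interval
    f = config.drift_f
    p4 = _balding_nichols(rng, pi, f["O"])
    p123 = _balding_nichols(rng, pi, f["P123"])
    p3 = _balding_nichols(rng, p123, f["P3"])
    p12 = _balding_nichols(rng, p123, f["P12"])
    p1 = _balding_nichols(rng, p12, f["P1"])
    p2 = _balding_nichols(rng, p12, f["P2"])

    gamma = np.where(is_s, config.gamma_s, config.gamma_l)
    p2 = gamma * p3 + (1.0 - gamma) * p2

    # diploid genotypes per population block
    samples: list[str] = []
    assignments: dict[str, str] = {}
    blocks: list[np.ndarray] = []
    pop_freq = {"P1": p1, "P2": p2, "P3": p3, "O": p4}
    for role in ROLES:
        n_ind = config.samples_per_population[role]
        for k in range(n_ind):
            name = f"{role.lower()}_{k:02d}"
            samples.append(name)
            assignments[name] = role.lower()
        freq = pop_freq[role][:, None]
        blocks.append(rng.binomial(2, np.broadcast_to(freq, (n_sites, n_ind))).astype(np.int8))
    doses = np.concatenate(blocks, axis=1)

    # random distinct ref/alt nucleotides
    ref_idx = rng.integers(0, 4, size=n_sites)
    alt_idx = (ref_idx + rng.integers(1, 4, size=n_sites)) % 4

    matrix = GenotypeMatrix(
        samples=samples,
        chrom=chrom_arr,
        pos=pos_arr,
        ref=_NUCS[ref_idx].astype(object),
        alt=_NUCS[alt_idx].astype(object),
        doses=doses,
    )
    popmap = PopulationMap(
        assignments=assignments,
        role_map={role: {role.lower()} for role in ROLES},
    )
    return SimulatedDataset(
        matrix=matrix,
        popmap=popmap,
        subgenome_map=sg_map,
        chrom_lengths=lengths,
        truth=replace(config),
    )


_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(dataset: SimulatedDataset, path: str | Path) -> None:
    """Write the dataset as a minimal VCF 4.2 with GT-only genotypes."""
    m = dataset.matrix
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=homeoflow-simulate\n")
        for chrom in sorted(dataset.chrom_lengths):
            fh.write(f"##contig=<ID={chrom},length={dataset.chrom_lengths[chrom]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(m.samples) + "\n")
        for i in range(m.n_sites):
            gts = "\t".join(_GT[int(d)] for d in m.doses[i])
            fh.write(
                f"{m.chrom[i]}\t{m.pos[i]}\t.\t{m.ref[i]}\t{m.alt[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write VCF plus companion popmap and chromosome-length files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "vcf": outdir / "dataset.vcf",
        "popmap": outdir / "popmap.txt",
        "chrom_lengths": outdir / "chrom_lengths.tsv",
    }
    write_vcf(dataset, paths["vcf"])
    with open(paths["popmap"], "w") as fh:
        for sample in dataset.matrix.samples:
            fh.write(f"{sample}\t{dataset.popmap.assignments[sample]}\n")
    with open(paths["chrom_lengths"], "w") as fh:
        for chrom in sorted(dataset.chrom_lengths):
            fh.write(f"{chrom}\t{dataset.chrom_lengths[chrom]}\n")
    return paths


def make_genic_bed(
    chrom_lengths: dict[str, int],
    fraction: float,
    seed: int | None = None,
    mean_gene_length: int = 50_000,
):
    """Random merged intervals covering ~``fraction`` of each chromosome.

    A synthetic stand-in for a genic (exon+intron) annotation: the
    chromosome is cut into blocks around ``mean_gene_length`` / fraction
    and one interval of length fraction x block is placed at a random
    offset within each block, giving near-exact coverage with sorted,
    non-overlapping output.
    """
    from .io import RegionSet

    if not (0.0 < fraction <= 1.0):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    triples: list[tuple[str, int, int]] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        block = max(1, int(round(mean_gene_length / fraction)))
        for start in range(0, length, block):
            b_len = min(block, length - start)
            g_len = max(1, int(round(fraction * b_len)))
            offset = int(rng.integers(0, b_len - g_len + 1))
            triples.append((chrom, start + offset, start + offset + g_len))
    return RegionSet.from_intervals(triples)
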