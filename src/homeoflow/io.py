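"""Genotype, population and interval I/O.

Conventions
-----------
* VCF positions are 1-based; all internal window/region arithmetic is
  0-based half-open; BED is read as 0-based half-open.
* Genotypes are stored as alternate-allele doses in {0, 1, 2}, with -1
  for missing or non-diploid calls.  This is the correct representation
  for a disomic allotetraploid mapped to a subgenome-resolved reference:
  each subgenome locus behaves as an ordinary diploid locus.
* Multiallelic and non-SNP records are dropped when ``biallelic_only``
  is set (the D statistic is defined for biallelic sites); the dropped
  count is logged.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "PopulationMap",
    "GenomicWindow",
    "RegionSet",
    "read_vcf",
    "read_population_map",
    "read_chrom_lengths",
    "read_bed",
    "subgenome_from_chrom_suffix",
    "make_windows",
    "restrict_to_regions",
]

MISSING = -1

ROLES = ("P1", "P2", "P3", "O")


@dataclass
class GenotypeMatrix:
    """Biallelic genotype calls for samples x sites.

    Attributes
    ----------
    samples : list of str
        Ordered, unique sample identifiers.
    chrom, pos : ndarray
        Per-site chromosome name and 1-based coordinate, sorted by
        (chrom, pos) with no duplicate coordinates.
    ref, alt : ndarray
        Single-character reference / alternate nucleotides.
    doses : ndarray of shape (n_sites, n_samples), int8
        Alternate-allele dose per site and sample; -1 = missing.
    """

    samples: list[str]
    chrom: np.ndarray
    pos: np.ndarray
    ref: np.ndarray
    alt: np.ndarray
    doses: np.ndarray

    def __post_init__(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("duplicate sample identifiers")
        n_sites = len(self.pos)
        if self.doses.shape != (n_sites, len(self.samples)):
            raise ValueError(
                f"doses shape {self.doses.shape} does not match "
                f"{n_sites} sites x {len(self.samples)} samples"
            )
        if n_sites and np.any(self.pos < 1):
            raise ValueError("positions must be 1-based (>= 1)")
        order = np.lexsort((self.pos, self.chrom))
        if not np.array_equal(order, np.arange(n_sites)):
            self.chrom = self.chrom[order]
            self.pos = self.pos[order]
            self.ref = self.ref[order]
            self.alt = self.alt[order]
            self.doses = self.doses[order]
        if n_sites > 1:
            same = (self.chrom[1:] == self.chrom[:-1]) & (self.pos[1:] == self.pos[:-1])
            if np.any(same):
                i = int(np.flatnonzero(same)[0])
                raise ValueError(
                    f"duplicate site {self.chrom[i]}:{self.pos[i]}"
                )

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def take_sites(self, index: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            samples=list(self.samples),
            chrom=self.chrom[index],
            pos=self.pos[index],
            ref=self.ref[index],
            alt=self.alt[index],
            doses=self.doses[index],
        )


@dataclass
class PopulationMap:
    """Sample -> population assignments plus the four analysis roles.

    ``role_map`` sends each of P1, P2, P3, O to a set of population
    labels; populations may pool several sampling localities (e.g. a
    "winter rainfall" population made of four localities).
    """

    assignments: dict[str, str]
    role_map: dict[str, set[str]]

    def __post_init__(self) -> None:
        missing = [r for r in ROLES if r not in self.role_map]
        if missing:
            raise ValueError(f"role_map missing roles: {missing}")
        seen: dict[str, str] = {}
        for role in ROLES:
            for pop in self.role_map[role]:
                if pop in seen:
                    raise ValueError(
                        f"population {pop!r} assigned to both {seen[pop]} and {role}"
                    )
                seen[pop] = role

    def samples_for_role(self, role: str) -> list[str]:
        pops = self.role_map[role]
        return [s for s, p in self.assignments.items() if p in pops]

    def role_indices(self, samples: list[str]) -> dict[str, np.ndarray]:
        """Column indices of each role's samples within ``samples``.

        Raises if a role has no sample present in the matrix.
        """
        pos = {s: i for i, s in enumerate(samples)}
        out: dict[str, np.ndarray] = {}
        for role in ROLES:
            idx = [pos[s] for s in self.samples_for_role(role) if s in pos]
            if not idx:
                raise ValueError(f"role {role} has no samples in the genotype matrix")
            out[role] = np.asarray(idx, dtype=np.intp)
        return out


@dataclass(frozen=True)
class GenomicWindow:
    """Half-open genomic interval [start, end) on one chromosome."""

    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    subgenome: str  # "L" or "S"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid window [{self.start}, {self.end})")
        if self.subgenome not in ("L", "S"):
            raise ValueError(f"subgenome must be L or S, got {self.subgenome!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RegionSet:
    """Per-chromosome sorted, merged half-open intervals (BED semantics)."""

    intervals: dict[str, np.ndarray] = field(default_factory=dict)

    @classmethod
    def from_intervals(cls, triples: list[tuple[str, int, int]]) -> "RegionSet":
        by_chrom: dict[str, list[tuple[int, int]]] = {}
        for chrom, start, end in triples:
            if start < 0 or end <= start:
                raise ValueError(f"invalid interval {chrom}:{start}-{end}")
            by_chrom.setdefault(chrom, []).append((int(start), int(end)))
        merged: dict[str, np.ndarray] = {}
        for chrom, ivs in by_chrom.items():
            ivs.sort()
            out: list[list[int]] = []
            for s, e in ivs:
                if out and s <= out[-1][1]:
                    out[-1][1] = max(out[-1][1], e)
                else:
                    out.append([s, e])
            merged[chrom] = np.asarray(out, dtype=np.int64)
        return cls(intervals=merged)

    def contains(self, chrom: str, pos0: np.ndarray) -> np.ndarray:
        """Boolean membership of 0-based positions in this chromosome's intervals."""
        ivs = self.intervals.get(chrom)
        if ivs is None or len(ivs) == 0:
            return np.zeros(len(pos0), dtype=bool)
        # intervals are disjoint and sorted: a position is covered iff the
        # interval whose start precedes it also ends after it
        i = np.searchsorted(ivs[:, 0], pos0, side="right") - 1
        ok = i >= 0
        out = np.zeros(len(pos0), dtype=bool)
        out[ok] = pos0[ok] < ivs[i[ok], 1]
        return out

    def total_length(self) -> int:
        return int(sum((ivs[:, 1] - ivs[:, 0]).sum() for ivs in self.intervals.values()))

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom in sorted(self.intervals):
                for s, e in self.intervals[chrom]:
                    fh.write(f"{chrom}\t{s}\t{e}\n")


class VcfParseError(ValueError):
    pass


def read_vcf(path: str | Path, biallelic_only: bool = True) -> GenotypeMatrix:
    """Read a VCF into a :class:`GenotypeMatrix` of alt-allele doses.

    Diploid GT fields become doses 0/1/2; uncalled (``./.``) or
    non-diploid genotypes become missing (-1).  With ``biallelic_only``
    (default) multiallelic and non-SNP records are dropped and counted.
    """
    from cyvcf2 import VCF

    path = str(path)
    try:
        vcf = VCF(path, gts012=False)
    except Exception as exc:  # htslib raises plain Exception subclasses
        raise VcfParseError(f"cannot parse VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    if not samples:
        raise VcfParseError(f"VCF {path!r} contains zero samples")

    chroms: list[str] = []
    poss: list[int] = []
    refs: list[str] = []
    alts: list[str] = []
    dose_rows: list[np.ndarray] = []
    n_dropped = 0
    for line_no, var in enumerate(vcf, start=1):
        is_snp = len(var.REF) == 1 and all(len(a) == 1 for a in var.ALT)
        if len(var.ALT) != 1 or not is_snp:
            if biallelic_only:
                n_dropped += 1
                continue
            raise VcfParseError(
                f"record {var.CHROM}:{var.POS} (record #{line_no}) is not a "
                "biallelic SNP and biallelic_only is off"
            )
        row = np.full(len(samples), MISSING, dtype=np.int8)
        for j, gt in enumerate(var.genotypes):
            alleles = gt[:-1]  # last element is the phasing flag
            if len(alleles) == 2 and all(a in (0, 1) for a in alleles):
                row[j] = alleles[0] + alleles[1]
        chroms.append(var.CHROM)
        poss.append(var.POS)
        refs.append(var.REF)
        alts.append(var.ALT[0])
        dose_rows.append(row)
    if n_dropped:
        logger.info("read_vcf: dropped %d multiallelic/non-SNP records", n_dropped)

    n = len(poss)
    return GenotypeMatrix(
        samples=samples,
        chrom=np.asarray(chroms, dtype=object),
        pos=np.asarray(poss, dtype=np.int64),
        ref=np.asarray(refs, dtype=object),
        alt=np.asarray(alts, dtype=object),
        doses=np.vstack(dose_rows) if n else np.zeros((0, len(samples)), dtype=np.int8),
    )


def read_population_map(path: str | Path, roles: dict[str, list[str]]) -> PopulationMap:
    """Read a two-column sample/population table and attach role groupings.

    ``roles`` maps each of P1, P2, P3, O to a list of population labels;
    a role may pool several populations (localities).
    """
    assignments: dict[str, str] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise ValueError(
                    f"{path}:{line_no}: expected 'sample population', got {line!r}"
                )
            sample, pop = parts
            if sample in assignments and assignments[sample] != pop:
                raise ValueError(
                    f"{path}:{line_no}: sample {sample!r} assigned to both "
                    f"{assignments[sample]!r} and {pop!r}"
                )
            assignments[sample] = pop
    present = set(assignments.values())
    role_map: dict[str, set[str]] = {}
    for role, pops in roles.items():
        absent = [p for p in pops if p not in present]
        if absent:
            raise ValueError(f"role {role}: populations {absent} not in popmap")
        role_map[role] = set(pops)
    return PopulationMap(assignments=assignments, role_map=role_map)


def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a two-column chromosome/length TSV."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, length = line.split()[:2]
            out[name] = int(length)
    return out


def read_bed(path: str | Path) -> RegionSet:
    """Read a BED3 file (0-based half-open) into a merged RegionSet."""
    triples: list[tuple[str, int, int]] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{line_no}: not a BED3 line: {line!r}")
            triples.append((parts[0], int(parts[1]), int(parts[2])))
    return RegionSet.from_intervals(triples)


_SUFFIX_RE = re.compile(r"([LS])$")


def subgenome_from_chrom_suffix(
    chrom_names: list[str], pattern: str | re.Pattern[str] = _SUFFIX_RE
) -> dict[str, str]:
    """Assign chromosomes to subgenomes by trailing L/S in the name.

    Follows the X. laevis v9.2 convention where homeologous chromosome
    pairs are named e.g. chr1L / chr1S.  Names without a recognizable
    suffix (unplaced scaffolds) raise, which excludes them explicitly.
    """
    pattern = re.compile(pattern)
    out: dict[str, str] = {}
    bad: list[str] = []
    for name in chrom_names:
        m = pattern.search(name)
        if m:
            out[name] = m.group(1)
        else:
            bad.append(name)
    if bad:
        raise ValueError(f"chromosomes without L/S subgenome suffix: {bad}")
    return out


def make_windows(
    chrom_lengths: dict[str, int],
    window_size: int,
    subgenomes: dict[str, str],
) -> list[GenomicWindow]:
    """Tile each chromosome with half-open windows of ``window_size``.

    The last window of each chromosome is truncated at its length.
    Windows inherit the chromosome's subgenome label.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    windows: list[GenomicWindow] = []
    for chrom in sorted(chrom_lengths):
        length = chrom_lengths[chrom]
        if chrom not in subgenomes:
            raise ValueError(f"chromosome {chrom!r} absent from subgenome map")
        sg = subgenomes[chrom]
        for start in range(0, length, window_size):
            windows.append(
                GenomicWindow(chrom, start, min(start + window_size, length), sg)
            )
    return windows


def restrict_to_regions(matrix: GenotypeMatrix, regions: RegionSet) -> GenotypeMatrix:
    """Keep exactly the sites whose 0-based position falls in a region."""
    keep = np.zeros(matrix.n_sites, dtype=bool)
    for chrom in np.unique(matrix.chrom):
        sel = matrix.chrom == chrom
        keep[sel] = regions.contains(str(chrom), matrix.pos[sel] - 1)
    return matrix.take_sites(np.flatnonzero(keep))
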