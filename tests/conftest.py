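import numpy as np
import pytest

import homeoflow as hf


@pytest.fixture(scope="session")
def null_dataset():
    """One simulated dataset with no admixture in either subgenome."""
    return hf.simulate(hf.SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def small_config():
    """A reduced genome for fast end-to-end runs."""
    return hf.SimulationConfig(
        n_chroms_per_subgenome=1,
        chrom_length=4_000_000,
        window_size=1_000_000,
        sites_per_window_mean=120.0,
        seed=7,
    )


def make_vcf(path, records, samples=("s1", "s2", "s3"), contigs=(("chr1L", 1_000_000),)):
    """Write a minimal VCF from (chrom, pos, ref, alt, gt-strings) tuples."""
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for chrom, pos, ref, alt, gts in records:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\tPASS\t.\tGT\t" + "\t".join(gts))
    path.write_text("\n".join(lines) + "\n")
    return path


def random_window_counts(rng, n_l=6, n_s=6, mean_sites=120):
    """Random subgenome-labeled window counts for algebraic property tests."""
    counts = []
    for sg, n in (("L", n_l), ("S", n_s)):
        for i in range(n):
            tot = int(rng.poisson(mean_sites)) + 2
            abba = int(rng.integers(0, tot + 1))
            counts.append(
                hf.WindowCounts(
                    window=hf.GenomicWindow(f"chr{i + 1}{sg}", 0, 1_000_000, sg),
                    n_abba=float(abba),
                    n_baba=float(tot - abba),
                    n_sites=tot,
                )
            )
    return counts
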