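#!/usr/bin/env python
"""Subgenome contrast tests on the simulated datasets.

For each dataset from 01_simulate.py, contrasts Patterson's D between
the L and S subgenomes: the weighted statistic T = |D_S| - |D_L|, a
1,000-permutation label test, the pooled SE of T, the 80%-power
threshold (2.8 x pooled SE) and Cohen's d.  Writes one report table
per dataset under results/contrast/ and prints the headline numbers.
"""

from pathlib import Path

import homeoflow as hf
from homeoflow.tables import comparison_to_frame, write_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"
ROLES = {"P1": ["p1"], "P2": ["p2"], "P3": ["p3"], "O": ["o"]}


def main() -> None:
    outdir = ROOT / "contrast"
    outdir.mkdir(parents=True, exist_ok=True)
    for name, seed in (("differential", 201), ("null", 202)):
        indir = ROOT / "sim" / name
        matrix = hf.read_vcf(indir / "dataset.vcf")
        popmap = hf.read_population_map(indir / "popmap.txt", roles=ROLES)
        lengths = hf.read_chrom_lengths(indir / "chrom_lengths.tsv")
        sg = hf.subgenome_from_chrom_suffix(sorted(lengths))
        windows = hf.make_windows(lengths, 5_000_000, sg)
        result, _ = hf.run_comparison(
            matrix, popmap, windows, n_permutations=1000, seed=seed
        )
        write_tsv(comparison_to_frame(name, result), outdir / f"{name}.tsv")
        effect = "-" if result.cohen_d is None else f"{result.cohen_d:.3f}"
        print(
            f"{name}: D_L={result.d_l.d:+.3f} D_S={result.d_s.d:+.3f} "
            f"T={result.t_obs:+.3f} p={result.p_value:.3f} "
            f"pooled_se={result.pooled_se:.3f} "
            f"power80={result.power80_threshold:.3f} effect={effect}"
        )


if __name__ == "__main__":
    main()
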