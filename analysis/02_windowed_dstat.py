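#!/usr/bin/env python
"""Windowed ABBA/BABA counts and per-subgenome Patterson's D.

Reads the simulated datasets written by 01_simulate.py back through the
VCF path (exercising the same I/O a real dataset would use), computes
5 Mb window counts and genome-wide D per subgenome with block-jackknife
CIs, and repeats the computation on the genic-only subset with 10 Mb
windows.  Writes per-window TSVs and a D summary under results/dstat/.
"""

from pathlib import Path

import pandas as pd

import homeoflow as hf
from homeoflow.tables import windows_to_frame, write_tsv

ROOT = Path(__file__).resolve().parent.parent / "results"
ROLES = {"P1": ["p1"], "P2": ["p2"], "P3": ["p3"], "O": ["o"]}


def analyse(name: str) -> None:
    indir = ROOT / "sim" / name
    outdir = ROOT / "dstat" / name
    outdir.mkdir(parents=True, exist_ok=True)

    matrix = hf.read_vcf(indir / "dataset.vcf")
    popmap = hf.read_population_map(indir / "popmap.txt", roles=ROLES)
    lengths = hf.read_chrom_lengths(indir / "chrom_lengths.tsv")
    sg = hf.subgenome_from_chrom_suffix(sorted(lengths))

    summary_rows = []
    for subset, window_size, regions in (
        ("whole", 5_000_000, None),
        ("genic", 10_000_000, hf.read_bed(indir / "genic.bed")),
    ):
        windows = hf.make_windows(lengths, window_size, sg)
        _, counts = hf.run_comparison(
            matrix, popmap, windows, regions=regions, n_permutations=1, seed=0
        )
        write_tsv(windows_to_frame(counts), outdir / f"windows_{subset}.tsv")
        from homeoflow.contrast import SubgenomePartition

        part = SubgenomePartition.from_counts(counts)
        for sg_label, wins in (("L", part.l_windows), ("S", part.s_windows)):
            res = hf.patterson_d(wins)
            summary_rows.append(
                dict(dataset=name, subset=subset, subgenome=sg_label,
                     d=round(res.d, 3), ci_low=round(res.ci_low, 3),
                     ci_high=round(res.ci_high, 3), n_windows=res.n_windows,
                     n_abba=round(res.n_abba, 1), n_baba=round(res.n_baba, 1))
            )
            print(f"{name}/{subset} {sg_label}: D={res.d:+.3f} "
                  f"[{res.ci_low:+.3f}, {res.ci_high:+.3f}] over {res.n_windows} windows")
    write_tsv(pd.DataFrame(summary_rows), outdir / "dstat_summary.tsv")


def main() -> None:
    for name in ("differential", "null"):
        analyse(name)


if __name__ == "__main__":
    main()
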