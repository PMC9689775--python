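"""Per-species, per-superfamily TE divergence landscapes: CpG-corrected
Kimura distance of each copy to its consensus, binned at 1% divergence,
masses as percent of genome.

Reads results/simdata/, writes results/landscapes/.
"""

import argparse
from pathlib import Path

import pandas as pd

from socialte import io
from socialte.divergence import build_landscape, divergence_table


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/simdata"))
    ap.add_argument("--out", type=Path, default=Path("results/landscapes"))
    ap.add_argument("--genome-size", type=int, default=2_000_000)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    meta = pd.read_csv(args.data / "species.tsv", sep="\t")
    for sp in meta.species:
        pairs = io.read_aligned_pairs(args.data / sp / "aligned_pairs.tsv")
        table = divergence_table(pairs, cpg_correct=True)
        landscape = build_landscape(table, genome_size=args.genome_size)
        io.write_tsv(table, args.out / f"{sp}_divergence.tsv")
        io.write_tsv(landscape, args.out / f"{sp}_landscape.tsv")
        peak = landscape.loc[landscape.groupby("superfamily").percent.idxmax()]
        summary = ", ".join(
            f"{r.superfamily}@{r.bin_low:g}-{r.bin_high:g}%" for r in peak.itertuples()
        )
        print(f"{sp}: mean K = {table.K.mean():.4f}; landscape peaks: {summary}")


if __name__ == "__main__":
    main()
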