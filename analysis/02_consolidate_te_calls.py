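"""Consolidate per-tool TE calls into one deduplicated library per species
(drop >10 kb artifacts, resolve >20% overlaps) and filter the genome-mapped
copies (drop scores <= 1, keep the best-scoring copy per overlap chain).

Reads results/simdata/, writes results/te_library/.
"""

import argparse
from pathlib import Path

import pandas as pd

from socialte import io
from socialte.telibrary import dedup_calls, filter_mapped


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/simdata"))
    ap.add_argument("--out", type=Path, default=Path("results/te_library"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    meta = pd.read_csv(args.data / "species.tsv", sep="\t")
    rows = []
    for sp in meta.species:
        d = args.data / sp
        calls = [c for bed in sorted(d.glob("calls_tool*.bed")) for c in io.read_tecalls_bed(bed)]
        library = dedup_calls(calls)
        io.write_tecalls_bed(library, args.out / f"{sp}_library.bed")
        mapped = io.read_mapped_bed(d / "mapped.bed")
        filtered = filter_mapped(mapped)
        io.write_mapped_bed(filtered, args.out / f"{sp}_mapped_filtered.bed")
        rows.append((sp, len(calls), len(library), len(mapped), len(filtered)))
        print(f"{sp}: {len(calls)} calls -> {len(library)} library entries; "
              f"{len(mapped)} mapped copies -> {len(filtered)} after filtering")
    pd.DataFrame(
        rows, columns=["species", "raw_calls", "library", "mapped", "mapped_filtered"]
    ).to_csv(args.out / "consolidation_summary.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
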