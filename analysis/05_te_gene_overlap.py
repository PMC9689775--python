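"""Relate filtered TE copies to gene models per species: closest same-strand
TE, within-gene insertion counts split exon/intron, insertions per gene
kilobase, TE-rich flags (rate > Q3), per-bias-class gene-length summaries,
and the long-format contingency tables for the factorial comparisons.

Reads results/simdata/ and results/te_library/, writes results/overlap/.
"""

import argparse
from pathlib import Path

import pandas as pd

from socialte import io
from socialte.expression import frame_to_records
from socialte.overlap import (
    assign_tes_to_genes,
    build_tables,
    flag_te_rich,
    profile_genes,
    profiles_to_frame,
    summarize_gene_length,
)


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--data", type=Path, default=Path("results/simdata"))
    ap.add_argument("--telib", type=Path, default=Path("results/te_library"))
    ap.add_argument("--de", type=Path, default=Path("results/expression"))
    ap.add_argument("--out", type=Path, default=Path("results/overlap"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    meta = pd.read_csv(args.data / "species.tsv", sep="\t")
    profiles_by_sp, tes_by_sp, asn_by_sp = {}, {}, {}
    for sp in meta.species:
        models = io.read_gff3(args.data / sp / "genes.gff3")
        tes = io.read_mapped_bed(args.telib / f"{sp}_mapped_filtered.bed")
        de = frame_to_records(pd.read_csv(args.de / f"{sp}_de.tsv", sep="\t"))
        profiles = flag_te_rich(profile_genes(models, tes, de))
        profiles_by_sp[sp] = profiles
        tes_by_sp[sp] = tes
        asn_by_sp[sp] = assign_tes_to_genes(models, tes, de)
        io.write_tsv(profiles_to_frame(profiles), args.out / f"{sp}_profiles.tsv")
        io.write_tsv(
            summarize_gene_length(profiles), args.out / f"{sp}_gene_length.tsv"
        )
        n_rich = sum(p.te_rich for p in profiles)
        with_te = sum(p.n_te > 0 for p in profiles)
        print(f"{sp}: {with_te}/{len(profiles)} genes carry a same-strand TE; "
              f"{n_rich} TE-rich (rate > Q3)")

    tables = build_tables(profiles_by_sp, meta, tes_by_sp, asn_by_sp)
    for name, df in tables.items():
        io.write_tsv(df, args.out / f"table_{name}.tsv")
    print("contingency tables written:", ", ".join(tables))


if __name__ == "__main__":
    main()
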