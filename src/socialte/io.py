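"""Readers and writers for the plain-text formats the pipeline consumes.

GFF3 for gene models (1-based inclusive), BED6+2 for TE calls and mapped
copies (0-based half-open; extra columns: superfamily, score or tool), TSV
for counts/samples/traits/GO maps, FASTA for consensus/copy sequences and
newick for species trees (via dendropy).
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import dendropy
import pandas as pd

from socialte.models import EXON_COLUMNS, GENE_COLUMNS, GeneModels, MappedTE, TECall

# ---------------------------------------------------------------- GFF3


def write_gff3(models: GeneModels, path: str | Path) -> None:
    buf = _io.StringIO()
    buf.write("##gff-version 3\n")
    for chrom, size in sorted(models.chrom_sizes.items()):
        buf.write(f"##sequence-region {chrom} 1 {size}\n")
    exons_by_gene = dict(tuple(models.exons.groupby("gene_id", sort=False))) if len(models.exons) else {}
    for g in models.genes.itertuples(index=False):
        buf.write(
            f"{g.chrom}\tsocialte\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.gene_id}\n"
        )
        for e in exons_by_gene.get(g.gene_id, pd.DataFrame(columns=EXON_COLUMNS)).itertuples(index=False):
            buf.write(
                f"{e.chrom}\tsocialte\texon\t{e.start + 1}\t{e.end}\t.\t{e.strand}\t.\t"
                f"ID={e.gene_id}.e{e.exon_number};Parent={e.gene_id}\n"
            )
    Path(path).write_text(buf.getvalue())


def _gff3_attr(attrs: str, key: str) -> str:
    for part in attrs.split(";"):
        k, _, v = part.partition("=")
        if k == key:
            return v
    return ""


def read_gff3(path: str | Path) -> GeneModels:
    genes, exons, sizes = [], [], {}
    for line in Path(path).read_text().splitlines():
        if line.startswith("##sequence-region"):
            _, chrom, _, end = line.split()
            sizes[chrom] = int(end)
            continue
        if not line or line.startswith("#"):
            continue
        chrom, _, ftype, start, end, _, strand, _, attrs = line.split("\t")
        start0 = int(start) - 1
        if ftype == "gene":
            genes.append((_gff3_attr(attrs, "ID"), chrom, start0, int(end), strand))
        elif ftype == "exon":
            gid = _gff3_attr(attrs, "Parent")
            num = int(_gff3_attr(attrs, "ID").rsplit(".e", 1)[1])
            exons.append((gid, chrom, start0, int(end), strand, num))
    return GeneModels(
        genes=pd.DataFrame(genes, columns=GENE_COLUMNS),
        exons=pd.DataFrame(exons, columns=EXON_COLUMNS),
        chrom_sizes=sizes,
    )


# ---------------------------------------------------------------- BED6+2
# Columns: chrom start end name score strand superfamily extra
# For tool call sets, name = call_id and extra = tool; for mapped copies,
# name = copy_id and extra = library_id.


def write_tecalls_bed(calls: list[TECall], path: str | Path) -> None:
    with open(path, "w") as fh:
        for c in calls:
            name = c.call_id or f"{c.tool}:{c.chrom}:{c.start}"
            fh.write(
                f"{c.chrom}\t{c.start}\t{c.end}\t{name}\t{c.score:g}\t{c.strand}\t"
                f"{c.superfamily}\t{c.tool}\n"
            )


def read_tecalls_bed(path: str | Path) -> list[TECall]:
    calls = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        chrom, start, end, name, score, strand, superfamily, tool = line.split("\t")
        calls.append(
            TECall(chrom, int(start), int(end), strand, tool, superfamily, float(score), name)
        )
    return calls


def write_mapped_bed(copies: list[MappedTE], path: str | Path) -> None:
    with open(path, "w") as fh:
        for m in copies:
            fh.write(
                f"{m.chrom}\t{m.start}\t{m.end}\t{m.copy_id}\t{m.score:g}\t{m.strand}\t"
                f"{m.superfamily}\t{m.library_id}\n"
            )


def read_mapped_bed(path: str | Path) -> list[MappedTE]:
    copies = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith(("#", "track")):
            continue
        chrom, start, end, name, score, strand, superfamily, lib = line.split("\t")
        copies.append(
            MappedTE(chrom, int(start), int(end), strand, superfamily, float(score), name, lib)
        )
    return copies


# ---------------------------------------------------------------- TSV tables


def write_tsv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", index=index)


def read_counts(path: str | Path) -> pd.DataFrame:
    """Gene x library count matrix; first column = gene_id index."""
    return pd.read_csv(path, sep="\t", index_col=0)


def read_samples(path: str | Path) -> pd.DataFrame:
    """Samples TSV: library, species, group columns."""
    return pd.read_csv(path, sep="\t")


def read_gene2go(path: str | Path) -> dict[str, set[str]]:
    df = pd.read_csv(path, sep="\t")
    out: dict[str, set[str]] = {}
    for gene, term in zip(df["gene_id"], df["term_id"]):
        out.setdefault(gene, set()).add(term)
    return out


def write_gene2go(annotations: dict[str, set[str]], path: str | Path) -> None:
    rows = [(g, t) for g in sorted(annotations) for t in sorted(annotations[g])]
    write_tsv(pd.DataFrame(rows, columns=["gene_id", "term_id"]), path)


def read_dag_edges(path: str | Path) -> list[tuple[str, str]]:
    df = pd.read_csv(path, sep="\t")
    return list(zip(df["child"], df["parent"]))


def write_dag_edges(edges: list[tuple[str, str]], path: str | Path) -> None:
    write_tsv(pd.DataFrame(sorted(edges), columns=["child", "parent"]), path)


# ---------------------------------------------------------------- FASTA / alignments


def write_fasta(records: dict[str, str], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_aligned_pairs(pairs: pd.DataFrame, path: str | Path) -> None:
    """TSV of (copy_id, superfamily, copy_aln, consensus_aln[, length])."""
    write_tsv(pairs, path)


def read_aligned_pairs(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------- trees & traits


def read_tree(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)


def read_traits(path: str | Path) -> pd.DataFrame:
    """Per-species trait table indexed by species id."""
    return pd.read_csv(path, sep="\t", index_col=0)
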