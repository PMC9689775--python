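"""Core genomic containers shared across the pipeline.

All internal coordinates are 0-based half-open; GFF3 emission converts to
1-based inclusive and BED emission keeps 0-based half-open, as each format
mandates.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import pandas as pd

GENE_COLUMNS = ["gene_id", "chrom", "start", "end", "strand"]
EXON_COLUMNS = ["gene_id", "chrom", "start", "end", "strand", "exon_number"]


class IntervalError(ValueError):
    """A malformed genomic interval (start >= end, bad strand ...)."""


@dataclass(frozen=True)
class TECall:
    """A de novo TE annotation call from one tool.

    ``length`` is ``end - start`` on the 0-based half-open interval.
    """

    chrom: str
    start: int
    end: int
    strand: str
    tool: str
    superfamily: str
    score: float = 0.0
    call_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise IntervalError(
                f"TE call {self.call_id or self.tool}: start {self.start} >= end {self.end}"
            )
        if self.strand not in ("+", "-"):
            raise IntervalError(f"TE call strand must be +/-, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class MappedTE:
    """A TE copy mapped onto the genome against a consensus library.

    ``score`` is the mapper's alignment score (unitless); ``copy_id``
    identifies the genomic copy and ``library_id`` its consensus.
    """

    chrom: str
    start: int
    end: int
    strand: str
    superfamily: str
    score: float
    copy_id: str
    library_id: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise IntervalError(
                f"mapped TE {self.copy_id}: start {self.start} >= end {self.end}"
            )
        if self.score is None or pd.isna(self.score):
            raise IntervalError(f"mapped TE {self.copy_id}: missing score")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class GeneModels:
    """Gene/exon interval sets: the coordinate backbone for overlap work.

    ``genes`` columns: gene_id, chrom, start, end, strand.
    ``exons`` columns: gene_id, chrom, start, end, strand, exon_number.
    Exons are nested within their parent gene span.
    """

    genes: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=GENE_COLUMNS))
    exons: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(columns=EXON_COLUMNS))
    chrom_sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.genes = pd.DataFrame(self.genes, columns=GENE_COLUMNS).reset_index(drop=True)
        self.exons = pd.DataFrame(self.exons, columns=EXON_COLUMNS).reset_index(drop=True)
        if len(self.genes) and (self.genes.start >= self.genes.end).any():
            bad = self.genes[self.genes.start >= self.genes.end].iloc[0]
            raise IntervalError(f"gene {bad.gene_id}: start >= end")

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def gene_lengths(self) -> pd.Series:
        out = (self.genes.end - self.genes.start).astype(int)
        out.index = self.genes.gene_id
        return out

    def exons_of(self, gene_id: str) -> pd.DataFrame:
        return self.exons[self.exons.gene_id == gene_id]


def tecalls_to_frame(calls: list[TECall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (c.chrom, c.start, c.end, c.tool, c.score, c.strand, c.superfamily, c.call_id)
            for c in calls
        ],
        columns=["chrom", "start", "end", "tool", "score", "strand", "superfamily", "call_id"],
    )


def mapped_to_frame(copies: list[MappedTE]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (m.chrom, m.start, m.end, m.copy_id, m.score, m.strand, m.superfamily, m.library_id)
            for m in copies
        ],
        columns=["chrom", "start", "end", "copy_id", "score", "strand", "superfamily", "library_id"],
    )


def with_field(obj, **kwargs):
    """Functional update helper for the frozen records."""
    return replace(obj, **kwargs)
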