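"""Gene-model simulation: non-overlapping multi-exon genes on linear chromosomes."""

from __future__ import annotations

import numpy as np
import pandas as pd

from socialte.models import EXON_COLUMNS, GENE_COLUMNS, GeneModels
from socialte.sim.config import SimConfig, stage_rng

MAX_PLACEMENT_TRIES = 200


class GenomeTooSmallError(RuntimeError):
    """Gene placement failed after bounded retries."""


def _gene_structure(rng: np.random.Generator, cfg: SimConfig) -> tuple[int, list[tuple[int, int]]]:
    """Draw exon/intron lengths; returns (gene_length, exon offsets)."""
    n_exons = int(rng.integers(cfg.exon_count_range[0], cfg.exon_count_range[1] + 1))
    exon_lens = rng.integers(
        cfg.exon_length_range[0], cfg.exon_length_range[1] + 1, size=n_exons
    )
    intron_lens = (
        rng.integers(cfg.intron_length_range[0], cfg.intron_length_range[1] + 1, size=n_exons - 1)
        if n_exons > 1
        else np.array([], dtype=int)
    )
    exons = []
    pos = 0
    for i, el in enumerate(exon_lens):
        exons.append((pos, pos + int(el)))
        pos += int(el)
        if i < len(intron_lens):
            pos += int(intron_lens[i])
    return pos, exons


def simulate_gene_models(config: SimConfig) -> GeneModels:
    """Place non-overlapping genes with >= 1 exon each; exons nested in the
    gene span; strands assigned at random.

    Raises :class:`GenomeTooSmallError` when a gene cannot be placed after
    bounded retries (genome too small for ``n_genes``).
    """
    rng = stage_rng(config.seed, "genes")
    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    sizes = {c: config.chrom_length for c in chroms}
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    genes, exons = [], []
    for gi in range(config.n_genes):
        gene_id = f"G{gi + 1:05d}"
        placed = False
        for _ in range(MAX_PLACEMENT_TRIES):
            chrom = chroms[int(rng.integers(len(chroms)))]
            glen, offsets = _gene_structure(rng, config)
            if glen >= sizes[chrom]:
                continue
            start = int(rng.integers(0, sizes[chrom] - glen))
            end = start + glen
            if any(s < end and start < e for s, e in occupied[chrom]):
                continue
            strand = "+" if rng.random() < 0.5 else "-"
            occupied[chrom].append((start, end))
            genes.append((gene_id, chrom, start, end, strand))
            for k, (es, ee) in enumerate(offsets):
                exons.append((gene_id, chrom, start + es, start + ee, strand, k + 1))
            placed = True
            break
        if not placed:
            raise GenomeTooSmallError(
                f"could not place gene {gi + 1}/{config.n_genes}: genome too small"
            )
    return GeneModels(
        genes=pd.DataFrame(genes, columns=GENE_COLUMNS),
        exons=pd.DataFrame(exons, columns=EXON_COLUMNS),
        chrom_sizes=sizes,
    )
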