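"""Simulate true TE insertions, redundant multi-tool call sets and mapped copies."""

from __future__ import annotations

import numpy as np
import pandas as pd

from socialte.models import GeneModels, MappedTE, TECall
from socialte.sim.config import SimConfig, stage_rng
from socialte.sim.truth import TruthTable


def _place_true_tes(
    models: GeneModels, cfg: SimConfig, rng: np.random.Generator, gene_bias: dict[str, str]
) -> pd.DataFrame:
    """True TE placements: background uniform insertions plus extra
    within-gene insertions for bias classes with a density multiplier > 1
    (extras share the gene's strand so they count as within-gene under the
    same-strand rule)."""
    chroms = sorted(models.chrom_sizes)
    genome_size = sum(models.chrom_sizes.values())
    lam_per_bp = cfg.te_density / 1e6
    rows = []
    counter = 0

    def add(chrom, start, end, strand, sf, gene_id=""):
        nonlocal counter
        counter += 1
        rows.append((f"TE{counter:06d}", chrom, int(start), int(end), strand, sf, gene_id))

    for sf in cfg.superfamilies:
        n_bg = rng.poisson(lam_per_bp * genome_size)
        for _ in range(n_bg):
            chrom = chroms[int(rng.integers(len(chroms)))]
            size = models.chrom_sizes[chrom]
            length = int(rng.integers(cfg.te_length_range[0], cfg.te_length_range[1] + 1))
            length = min(length, size - 1)
            start = int(rng.integers(0, size - length))
            strand = "+" if rng.random() < 0.5 else "-"
            add(chrom, start, start + length, strand, sf)
        mult = cfg.density_mult()
        if mult:
            for g in models.genes.itertuples(index=False):
                m = mult.get(gene_bias.get(g.gene_id, ""), 1.0)
                if m <= 1.0:
                    continue
                glen = g.end - g.start
                n_extra = rng.poisson((m - 1.0) * lam_per_bp * glen)
                for _ in range(n_extra):
                    length = int(
                        rng.integers(cfg.te_length_range[0], cfg.te_length_range[1] + 1)
                    )
                    length = min(length, max(glen - 1, 1))
                    start = g.start + int(rng.integers(0, max(glen - length, 1)))
                    add(g.chrom, start, start + length, g.strand, sf, g.gene_id)
    return pd.DataFrame(
        rows, columns=["te_id", "chrom", "start", "end", "strand", "superfamily", "gene_id"]
    )


def simulate_te_callsets(
    models: GeneModels,
    config: SimConfig,
    gene_bias: dict[str, str] | None = None,
) -> tuple[list[list[TECall]], TruthTable]:
    """Per-tool TE call sets with planted truth.

    Each true TE is reported by one primary tool; every other tool
    re-reports it with probability ``redundancy``, with N(0, jitter_sd)
    boundary jitter. Each tool additionally emits ~``fp_rate`` spurious
    calls per true call. With redundancy=0 and fp_rate=0 the union of call
    sets has exactly one call per true TE.
    """
    if config.n_tools < 1:
        raise ValueError("need >= 1 annotation tool")
    rng = stage_rng(config.seed, "tecalls")
    truth_tes = _place_true_tes(models, config, rng, gene_bias or {})
    tools = [f"tool{i + 1}" for i in range(config.n_tools)]
    callsets: list[list[TECall]] = [[] for _ in tools]

    def jitter(v, lo, hi):
        if config.jitter_sd == 0:
            return int(v)
        return int(np.clip(round(v + rng.normal(0, config.jitter_sd)), lo, hi))

    for te in truth_tes.itertuples(index=False):
        size = models.chrom_sizes[te.chrom]
        primary = int(rng.integers(len(tools)))
        reporters = [primary] + [
            i for i in range(len(tools)) if i != primary and rng.random() < config.redundancy
        ]
        for ti in reporters:
            if ti == primary:
                s, e = te.start, te.end
            else:
                s = jitter(te.start, 0, size - 2)
                e = jitter(te.end, s + 1, size)
            callsets[ti].append(
                TECall(
                    te.chrom, int(s), int(e), te.strand, tools[ti], te.superfamily,
                    score=float(rng.integers(10, 1000)),
                    call_id=f"{te.te_id}:{tools[ti]}",
                )
            )

    if config.fp_rate > 0:
        chroms = sorted(models.chrom_sizes)
        for ti, tool in enumerate(tools):
            n_fp = rng.poisson(config.fp_rate * len(callsets[ti]))
            for k in range(n_fp):
                chrom = chroms[int(rng.integers(len(chroms)))]
                size = models.chrom_sizes[chrom]
                length = int(rng.integers(100, 1000))
                start = int(rng.integers(0, size - length))
                callsets[ti].append(
                    TECall(
                        chrom, start, start + length,
                        "+" if rng.random() < 0.5 else "-",
                        tool, str(rng.choice(list(config.superfamilies))),
                        score=float(rng.integers(10, 1000)),
                        call_id=f"FP:{tool}:{k + 1}",
                    )
                )

    truth = TruthTable(true_tes=truth_tes.assign(in_gene=truth_tes.gene_id != ""))
    return callsets, truth


def simulate_mapped_copies(
    models: GeneModels,
    truth: TruthTable,
    config: SimConfig,
    low_quality_frac: float = 0.05,
) -> list[MappedTE]:
    """Genome-mapped TE copies derived from the true insertions.

    Each true TE becomes one mapped copy with a mapping score drawn
    uniformly in [50, 5000]; a ``low_quality_frac`` of additional junk
    copies carry scores <= 1 and should be removed by filtering.
    """
    rng = stage_rng(config.seed, "mapped")
    copies = []
    for te in truth.true_tes.itertuples(index=False):
        copies.append(
            MappedTE(
                te.chrom, te.start, te.end, te.strand, te.superfamily,
                score=float(rng.integers(50, 5000)),
                copy_id=te.te_id,
                library_id=f"cons_{te.superfamily}",
            )
        )
    chroms = sorted(models.chrom_sizes)
    n_junk = rng.poisson(low_quality_frac * max(len(copies), 1))
    for k in range(n_junk):
        chrom = chroms[int(rng.integers(len(chroms)))]
        size = models.chrom_sizes[chrom]
        length = int(rng.integers(50, 300))
        start = int(rng.integers(0, size - length))
        copies.append(
            MappedTE(
                chrom, start, start + length,
                "+" if rng.random() < 0.5 else "-",
                str(rng.choice(list(config.superfamilies))),
                score=float(rng.uniform(0, 1)),
                copy_id=f"JUNK{k + 1:04d}",
                library_id="cons_junk",
            )
        )
    return copies
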