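"""Generate a complete synthetic study: every pipeline input, with truth.

The emitted layout mirrors the real study's shape: two gregarious and four
eusocial species, each with gene models (GFF3), per-tool TE call sets
(BED6+2), genome-mapped TE copies (BED6+2), copy/consensus alignments
(TSV), a count matrix with a samples table, and gene->GO annotations over
a shared DAG; plus a shared species tree (newick) and per-species trait
table. Opposite caste trends are planted by multiplying within-gene TE
insertion rates for worker-biased genes in eusocial species and for
queen/adult-female-biased genes in gregarious species.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from socialte import io
from socialte.expression import BIAS_QUEEN, BIAS_WORKER
from socialte.sim.config import SimConfig
from socialte.sim.evolve import evolve_te_copies
from socialte.sim.expression import simulate_expression
from socialte.sim.genome import simulate_gene_models
from socialte.sim.ontology import simulate_go
from socialte.sim.tecalls import simulate_mapped_copies, simulate_te_callsets
from socialte.sim.traits import simulate_bm_traits
from socialte.sim.truth import TruthTable

DEFAULT_SPECIES = (
    ("greg1", "gregarious"),
    ("greg2", "gregarious"),
    ("eu1", "eusocial"),
    ("eu2", "eusocial"),
    ("eu3", "eusocial"),
    ("eu4", "eusocial"),
)

SPECIES_TREE_NEWICK = (
    "((greg1:1.0,greg2:1.0):0.6,((eu1:0.5,eu2:0.5):0.4,(eu3:0.5,eu4:0.5):0.4):0.7);"
)

PLANTED_DENSITY_MULT = 2.0


def species_seed(root_seed: int, index: int) -> int:
    """Deterministic per-species child seed (< 2^31)."""
    ss = np.random.SeedSequence(root_seed, spawn_key=(1000 + index,))
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_species(
    config: SimConfig, out_dir: str | Path, species: str, social_level: str
) -> TruthTable:
    """Generate all inputs for one species under ``out_dir/<species>/``."""
    out = Path(out_dir) / species
    out.mkdir(parents=True, exist_ok=True)

    focal = BIAS_WORKER if social_level == "eusocial" else BIAS_QUEEN
    cfg = replace(config, bias_density_mult=((focal, PLANTED_DENSITY_MULT),))

    models = simulate_gene_models(cfg)
    io.write_gff3(models, out / "genes.gff3")

    counts, samples, truth_expr = simulate_expression(models, cfg, species=species)
    io.write_tsv(counts, out / "counts.tsv", index=True)
    io.write_tsv(samples, out / "samples.tsv")

    callsets, truth_te = simulate_te_callsets(models, cfg, gene_bias=truth_expr.true_bias)
    for ti, calls in enumerate(callsets):
        io.write_tecalls_bed(calls, out / f"calls_tool{ti + 1}.bed")
    mapped = simulate_mapped_copies(models, truth_te, cfg)
    io.write_mapped_bed(mapped, out / "mapped.bed")

    pairs = pd.concat(
        [
            evolve_te_copies(
                2000, 50, replace(cfg, seed=(cfg.seed + si) % (2**31)), superfamily=sf
            ).assign(copy_id=lambda d, s=sf: s + "_" + d.copy_id)
            for si, sf in enumerate(cfg.superfamilies)
        ],
        ignore_index=True,
    )
    io.write_aligned_pairs(pairs, out / "aligned_pairs.tsv")

    # plant one enriched term over focal-biased genes carrying extra TEs
    in_gene = set(truth_te.true_tes.loc[truth_te.true_tes.gene_id != "", "gene_id"])
    focal_te_genes = sorted(
        g for g, b in truth_expr.true_bias.items() if b == focal and g in in_gene
    )
    planted_sets = {"te_rich_focal": focal_te_genes} if focal_te_genes else {}
    edges, annotations, truth_go = simulate_go(models, cfg, planted_gene_sets=planted_sets)
    io.write_dag_edges(edges, out / "go_edges.tsv")
    io.write_gene2go(annotations, out / "gene2go.tsv")

    truth = truth_te.merge(truth_expr).merge(truth_go)
    truth.write(out / "truth")
    return truth


def simulate_all(
    config: SimConfig,
    out_dir: str | Path,
    species: tuple[tuple[str, str], ...] = DEFAULT_SPECIES,
    trait_rho: float = 0.8,
    trait_sigma: float = 1.0,
) -> dict[str, TruthTable]:
    """Generate the whole synthetic study under ``out_dir``.

    Per-species inputs are generated with deterministically derived child
    seeds; a shared species tree and a correlated Brownian trait table
    (true correlation ``trait_rho``) are written at the top level, along
    with a species metadata table (species, social_level).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truths: dict[str, TruthTable] = {}
    for i, (sp, lvl) in enumerate(species):
        cfg = replace(config, seed=species_seed(config.seed, i))
        truths[sp] = simulate_species(cfg, out, sp, lvl)

    meta = pd.DataFrame(species, columns=["species", "social_level"])
    io.write_tsv(meta, out / "species.tsv")

    tree = dendropy.Tree.get(data=SPECIES_TREE_NEWICK, schema="newick")
    io.write_tree(tree, out / "species_tree.nwk")
    traits, truth_traits = simulate_bm_traits(
        tree, rho=trait_rho, sigma=trait_sigma, seed=species_seed(config.seed, 999)
    )
    io.write_tsv(traits, out / "traits.tsv", index=True)
    truth_traits.write(out / "truth_shared")
    truths["__shared__"] = truth_traits
    return truths
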