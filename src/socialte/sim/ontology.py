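"""Random GO DAGs with planted enriched terms."""

from __future__ import annotations

import numpy as np

from socialte.models import GeneModels
from socialte.sim.config import SimConfig, stage_rng
from socialte.sim.truth import TruthTable

ROOT = "GO:0000000"


def simulate_go(
    models: GeneModels,
    config: SimConfig,
    planted_gene_sets: dict[str, list[str]] | None = None,
    mean_terms_per_gene: float = 3.0,
    planted_coverage: float = 0.8,
) -> tuple[list[tuple[str, str]], dict[str, set[str]], TruthTable]:
    """A single-root acyclic GO DAG, a gene->term map, and planted truth.

    Terms are layered up to ``go_depth`` below the root; each term gets one
    or two parents in the layer above. Genes receive ~Poisson random term
    annotations (ancestor closure is applied downstream at load). For every
    entry in ``planted_gene_sets`` (set name -> gene ids) one dedicated
    deep term is created and annotated to ``planted_coverage`` of that set,
    planting an enrichment signal. With ``go_depth = 1`` the DAG is a star.
    """
    rng = stage_rng(config.seed, "go")
    planted_gene_sets = planted_gene_sets or {}
    depth = max(config.go_depth, 1)
    n_terms = max(config.go_terms, 1 + len(planted_gene_sets))

    layers: list[list[str]] = [[ROOT]]
    terms = []
    for i in range(n_terms):
        terms.append(f"GO:{i + 1:07d}")
    # spread terms over layers 1..depth, deeper layers no larger than needed
    per_layer = max(1, n_terms // depth)
    edges: list[tuple[str, str]] = []
    idx = 0
    for d in range(1, depth + 1):
        take = per_layer if d < depth else n_terms - idx
        layer = terms[idx : idx + take]
        idx += take
        if not layer:
            break
        for t in layer:
            parents = layers[d - 1]
            n_par = 1 if (len(parents) == 1 or rng.random() < 0.6) else 2
            chosen = rng.choice(len(parents), size=min(n_par, len(parents)), replace=False)
            for c in np.atleast_1d(chosen):
                edges.append((t, parents[int(c)]))
        layers.append(layer)

    gene_ids = list(models.genes.gene_id)
    annotations: dict[str, set[str]] = {}
    non_root = terms[:idx]
    if non_root:
        for g in gene_ids:
            k = rng.poisson(mean_terms_per_gene)
            if k == 0:
                continue
            chosen = rng.choice(len(non_root), size=min(k, len(non_root)), replace=False)
            annotations[g] = {non_root[int(c)] for c in np.atleast_1d(chosen)}

    truth_terms: dict[str, list[str]] = {}
    deep_layer = layers[-1] if len(layers) > 1 else [ROOT]
    for si, (set_name, genes) in enumerate(sorted(planted_gene_sets.items())):
        term = f"GO:9{si + 1:06d}"
        parent = deep_layer[si % len(deep_layer)]
        edges.append((term, parent if parent != ROOT else ROOT))
        for g in genes:
            if rng.random() < planted_coverage:
                annotations.setdefault(g, set()).add(term)
        truth_terms[term] = list(genes)

    return edges, annotations, TruthTable(true_enriched_terms=truth_terms)
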