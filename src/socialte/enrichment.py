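"""Score-based GO-term enrichment with elim pruning and specificity filtering.

Enrichment of a term is tested with a one-sided two-sample
Kolmogorov-Smirnov statistic on gene scores (term genes vs all scored
genes), the rank-based test commonly paired with GO gene-score analyses.
The elim procedure walks the DAG from the most specific terms to the root;
whenever a term is significant below the elim cutoff, its flagged
(significant) genes are removed from all ancestor terms' gene sets before
those are tested, so parents are not called significant merely because they
inherit an enriched child.

Two scoring schemes feed the tests: expression-bias scores
(-log10 adjusted p, with genes biased toward the opposite life stage
neutralised) and TE-insertion scores (insertions per gene kilobase, with
the TE-rich flag as the significance flag).

The specificity cascade removes a term enriched in TE-rich DEGs of one
(social level, life stage) cell when the same term is significant in
(1) plain DEG enrichment at that stage in BOTH social levels, (2) TE-rich
enrichment at that stage in the other social level, or (3) TE-rich
enrichment of any other stage (including no bias) in the same social level.
Surviving terms are therefore specific to their stage and social level.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import networkx as nx
import numpy as np
from scipy import stats

from socialte.expression import BIAS_QUEEN, BIAS_UNTESTED, BIAS_WORKER, DERecord
from socialte.overlap import GeneTEProfile

DEFAULT_ELIM_CUTOFF = 0.01
DEFAULT_ALPHA = 0.05

REMOVAL_NONE = "none"
REMOVAL_CRITERIA = ("criterion1", "criterion2", "criterion3")


@dataclass(frozen=True)
class GeneScore:
    gene_id: str
    score: float
    significant: bool = False


@dataclass(frozen=True)
class EnrichmentResult:
    term_id: str
    statistic: float
    pvalue: float
    n_annotated: int
    survived_specificity: bool = True
    removal_reason: str = REMOVAL_NONE


class GODag:
    """A gene-ontology DAG with ancestor-closed gene annotations.

    Edges point child -> parent. Annotating a gene to a term implicitly
    annotates it to every ancestor of that term (closure applied on
    construction).
    """

    def __init__(
        self,
        edges: list[tuple[str, str]],
        annotations: dict[str, set[str]],
        terms: list[str] | None = None,
    ):
        self.graph = nx.DiGraph()
        if terms:
            self.graph.add_nodes_from(terms)
        self.graph.add_edges_from(edges)
        for t in {t for ts in annotations.values() for t in ts}:
            self.graph.add_node(t)
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("GO edge list contains a cycle")
        self.gene2terms: dict[str, set[str]] = {}
        for gene, ts in annotations.items():
            closed = set()
            for t in ts:
                closed.add(t)
                closed.update(nx.descendants(self.graph, t))  # ancestors (child->parent)
            self.gene2terms[gene] = closed
        self.term2genes: dict[str, set[str]] = {t: set() for t in self.graph.nodes}
        for gene, ts in self.gene2terms.items():
            for t in ts:
                self.term2genes[t].add(gene)

    @property
    def terms(self) -> list[str]:
        return sorted(self.graph.nodes)

    def ancestors(self, term: str) -> set[str]:
        return nx.descendants(self.graph, term)

    def roots(self) -> list[str]:
        return [n for n in self.graph.nodes if self.graph.out_degree(n) == 0]

    def depths(self) -> dict[str, int]:
        """Longest-path-to-root depth for every term, computed in one
        topological sweep."""
        depth: dict[str, int] = {}
        for node in reversed(list(nx.topological_sort(self.graph))):
            parents = list(self.graph.successors(node))
            depth[node] = 0 if not parents else 1 + max(depth[p] for p in parents)
        return depth


# ---------------------------------------------------------------- gene scores


def bias_gene_scores(
    de_records: list[DERecord],
    focal_stage: str,
    opposite_mode: str = "pvalue_one",
) -> list[GeneScore]:
    """Expression-bias gene scores for a focal life stage.

    Scores are -log10(padj). Genes biased toward the opposite stage are
    neutralised: with ``opposite_mode="pvalue_one"`` (default) their
    adjusted p is reset to 1, giving score 0 (maximally non-focal); with
    ``"score_one"`` the literal reading, their score is set to 1. Untested
    genes must already be discarded. The significance flag marks genes
    biased toward the focal stage.
    """
    if focal_stage not in (BIAS_WORKER, BIAS_QUEEN):
        raise ValueError(f"focal_stage must be a bias class, got {focal_stage!r}")
    opposite = BIAS_QUEEN if focal_stage == BIAS_WORKER else BIAS_WORKER
    out = []
    for r in de_records:
        if r.bias_class == BIAS_UNTESTED:
            raise ValueError(f"untested gene {r.gene_id} must be discarded before scoring")
        if r.bias_class == opposite:
            score = 0.0 if opposite_mode == "pvalue_one" else 1.0
        else:
            score = -np.log10(max(r.padj, 1e-300))
        out.append(GeneScore(r.gene_id, float(score), r.bias_class == focal_stage))
    return out


def te_gene_scores(profiles: list[GeneTEProfile]) -> list[GeneScore]:
    """TE-insertion gene scores: insertions per kilobase, flagged TE-rich."""
    return [GeneScore(p.gene_id, p.rate, p.te_rich) for p in profiles]


# ---------------------------------------------------------------- tests


def ks_term_test(
    term_scores: np.ndarray | list[float],
    background_scores: np.ndarray | list[float],
    direction: str = "greater",
) -> tuple[float, float]:
    """One-sided two-sample KS test for term genes having larger scores.

    Returns (statistic, p). With the term set equal to the background the
    test is degenerate and p = 1.
    """
    term = np.asarray(term_scores, dtype=float)
    bg = np.asarray(background_scores, dtype=float)
    if len(term) == 0 or len(bg) == 0:
        raise ValueError("empty term or background score set")
    if len(term) == len(bg) and np.array_equal(np.sort(term), np.sort(bg)):
        return 0.0, 1.0
    # scipy convention: alternative="less" tests CDF(term) < CDF(background),
    # i.e. term scores stochastically larger.
    alt = "less" if direction == "greater" else "greater"
    res = stats.ks_2samp(term, bg, alternative=alt, method="auto")
    return float(res.statistic), float(res.pvalue)


def classical_enrichment(
    dag: GODag, scores: list[GeneScore], min_genes: int = 1
) -> list[EnrichmentResult]:
    """Independent per-term KS tests against the full scored background."""
    score_map = {s.gene_id: s.score for s in scores}
    bg = np.array(list(score_map.values()))
    out = []
    for term in dag.terms:
        genes = [g for g in dag.term2genes.get(term, ()) if g in score_map]
        if len(genes) < min_genes:
            continue
        stat, p = ks_term_test([score_map[g] for g in genes], bg)
        out.append(EnrichmentResult(term, stat, p, len(genes)))
    return out


def elim_enrichment(
    dag: GODag,
    scores: list[GeneScore],
    elim_cutoff: float = DEFAULT_ELIM_CUTOFF,
    min_genes: int = 1,
) -> list[EnrichmentResult]:
    """Elim-pruned enrichment over the DAG.

    Terms are processed from most specific (greatest longest-path depth) to
    the root, ties in lexicographic term order. When a term's p falls below
    ``elim_cutoff``, its annotated significant (flagged) genes are removed
    from all ancestors' gene sets before those are tested. With
    ``elim_cutoff = 0`` this reduces exactly to classical testing.
    """
    score_map = {s.gene_id: s.score for s in scores}
    flagged = {s.gene_id for s in scores if s.significant}
    bg = np.array(list(score_map.values()))
    depths = dag.depths()
    order = sorted(dag.terms, key=lambda t: (-depths[t], t))
    working = {t: {g for g in dag.term2genes.get(t, ()) if g in score_map} for t in dag.terms}
    out = []
    for term in order:
        genes = working[term]
        if len(genes) < min_genes:
            continue
        stat, p = ks_term_test([score_map[g] for g in genes], bg)
        out.append(EnrichmentResult(term, stat, p, len(genes)))
        if p < elim_cutoff:
            eliminate = genes & flagged & set(dag.term2genes.get(term, ()))
            for anc in dag.ancestors(term):
                working[anc] -= eliminate
    return sorted(out, key=lambda r: r.term_id)


# ---------------------------------------------------------------- cascade


def significant_terms(results: list[EnrichmentResult], alpha: float = DEFAULT_ALPHA) -> set[str]:
    return {r.term_id for r in results if r.pvalue < alpha}


def specificity_filter(
    primary: list[EnrichmentResult],
    deg_same_stage_by_social: dict[str, list[EnrichmentResult]],
    terich_same_stage_other_social: list[EnrichmentResult],
    terich_other_stages_same_social: list[list[EnrichmentResult]],
    alpha: float = DEFAULT_ALPHA,
) -> list[EnrichmentResult]:
    """Three-criterion specificity cascade for TE-rich DEG enrichment.

    A primary term is removed iff it is significant (p < alpha) in:

    1. plain DEG enrichment at the same life stage in *both* social levels
       (``deg_same_stage_by_social`` keyed by social level; criterion
       requires significance in every provided level, and at least two
       levels to fire);
    2. TE-rich DEG enrichment at the same stage in the other social level;
    3. TE-rich enrichment of any other life stage (including no-bias) in
       the same social level.

    ``removal_reason`` records the first criterion that fires, in order.
    Empty comparison sets remove nothing.
    """
    crit1: set[str] | None = None
    if len(deg_same_stage_by_social) >= 2:
        sets = [significant_terms(r, alpha) for r in deg_same_stage_by_social.values()]
        crit1 = set.intersection(*sets)
    crit2 = significant_terms(terich_same_stage_other_social, alpha)
    crit3 = set()
    for results in terich_other_stages_same_social:
        crit3 |= significant_terms(results, alpha)

    out = []
    for r in primary:
        reason = REMOVAL_NONE
        if crit1 is not None and r.term_id in crit1:
            reason = "criterion1"
        elif r.term_id in crit2:
            reason = "criterion2"
        elif r.term_id in crit3:
            reason = "criterion3"
        out.append(replace(r, survived_specificity=reason == REMOVAL_NONE, removal_reason=reason))
    return out


def results_to_frame(results: list[EnrichmentResult]):
    import pandas as pd

    return pd.DataFrame(
        [
            (r.term_id, r.statistic, r.pvalue, r.n_annotated, r.survived_specificity, r.removal_reason)
            for r in results
        ],
        columns=["term_id", "statistic", "pvalue", "n_annotated", "survived", "removal_reason"],
    )
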