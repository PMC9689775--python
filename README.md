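# socialte

Transposable elements (TEs) are mutagens of genome regulation: where they
insert relative to genes can rewire expression. In Blattodea — gregarious
cockroaches and their eusocial relatives, the termites — a natural question
is whether TE insertions track the genes whose expression differs between
castes or life stages (worker/nymph versus queen/adult female), and whether
that association differs between social levels. `socialte` implements the
full analysis chain for that question as a tested, reusable Python package:

1. **TE call consolidation** — multi-tool de novo TE annotations are merged
   by removing calls longer than 10 kb and resolving same-strand overlaps
   above 20% of the shorter call; genome-mapped copies are filtered by
   mapping score (> 1) keeping the best-scoring copy per overlap chain.
2. **Divergence landscapes** — each copy's distance to its consensus is the
   Kimura 2-parameter estimate K = −½ ln((1−2p−q)·√(1−2q)) with transitions
   at consensus CpG dinucleotides down-weighted (CpG hypermutability);
   copy lengths are binned by divergence into percent-of-genome landscapes
   per superfamily (Tc-Mariner, hAT, Gypsy, LINE).
3. **Expression-bias classification** — genes are called worker/nymph- or
   queen/adult-female-biased when the BH-adjusted p of their between-stage
   contrast is below 0.05 (sign of the log2 fold change gives the
   direction); summaries report class percentages and ≥2-fold subsets.
4. **TE–gene overlap profiling** — closest same-strand TE per gene,
   within-gene insertion counts split exon/intron, insertions per gene
   kilobase, TE-rich flags (rate strictly above the third quartile), and
   the long-format contingency tables for factorial count models.
5. **GO enrichment with elim pruning** — a one-sided two-sample KS test on
   gene scores per GO term, walking the DAG from specific terms to the
   root and eliminating significant descendants' genes from ancestors;
   then a three-criterion specificity cascade that keeps only terms unique
   to one (social level, life stage) cell of TE-rich biased genes.
6. **Comparative statistics** — phylogenetically independent contrasts
   (Felsenstein pruning) with the contrast correlation test
   t = r·√(df/(1−r²)), df = k−2; and Poisson log-linear models with
   likelihood-ratio tests for the contingency tables, plus model-ready
   exports for external phylogenetic mixed models.
7. **Synthetic data with planted truth** — every input above can be
   simulated (redundant multi-tool call sets, K2P-evolved copies with CpG
   acceleration, negative-binomial counts with planted biased genes, GO
   DAGs with planted enriched terms, correlated Brownian traits on a
   tree), so each stage is testable against known ground truth.

## Worked example

Generate the six-species synthetic study and run the analysis chain:

```bash
python analysis/01_simulate_study.py --seed 1
python analysis/02_consolidate_te_calls.py
python analysis/03_divergence_landscapes.py
python analysis/04_expression_bias.py
python analysis/05_te_gene_overlap.py
python analysis/06_go_enrichment.py
python analysis/07_comparative_stats.py
```

Selected output at seed 1:

```
greg1: 844 calls -> 315 library entries; 343 mapped copies -> 243 after filtering
greg1: worker/nymph-biased 4.3%, queen/female-biased 5% of 300 tested genes; planted-bias recovery 28/30
greg1: 82/300 genes carry a same-strand TE; 75 TE-rich (rate > Q3)
eusocial/worker_nymph: 44 terms tested, 1 significant survive the cascade; planted term(s) recovered: GO:9000001
PIC contrast correlation: r = 0.840, t = 2.680, df = 3, p = 0.075 (true rho = 0.8)
gene_te: three-way interaction te_overlap:social_level:bias: G = 5.69, df = 2, p = 0.05819
```

Reading this: four redundant annotation tools collapsed to one call per
true element; the bias caller recovered 28 of 30 planted biased genes at
a ~5% false-positive-free rate; exactly one GO term — the one planted over
TE-rich worker-biased genes of the eusocial set — survived the specificity
cascade in the eusocial/worker cell and nowhere else; and the contrast
correlation on the six-tip tree (five contrasts, df = 3) estimated r = 0.84
against a true Brownian correlation of 0.8.

The same operations are exposed as a CLI (`socialte te-merge`, `te-filter`,
`divergence`, `debias`, `overlap`, `pic`, `simulate`) for use on real
gene models (GFF3), TE calls (BED6+2), count tables and trees; externally
computed differential-expression tables are accepted as-is.

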