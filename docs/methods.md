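# Methods

This note documents the models, conventions and design choices behind
`socialte`, in the spirit of a statistical software methods appendix. It
states no empirical claim that the test suite or `scripts/acceptance.py`
does not itself compute.

## TE call consolidation (`socialte.telibrary`)

`dedup_calls` merges the call sets of several de novo TE annotation tools.
Calls longer than 10 kb (default `max_len`) are removed first, so over-long
artifacts never displace valid calls during conflict resolution. Two calls
conflict when they share chromosome and strand and their overlap exceeds
20% (default `max_overlap_frac`) **of the shorter call** — the published
rule states only "more than 20% overlap"; the shorter-element denominator
is symmetric and conservative toward removing nested duplicates, and is
configurable. Conflicts are resolved by a greedy sweep in priority order:
longer call first, ties by earlier start, then lexicographic tool id —
deterministic, order-invariant, and equivalent to the exhaustive
pairwise-check oracle used in the tests. Opposite-strand overlaps are not
conflicts: strand is part of the element's identity (the source procedure
is silent here; the choice is explicit and configurable).

`filter_mapped` removes genome-mapped copies with mapping score ≤ 1 and
then keeps, within each chain of location-overlapping copies (same
chromosome, any strand — mapped copies compete for genomic space), only the
highest-scoring member; score ties keep the earlier start. Both filters are
idempotent.

## Divergence estimation (`socialte.divergence`)

The copy-to-consensus distance is the Kimura 2-parameter estimator
K = −½ ln((1−2p−q)·√(1−2q)), with p the transition and q the transversion
proportion over ungapped, unambiguous alignment columns. Arguments outside
the logarithm's domain raise a saturation error rather than returning NaN.

The CpG correction mirrors the widely used RepeatMasker divergence-summary
convention: a transition observed at a consensus CpG position (the C of a
CpG dinucleotide or the G it precedes, read across gap columns) contributes
weight 1/10 to the transition count instead of 1. The weight is
configurable because the exact scheme behind "accounting for the GC level"
in the source procedure is not documented; double transitions at one CpG
dinucleotide count as two (down-weighted) events.

Landscapes assign each copy's ungapped length to the 1%-wide bin containing
100·K, over a default range of 0–55% divergence, and report masses as
percent of genome size per superfamily. Per-superfamily masses are additive
to the all-TE landscape by construction.

## Expression-bias classification (`socialte.expression`)

Fold changes are oriented queen/adult-female over worker/nymph (the
direction convention is fixed and documented because the source analysis
does not state one). A gene is biased when its BH-adjusted p is strictly
below alpha = 0.05; padj exactly at the threshold is unbiased; genes whose
adjusted p was never computed are "untested" and excluded from all
downstream analyses. "≥2-fold" subsets use |log2FC| ≥ 1 on the DE table's
fold-change field. Reported percentages use the number of DE-tested genes
as denominator and render at two significant figures, which reproduces all
twelve published biased-gene percentages from their count pairs.

`de_lite` is a deliberately lightweight stand-in for a negative-binomial
differential-expression engine, intended for synthetic data only:
median-of-ratios size factors, Welch's t on log2(normalised count + 1), BH
adjustment over tested genes. On NB counts at 6 vs 6 libraries it is
slightly conservative under the null (raw p mildly sub-uniform), which the
null-calibration test asserts as an upper bound on the false-positive rate
rather than exact uniformity. Real analyses should inject an external DE
table (gene_id, log2fc, pvalue, padj), which passes through untouched.

## TE–gene overlap (`socialte.overlap`)

A TE is "within" a gene when it overlaps the gene span by ≥ 1 bp **on the
same strand**, mirroring the closest-TE rule (`bedtools closest`-style with
strand matching); the same-strand requirement is configurable because the
source procedure does not state strand handling for within-gene counts. A
TE overlapping any exon of its host gene counts as exonic, else intronic —
boundary-straddling insertions are exonic, giving one deterministic
category per insertion. A TE overlapping two genes counts in both profiles
(per-gene multiplicity); the TE-level contingency tables use the same
assignment.

The insertion rate is TEs per gene kilobase; a gene is TE-rich when its
rate strictly exceeds the third quartile (numpy linear-interpolation
quantile; the convention is configurable, none is documented upstream) of
the evaluated gene set. The evaluation set defaults to the subset under
test in each enrichment run and can be widened to the full gene set. With
strict inequality at most ~25% of a subset is flagged, and uniform-rate
subsets flag nothing.

Closest-TE ties break on smaller distance, then lower TE start, then
lexicographic copy id. Gene-length summaries report the mean and a
t-based 95% confidence interval per group, flagging single-gene groups as
degenerate.

## GO enrichment and the specificity cascade (`socialte.enrichment`)

Annotations are closed over the DAG (a gene annotated to a term is
annotated to all ancestors). Enrichment per term is a one-sided two-sample
Kolmogorov–Smirnov test of the term's gene scores against all scored genes,
asking whether term genes score higher; a term covering the entire
background is degenerate with p = 1. Two scoring schemes are used:
−log10(padj) for expression bias, and insertions per kilobase (flag:
TE-rich) for TE content.

Genes biased toward the **opposite** life stage are neutralised before
bias-score enrichment. The upstream instruction "the gene score was set
to 1" is ambiguous between score = 1 and p = 1; the default here resets the
adjusted p to 1 (score 0 — maximally non-focal), because a literal score of
1 would rank opposite-biased genes above genuinely unremarkable genes
(p > 0.1). The literal reading is available via `opposite_mode="score_one"`.

The elim procedure processes terms from greatest longest-path-to-root depth
to the root (ties lexicographic). When a term's p falls below the elim
cutoff (0.01, the method's customary default), its flagged significant
genes are removed from all ancestors' working gene sets before those are
tested. With cutoff 0 or an edge-free DAG, elim reduces exactly to
classical per-term testing, which the tests assert. No multiple-testing
correction is applied across GO terms, matching common practice for
dependency-adjusted DAG methods; a BH layer can be applied by callers.

The specificity cascade removes a term enriched in TE-rich biased genes of
cell (social level S, stage L) when the term is also significant in:
(1) expression-bias enrichment at stage L in *both* social levels,
(2) TE-rich enrichment at stage L in the other social level, or
(3) TE-rich enrichment of any other stage (including no-bias) at social
level S. The first criterion to fire is recorded; empty comparison sets
remove nothing, and criterion 1 requires at least two social levels to be
present.

## Comparative statistics (`socialte.phylo`)

Independent contrasts follow Felsenstein's pruning: at each bifurcation the
contrast is (x_i − x_j)/√(v_i + v_j), the nodal estimate is the 1/v-weighted
mean, and the node's branch is extended by v_i·v_j/(v_i + v_j). Polytomies
and non-positive branch lengths are rejected rather than resolved silently.
The implementation is cross-checked in the tests against an independent
recursive oracle and against `ape::pic` in R.

The contrast correlation test uses the ordinary Pearson correlation of the
two contrast vectors with t = r·√(df/(1−r²)) and df = k − 2 for k
contrasts. This convention reproduces the degrees of freedom printed for
six-species (df = 3) and four-species (df = 1) analyses; the textbook
through-origin variant (no centring, df = k − 1) is available behind
`through_origin=True`. |r| = 1 is flagged degenerate with p reported as 0.

The factorial count analyses are frequentist Poisson log-linear models (GLM
with log link, IRLS to deviance change < 1e-8, max 100 iterations, backed
by statsmodels) with deviance-difference likelihood-ratio tests between
nested models. This is explicitly a non-phylogenetic stand-in: the Bayesian
phylogenetic mixed models with Brownian covariance are out of scope, and
`export_model_tables` writes the long-format tables (with the 0/1/2 bias
coding: 0 = no bias, 1 = worker/nymph, 2 = queen/female adult) plus the
species tree so they can be fitted externally.

## Synthetic data (`socialte.sim`)

The generator emulates the shape of the real study at desk scale: six
species (two gregarious, four eusocial), each with, by default, 300
non-overlapping multi-exon genes on 2 Mb of genome, four annotation tools,
40 true insertions per Mb per superfamily for the four main superfamilies,
50% redundant re-reporting with 10 bp boundary jitter, 5% spurious calls,
copies diverged to K = 0.10 with transition:transversion ratio 2 and
10-fold CpG transition acceleration, six libraries per caste with NB
dispersion 0.1, 10% of genes planted at |log2FC| = 2 (half per direction),
a 50-term GO DAG of depth 4, and bivariate Brownian traits with true
correlation 0.8 on a fixed six-tip tree. These sizes keep the full study
under a few seconds while leaving planted signals detectable; they are the
package's default study conditions, not tuned per analysis.

Opposite caste trends are planted by doubling the within-gene insertion
rate for worker-biased genes in eusocial species and for queen/adult-female-
biased genes in gregarious species; the extra insertions share the host
gene's strand so they register under the same-strand overlap rule. One
enriched GO term per species is planted over the focal biased genes that
carry extra insertions.

Randomness uses a single root seed with per-stage child streams spawned
through fixed `SeedSequence` spawn keys, so identical configurations yield
byte-identical output files and any stage can be re-run in isolation.

K2P evolution is sitewise: branch length is calibrated so the sequence-wide
expected substitutions per site equal `k_true` given the realised CpG
fraction; per-site transition/transversion outcomes are drawn from the
exact K2P transition probabilities (CpG sites with transition rate
multiplied by `cpg_mult`). Alignments are gap-free; indel processes, TE
nesting/fragmentation, realistic base composition and tool-specific error
modes are deliberately not modelled — recovery results on these data
therefore speak to estimator correctness, not to robustness against
alignment error or annotation artefacts.

Known desk-scale limitations: with 300 genes and ~15 planted genes per
bias class, single cells of the enrichment design can be underpowered (a
planted term may fall short of significance in one species' small biased
subset, as the seed-1 worked example shows for the gregarious queen cell);
the acceptance checks that quantify planted-term recovery therefore use a
denser configuration (80 insertions/Mb, 20% planted genes). The GO DAG and
gene id space are simulated per species, so the enrichment drivers use one
representative species per social level rather than pooling annotations
across species as a real study would over a shared ontology.
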