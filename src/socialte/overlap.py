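"""Relate filtered TE copies to gene models.

Per-gene profiling: the closest TE on the same DNA strand (distance 0 when
overlapping), within-gene insertion counts split into exonic and intronic,
TE insertions per gene kilobase, and a TE-rich flag for genes whose rate
exceeds the third quartile of the evaluated gene set. Aggregations: the
long-format contingency tables contrasting TE overlap, social level, bias
class and TE superfamily across species, and per-group gene-length
summaries with 95% confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from socialte.expression import (
    BIAS_NONE,
    BIAS_QUEEN,
    BIAS_UNTESTED,
    BIAS_WORKER,
    DERecord,
)
from socialte.models import GeneModels, MappedTE


@dataclass(frozen=True)
class GeneTEProfile:
    """Per-gene TE insertion profile."""

    gene_id: str
    gene_length: int
    bias_class: str
    n_te: int
    n_exonic: int
    n_intronic: int
    rate: float  # insertions per gene kilobase
    te_rich: bool = False
    closest_te_id: str | None = None
    closest_distance: int | None = None


# ---------------------------------------------------------------- closest TE


def _interval_distance(g_start: int, g_end: int, t_start: int, t_end: int) -> int:
    if t_end <= g_start:
        return g_start - t_end  # gap bp between half-open intervals
    if t_start >= g_end:
        return t_start - g_end
    return 0


def closest_te(
    genes: GeneModels,
    tes: list[MappedTE],
    same_strand: bool = True,
) -> pd.DataFrame:
    """Closest TE per gene, optionally restricted to the gene's strand.

    Distance is 0 iff the TE overlaps the gene span; otherwise the gap in
    bp. Ties go to the smaller distance, then the lower TE start, then the
    lexicographically smaller copy id. Genes with no candidate TE get a
    null record (closest_te_id = None, distance = NaN).
    """
    buckets: dict[tuple[str, str] | str, list[MappedTE]] = {}
    for t in tes:
        key = (t.chrom, t.strand) if same_strand else t.chrom
        buckets.setdefault(key, []).append(t)
    for v in buckets.values():
        v.sort(key=lambda t: (t.start, t.end, t.copy_id))

    rows = []
    for g in genes.genes.itertuples(index=False):
        key = (g.chrom, g.strand) if same_strand else g.chrom
        cands = buckets.get(key, [])
        best = None
        for t in cands:
            d = _interval_distance(g.start, g.end, t.start, t.end)
            item = (d, t.start, t.copy_id)
            if best is None or item < best:
                best = item
        if best is None:
            rows.append((g.gene_id, None, np.nan))
        else:
            rows.append((g.gene_id, best[2], best[0]))
    return pd.DataFrame(rows, columns=["gene_id", "closest_te_id", "closest_distance"])


def closest_te_bruteforce(
    genes: GeneModels, tes: list[MappedTE], same_strand: bool = True
) -> pd.DataFrame:
    """All-pairs scan oracle for :func:`closest_te` (small inputs only)."""
    rows = []
    for g in genes.genes.itertuples(index=False):
        best = None
        for t in tes:
            if t.chrom != g.chrom:
                continue
            if same_strand and t.strand != g.strand:
                continue
            d = _interval_distance(g.start, g.end, t.start, t.end)
            item = (d, t.start, t.copy_id)
            if best is None or item < best:
                best = item
        if best is None:
            rows.append((g.gene_id, None, np.nan))
        else:
            rows.append((g.gene_id, best[2], best[0]))
    return pd.DataFrame(rows, columns=["gene_id", "closest_te_id", "closest_distance"])


# ---------------------------------------------------------------- profiles


def profile_genes(
    genes: GeneModels,
    tes: list[MappedTE],
    de_records: list[DERecord] | None = None,
    same_strand: bool = True,
    with_closest: bool = True,
) -> list[GeneTEProfile]:
    """Per-gene TE insertion profiles.

    A TE is "within" a gene if it overlaps the gene span by >= 1 bp (same
    strand by default, mirroring the closest-TE rule); it is exonic if it
    overlaps any exon of that gene by >= 1 bp, else intronic — a TE
    straddling an exon-intron boundary counts as exonic. A TE overlapping
    two genes is counted in both genes' profiles.
    """
    bias = {}
    if de_records is not None:
        bias = {r.gene_id: r.bias_class for r in de_records}

    te_trees: dict[tuple[str, str] | str, IntervalTree] = {}
    for t in tes:
        key = (t.chrom, t.strand) if same_strand else t.chrom
        te_trees.setdefault(key, IntervalTree()).addi(t.start, t.end, t)

    exon_trees: dict[str, IntervalTree] = {}
    for e in genes.exons.itertuples(index=False):
        exon_trees.setdefault(e.gene_id, IntervalTree()).addi(e.start, e.end)

    closest = None
    if with_closest:
        closest = closest_te(genes, tes, same_strand=same_strand).set_index("gene_id")

    profiles = []
    for g in genes.genes.itertuples(index=False):
        key = (g.chrom, g.strand) if same_strand else g.chrom
        hits = sorted(
            (iv.data for iv in te_trees.get(key, IntervalTree()).overlap(g.start, g.end)),
            key=lambda t: (t.start, t.end, t.copy_id),
        )
        etree = exon_trees.get(g.gene_id, IntervalTree())
        n_ex = sum(1 for t in hits if etree.overlaps(t.start, t.end))
        length = g.end - g.start
        c_id, c_d = None, None
        if closest is not None:
            row = closest.loc[g.gene_id]
            c_id = row.closest_te_id
            c_d = None if pd.isna(row.closest_distance) else int(row.closest_distance)
        profiles.append(
            GeneTEProfile(
                gene_id=g.gene_id,
                gene_length=length,
                bias_class=bias.get(g.gene_id, BIAS_UNTESTED),
                n_te=len(hits),
                n_exonic=n_ex,
                n_intronic=len(hits) - n_ex,
                rate=len(hits) / (length / 1000.0),
                closest_te_id=c_id,
                closest_distance=c_d,
            )
        )
    return profiles


def profiles_to_frame(profiles: list[GeneTEProfile]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                p.gene_id,
                p.gene_length,
                p.bias_class,
                p.n_te,
                p.n_exonic,
                p.n_intronic,
                p.rate,
                p.te_rich,
                p.closest_te_id,
                p.closest_distance,
            )
            for p in profiles
        ],
        columns=[
            "gene_id",
            "gene_length",
            "bias_class",
            "n_te",
            "n_exonic",
            "n_intronic",
            "rate",
            "te_rich",
            "closest_te_id",
            "closest_distance",
        ],
    )


def flag_te_rich(
    profiles: list[GeneTEProfile],
    subset_filter=None,
) -> list[GeneTEProfile]:
    """Set te_rich on genes whose insertion rate strictly exceeds Q3.

    Q3 (linear interpolation between order statistics) is computed over the
    rates of the genes selected by ``subset_filter`` (all genes when None);
    only genes in that subset can be flagged. With all rates equal, or a
    single gene, nothing is flagged (strict >).
    """
    in_subset = [subset_filter(p) if subset_filter else True for p in profiles]
    rates = [p.rate for p, keep in zip(profiles, in_subset) if keep]
    if not rates:
        raise ValueError("empty evaluation subset for TE-rich flagging")
    q3 = float(np.quantile(rates, 0.75))  # linear interpolation
    return [
        replace(p, te_rich=bool(keep and p.rate > q3))
        for p, keep in zip(profiles, in_subset)
    ]


# ---------------------------------------------------------------- tables

SOCIAL_LEVELS = ("gregarious", "eusocial")
MAIN_SUPERFAMILIES = ("Tc-Mariner", "hAT", "Gypsy", "LINE")
BIAS_LEVELS = (BIAS_NONE, BIAS_WORKER, BIAS_QUEEN)


def assign_tes_to_genes(
    genes: GeneModels,
    tes: list[MappedTE],
    de_records: list[DERecord] | None = None,
    same_strand: bool = True,
) -> pd.DataFrame:
    """One row per (TE copy, host gene) pair, per the within-gene rule.

    A TE overlapping two genes yields two rows (per-gene multiplicity).
    Columns: copy_id, superfamily, gene_id, bias_class.
    """
    bias = {r.gene_id: r.bias_class for r in de_records} if de_records else {}
    gene_trees: dict[tuple[str, str] | str, IntervalTree] = {}
    for g in genes.genes.itertuples(index=False):
        key = (g.chrom, g.strand) if same_strand else g.chrom
        gene_trees.setdefault(key, IntervalTree()).addi(g.start, g.end, g.gene_id)
    rows = []
    for t in tes:
        key = (t.chrom, t.strand) if same_strand else t.chrom
        for iv in gene_trees.get(key, IntervalTree()).overlap(t.start, t.end):
            rows.append((t.copy_id, t.superfamily, iv.data, bias.get(iv.data, BIAS_UNTESTED)))
    return pd.DataFrame(rows, columns=["copy_id", "superfamily", "gene_id", "bias_class"])


def build_tables(
    profiles_by_species: dict[str, list[GeneTEProfile]],
    species_meta: pd.DataFrame,
    tes_by_species: dict[str, list[MappedTE]] | None = None,
    assignments_by_species: dict[str, pd.DataFrame] | None = None,
) -> dict[str, pd.DataFrame]:
    """Long-format contingency tables for the factorial comparisons.

    ``species_meta`` needs columns species, social_level. Untested genes
    (no adjusted p) are excluded throughout. Four designs are emitted:

    * ``gene_te`` — gene counts by TE overlap (yes/no) x social level x bias;
    * ``exon_intron`` — gene counts with >= 1 insertion by compartment
      (exon/intron; a gene with any exonic insertion counts as exon) x
      social level x bias;
    * ``superfamily_gene`` — TE counts by within-gene (yes/no) x social
      level x superfamily (main four only);
    * ``superfamily_bias`` — within-DEG TE counts by social level x
      superfamily x bias of the host gene (multiplicity per host gene).

    The last two need ``tes_by_species`` plus the matching
    ``assignments_by_species`` from :func:`assign_tes_to_genes`.
    """
    social = species_meta.set_index("species")["social_level"]
    gene_rows, ei_rows, sfg_rows, sfb_rows = [], [], [], []

    for sp, profiles in profiles_by_species.items():
        lvl = social[sp]
        tested = [p for p in profiles if p.bias_class != BIAS_UNTESTED]
        for b in BIAS_LEVELS:
            sub = [p for p in tested if p.bias_class == b]
            n_yes = sum(1 for p in sub if p.n_te > 0)
            gene_rows.append((sp, lvl, b, "yes", n_yes))
            gene_rows.append((sp, lvl, b, "no", len(sub) - n_yes))
            ei_rows.append((sp, lvl, b, "exon", sum(1 for p in sub if p.n_exonic > 0)))
            ei_rows.append(
                (sp, lvl, b, "intron", sum(1 for p in sub if p.n_exonic == 0 and p.n_te > 0))
            )

    if tes_by_species is not None and assignments_by_species is not None:
        for sp, tes in tes_by_species.items():
            lvl = social[sp]
            asn = assignments_by_species[sp]
            in_gene_ids = set(asn["copy_id"])
            for sf in MAIN_SUPERFAMILIES:
                sub_ids = [t.copy_id for t in tes if t.superfamily == sf]
                n_in = sum(1 for cid in sub_ids if cid in in_gene_ids)
                sfg_rows.append((sp, lvl, sf, "yes", n_in))
                sfg_rows.append((sp, lvl, sf, "no", len(sub_ids) - n_in))
                sf_asn = asn[asn.superfamily == sf]
                for b in BIAS_LEVELS:
                    sfb_rows.append((sp, lvl, sf, b, int((sf_asn.bias_class == b).sum())))

    return {
        "gene_te": pd.DataFrame(
            gene_rows, columns=["species", "social_level", "bias", "te_overlap", "count"]
        ),
        "exon_intron": pd.DataFrame(
            ei_rows, columns=["species", "social_level", "bias", "compartment", "count"]
        ),
        "superfamily_gene": pd.DataFrame(
            sfg_rows, columns=["species", "social_level", "superfamily", "in_gene", "count"]
        ),
        "superfamily_bias": pd.DataFrame(
            sfb_rows, columns=["species", "social_level", "superfamily", "bias", "count"]
        ),
    }


def summarize_gene_length(
    profiles: list[GeneTEProfile],
    group_key=lambda p: p.bias_class,
) -> pd.DataFrame:
    """Per-group mean gene length with a t-based 95% confidence interval.

    Groups with a single gene get a degenerate (NaN) interval and are
    flagged. Lengths are reported in bp.
    """
    by_group: dict[str, list[int]] = {}
    for p in profiles:
        by_group.setdefault(group_key(p), []).append(p.gene_length)
    rows = []
    for grp in sorted(by_group):
        x = np.asarray(by_group[grp], dtype=float)
        mean = x.mean()
        if len(x) < 2 or x.std(ddof=1) == 0:
            rows.append((grp, len(x), mean, np.nan, np.nan, True))
            continue
        sem = stats.sem(x)
        lo, hi = stats.t.interval(0.95, df=len(x) - 1, loc=mean, scale=sem)
        rows.append((grp, len(x), mean, lo, hi, False))
    return pd.DataFrame(
        rows, columns=["group", "n", "mean_length", "ci_low", "ci_high", "degenerate"]
    )
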