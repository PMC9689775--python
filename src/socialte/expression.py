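"""Caste/stage-biased expression classification and summary statistics.

Genes are contrasted between the reproductive stage (queen in termites,
adult female in cockroaches) and the non-reproductive stage (worker, nymph).
log2 fold changes are oriented queen/adult-female over worker/nymph, so
positive values mean queen/female-biased. A gene is significantly biased
when its BH-adjusted p-value is below alpha (0.05); genes whose adjusted p
could not be computed are "untested" and excluded downstream.

:func:`de_lite` is a deliberately lightweight differential-expression
stand-in for synthetic data (median-of-ratios normalisation, Welch t on
log2(normalised count + 1), BH adjustment). Pipelines on real data should
inject an external DE table (gene_id, log2fc, pvalue, padj) instead, which
passes through untouched apart from bias classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

BIAS_NONE = "none"
BIAS_WORKER = "worker_nymph"
BIAS_QUEEN = "queen_female"
BIAS_UNTESTED = "untested"
BIAS_CLASSES = (BIAS_NONE, BIAS_WORKER, BIAS_QUEEN, BIAS_UNTESTED)


@dataclass(frozen=True)
class DERecord:
    """Per-gene expression contrast (queen/adult-female over worker/nymph)."""

    gene_id: str
    log2fc: float
    pvalue: float
    padj: float  # NaN when not computed
    bias_class: str = BIAS_UNTESTED


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios library size factors.

    The geometric-mean reference uses genes expressed in every library; at
    least one such gene is required.
    """
    mat = counts.to_numpy(dtype=float)
    if mat.shape[1] == 1:
        return pd.Series([1.0], index=counts.columns)
    expressed = (mat > 0).all(axis=1)
    if not expressed.any():
        raise ValueError("no gene expressed in all libraries; cannot normalise")
    ref = mat[expressed]
    log_geo_mean = np.log(ref).mean(axis=1)
    factors = np.exp(np.median(np.log(ref) - log_geo_mean[:, None], axis=0))
    return pd.Series(factors, index=counts.columns)


def bh_adjust(pvalues: np.ndarray | pd.Series | list[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (NaN-preserving)."""
    p = np.asarray(pvalues, dtype=float)
    out = np.full_like(p, np.nan)
    ok = ~np.isnan(p)
    if ok.any():
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    return out


def de_lite(counts: pd.DataFrame, samples: pd.DataFrame) -> list[DERecord]:
    """Lightweight two-group differential-expression stand-in.

    ``samples`` maps each library to a group; exactly the groups
    "queen_female" and "worker_nymph" are contrasted, each needing >= 2
    libraries. Genes with all-zero counts are untested (padj = NaN). The
    per-gene test is Welch's t on log2(count / size factor + 1); p-values
    are BH-adjusted over the tested genes.
    """
    groups = samples.set_index("library")["group"]
    q_libs = [c for c in counts.columns if groups.get(c) == BIAS_QUEEN]
    w_libs = [c for c in counts.columns if groups.get(c) == BIAS_WORKER]
    if len(q_libs) < 2 or len(w_libs) < 2:
        raise ValueError(
            f"need >=2 libraries per group, got {len(q_libs)} queen_female / "
            f"{len(w_libs)} worker_nymph"
        )
    sf = size_factors(counts[q_libs + w_libs])
    norm = counts[q_libs + w_libs].to_numpy(dtype=float) / sf.to_numpy()
    logn = np.log2(norm + 1.0)
    q_mat = logn[:, : len(q_libs)]
    w_mat = logn[:, len(q_libs) :]
    tested = counts[q_libs + w_libs].to_numpy().sum(axis=1) > 0
    lfc = q_mat.mean(axis=1) - w_mat.mean(axis=1)
    t, p = stats.ttest_ind(q_mat, w_mat, axis=1, equal_var=False)
    p = np.where(np.isnan(p), 1.0, p)  # zero-variance ties: no evidence
    p = np.where(tested, p, np.nan)
    padj = bh_adjust(p)
    return [
        DERecord(gene_id=g, log2fc=float(l), pvalue=float(pv), padj=float(pa))
        for g, l, pv, pa in zip(counts.index, lfc, p, padj)
    ]


def classify_bias(records: list[DERecord], alpha: float = 0.05) -> list[DERecord]:
    """Assign each gene a bias class from its adjusted p and fold change.

    padj < alpha and log2fc > 0 -> queen_female; padj < alpha and
    log2fc < 0 -> worker_nymph; padj >= alpha -> none ("below 0.05" is
    strict, so padj exactly at alpha is unbiased); padj missing -> untested.
    """
    out = []
    for r in records:
        if r.padj is None or np.isnan(r.padj):
            cls = BIAS_UNTESTED
        elif r.padj < alpha and r.log2fc > 0:
            cls = BIAS_QUEEN
        elif r.padj < alpha and r.log2fc < 0:
            cls = BIAS_WORKER
        else:
            cls = BIAS_NONE
        out.append(DERecord(r.gene_id, r.log2fc, r.pvalue, r.padj, cls))
    return out


def records_to_frame(records: list[DERecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [(r.gene_id, r.log2fc, r.pvalue, r.padj, r.bias_class) for r in records],
        columns=["gene_id", "log2fc", "pvalue", "padj", "bias_class"],
    )


def frame_to_records(df: pd.DataFrame) -> list[DERecord]:
    """External DE tables pass through here untouched (no re-testing)."""
    return [
        DERecord(
            gene_id=str(r.gene_id),
            log2fc=float(r.log2fc),
            pvalue=float(r.pvalue),
            padj=float(r.padj) if pd.notna(r.padj) else float("nan"),
            bias_class=getattr(r, "bias_class", BIAS_UNTESTED),
        )
        for r in df.itertuples(index=False)
    ]


def format_percent(x: float, sig: int = 2) -> str:
    """Render a percentage at two significant figures, the reporting
    precision used for bias proportions (e.g. 8.2, 21, 0.33)."""
    if x == 0:
        return "0"
    from decimal import Decimal

    d = Decimal(f"{x:.{sig}g}")
    s = format(d.normalize(), "f")
    return s


def summarize_bias(records: list[DERecord], fc_threshold: float = 2.0) -> pd.DataFrame:
    """Counts and percentages per bias class among tested DEGs.

    The denominator is the number of DE-tested genes (padj computed); the
    ">= fc_threshold-fold" subsets additionally require
    |log2fc| >= log2(fc_threshold). Percentages are 100*count/denominator,
    with a two-significant-figure rendering alongside the raw value.
    """
    tested = [r for r in records if r.bias_class != BIAS_UNTESTED]
    total = len(tested)
    lfc_cut = np.log2(fc_threshold)
    rows = []

    def add(name: str, members: list[DERecord]) -> None:
        n = len(members)
        pct = 100.0 * n / total if total else 0.0
        rows.append((name, n, total, pct, format_percent(pct)))

    for cls in (BIAS_NONE, BIAS_WORKER, BIAS_QUEEN):
        members = [r for r in tested if r.bias_class == cls]
        add(cls, members)
        if cls in (BIAS_WORKER, BIAS_QUEEN):
            add(
                f"{cls}_fc{fc_threshold:g}",
                [r for r in members if abs(r.log2fc) >= lfc_cut],
            )
    n_untested = sum(1 for r in records if r.bias_class == BIAS_UNTESTED)
    rows.append((BIAS_UNTESTED, n_untested, total, float("nan"), ""))
    return pd.DataFrame(
        rows, columns=["class", "count", "total_tested", "percent", "percent_printed"]
    )


def percent_of_degs(numerator: int, denominator: int) -> tuple[float, str]:
    """Raw and printed (two significant figures) percentage of a DEG count."""
    pct = 100.0 * numerator / denominator
    return pct, format_percent(pct)
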