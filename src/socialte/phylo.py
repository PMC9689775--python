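"""Phylogenetic comparative statistics and log-linear contingency models.

Phylogenetically independent contrasts (PIC) convert per-species trait
values into n-1 branch-length-standardised differences that are mutually
independent under Brownian motion, so cross-species correlations (genome
size vs TE content, for instance) are not inflated by shared ancestry. The
contrast correlation is tested with an ordinary Pearson r over the
contrasts: t = r*sqrt(df/(1-r^2)) with df = (number of contrasts) - 2 by
default, the convention matching reported degrees of freedom for six- and
four-species analyses; the textbook through-origin variant (df = k - 1) is
available behind a flag.

The factorial comparisons of gene/TE counts across TE overlap, social level,
bias class and superfamily are fitted as frequentist Poisson log-linear
models (GLM with log link) with likelihood-ratio tests between nested
models. This is a deliberately non-phylogenetic stand-in: model-ready
tables and the species tree are exported for external phylogenetic mixed
modelling.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from socialte.expression import BIAS_NONE, BIAS_QUEEN, BIAS_WORKER

BIAS_CODES = {BIAS_NONE: 0, BIAS_WORKER: 1, BIAS_QUEEN: 2}


@dataclass(frozen=True)
class ContrastResult:
    contrasts_x: np.ndarray
    contrasts_y: np.ndarray
    r: float
    t: float
    df: int
    p: float
    degenerate: bool = False  # |r| = 1: t unbounded


@dataclass(frozen=True)
class LogLinearFit:
    formula: str
    coefficients: pd.Series
    deviance: float
    df_resid: int
    fitted: np.ndarray
    converged: bool


# ---------------------------------------------------------------- PIC


def contrast_t_pvalue(t: float, df: int) -> float:
    """Two-sided Student-t tail probability for a contrast correlation."""
    return float(2.0 * stats.t.sf(abs(t), df))


def pic_contrasts(tree: dendropy.Tree, trait: dict[str, float] | pd.Series) -> np.ndarray:
    """Felsenstein's standardised independent contrasts, post-order.

    At each internal node joining children i, j with (possibly extended)
    branch lengths v_i, v_j the contrast is (x_i - x_j)/sqrt(v_i + v_j),
    the nodal value is the 1/v-weighted mean of x_i and x_j, and the node's
    own branch is extended by v_i*v_j/(v_i + v_j). Requires a rooted,
    fully bifurcating tree with positive branch lengths and a trait value
    for every tip. Returns n_tips - 1 contrasts in post-order.
    """
    trait = dict(trait)
    values: dict[int, float] = {}
    lengths: dict[int, float] = {}
    contrasts: list[float] = []
    for node in tree.postorder_node_iter():
        edge = node.edge.length
        if node.is_leaf():
            label = node.taxon.label if node.taxon else None
            if label not in trait:
                raise ValueError(f"missing trait value for tip {label!r}")
            if edge is None or edge <= 0:
                raise ValueError(f"non-positive branch length at tip {label!r}")
            values[id(node)] = float(trait[label])
            lengths[id(node)] = float(edge)
            continue
        children = node.child_nodes()
        if len(children) != 2:
            raise ValueError(
                f"polytomy ({len(children)} children) at an internal node; "
                "resolve the tree before computing contrasts"
            )
        ci, cj = children
        vi, vj = lengths[id(ci)], lengths[id(cj)]
        xi, xj = values[id(ci)], values[id(cj)]
        contrasts.append((xi - xj) / np.sqrt(vi + vj))
        values[id(node)] = (xi / vi + xj / vj) / (1.0 / vi + 1.0 / vj)
        extra = vi * vj / (vi + vj)
        if node.parent_node is None:
            lengths[id(node)] = extra
        else:
            if edge is None or edge <= 0:
                raise ValueError("non-positive internal branch length")
            lengths[id(node)] = float(edge) + extra
    return np.asarray(contrasts)


def pic_correlation(
    cx: np.ndarray, cy: np.ndarray, through_origin: bool = False
) -> ContrastResult:
    """Correlation test between two contrast vectors.

    Default: ordinary Pearson r with df = k - 2 (k contrasts). With
    ``through_origin`` the correlation is computed without centring and
    df = k - 1. Two-sided p from the Student t distribution; |r| = 1 is
    flagged degenerate with p = 0.
    """
    cx = np.asarray(cx, dtype=float)
    cy = np.asarray(cy, dtype=float)
    k = len(cx)
    if k < 3 or len(cy) != k:
        raise ValueError("need >= 3 contrasts in both vectors")
    if through_origin:
        r = float(np.sum(cx * cy) / np.sqrt(np.sum(cx**2) * np.sum(cy**2)))
        df = k - 1
    else:
        r = float(np.corrcoef(cx, cy)[0, 1])
        df = k - 2
    if abs(r) >= 1.0 - 1e-12:
        return ContrastResult(cx, cy, float(np.sign(r)), np.inf, df, 0.0, degenerate=True)
    t = r * np.sqrt(df / (1.0 - r * r))
    p = contrast_t_pvalue(float(t), df)
    return ContrastResult(cx, cy, r, float(t), df, p)


def pic_correlation_test(
    tree: dendropy.Tree,
    traits: pd.DataFrame,
    x: str,
    y: str,
    through_origin: bool = False,
) -> ContrastResult:
    """Contrast correlation between two trait columns of a per-species table."""
    cx = pic_contrasts(tree, traits[x])
    cy = pic_contrasts(tree, traits[y])
    return pic_correlation(cx, cy, through_origin=through_origin)


# ---------------------------------------------------------------- log-linear


def loglinear_fit(table: pd.DataFrame, formula: str) -> LogLinearFit:
    """Poisson log-linear model on a long-format contingency table.

    ``table`` must carry a ``count`` column plus factor columns referenced
    by the patsy ``formula`` right-hand side (e.g.
    ``"te_overlap * social_level * bias"``). Fitted by IRLS to a deviance
    change below 1e-8 (max 100 iterations).
    """
    import warnings

    model = smf.glm(
        f"count ~ {formula}", data=table, family=sm.families.Poisson()
    )
    with warnings.catch_warnings():
        # saturated fits have df_resid = 0 (scale division) and can trip
        # perfect-separation heuristics; both are expected here
        warnings.simplefilter("ignore", RuntimeWarning)
        warnings.simplefilter("ignore")
        res = model.fit(maxiter=100, tol=1e-8)
    return LogLinearFit(
        formula=formula,
        coefficients=res.params,
        deviance=float(res.deviance),
        df_resid=int(res.df_resid),
        fitted=np.asarray(res.fittedvalues),
        converged=bool(res.converged),
    )


def lrt(reduced: LogLinearFit, full: LogLinearFit) -> tuple[float, int, float]:
    """Likelihood-ratio (deviance-difference) test of nested Poisson fits."""
    statistic = reduced.deviance - full.deviance
    df = reduced.df_resid - full.df_resid
    if df < 0 or statistic < -1e-8:
        raise ValueError("models are not nested (reduced must be within full)")
    statistic = max(statistic, 0.0)
    p = float(stats.chi2.sf(statistic, df)) if df > 0 else 1.0
    return float(statistic), int(df), p


# ---------------------------------------------------------------- exports


def export_model_tables(
    tables: dict[str, pd.DataFrame],
    tree: dendropy.Tree,
    out_dir,
) -> dict[str, str]:
    """Write model-ready long tables plus the species tree.

    Bias classes are re-encoded 0/1/2 (0 = no bias, 1 = worker/nymph,
    2 = queen/female adult) in an added ``bias_code`` column where a bias
    factor is present; counts and factor columns are preserved so external
    phylogenetic mixed models can be fitted directly.
    """
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        df = df.copy()
        if "bias" in df.columns:
            df["bias_code"] = df["bias"].map(BIAS_CODES)
        path = out_dir / f"model_table_{name}.tsv"
        df.to_csv(path, sep="\t", index=False)
        written[name] = str(path)
    tree_path = out_dir / "species_tree.nwk"
    tree.write(path=str(tree_path), schema="newick", suppress_rooting=True)
    written["tree"] = str(tree_path)
    return written
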