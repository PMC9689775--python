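"""CpG-aware Kimura 2-parameter divergence and repeat landscapes.

Each genomic TE copy is compared with its consensus over a gap-free
alignment; transitions (p) and transversions (q) per ungapped site give the
K2P distance

    K = -1/2 * ln((1 - 2p - q) * sqrt(1 - 2q))

CpG dinucleotides are hypermutable (spontaneous deamination of methylated
cytosine), so transitions observed at consensus CpG positions carry reduced
weight (1/10 by default, the convention of the RepeatMasker divergence
summary) when ``cpg_correct`` is on. Binning copy lengths by 100*K yields
the classic divergence landscape: percent of genome per divergence bin and
superfamily, a proxy for TE activity through time.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
VALID = {"A", "C", "G", "T"}

DEFAULT_CPG_WEIGHT = 0.1
DEFAULT_BIN_WIDTH = 1.0
DEFAULT_MAX_DIVERGENCE = 55.0


class SaturationError(ValueError):
    """p, q outside the domain of the K2P log: divergence saturated."""


@dataclass(frozen=True)
class DivergenceEstimate:
    """Transition/transversion proportions and the K2P distance of one copy."""

    p: float
    q: float
    n_sites: int
    K: float


def kimura_k2p(p: float, q: float) -> float:
    """Kimura 2-parameter distance from transition (p) and transversion (q)
    proportions.

    Raises :class:`SaturationError` when ``1 - 2p - q <= 0`` or
    ``1 - 2q <= 0`` (the estimator saturates).
    """
    if p < 0 or q < 0:
        raise ValueError(f"negative proportions p={p}, q={q}")
    a = 1.0 - 2.0 * p - q
    b = 1.0 - 2.0 * q
    if a <= 0 or b <= 0:
        raise SaturationError(f"saturated divergence: p={p}, q={q}")
    return -0.5 * math.log(a * math.sqrt(b))


def is_transition(x: str, y: str) -> bool:
    return x != y and ((x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES))


def consensus_cpg_mask(consensus_aln: str) -> list[bool]:
    """Mark alignment columns that are part of a CpG dinucleotide in the
    consensus: the C and the G it precedes. The dinucleotide is read across
    gap columns so that indels do not hide a consensus CpG."""
    mask = [False] * len(consensus_aln)
    prev_base_idx = -1
    for i, base in enumerate(consensus_aln.upper()):
        if base == "-":
            continue
        if prev_base_idx >= 0 and consensus_aln[prev_base_idx].upper() == "C" and base == "G":
            mask[prev_base_idx] = True
            mask[i] = True
        prev_base_idx = i
    return mask


def alignment_divergence(
    copy_aln: str,
    consensus_aln: str,
    cpg_correct: bool = True,
    cpg_weight: float = DEFAULT_CPG_WEIGHT,
) -> DivergenceEstimate:
    """Estimate K2P divergence of one copy/consensus alignment.

    Columns with gaps or ambiguity codes (anything outside ACGT on either
    row) are excluded from counts and from ``n_sites``. With ``cpg_correct``,
    a transition at a consensus CpG position contributes ``cpg_weight``
    (default 1/10) to the transition count instead of 1.
    """
    if len(copy_aln) != len(consensus_aln):
        raise ValueError(
            f"alignment length mismatch: {len(copy_aln)} vs {len(consensus_aln)}"
        )
    cpg = consensus_cpg_mask(consensus_aln) if cpg_correct else None
    n_sites = 0
    ts_weighted = 0.0
    tv = 0
    for i, (x, y) in enumerate(zip(copy_aln.upper(), consensus_aln.upper())):
        if x not in VALID or y not in VALID:
            continue
        n_sites += 1
        if x == y:
            continue
        if is_transition(x, y):
            ts_weighted += cpg_weight if (cpg is not None and cpg[i]) else 1.0
        else:
            tv += 1
    if n_sites == 0:
        raise ValueError("empty ungapped overlap between copy and consensus")
    p = ts_weighted / n_sites
    q = tv / n_sites
    return DivergenceEstimate(p=p, q=q, n_sites=n_sites, K=kimura_k2p(p, q))


def divergence_table(
    pairs: pd.DataFrame,
    cpg_correct: bool = True,
    cpg_weight: float = DEFAULT_CPG_WEIGHT,
) -> pd.DataFrame:
    """Per-copy divergence estimates from an aligned-pairs table.

    ``pairs`` needs columns copy_id, superfamily, copy_aln, consensus_aln;
    the returned frame adds p, q, n_sites, K and length (ungapped copy bp).
    """
    rows = []
    for r in pairs.itertuples(index=False):
        est = alignment_divergence(r.copy_aln, r.consensus_aln, cpg_correct, cpg_weight)
        length = sum(1 for ch in r.copy_aln if ch != "-")
        rows.append((r.copy_id, r.superfamily, est.p, est.q, est.n_sites, est.K, length))
    return pd.DataFrame(
        rows, columns=["copy_id", "superfamily", "p", "q", "n_sites", "K", "length"]
    )


def build_landscape(
    copies: pd.DataFrame,
    genome_size: int,
    bin_width: float = DEFAULT_BIN_WIDTH,
    max_divergence: float = DEFAULT_MAX_DIVERGENCE,
) -> pd.DataFrame:
    """Bin per-copy divergences into a per-superfamily repeat landscape.

    ``copies`` needs columns superfamily, K, length. Each copy's length is
    assigned to the bin containing 100*K; masses are percent of
    ``genome_size``. Returns long format: superfamily, bin_low, bin_high,
    percent — including empty bins so landscapes align across superfamilies.
    """
    if genome_size <= 0:
        raise ValueError("genome_size must be positive")
    edges = np.arange(0.0, max_divergence + bin_width, bin_width)
    superfamilies = sorted(copies["superfamily"].unique()) if len(copies) else []
    out = []
    for sf in superfamilies:
        sub = copies[copies.superfamily == sf]
        idx = np.clip(
            np.digitize(100.0 * sub["K"].to_numpy(), edges) - 1, 0, len(edges) - 2
        )
        mass = np.zeros(len(edges) - 1)
        np.add.at(mass, idx, sub["length"].to_numpy(dtype=float))
        for b in range(len(edges) - 1):
            out.append((sf, edges[b], edges[b + 1], 100.0 * mass[b] / genome_size))
    return pd.DataFrame(out, columns=["superfamily", "bin_low", "bin_high", "percent"])
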