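"""Evolve TE copies from a consensus under a CpG-accelerated K2P process.

Substitutions are drawn sitewise from the Kimura 2-parameter transition
probabilities at divergence time t: with transition rate a and per-type
transversion rate b (kappa = a/b),

    p(t) = 1/4 + 1/4*exp(-4bt) - 1/2*exp(-2(a+b)t)
    q(t) = 1/2 - 1/2*exp(-4bt)

and the expected K2P distance is (a + 2b)t. At consensus CpG dinucleotides
(the C and the G it precedes) the transition rate is multiplied by
``cpg_mult``, emulating deamination hypermutability. The branch length is
calibrated so the sequence-wide expected number of substitutions per site
equals ``k_true``, given the realised CpG fraction of the consensus.
Alignments are gap-free.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from socialte.divergence import SaturationError, consensus_cpg_mask
from socialte.sim.config import SimConfig, stage_rng

BASES = np.array(list("ACGT"))
TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}


def _k2p_pq(a_t: float, b_t: float) -> tuple[float, float]:
    p = 0.25 + 0.25 * np.exp(-4.0 * b_t) - 0.5 * np.exp(-2.0 * (a_t + b_t))
    q = 0.5 - 0.5 * np.exp(-4.0 * b_t)
    return float(p), float(q)


def evolve_te_copies(
    consensus_length: int,
    n_copies: int,
    config: SimConfig,
    superfamily: str = "TE",
) -> pd.DataFrame:
    """Simulate ``n_copies`` diverged copies of a random consensus.

    Returns a frame with columns copy_id, superfamily, copy_aln,
    consensus_aln (gap-free, equal length). Raises
    :class:`~socialte.divergence.SaturationError` when ``k_true`` puts the
    expected (p, q) outside the K2P domain.
    """
    if config.k_true < 0:
        raise ValueError("k_true must be >= 0")
    rng = stage_rng(config.seed, "evolve")
    consensus = "".join(rng.choice(BASES, size=consensus_length))
    cpg = np.array(consensus_cpg_mask(consensus))
    f_cpg = cpg.mean() if consensus_length else 0.0

    kappa = config.kappa
    # per-site substitution rate a + 2b with a = kappa*b; CpG sites have
    # a*cpg_mult + 2b. Calibrate total branch length t so the average over
    # sites equals k_true.
    mean_rate_factor = (1.0 - f_cpg) * (kappa + 2.0) + f_cpg * (kappa * config.cpg_mult + 2.0)
    b_t = config.k_true / mean_rate_factor  # b*t
    a_t = kappa * b_t
    a_t_cpg = a_t * config.cpg_mult

    p_n, q_n = _k2p_pq(a_t, b_t)
    p_c, q_c = _k2p_pq(a_t_cpg, b_t)
    for p, q in ((p_n, q_n), (p_c, q_c)):
        if 1.0 - 2.0 * p - q <= 1e-9 or 1.0 - 2.0 * q <= 1e-9:
            raise SaturationError(f"k_true={config.k_true} saturates the K2P process")

    cons_arr = np.array(list(consensus))
    p_site = np.where(cpg, p_c, p_n)
    q_site = np.where(cpg, q_c, q_n)
    rows = []
    for ci in range(n_copies):
        u = rng.random(consensus_length)
        copy = cons_arr.copy()
        ts_mask = u < p_site
        tv_mask = (u >= p_site) & (u < p_site + q_site)
        if ts_mask.any():
            copy[ts_mask] = [TRANSITION[b] for b in cons_arr[ts_mask]]
        if tv_mask.any():
            which = rng.integers(0, 2, size=int(tv_mask.sum()))
            copy[tv_mask] = [
                TRANSVERSIONS[b][w] for b, w in zip(cons_arr[tv_mask], which)
            ]
        rows.append((f"copy{ci + 1:04d}", superfamily, "".join(copy), consensus))
    return pd.DataFrame(rows, columns=["copy_id", "superfamily", "copy_aln", "consensus_aln"])
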