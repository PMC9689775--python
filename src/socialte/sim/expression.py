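"""Negative-binomial RNA-seq count simulation with planted caste bias."""

from __future__ import annotations

import numpy as np
import pandas as pd

from socialte.models import GeneModels
from socialte.sim.config import SimConfig, stage_rng
from socialte.expression import BIAS_NONE, BIAS_QUEEN, BIAS_WORKER
from socialte.sim.truth import TruthTable


def nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """NB draws parameterised by mean and dispersion a (var = mu + a*mu^2)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    n = 1.0 / dispersion
    p = n / (n + mean)
    return rng.negative_binomial(n, p)


def simulate_expression(
    models: GeneModels,
    config: SimConfig,
    species: str = "sp1",
) -> tuple[pd.DataFrame, pd.DataFrame, TruthTable]:
    """Count table and samples table with planted biased genes.

    A ``planted_frac`` of genes is shifted by ``planted_lfc`` log2 units in
    the queen/adult-female group (half up => queen-biased truth, half down
    => worker-biased truth). Baseline means are log-normal, library size
    factors vary uniformly in [0.7, 1.3], counts are negative binomial with
    the configured dispersion. Returns (counts, samples, truth).
    """
    if config.n_libs_per_group < 2:
        raise ValueError("need >= 2 libraries per group")
    rng = stage_rng(config.seed, "expression")
    gene_ids = list(models.genes.gene_id)
    n = len(gene_ids)
    base = rng.lognormal(mean=np.log(100.0), sigma=1.0, size=n)

    n_planted = int(round(config.planted_frac * n))
    planted_idx = rng.choice(n, size=n_planted, replace=False) if n_planted else np.array([], int)
    direction = np.zeros(n)
    half = n_planted // 2
    direction[planted_idx[:half]] = 1.0   # up in queen group
    direction[planted_idx[half:]] = -1.0  # down in queen group
    truth_bias = {}
    for gi in range(n):
        if direction[gi] > 0:
            truth_bias[gene_ids[gi]] = BIAS_QUEEN
        elif direction[gi] < 0:
            truth_bias[gene_ids[gi]] = BIAS_WORKER
        else:
            truth_bias[gene_ids[gi]] = BIAS_NONE

    libs, groups = [], []
    for g, tag in ((BIAS_QUEEN, "Q"), (BIAS_WORKER, "W")):
        for i in range(config.n_libs_per_group):
            libs.append(f"{species}_{tag}{i + 1}")
            groups.append(g)
    counts = np.zeros((n, len(libs)), dtype=int)
    for li, grp in enumerate(groups):
        sf = rng.uniform(*config.libsize_range)
        mu = base * sf
        if grp == BIAS_QUEEN:
            mu = mu * np.power(2.0, config.planted_lfc * direction)
        counts[:, li] = nb_draw(rng, mu, config.nb_dispersion)

    counts_df = pd.DataFrame(counts, index=pd.Index(gene_ids, name="gene_id"), columns=libs)
    samples = pd.DataFrame({"library": libs, "species": species, "group": groups})
    return counts_df, samples, TruthTable(true_bias=truth_bias)
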