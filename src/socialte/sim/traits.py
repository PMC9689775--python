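"""Correlated bivariate Brownian motion along a phylogeny."""

from __future__ import annotations

import dendropy
import numpy as np
import pandas as pd

from socialte.sim.truth import TruthTable


def simulate_bm_traits(
    tree: dendropy.Tree,
    rho: float,
    sigma: float,
    seed: int,
    root_value: tuple[float, float] = (0.0, 0.0),
) -> tuple[pd.DataFrame, TruthTable]:
    """Evolve two traits by correlated Brownian motion along branch lengths.

    Each branch of length v adds a bivariate normal step with covariance
    sigma^2 * v * [[1, rho], [rho, 1]]. Non-ultrametric trees are fine;
    zero- or negative-length branches are rejected. Returns a tip table
    (trait_x, trait_y indexed by taxon label) and the truth (rho).
    """
    if not -1.0 <= rho <= 1.0:
        raise ValueError(f"rho must be in [-1,1], got {rho}")
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    chol = np.linalg.cholesky(cov) if abs(rho) < 1 else None
    values: dict[int, np.ndarray] = {}
    rows = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            values[id(node)] = np.asarray(root_value, dtype=float)
        else:
            v = node.edge.length
            if v is None or v <= 0:
                raise ValueError("zero- or negative-length branch in tree")
            z = rng.standard_normal(2)
            if chol is not None:
                step = sigma * np.sqrt(v) * (chol @ z)
            else:  # |rho| = 1: perfectly (anti)correlated steps
                step = sigma * np.sqrt(v) * np.array([z[0], np.sign(rho) * z[0]])
            values[id(node)] = values[id(node.parent_node)] + step
        if node.is_leaf():
            rows.append((node.taxon.label, *values[id(node)]))
    traits = pd.DataFrame(rows, columns=["species", "trait_x", "trait_y"]).set_index("species")
    return traits, TruthTable(true_trait_correlation=rho)
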