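import numpy as np
import pandas as pd
import pytest

from socialte.models import GeneModels, MappedTE, TECall
from socialte.sim.config import SimConfig


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=42, n_chroms=1, chrom_length=200_000, n_genes=30, te_density=60.0)


@pytest.fixture(scope="session")
def gene_models(small_config):
    from socialte.sim.genome import simulate_gene_models

    return simulate_gene_models(small_config)


def make_call(start, end, chrom="chr1", strand="+", tool="t1", sf="LINE", score=10.0, cid=""):
    return TECall(chrom, start, end, strand, tool, sf, score, cid or f"{tool}:{start}")


def make_mapped(start, end, score, chrom="chr1", strand="+", sf="LINE", cid=None):
    return MappedTE(chrom, start, end, strand, sf, score, cid or f"c{start}_{end}")


def random_calls(rng, n, span=1000, n_chroms=2):
    calls = []
    for i in range(n):
        chrom = f"chr{rng.integers(1, n_chroms + 1)}"
        start = int(rng.integers(0, span))
        length = int(rng.integers(1, span // 3))
        calls.append(
            TECall(
                chrom,
                start,
                start + length,
                "+" if rng.random() < 0.5 else "-",
                f"tool{rng.integers(1, 4)}",
                "LINE",
                float(rng.integers(1, 100)),
                f"c{i}",
            )
        )
    return calls


def random_gene_set(rng, n_genes, span=10_000):
    rows = []
    for i in range(n_genes):
        start = int(rng.integers(0, span - 100))
        length = int(rng.integers(50, 500))
        rows.append(
            (f"G{i}", f"chr{rng.integers(1, 3)}", start, start + length,
             "+" if rng.random() < 0.5 else "-")
        )
    return GeneModels(genes=pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"]))


def random_mapped(rng, n, span=10_000):
    out = []
    for i in range(n):
        start = int(rng.integers(0, span - 50))
        length = int(rng.integers(20, 400))
        out.append(
            MappedTE(
                f"chr{rng.integers(1, 3)}", start, start + length,
                "+" if rng.random() < 0.5 else "-",
                "LINE", float(rng.integers(2, 100)), f"te{i}",
            )
        )
    return out
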