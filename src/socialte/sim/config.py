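"""Simulation configuration and deterministic per-stage RNG derivation."""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

# stable stage indices: partial reruns of any stage reuse the same stream
STAGES = {
    "genes": 0,
    "tecalls": 1,
    "mapped": 2,
    "evolve": 3,
    "expression": 4,
    "go": 5,
    "traits": 6,
}

DEFAULT_SUPERFAMILIES = ("Tc-Mariner", "hAT", "Gypsy", "LINE")


@dataclass(frozen=True)
class SimConfig:
    """All knobs of the synthetic study, with desk-scale defaults.

    Densities are per Mb per superfamily; ``redundancy`` is the probability
    that a true TE is re-reported by each additional tool with boundary
    jitter; ``fp_rate`` the expected fraction of spurious calls per tool;
    ``k_true`` the target Kimura divergence of simulated copies; ``kappa``
    the transition:transversion rate ratio; ``cpg_mult`` the CpG
    transition-rate multiplier; ``nb_dispersion`` the NB dispersion (var =
    mu + a*mu^2); ``bias_density_mult`` multiplies within-gene insertion
    rates per planted bias class (how opposite caste trends are planted).
    """

    seed: int = 0
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 300
    exon_count_range: tuple[int, int] = (2, 6)
    exon_length_range: tuple[int, int] = (100, 400)
    intron_length_range: tuple[int, int] = (200, 1500)
    n_tools: int = 4
    te_density: float = 40.0
    redundancy: float = 0.5
    jitter_sd: float = 10.0
    fp_rate: float = 0.05
    te_length_range: tuple[int, int] = (300, 3000)
    k_true: float = 0.10
    kappa: float = 2.0
    cpg_mult: float = 10.0
    n_libs_per_group: int = 6
    nb_dispersion: float = 0.1
    libsize_range: tuple[float, float] = (0.7, 1.3)
    planted_frac: float = 0.1
    planted_lfc: float = 2.0
    go_terms: int = 50
    go_depth: int = 4
    superfamilies: tuple[str, ...] = DEFAULT_SUPERFAMILIES
    bias_density_mult: tuple[tuple[str, float], ...] = ()

    def __post_init__(self) -> None:
        counts = dict(
            n_chroms=self.n_chroms,
            chrom_length=self.chrom_length,
            n_genes=self.n_genes,
            n_tools=self.n_tools,
            n_libs_per_group=self.n_libs_per_group,
            go_terms=self.go_terms,
            go_depth=self.go_depth,
        )
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        for name, v in dict(
            redundancy=self.redundancy, fp_rate=self.fp_rate, planted_frac=self.planted_frac
        ).items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a probability in [0,1], got {v}")
        if self.k_true < 0:
            raise ValueError("k_true must be >= 0")
        if not np.isfinite(self.planted_lfc):
            raise ValueError("planted_lfc must be finite")
        if self.te_density < 0 or self.jitter_sd < 0 or self.nb_dispersion < 0:
            raise ValueError("densities, jitter and dispersion must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)

    def density_mult(self) -> dict[str, float]:
        return dict(self.bias_density_mult)


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """Deterministic child RNG for a named pipeline stage.

    Children are spawned from a single root :class:`~numpy.random.SeedSequence`
    with a fixed per-stage spawn key, so rerunning one stage reproduces its
    stream regardless of which other stages ran.
    """
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(STAGES[stage],)))
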