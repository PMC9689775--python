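"""Planted-truth bookkeeping for the synthetic study."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd


@dataclass
class TruthTable:
    """Every planted entity, resolvable by id in the emitted files.

    ``true_tes``: one row per true TE (te_id, chrom, start, end, strand,
    superfamily, in_gene, gene_id). ``true_bias``: planted bias class per
    gene. ``true_enriched_terms``: GO terms planted as enriched, with the
    gene set they were planted over. ``true_trait_correlation``: the rho of
    the bivariate Brownian simulation.
    """

    true_tes: pd.DataFrame | None = None
    true_bias: dict[str, str] = field(default_factory=dict)
    true_enriched_terms: dict[str, list[str]] = field(default_factory=dict)
    true_trait_correlation: float | None = None

    def merge(self, other: "TruthTable") -> "TruthTable":
        return TruthTable(
            true_tes=other.true_tes if other.true_tes is not None else self.true_tes,
            true_bias={**self.true_bias, **other.true_bias},
            true_enriched_terms={**self.true_enriched_terms, **other.true_enriched_terms},
            true_trait_correlation=(
                other.true_trait_correlation
                if other.true_trait_correlation is not None
                else self.true_trait_correlation
            ),
        )

    def write(self, out_dir: str | Path) -> None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if self.true_tes is not None:
            self.true_tes.to_csv(out_dir / "truth_tes.tsv", sep="\t", index=False)
        meta = {
            "true_bias": self.true_bias,
            "true_enriched_terms": self.true_enriched_terms,
            "true_trait_correlation": self.true_trait_correlation,
        }
        (out_dir / "truth.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
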