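"""Generate the synthetic study: six species (two gregarious cockroach-like,
four eusocial termite-like), each with gene models, redundant multi-tool TE
call sets, mapped TE copies, copy/consensus alignments, count tables, and
GO annotations; plus a shared species tree and Brownian trait table.

Writes everything under results/simdata/ with planted truth recorded per
species. Run me first; later scripts read this directory.
"""

import argparse
from pathlib import Path

from socialte.sim.config import SimConfig
from socialte.sim.runner import simulate_all


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/simdata"))
    args = ap.parse_args()

    cfg = SimConfig(seed=args.seed)
    truths = simulate_all(cfg, args.out)
    n_species = len(truths) - 1  # minus the shared-truth entry
    total_tes = sum(
        len(t.true_tes) for k, t in truths.items() if k != "__shared__"
    )
    print(f"simulated {n_species} species into {args.out}")
    print(f"planted {total_tes} true TE insertions; "
          f"trait correlation rho = {truths['__shared__'].true_trait_correlation}")


if __name__ == "__main__":
    main()
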