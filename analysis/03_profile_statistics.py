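#!/usr/bin/env python
"""Profile statistics on the bundled fungal peptidase census.

Runs ANOSIM and SIMPER (Bray-Curtis) between the 8 mesophilic and 13
thermophilic species of the bundled catalytic-type count matrix
(thermotolerant species excluded), plus the full sensitivity grid
(raw counts vs row percentages; all 9 categories vs the 7 mechanistic
types), and writes the per-type SIMPER contribution table.
"""

import json
from pathlib import Path

from thermopep.experiments import (
    GROUP_PAIR,
    census_two_group,
    headline_anosim,
    simper_sensitivity_grid,
)
from thermopep.stats import simper

SEED = 20240917
OUT = Path(__file__).resolve().parent.parent / "results" / "profile_stats"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    res_a = headline_anosim(n_perm=9999, seed=SEED)
    print(f"ANOSIM (raw counts, Bray-Curtis): R = {res_a.R:.4f}, "
          f"P = {res_a.p_value:.4g} ({res_a.n_permutations} permutations)")

    res_s = simper(census_two_group(), GROUP_PAIR)
    print(f"SIMPER overall between-group dissimilarity: {res_s.overall:.2f}%")
    top = res_s.table.head(3)
    print("largest contributors:")
    for _, row in top.iterrows():
        print(f"  {row['variable']:<10s} {row['average_contribution']:6.2f} "
              f"({row['percent_contribution']:5.1f}% of total)")
    res_s.table.to_csv(OUT / "simper_contributions.tsv", sep="\t", index=False)

    grid = simper_sensitivity_grid()
    grid.to_csv(OUT / "simper_sensitivity_grid.tsv", sep="\t", index=False)
    print("\nsensitivity grid (overall %):")
    print(grid.to_string(index=False))
    print("\nthe raw-count configuration is the one matching the published "
          "26.08%; row percentages tell a different (size-removed) story.")

    (OUT / "anosim.json").write_text(json.dumps({
        "R": res_a.R, "p": res_a.p_value, "n_perm": res_a.n_permutations,
        "seed": SEED, "metric": "braycurtis"}, indent=2))


if __name__ == "__main__":
    main()
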