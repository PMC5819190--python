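#!/usr/bin/env python
"""Recovery of the thermophilic amino-acid composition signature.

Simulates 10 mesophilic + 10 thermophilic proteomes per replicate, the
thermophilic group carrying the planted shift (more Ala, Glu, Gly, Pro,
Arg, Val; less Cys, His, Ile, Lys, Met, Asn, Gln, Ser, Thr, Trp), and asks
whether the per-variable Welch tests on species means recover every
planted direction at P < 0.05. Writes one example test table and the
replicated recovery rates.
"""

import json
from pathlib import Path

from thermopep.experiments import (
    composition_direction_experiment,
    composition_direction_replicate,
)

SEED = 20240917
OUT = Path(__file__).resolve().parent.parent / "results" / "composition"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    rep = composition_direction_replicate(SEED)
    table = rep["table"].reset_index()
    table.to_csv(OUT / "example_tests.tsv", sep="\t", index=False)
    sig = table[table["direction"] != "ns"]
    print("one replicate (10 vs 10 species, 150 proteins each):")
    print(f"  significant increases: {sorted(sig.loc[sig['direction'] == '+', 'variable'])}")
    print(f"  significant decreases: {sorted(sig.loc[sig['direction'] == '-', 'variable'])}")

    out = composition_direction_experiment(n_replicates=100, seed=SEED)
    print(f"\nover {out['n_replicates']} replicates:")
    print(f"  all six planted residue increases recovered: {out['residue_rate']:.0%}")
    print(f"  class directions (charged+, hydrophobic+, polar-): {out['class_rate']:.0%}")
    (OUT / "recovery_rates.json").write_text(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
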