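#!/usr/bin/env python
"""Generate the synthetic study inputs with known ground truth.

Writes a reference peptidase library, one proteome per synthetic species
(4 mesophilic baseline + 4 thermophilic carrying the compositional shift),
a labeled hallmark sequence set, and PDB structures with 0-3 known voids,
all under results/synthetic/.
"""

from pathlib import Path

from thermopep.records import write_fasta
from thermopep.synthetic import (
    THERMOPHILIC_SHIFT,
    ProteomeRegime,
    derive_seed,
    make_hallmark_set,
    make_proteome,
    make_reference_library,
    make_structure,
    write_pdb,
)

SEED = 20240917
OUT = Path(__file__).resolve().parent.parent / "results" / "synthetic"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    reference = make_reference_library(
        [("A01", "A", 4, 350), ("S08", "S", 4, 400), ("M12", "M", 4, 300)],
        seed=derive_seed(SEED, 0))
    write_fasta(reference, OUT / "reference.fasta")
    print(f"reference library: {len(reference)} members, 3 families")

    truths = []
    for g, group in enumerate(("mesophilic", "thermophilic")):
        for i in range(4):
            sp = f"{group}_{i + 1:02d}"
            regime = ProteomeRegime(n_proteins=150, peptidase_fraction=0.1,
                                    mutation_rate=0.1,
                                    seed=derive_seed(SEED, 10 * (g + 1) + i))
            if group == "thermophilic":
                regime = regime.with_shift(THERMOPHILIC_SHIFT)
            records, truth = make_proteome(regime, reference, sp, group)
            write_fasta(records, OUT / f"{sp}.fasta")
            truths.append(truth.proteins)
    import pandas as pd
    pd.concat(truths, ignore_index=True).to_csv(OUT / "proteome_truth.tsv",
                                                sep="\t", index=False)
    print(f"proteomes: 8 species x 150 proteins (truth table written)")

    records, truth = make_hallmark_set(25, 25, seed=derive_seed(SEED, 99))
    write_fasta(records, OUT / "hallmark_set.fasta")
    truth.to_csv(OUT / "hallmark_truth.tsv", sep="\t", index=False)
    print("hallmark set: 25 positives + 25 negatives")

    for k in range(4):
        model, _ = make_structure(k, seed=derive_seed(SEED, 200 + k),
                                  source_id=f"voids{k}")
        write_pdb(model, OUT / f"voids{k}.pdb")
    print("structures: voids0.pdb .. voids3.pdb (0-3 known cavities)")


if __name__ == "__main__":
    main()
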