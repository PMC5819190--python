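"""Amino-acid alphabets, physicochemical classes and ionization constants.

The class definitions (charged / polar / hydrophobic) follow the EMBOSS
PEPSTATS convention, in which the classes overlap: charged residues are a
subset of the polar ones, and every residue belongs to either the polar or
the hydrophobic (non-polar) class.
"""

from __future__ import annotations

import numpy as np

#: The 20 standard amino acids, alphabetical one-letter order.
STANDARD_AA: str = "ACDEFGHIKLMNPQRSTVWY"

AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(STANDARD_AA)}

#: Ambiguity / non-standard one-letter codes excluded from compositional
#: statistics and scored as neutral (0) in alignments.
NON_STANDARD_AA: frozenset[str] = frozenset("BJOUXZ")

# EMBOSS PEPSTATS physicochemical classes (overlapping by design).
CHARGED: frozenset[str] = frozenset("DEHKR")
POLAR: frozenset[str] = frozenset("DEHKNQRST")
HYDROPHOBIC: frozenset[str] = frozenset("ACFGILMPVWY")

#: Swiss-Prot-style average background frequencies, used as the default
#: residue distribution of the synthetic proteome generator.
BACKGROUND_FREQS: dict[str, float] = {
    "A": 0.0826, "C": 0.0139, "D": 0.0546, "E": 0.0672, "F": 0.0387,
    "G": 0.0708, "H": 0.0228, "I": 0.0593, "K": 0.0580, "L": 0.0965,
    "M": 0.0241, "N": 0.0406, "P": 0.0475, "Q": 0.0393, "R": 0.0553,
    "S": 0.0660, "T": 0.0535, "V": 0.0686, "W": 0.0110, "Y": 0.0292,
}

# pKa values of ionizable groups, EMBOSS set.
PKA_NTERM: float = 8.6
PKA_CTERM: float = 3.6
PKA_SIDECHAIN: dict[str, float] = {
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}
#: Side chains that are positively charged when protonated.
BASIC_SIDECHAINS: frozenset[str] = frozenset("HKR")
#: Side chains that are negatively charged when deprotonated.
ACIDIC_SIDECHAINS: frozenset[str] = frozenset("CDEY")


def background_vector() -> np.ndarray:
    """Background frequencies as a 20-vector in ``STANDARD_AA`` order, normalized."""
    v = np.array([BACKGROUND_FREQS[aa] for aa in STANDARD_AA], dtype=float)
    return v / v.sum()


def encode(sequence: str) -> np.ndarray:
    """Encode a sequence as integer indices into ``STANDARD_AA``.

    Non-standard residues are encoded as -1.
    """
    table = np.full(128, -1, dtype=np.int8)
    for aa, i in AA_INDEX.items():
        table[ord(aa)] = i
    raw = np.frombuffer(sequence.upper().encode("ascii"), dtype=np.uint8)
    return table[raw]
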