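# thermopep

Comparative genome mining of fungal peptidases: do heat-tolerant fungi
carry fewer peptidase genes than their mesophilic relatives, and do their
enzymes show sequence- and structure-level signatures of thermal
adaptation?

`thermopep` implements that comparison as a tested pipeline:

1. **Peptidase mining** — assign proteome sequences to MEROPS-style
   peptidase families (A01, S08, …) and catalytic types (Aspartic, Serine,
   Metallo, …) by best-hit similarity against an annotated reference
   library: a k-mer prescreen followed by exact Smith-Waterman rescoring
   (BLOSUM62, affine gaps 11/1), with score / identity / coverage
   thresholds.
2. **Profile statistics** — species-by-category count matrices compared
   with Bray-Curtis dissimilarity, BC(x, y) = Σ|xᵢ−yᵢ| / Σ(xᵢ+yᵢ), the
   ANOSIM rank permutation test, R = (r̄_between − r̄_within)/(M/2), and
   SIMPER, which decomposes the average between-group dissimilarity into
   per-category contributions.
3. **Composition statistics** — percent amino-acid composition and the
   overlapping EMBOSS charged / polar / hydrophobic class fractions, per
   protein or per species, with per-variable Welch / Student / paired
   t tests for mesophile-vs-thermophile shifts.
4. **Hallmark filtering** — functional A1A (pepsin-like) aspartic-peptidase
   homologs identified by the five ordered motifs D[TS]G, Y, XXG, D[TS]G,
   XXG (X ∈ {A,F,I,L,M,V}).
5. **Structure metrics** — internal-cavity counting on PDB models by
   probe-augmented voxel flood fill, HELIX/SHEET record counts, and
   sequence-derived molecular weight and isoelectric point
   (Henderson–Hasselbalch with the EMBOSS pKa set), compared between groups
   with the tie-corrected Kruskal-Wallis test (chi-square and Monte-Carlo
   permutation P).

Every stage has a synthetic-data generator with exact ground truth
(`thermopep.synthetic`), so the whole pipeline is testable offline. Two
small bundled tables — a 23-species census of peptidase counts by catalytic
type, and per-structure metrics of 12 modeled aspartic peptidases — let the
statistical stages run without any sequence or structure downloads.

## Worked example

The bundled census (8 mesophilic vs 13 thermophilic species; the 2
thermotolerant species are excluded from two-group comparisons):

```bash
$ thermopep simper
overall between-group dissimilarity: 26.12%
...

$ thermopep anosim --nperm 9999 --seed 42
{"R": 0.7530841799709724, "p": 0.0001, "n_perm": 9999, "metric": "braycurtis"}

$ thermopep kw --nperm 100000 --seed 42
{"H": 5.966789667896679, "df": 1, "p_chi2": 0.01457..., "p_perm": 0.01410..., ...}
```

Reading these numbers: the peptidase profiles of mesophilic and
thermophilic species differ by 26.1% on average (SIMPER; the Serine,
Metallo and Aspartic columns contribute ~80% of that difference), the
separation is strong and highly non-random (ANOSIM R = 0.753 at the
minimal attainable P of 1/10000), and the thermophilic structures have
significantly fewer internal cavities (Kruskal-Wallis H = 5.97,
permutation P ≈ 0.014).

The same computations from Python:

```python
from thermopep.experiments import headline_anosim, headline_simper, cavity_kw
print(headline_simper())              # 26.115...
print(headline_anosim(seed=42).R)     # 0.7530...
print(cavity_kw(seed=42).p_perm)      # 0.014...
```

The numbered scripts under `analysis/` run the full study narrative
(simulate inputs → mine → profile statistics → composition shifts →
structure comparison) and write their tables under `results/`.

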