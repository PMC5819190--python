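# Methods

This note documents the models, numerical choices and known limitations of
the `thermopep` pipeline. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Peptidase mining

Queries are assigned to reference families by best-hit similarity. BLAST is
replaced by a two-stage, fully self-contained classifier:

1. **k-mer prescreen.** Each reference entry is indexed by its distinct
   k-mers (default k = 4). Candidates sharing at least `min_shared_kmers`
   (default 8) distinct k-mers with the query are ranked by shared count;
   the top `max_candidates` (default 50) go to rescoring.
2. **Smith-Waterman rescoring.** Exact local alignment
   (`Bio.Align.PairwiseAligner`) with BLOSUM62 and affine gaps in the
   BLAST convention — a gap of length *g* costs 11 + *g* (biopython
   `open_gap_score = -12`, `extend_gap_score = -1`). Non-standard residues
   (B, J, O, U, X, Z) score 0 against everything, so they neither reward
   nor punish an alignment. The test suite checks the scores against an
   independent quadratic-space affine-gap DP.

A hit is emitted only if raw score ≥ 60, percent identity ≥ 30 and query
coverage ≥ 0.5 (aligned query columns / query length). These thresholds
are conventions, not published values; they are exposed in `MiningParams`
and logged with every run. Ties are broken by higher identity, then
lexicographic reference id. One annotation per query (best hit); "Mixed"
catalytic types are carried by P-family reference entries, not by
multi-hit logic. Exact reproduction of a published gene census from real
genomes is deliberately **not** claimed — search settings of such censuses
are typically unstated — which is why the bundled count table enters the
pipeline as a fixed input rather than something to re-derive.

## Profile statistics

* **Bray-Curtis** on raw counts is the default (the convention of the Past
  toolbox's SIMPER); `euclidean` and row-percentage (`relativize`) modes
  exist as sensitivity switches, because which convention produced the
  published values is not stated. The sensitivity grid
  (`experiments.simper_sensitivity_grid`) shows the raw-count
  configuration is the matching one: on raw counts the overall
  between-group dissimilarity is ~26.1% (9 or 7 categories), on row
  percentages ~12.8% — the published 26.08% is a raw-count quantity, i.e.
  it mixes profile shape with the overall reduction in gene counts.
* **ANOSIM** ranks all n(n−1)/2 distances with mid-ranks on ties;
  R = (mean between-group rank − mean within-group rank)/(M/2). The
  permutation P uses label shuffles with the "+1 in numerator and
  denominator" convention, so P ≥ 1/(n_perm + 1) and a reported P can
  never be zero. Default 9,999 permutations.
* **SIMPER** averages the per-variable terms |x_vj − x_vk| / Σ_u(x_uj + x_uk)
  over all cross-group pairs; contributions sum to the overall average
  Bray-Curtis dissimilarity exactly (asserted to 1e-9 under fuzzing). Ties
  in the ranked table break lexicographically by variable name.
* **Kruskal-Wallis** uses mid-ranks and the tie correction
  C = 1 − Σ(t³−t)/(N³−N); the chi-square P comes from the χ² survival
  function (df = k−1), the optional Monte-Carlo P from label shuffles with
  the +1 convention. On the bundled cavity counts the permutation P
  (~0.014) and the chi-square P (~0.0146) are both slightly below the
  published 0.0185; the exact enumeration over all C(12,4) = 495 splits
  gives 7/495 = 0.0141, so the published value was presumably a
  Monte-Carlo estimate under a slightly different convention. Both P
  values are always reported.
* Group-label permutations are vectorized (argsort of uniform draws), and
  all permutation procedures are reproducible given a seed and invariant
  to input row order.

## Composition statistics

Fractions are percentages over the 20 standard residues; ambiguity codes
are excluded from numerator and denominator. Class fractions use the
overlapping EMBOSS PEPSTATS sets (charged ⊂ polar; polar ∪ hydrophobic =
everything), so the three classes do not sum to 100.

A "paired" t test between groups of ~10⁵ proteins is not well defined at
the protein level, so the default is a **Welch two-sample test on
per-species means** (each protein weighted equally within a species;
a pooled, length-weighted species profile is available as a flag). Student
and paired modes are provided; paired mode requires matched unit lists and
raises on zero-variance non-zero differences. Raw P values are primary —
consistent with significance-starred box-plot conventions —
Benjamini-Hochberg adjustment is an optional flag. Reported significance
levels are α = 0.05, 0.01, 0.0001.

## Hallmark filter

The five A1A signatures D[TS]G, Y, XXG, D[TS]G, XXG (X hydrophobic:
A, F, I, L, M, V) are searched greedily left to right, each motif strictly
after the end of the previous match. Greedy earliest matching cannot
produce a false negative for this motif set relative to exhaustive ordered
search — this is asserted by comparing against a brute-force
all-combinations oracle on fuzzed sequences, not assumed. The "Y" hallmark
is a single tyrosine anywhere after the first D[TS]G (no context window),
and no minimum spacing between the two catalytic lobes is imposed; both
are documented limitations of a pure sequence scan.

## Structure metrics

Cavities are counted on a regular voxel grid (default resolution 0.8 Å):
voxels within (van der Waals radius + probe radius, default probe 1.4 Å)
of an atom center are occupied; empty space is labeled by 6-connected
components; components touching the grid boundary are exterior; interior
components of ≥ `min_voxels` (default 5) voxels are cavities, with volume
= voxel count × res³. Absolute counts on real models depend on these
parameters — any grid method shares this property — so group comparisons
must hold them fixed, and the bundled 12-structure metric table is used
for the published statistical comparison rather than re-deriving its
cavity counts from coordinates. Surface-area and volume columns of that
table are carried as data but never recomputed: their units in the source
are not interpretable as molecular surfaces.

Molecular weight is the sum of average residue masses plus one water
(18.0153 Da), in kDa. Net charge is Henderson–Hasselbalch with the EMBOSS
pKa set (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8,
R 12.5, Y 10.1); pI is found by bisection on pH ∈ [0, 14] to |charge| <
1e-4 in ≤ 60 iterations (charge is monotone non-increasing in pH, so
bisection is guaranteed). Secondary structure comes from HELIX/SHEET
record counts only — no DSSP-style assignment from coordinates.

## Synthetic data: what it emulates, and what it does not

* **Background proteins** are i.i.d. residue draws from a Swiss-Prot-like
  frequency vector with an optional additive shift (clipped at 0,
  renormalized); lengths are log-normal with median 400. This is
  sufficient for compositional statistics — which only see counts — but
  has no positional structure, domains or homology, so passing tests say
  nothing about, e.g., alignment behavior on real paralogs.
* **The thermophilic shift** raises A, E, G, P, R, V by +0.005 each and
  lowers C, H, I, K, M, N, Q, S, T, W by 0.003 each (D, F, L, Y
  untouched; the vector is balanced). The directions mirror the reported
  mesophile→thermophile signature; the magnitudes are generator
  parameters — the source reports directions and significance, not
  per-residue effect sizes — chosen once as a clearly detectable but
  sub-percent perturbation.
* **Peptidase homologs** are reference members mutated by uniform
  substitution over the 19 alternatives, no indels by default — this keeps
  identity and coverage semantics exact. Reference families descend from
  a common ancestor at 5% substitution, giving ≤ ~10% within-family
  divergence.
* **Count matrices** are gamma-Poisson (negative binomial): variance
  μ + φμ² with dispersion φ (default 0.2, matching the spread of real
  species-level counts; φ = 0 gives exactly Poisson). At φ = 0.2 a
  50% knock-down of the largest category is detected (ANOSIM R > 0) in
  ~92% of 8-vs-13 replicates; detection is dispersion-limited, reaching
  ~100% at φ ≤ 0.05.
* **Structures** are jittered cubic lattices of carbon atoms (spacing
  1.8 Å ≤ 2 × probe radius, so shells are watertight at the default grid)
  with spherical interiors of radius 8 Å carved out around well-separated
  centers — exactly n disjoint voids by construction.
* **Hallmark sets** draw background from an alphabet without D and G, so
  no accidental motif can form; positives plant all five motifs in order,
  negatives omit exactly one motif class (the no-Y variant also strips Y
  from the background). Truth labels are therefore correct by
  construction, independent of the scanner under test.
* Seed handling: every generator is bit-reproducible given (parameters,
  seed); nested generators derive independent child seeds via
  `SeedSequence` (`synthetic.derive_seed`) — reusing one integer seed
  across two generators would align their streams and leak reference
  sequences into "background" proteins.
* Not modeled: phylogenetic correlation between species, codon/GC
  structure, indels (optional nowhere yet), domain architecture.

## Problem sizes in tests and scripts

The replicated experiments run at deliberately moderate sizes chosen as
the package's own defaults: composition recovery uses 10 species per group
× 150 proteins (≈ 1.3 M residues per replicate, 100 replicates); ANOSIM
calibration uses 500 null matrices at 199 permutations (achievable P
values then sit on a grid of 1/200, making the 5% level exact under the
null); the cavity permutation P uses 5 × 10⁵ draws. Power at these sizes
is documented by the tests themselves (e.g. planted-shift recovery at
100%, a cavity-count shift of 2 detected in > 80% of 25-vs-25 designs).

## Known limitations

* Thresholds of the mining stage are conventions; absolute annotation
  counts move with them. They are logged, and truth-table recovery — not a
  published census — is the validation target.
* The composition test treats species as exchangeable units; real species
  share phylogeny, so effective sample sizes are optimistic there too.
  The synthetic generator reproduces that assumption rather than
  challenging it.
* Cavity counts are resolution- and probe-dependent; only within-run
  comparisons at fixed parameters are meaningful.
* pI assumes independent ionizable groups (no electrostatic coupling,
  no structural burial of side chains).
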