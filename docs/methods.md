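# Methods notes

## Model and assumptions

The pipeline rests on three modelling assumptions:

1. **Harmonic dynamics.** Collective motions are taken from an
   anisotropic network model: Cα nodes, uniform springs (γ, default
   1.00 kcal/(mol·Å²)) between nodes within a cutoff r_c (default
   15 Å). The Hessian's low-frequency eigenvectors approximate the
   functional motions; anharmonic effects, side chains, solvent and
   metal-specific force constants are outside the model.
2. **Dynamical fingerprints are local diagonal blocks.** A tile of
   length L is represented by the L×L diagonal block of its own
   protein's normalized cross-correlation matrix. Query and target
   blocks are compared directly — no superposition is ever performed,
   which is valid because correlation coefficients are already
   invariant under rigid-body motion (verified to 1e-8 in the tests).
   A cross-protein *off-diagonal* coupling comparison would be a
   different method and is deliberately not implemented.
3. **Fe–S chemistry as a hard filter.** A candidate region is only
   biologically plausible as a ferredoxin-like domain if it supplies a
   first-shell cysteine thiolate ligand; the filter keeps a tile iff
   some Cys SG lies within 2.18–2.35 Å of an iron (inclusive bounds,
   with a 1e-9 Å tolerance so exact boundary values cannot be flipped
   by float rounding). Cysteines with disordered (absent) SG fail the
   filter but remain in the model.

## Parameters that matter

| parameter | default | units | rationale |
|---|---|---|---|
| γ (spring constant) | 1.00 | kcal/(mol·Å²) | uniform-network convention; only sets the eigenvalue scale |
| r_c (cutoff) | 15 | Å | standard ANM contact range for Cα networks |
| retained modes | 10 | – | lowest non-trivial modes; rigid-body modes are excluded *before* counting (the standard convention; config-exposed) |
| tile length range | 6..N_query | residues | 6 is the smallest window that resolves a strand/short helix; the query length bounds the match size |
| landscape length cap | ⌊N_query/2⌋ | residues | the examination window used for island/path construction |
| cosine / sequence cutoffs | 0.5 / 50% | – | ranking-track thresholds; cosine is interpreted on its native [−1,1] scale |
| top fraction per length class | 20% | – | ranking-track selection (ceil, so a non-empty class keeps ≥1 pair) |
| Fe–S window | 2.18–2.35 | Å | canonical cysteine-thiolate Fe–S bond length range |
| BO budget | 15 random + 100 guided | calls | the optimization schedule for the metric weights |
| convergence | degree 5 poly, σ=2, window 5, eps 0.005 | – | smoothing of S′(L); all config keys |

Other fixed choices: Smith–Waterman uses BLOSUM62 with Biopython's
`PairwiseAligner` defaults for gap penalties (presets `zero` = 0/0 and
`blast` = −11/−1 are available via config); the sequence percentage is
rescaled to [0,1] before entering the weighted sum so all three metrics
share a scale; "correlation" in the weight objective is Pearson;
d_Frobenius,max is taken **per tile length** over all pairs of the run,
because the Frobenius distance grows with matrix size and a global
maximum would distort the Gower mapping across lengths.

## Weight optimization

The objective O(w) is the mean Pearson correlation of the weighted score
with each metric column, maximized over the probability simplex. The
surrogate is a zero-mean Gaussian process with squared-exponential
kernel; (σ², ℓ) are refit by maximum marginal likelihood at every guided
iteration (initialized at σ²=1, ℓ=0.2); expected improvement (in the
maximization form — the improvement term is mean − best) is maximized
over 2000 fresh uniform-simplex candidates per iteration. Random-phase
points are uniform on the simplex (Dirichlet(1,1,1)). A 1e-10 jitter
(escalated ×10 on failure, logged) stabilizes the Cholesky
factorization. Everything is driven by one seed and is exactly
reproducible.

A property worth knowing: because O rewards correlation with *every*
metric, a pure-noise metric does not get driven to zero weight. For two
identical signal metrics plus one noise metric the optimum is exactly
uniform weights (1/3 each, closed form), so "noise gets less weight" is
only true up to equality — the tests check non-dominance rather than
strict inequality.

## Pipeline wiring

Island construction uses the weighted-sum landscape of **all** scored
pairs at lengths 6..⌊N_q/2⌋ followed by the cysteine–iron mask; the
ranking thresholds (cosine ≥ 0.5, s_sw ≥ 50%, top 20% per length class)
form a separate selection track exported as `top_tiles.tsv`. Feeding
the thresholded subset into the landscape fragments islands (missing
(L, center) cells split contiguous runs) and is not what the method's
overview prescribes.

Per-island matching: the DP rows are the island's surviving tile
lengths in ascending order; the recurrence looks ±2 center columns into
the previous row, masked cells are −∞ (impassable), and every argmax
tie breaks toward the smallest column index so results are
deterministic. A row with no reachable cell terminates the path at the
previous row. The per-path S(L) series used for convergence is the
weighted-sum value at the path's step of each length (a path visits one
tile per length); the converged length is the smallest L whose
smoothed, rolling-averaged polynomial derivative falls below eps, with
a logged fall-back to the largest L when it never settles.

## Numerical choices

- Rigid-body modes: |λ| < 1e-8 × λ_max. A connected network has exactly
  6; any other count logs a warning and *all* sub-tolerance modes are
  discarded.
- Dense eigensolver below 500 residues, shift-invert sparse `eigsh`
  (σ = −0.01) above; both paths agree to 1e-6 (tested).
- The vectorized Frobenius distance uses the ‖q‖²+‖t‖²−2q·t identity;
  self-pairs therefore carry ~1e-8 cancellation noise instead of exact
  zeros.
- Even tile lengths use the floor convention center = start + (L−1)//2.
- Multi-model files: model 1 only. Insertion-coded residues are kept as
  distinct residues in file order. Altlocs resolve to highest
  occupancy. Biological assemblies are not expanded — analyses operate
  on the file as given, so supply an assembly file if that is the
  intended unit.

## Synthetic fixtures: what they do and do not show

The generator builds idealized Cα traces (helix: rise 1.5 Å/res, 100°
twist, 2.3 Å radius; hairpin/βαβ-like mixed folds from 3.8 Å-spaced
strands) with ferredoxin-style cysteine clusters (relative positions
8/11/14 and L−9/L−6/L−3), SG placed 2.8 Å off the Cα and one iron per
cysteine at 2.25 Å from the SG. The embedded fixture concatenates exact
domain copies behind cysteine-free coil linkers (default: 40-residue
mixed-fold domain, two copies, 30-residue linker), applies optional
Gaussian coordinate noise (default study condition 0.3 Å RMSD), and
plants the irons *after* the noise because real Fe–S bond lengths are
chemically rigid.

Passing the planted-domain tests therefore shows that the machinery —
ANM, tiling, weighting, filtering, segmentation, DP, mapping — recovers
exact duplicated domains under modest coordinate noise. It does not
show sensitivity to genuinely diverged sequences, to domains with
different internal packing, or to crystallographic artifacts; those
require real deposited structures. One fixture-specific artifact: the
thin coil linker makes the elastic network nearly one-dimensional
locally, which produces a few extra near-zero (mechanism-like) modes;
they fall below the rigid-body tolerance, are discarded with a warning,
and do not affect the retained spectrum.

## Problem sizes

Desk-scale runs use a 40-residue query against a ~110-residue target
(≈59k tile pairs over lengths 6..40), chosen so the full pipeline
completes in a few seconds per seed and the whole suite in about a
minute. The implementation handles real targets (thousands of residues)
through the sparse eigensolver and per-stage caching, but no result in
this repository depends on downloaded structures.

## Known limitations

- Harmonic ANM only: no anharmonicity, mass-weighting, or Gaussian
  network variant.
- Matches are reported without a statistical significance estimate
  (none is defined for the composite score).
- The off-diagonal reading of cross-protein tile coupling is exposed
  nowhere; only diagonal-block comparison is supported.
- PyMOL output is a selection/coloring script; no rendering is done.
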