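# Methods

## The conservancy model

An IgE-binding epitope is a short linear peptide (here 8–20 residues)
within a source allergen. Cross-reactivity risk is modelled purely at
the sequence level: an epitope is *conserved* in a homolog protein when
some ungapped window of the homolog differs from the peptide at no more
than `max_mismatch` positions. The scan is an exhaustive sliding-window
minimum Hamming distance:

- Every length-*L* window of the homolog is compared; ties in the
  minimum break to the smallest offset, so results are deterministic.
- A homolog shorter than the peptide has no window; this is a sentinel
  outcome ("no window"), reported distinctly from zero mismatches and
  counted as *not conserved* in every denominator.
- The ambiguity letter X is accepted in protein sequences and always
  scores as a mismatch — including against another X — a deliberately
  conservative treatment of database ambiguity codes. Epitope peptides
  themselves must use the 20 standard letters.
- No substitution-matrix weighting and no gaps: the model counts
  identities only. An auxiliary MSA-anchored mode (map the epitope's
  reference columns through an alignment and count mismatches in those
  columns, gaps counting as mismatches) exists for sensitivity
  analysis; the ungapped scan is the default and the only mode used in
  the shipped analyses.

`max_mismatch` defaults to 2 substitutions. Published conservancy work
on linear allergen epitopes alternates between tolerances of one and
two substitutions; we default to the more permissive 2 and keep the
threshold a first-class parameter of every operation, so a ≤1 analysis
is a parameter change, not a code change.

## Group aggregation

Presentation percentages use the *species* as the denominator unit:
multiple isoforms of one species are collapsed by taking the minimum
mismatch across isoforms before thresholding (a per-sequence mode is
available). A group's presentation for an epitope is
`100 × conserved_species / group_size`. Venn membership ("conserved in
a group") defaults to presentation > 0 — a single conserved species
suffices — because pan-epitope tables list group values as low as a few
percent. Region-level mollusc-class patterns instead use the stricter
> 50 % rule, matching how class-specific avoidance advice is framed.
Both thresholds are configurable and intentionally distinct.

Merged regions are unions of *overlapping* epitope spans (1-based
inclusive); adjacent-but-disjoint spans stay separate, since a region
is meant to be a contiguous stretch supported by overlapping epitope
evidence, not a bookkeeping interval. A region's per-class percentage
is the maximum over its member epitopes: a class reacts with a region
if any member epitope is conserved there.

The between-group comparison is a classical one-way ANOVA over
per-species conserved-epitope fractions grouped by taxon, computed
untransformed by default (an arcsine-square-root option exists). Only
the omnibus F is reported; no post-hoc contrasts. Degenerate inputs
(all within-group variances zero) raise rather than returning an
infinite F.

Heatmap clustering uses Manhattan (cityblock) distance with average
linkage on both axes; no-window sentinels are imputed as L+1 for an
epitope of length L — one worse than the worst realisable mismatch
count — before distances are computed.

## Residue-level grading

Per-column conservation grades (1 = variable … 9 = conserved) are
computed as sequence-weighted Shannon entropy with Henikoff
position-based weights, the gap as a 21st state, z-normalised across
columns and binned into 9 equal-width grades (grade 9 = lowest
entropy). If every column scores identically the alignment gets grade 9
when fully conserved and the neutral grade 5 otherwise. Grading
requires at least five sequences; smaller homolog sets are rejected.

This is an explicit methodological substitution: tree-aware empirical
Bayesian rate estimation (Rate4Site/ConSurf-style) is *not*
re-implemented. The entropy proxy provides the 1–9 grade interface and
its qualitative guarantees — invariant columns at grade 9, maximal
diversity at grade 1, monotone response to reduced diversity — but its
absolute grade distribution is not comparable to ConSurf output, and
published residue-count statistics from such tools are not reproduction
targets here.

## Relatedness

Pairwise distances are identity distances over an existing alignment,
`1 − matches/compared`, with pairwise deletion (columns gapped in
either sequence are skipped; a pair with no comparable columns is an
error). Trees are built by standard neighbor joining, implemented
in-package to guarantee two contract details: ties in the Q-criterion
break to the lexicographically smallest active-node index pair, and
negative branch lengths are clamped to zero with a warning. The
implementation is cross-checked in the test suite against an
independent NJ implementation and against brute-force topology
enumeration on four taxa. Bayesian and maximum-likelihood inference,
bootstrap support and alignment construction are out of scope.

## Decision tree

The tree has two serology branches. TM positivity requires both the
conventional clinical cutoff (sIgE ≥ 0.35, arbitrary units,
configurable) and TM sIgE "similar to" the whole-extract sIgE,
operationalised as `tm/extract ≥ 0.7` (configurable; no published
number exists for this ratio, and extract = 0 counts as dominant). On
the TM branch, reactive regions are checked in the fixed priority order
all_mollusc > cephalopod_gastropod > bivalve_cephalopod, so the
broadest predicted avoidance dominates; no hit means crustacean
mono-reactivity. A TM-positive but non-dominant profile falls through
to the AK branch — the tree's internal node order beyond the two main
branches is only loosely constrained by the source material, and this
fall-through is our design choice: without immune-dominant TM
sensitization, TM-epitope reactivity is not treated as predictive. On
the AK branch only the designated cephalopod-conserved AK region can
upgrade the call (to crustacean_cephalopod_AK). Neither branch positive
yields none_detected. Exhaustive enumeration over boolean region
profiles and serology signs reaches exactly 4 classes on the TM branch
and 5 over both (excluding none_detected).

Region definitions for the tree are meant to be computed from data
(`merge_epitope_regions` + `classify_regions` +
`config_from_regions`); `default_config()` is a generic
one-region-per-pattern configuration for testing and illustration.

## Synthetic families

The simulator emulates the structure that makes an invertebrate
pan-allergen family analytically interesting: a 284-residue ancestor
(the length of shrimp tropomyosin) with conserved blocks at both
termini (defaults 1–42 and 243–284, mirroring tropomyosin's conserved
N-/C-terminal regions), four taxonomic groups — 18 crustacean, 6
cockroach, 6 mite, 30 mollusc species, molluscs split evenly into
bivalve/cephalopod/gastropod — and 15-mer epitopes tiled at step 3, the
typical overlapping-peptide-library geometry.

Each species derives from the ancestor by independent per-site
substitution: probability `p_outside` (default 0.3 for every group)
outside conserved blocks and `q_inside` (default 0) inside; the
replacement residue is uniform over the other 19, so a substituted site
always mismatches the ancestor. With these defaults, a fully in-block
15-mer is conserved in 100 % of species while a fully out-of-block
15-mer survives a ≤2-substitution test with probability
P[Bin(15, 0.3) ≤ 2] ≈ 0.10, giving the large in/out presentation gap
the recovery analyses rely on. A `divergence_hierarchy_params()` preset
instead grades out-of-block divergence crustacean < cockroach < mite <
mollusc for relatedness and clustering exercises.

Because substitutions are site-independent with no indels, the ungapped
scan is the *exactly correct* matching model, and a brute-force oracle
(pure-Python character loops, deliberately sharing no code with the
pipeline) can compute exact ground truth for every epitope × species
pair. An optional indel mode exists for robustness exercises but is
excluded from oracle-equivalence guarantees. Species within a group are
drawn independently (a star phylogeny); hierarchical families are built
by pre-diverging per-group ancestors via the explicit-ancestor argument
and simulating each group from its own ancestor.

What the simulator does **not** emulate — and what passing tests
therefore do not establish about real data: indel variation and
alignment uncertainty, substitution-matrix-structured amino-acid
preferences, site-rate heterogeneity beyond the two-rate block
structure, phylogenetic correlation within groups (in the default
scenario), realistic isoform structure, and any property of actual
patient IgE repertoires. Tests against simulated truth validate the
*code*; the packaged published tables validate the arithmetic on real
epitope data.

## Problem sizes and determinism

The shipped analyses run at desk scale: the default simulated family is
60 species × 284 residues with 90 tiled epitopes (a full scan plus
oracle takes ~1–2 s), oracle cross-validation uses 1000 random
peptide/protein pairs (L ≤ 20, protein ≤ 400) plus every cell of one
full family, and monotonicity sweeps cover seven thresholds. All
randomness flows from a single integer seed (`numpy.random.default_rng`);
CLI artifacts embed a provenance record (parameters, package version,
input hashes) and are byte-identical across reruns with the same seed.

## Known limitations

- Linear epitopes only; conformational epitopes are outside the model.
- Ungapped matching cannot credit homologs whose epitope copy contains
  an indel; the MSA-anchored mode mitigates this only as well as the
  supplied alignment does.
- The entropy grading is not ConSurf-comparable (see above).
- Presentation percentages inherit whatever taxon sampling bias the
  input homolog set carries; the package reports the denominator
  (group sizes) alongside every table so this is auditable.
- The decision tree encodes sequence-conservation reasoning only. It
  carries no clinical validation and must not be used for diagnosis.
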