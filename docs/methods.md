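# Methods

## Scope and data model

`cyclodesc` characterizes cyclic knotted peptides by five surface
descriptors (L_S, L_S*, L_M, E_S, E_M), fits a dummy-variable QSAR with a
grid-searched critical point, clusters peptides in descriptor space, and
applies cladogram rules for homology-template selection.  Structures
enter as single-model PDB files (hydrogens optional); homology modeling
itself — alignment, tree construction, model building and refinement — is
out of scope: modeled structures and bootstrap trees are *inputs*.

A peptide is an ordered residue list; side chains are defined from Cβ
onward (Cα and backbone N/C/O and their hydrogens are never side-chain
atoms).  Van der Waals radii come from a single uniform table (Bondi
1964).  For cyclic-cystine-knot peptides, loop *k* is the segment
strictly between Cys *k* and Cys *k+1*, with loop 6 wrapping across the
ligation point (split at the termini for linear peptides); cysteines
carry no loop id.

**Loop anchor.** Loop numbering needs a loop-1 cysteine.  The field
convention — "the file starts at the loop-1 Cys" — is not invariant to
cyclic rotation of the residue order, so the default anchor is canonical:
the cysteine whose rotation yields the lexicographically smallest code
sequence.  This makes loop memberships independent of where a cyclic
sequence was cut.  When the biological numbering is known, pass
`assign_loops(pep, anchor=...)` explicitly; the canonical choice can
differ from the biological one for sequences whose rotations tie or sort
differently.

## Lipophilicity scale

Raw side-chain logP values map through two affine steps:
`scaled = (raw + 3.800)/6.457` (anchors: Arg⁺ at 0, Ile at 1, since
6.457 = |−3.800| + |2.657|) and `normalized = scaled − scaled(Gly)`, so
Gly is exactly 0 and the Ile−Arg⁺ difference is exactly 1.  The packaged
scale stores the normalized column directly — raw logP values are not all
recoverable and only normalized values are consumed downstream — together
with each residue's maximal side-chain SASA.  Users may extend the scale
from raw values (`add_raw`) or a TSV file; four modified residues are
packaged (acetyl-Lys, cyclohexanedione-Arg⁺, kynurenine, methyl-δ-Glu).

Ionizable residues enter at pH 7.4: His is the Henderson–Hasselbalch
mixture of imidazolium and neutral forms (pKa 6.50 by default, which
gives 11.2%/88.8% at pH 7.4); half-cystine carries half the cystine
lipophilicity.

**Maximal side-chain SASA** is the side-chain area of X in an extended
Gly-X-Gly tripeptide (Φ = ψ = ω = 180°, ideal bond geometry).  Side
chains come from bundled idealized residue templates grafted onto the
built backbone via superposition of the N/CA/C frame; side-chain
hydrogens are included (heavy-atom-only areas run systematically ~25%
low against the packaged reference values).  Because the radii set,
rotamer library and probe radius behind the packaged reference column are
not fully specified, recomputed values agree with it only to ~10–20%
(Ala 76.3 vs 65.85 Ų, Trp 247.9 vs 229.66 Ų); the packaged column is
therefore the ground truth used by the descriptor pipeline, and
recomputation is a consistency check, not a round trip.

## Surface sampling and electrostatics

SASA uses the Shrake–Rupley construction: 960 quasi-uniform points
(golden spiral) per probe-inflated sphere (probe 1.4 Å), a point is
exposed when outside every neighbouring sphere, and each exposed point
carries area weight 4π(r+probe)²/n.  The exposed-point set is retained —
it is the substrate of the electrostatic descriptors and can be exported
as TSV.

The quadrature point set is anchored to a molecule-covariant frame
(principal axes of the atom cloud, axis signs fixed by third moments of
the projections).  This makes the sampled surface rotate rigidly with the
molecule, so all areas and descriptors are rigid-motion invariant to
numerical precision rather than to quadrature resolution (~0.1% at 960
points).  The frame is indeterminate for exactly symmetric atom clouds;
such inputs remain deterministic but their invariance degrades to
quadrature resolution.

Electrostatic potential at a sample is a screened Coulomb sum
V = Σ q_j/(ε(r)·r) with the distance-dependent dielectric ε(r) = 4r, i.e.
q/(4r²), with formal charges (Arg⁺/Lys⁺ +1, Asp⁻/Glu⁻ −1, His neutral by
default, Cdr⁺ +1, Ack 0) shared equally over the charged group's terminal
heavy atoms.  Distances below 0.1 Å are clamped with a warning.  The
potential model is an implicit-screening convention, not a
Poisson–Boltzmann solution: only the sign pattern and relative magnitudes
are meaningful, so absolute E_S values are defined by this artifact.

A sample belongs to the **HBD surface** when its owner atom is a donor
atom of a positively charged side chain (or a hydrogen on one) *and* the
local potential is positive — a lysine surrounded by carboxylates loses
HBD area.  E_S is the summed area of that surface; E_M is the distance
between the area-weighted HBD centroid and the area-weighted centroid of
the surface owned by uncharged lipophilic residues (zero if either set is
empty).  E_M is the bare centroid distance, with no extra
area-proportional factor.

## Descriptors

Lipophilic intensity, direction and the five descriptors are defined in
the README.  Conventions worth stating:

* L_M is normalized by residue count, making it length-independent and
  comparable across 28–31-residue peptides; the default grid bound 0.050
  reflects this scale and is configurable.
* The "lipid-attractive region" for L_S* is the hemisphere of positive
  projection on the lipophilic resultant — the only direction the model
  defines.  A vanishing resultant triggers a flagged fallback (sum of all
  positive intensities).
* Directions use the unweighted side-chain heavy-atom centroid; Gly and
  zero-intensity residues contribute nothing, so their direction is moot.
* The pipeline is fully deterministic: recomputation is bit-identical.

## QSAR

Relative potency is x = IC50(reference)/IC50(peptide) — larger means more
potent — so censored records ("> highest tested concentration", 11.5 µM
in the anthelmintic assay) map consistently to x = 0.  The *classification*
ratio keeps the opposite orientation (IC50/IC50_ref, <0.2 → A2,
0.2–1.0 → A1, >1 → A0, unknown → An); the two orientations are
deliberate, as each matches how the corresponding rule is stated.
Transforms: y = log10(x+1) (λ = 1) keeps censored records at exactly 0;
the λ = −0.5 Box-Cox path uses the shifted power (x+1)^(−0.5), which is
finite at x = 0 and order-inverting (composing a power with log10(x+1)
would diverge at 0, so the shifted-power reading is used).

The regression is OLS of y on [1, τ·L_S*, τ·E_S] with
τ_ii = 0 iff both moments are *strictly* below the critical point
(boundary counts as "not below").  Reported statistics: r²; LOO
q² = 1 − PRESS/TSS via the hat-matrix identity e_(i) = e_i/(1−h_ii);
F = (SSR/2)/(SSE/(n−3)) against the 95% quantile of F(2, n−3).
Studentized residuals are available for outlier *flagging*; exclusions
are always explicit (`refit_excluding`), never automatic.

**Grid search.**  Default 17×17 nodes over [0, 0.050] × [0, 9.000]
(step = range/16, chosen because the reference critical points
(0.03750, 4.5000) and (0.02813, 5.6250) are integer multiples of those
steps).  Every node is fitted; the objective is q² with r² tie-break,
then lowest node index.  Degenerate nodes (all τ = 0, or rank-deficient)
are skipped with a warning.  The node (0, 0) reduces exactly to the
no-dummy linear model.

**Breakpoint identifiability.**  Adjacent grid nodes are observationally
equivalent whenever no record's moments fall in the strip between them:
they induce identical τ vectors, hence bit-identical fits, and no
tie-break can distinguish them.  At n = 60 over the default grid this
happens in a substantial fraction of samples, so "recovering" a planted
breakpoint is defined up to this equivalence — the recovered node must
classify every record the same way as the planted one.  Under that
definition recovery is essentially certain at σ = 0.02; the coefficients
l and m are recovered to a few percent median relative error.

## Clustering and template selection

Descriptors (E_M, E_S, L_M, L_S*) are min-max normalized per column to
[0, 1] (constant columns map to 0 with a warning).  Min-max rather than
z-scoring matches a bounded "relative distance" dendrogram axis; the
choice is a package convention.  Clustering is Ward's minimum-variance
criterion via the reciprocal-nearest-neighbour chain algorithm with the
Lance–Williams update; Ward's reducibility guarantees the same dendrogram
as globally-greedy merging, which the tests verify against both a naive
Lance–Williams implementation and an established linkage routine.  Merge
output follows the standard linkage-matrix convention; trees export to
Newick with height-difference branch lengths, and `cut(tree, k)` yields
k groups.  Leaf labels follow the `G{group}-A{class}-{subfamily}{num}`
style.

Template selection takes a Newick tree with bootstrap supports as
internal-node labels.  Rules: known sister leaf with support > 50% → that
leaf alone; support ≤ 50% (50 exactly is deliberately conservative) → the
sister plus the nearest other known leaf (topological edge count, ties
alphabetical); a two-leaf fully known sister clade → both, regardless of
support; a sister clade with ≥2 known leaves otherwise → two drawn
uniformly at random from a seeded generator; fallback → nearest known
leaf.  Selection is deterministic given (tree, target, seed) and
unaffected by relabeling unknown leaves.

## Synthetic generators

`make_toy_peptide` places pseudo-residues (backbone CA plus a single
side-chain sphere) on a sphere of radius 10 Å; a segregation parameter
in [0, 1] interpolates between random residue placement and a perfect
hemispheric split (lipophilic residues at +z, charged at −z).  Defaults —
30 residues, 40% lipophilic, 3 charged — mirror a cyclotide-like
composition.  These toys have analytic surface oracles but no backbone
connectivity, no packing, and single-sphere side chains: tests passing on
them validate the descriptor algebra and surface machinery, not the
realism of any particular structural model.  `make_cck_toy` builds a
cyclic ring with six cysteines for exercising loop annotation.
`make_qsar_dataset` draws descriptors uniformly over ranges spanning the
search grid (L_S* ∈ [0, 4], E_S ∈ [0, 300] Ų, moments over the full grid)
and generates responses from the model equation with Gaussian noise —
a synthetic twin whose planted parameters anchor the recovery tests.
The packaged activity table ships with the library (75 peptides, IC50s
with censoring flags); it yields 47 anthelmintic and 30 cytotoxic
quantitative records.

All generators are reproducible by seed; identical seeds give
bit-identical output.

## Problem sizes and numerical choices

Quadrature: 960 points/atom (configurable; rejected below 16), probe
1.4 Å.  Recovery simulations use n = 60 records, σ = 0.02, 100
replicates; clustering checks use n ≤ 20 instances against the naive
oracle and 12-peptide populations over 50 seeds for the two-group moment
split.  Ties in τ at the critical point resolve to 1; ties in the grid
objective resolve by r², then lowest node index; nearest-template ties
resolve alphabetically.  Degenerate inputs (empty residue lists, zero
resultants, constant descriptor columns, all-τ-zero nodes) either return
the documented neutral value with a warning or raise a typed error —
never silently guess.

## Known limitations

* Absolute descriptor scales (especially E_S, E_M and the L_M grid
  bounds) are artifact conventions; published reference values computed
  with proprietary surface/potential engines and unpublished homology
  models are not numerically reproducible here, and no test claims they
  are.
* The electrostatic model is a screened point-charge sum; no partial
  charges, no Poisson–Boltzmann.
* Peptide termini are treated as uncharged by default (appropriate for
  cyclic peptides); configure charge shares manually for linear species
  if needed.
* Mutant nomenclature in activity labels (e.g. `[T20K]-kB1`) is treated
  as opaque; positions are not parsed and mutant structures are not
  reconstructed.
* The canonical loop anchor can disagree with biological loop numbering;
  supply the anchor explicitly when it matters.
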