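# Methods

## Scope and data model

herbnet analyses a multi-herb formula in five stages: (1) rule-based ADME/T
filtering of the ingredient library, (2) ligand-based target fishing by 3D
shape similarity, (3) mapping predicted targets onto a disease protein set
and decomposing per-herb target sets into Venn regions, (4) bipartite
network construction with degree statistics, (5) hypergeometric functional
enrichment with module clustering. Molecules are single-conformer heavy-atom
clouds: element, Cartesian coordinates (Å), van der Waals radius (Å).
Hydrogens are suppressed on input by default (united-atom shape comparison,
standard in shape screening). Radii come from a built-in Bondi-style table
(C 1.70, N 1.55, O 1.52, S 1.80, P 1.80, halogens per lookup, 1.70
fallback); a custom table can be passed to the readers. Only V2000 SD files
are read; V3000 is rejected with a clear error.

## ADME/T filter

A compound is removed iff `solubility_level < −8` (strict) OR
`bbb_level == 3` OR `cyp2d6` OR `absorption_level == 3`. The boundary
semantics are deliberate: −8 exactly is retained, BBB/absorption are ordinal
equality tests on the "worst" level. All violated codes are reported, so
per-rule attrition is auditable. A record with a missing descriptor value is
removed with code `MISSING` and a warning — conservative, since an
unevaluable compound cannot be certified drug-like. Thresholds are
`AdmetThresholds` fields, never hard-coded downstream.

## Gaussian shape engine

Atom *i* contributes `ρᵢ(r) = wᵢ p exp(−αᵢ|r−cᵢ|²)` with amplitude
`p = 2.7` and `αᵢ = π (3p / 4πRᵢ³)^{2/3}`, fixed so the Gaussian's integral
`p(π/αᵢ)^{3/2}` equals the hard-sphere volume `(4/3)πRᵢ³`. The molecular
density is the plain sum of atom Gaussians (first order), giving the
closed-form pair overlap used throughout:

    O_AB(t) = Σᵢⱼ wᵢwⱼ p² (π/(αᵢ+αⱼ))^{3/2} exp(−αᵢαⱼ dᵢⱼ(t)²/(αᵢ+αⱼ)).

Summing Gaussians over-counts density where atoms interpenetrate. The
default *weighted* mode compensates: `wᵢ = Vᵢʰˢ / Σⱼ Vᵢⱼ`, where the
normaliser's diagonal term is the atom's own Gaussian volume (= `Vᵢʰˢ` by
construction) and off-diagonals are the unweighted closed-form pair
overlaps; weights are clipped to (0, 1.2]. An isolated atom keeps weight
exactly 1; interpenetrating atoms are down-weighted so the molecule's
self-overlap tracks its hard-sphere volume. Similarity is the
shape-Tanimoto `T = O_AB / (O_AA + O_BB − O_AB) ∈ [0, 1]`; Cauchy–Schwarz
guarantees T ≤ 1.

Only the steric (shape) channel is scored. Chemotype/pharmacophore ("static
feature") scoring that some shape-screening tools blend in is intentionally
not implemented; the 0.8 screening threshold applies to the pure
shape-Tanimoto.

### Superposition optimiser

Deterministic, no randomness in the default path:

1. centre both shapes on their Gaussian-weighted centroids and rotate into
   the principal axes of the Gaussian-weighted inertia tensor (eigenvalues
   descending; per-axis sign fixed by the largest-magnitude component;
   right-handedness enforced);
2. start from the four handedness-preserving axis flips
   (identity, and 180° about x, y, z). When two adjacent inertia
   eigenvalues of either shape are within 20% of each other, the principal
   frame is rotationally ambiguous in that plane, so 45°/90°/135° rotations
   about the complementary axis are composed onto each flip and added as
   starts — without these, near-spherical molecules occasionally converge
   to a local optimum (about 1 in 200 jittered copies in our screens, where
   seeded random-restart search confirms the global optimum);
3. refine each start by L-BFGS-B on (quaternion, translation) with analytic
   gradients (the quaternion is kept unnormalised in the parameter vector;
   the objective normalises it and the gradient is projected onto the unit
   sphere's tangent), relative function tolerance 1e-6, at most 200
   iterations; the best converged start wins.

Degenerate shapes (single atoms, all-coincident centres) skip rotation and
optimise translation only. The returned transform maps the query's original
frame onto the reference's, and the reported overlap is clipped into
[0, min(O_AA, O_BB)] to absorb last-digit numerical overshoot.

The closed form is validated against an independent 3D grid quadrature of
the product density (0.1 Å spacing, 4 Å padding) — agreement is at
machine precision for the first-order density, so the 2% test tolerance
covers only discretisation error.

## Target fishing

Per-target score = maximum shape-Tanimoto over that target's reference
ligands (monotone under library growth); a target is predicted at score
≥ threshold (default 0.8). Results are sorted by descending score with
lexicographic tie-break, so output order is total and stable. Disease
mapping normalises identifiers by upper-casing and whitespace-stripping; no
alias/ortholog resolution is attempted. The reported disease fraction is
`100 × |distinct predicted targets ∩ disease| / |distinct predicted
targets|`, rounded half-up to two decimals. The Venn decomposition supports
2–6 sets and returns exclusive region counts, which provably sum to the
union size.

## Networks

Nodes are typed (herb / compound / target / function_module); edges must
join distinct classes, with no self or duplicate edges. The compound–target
network includes herb-membership edges for orientation, but degree
statistics for a class pair count only edges of that pair — so the
compound/target means are `E/276`-style exact rationals, rounded half-up to
one decimal (two decimals for modules-per-target in the target–function
network). Sub-network extraction induces on the chosen nodes plus their
target-class neighbours and never adds edges. Exports are Cytoscape-ready
node/edge TSVs plus optional GraphML.

## Enrichment

Upper-tail hypergeometric p per term via `scipy.stats.hypergeom.sf`;
query identifiers outside the background are dropped with a logged count.
Terms with raw p < 0.05 are kept, mirroring the common annotation-browsing
convention; a Benjamini–Hochberg mode exists behind a flag (off by
default). Enriched terms are grouped into functional modules by
single-linkage over the Jaccard index of their protein sets at threshold
0.5 (configurable): modules are the connected components of the threshold
graph, labelled by their most significant term. This is a deterministic,
oracle-testable replacement for service-side annotation clustering
(kappa-statistic based), so published module counts are treated as
generator ground truth, not as a reproduction target.

## Synthetic data

The generators define the study conditions and are first-class, tested
code. One global seed fans out to fixed per-artifact child seeds (library
+1, screen +2, descriptors +3, annotations +4) so any artifact regenerates
independently; all file output uses fixed-precision text, so identical
specs give byte-identical bundles.

* **Molecules** are geometry-only Gaussian clouds (sd 1.8 Å, drug-like
  radius of gyration) with a 1.2 Å nearest-neighbour floor enforced by
  rejection (error after 1000 failures), elements drawn from {C, N, O, S}
  at 70/10/15/5%; 8–16 heavy atoms per molecule. No valence or bonding
  realism — the pipeline consumes only coordinates and radii.
* **Screen sets** plant actives as library templates with per-coordinate
  Gaussian jitter (default sd 0.05 Å) plus a random rigid motion, so the
  optimiser is genuinely exercised; decoys are fresh clouds. Compounds are
  assigned round-robin to herbs. Defaults: 5 targets × 2 ligands,
  20 actives, 20 decoys, 6 herbs.
* **Descriptor tables** plant per-rule violations independently at the
  spec'd rates (default 15% per rule, giving ≈ 48% overall removal —
  comparable to the roughly half attrition seen in real formula
  libraries), with violating values just past each threshold (e.g.
  solubility in [−12, −8.2]) and safe values well inside.
* **Annotation databases** plant `module_blocks` blocks of terms whose
  bases are disjoint slices of the in-universe disease pool; per-term
  variation (drop one member / add one filler) is applied only when the
  base is large enough that within-block Jaccard provably stays ≥ 0.5,
  while between-block Jaccard stays near 0. Null terms drawn from
  background filler calibrate the p < 0.05 cut. The disease set covers
  `disease_fraction` of the target universe plus filler proteins.

What passing tests on this data do **not** show: robustness to conformer
flexibility, tautomers/protonation, real pharmacophore chemistry, gene-ID
aliasing, or annotation DAG structure — none of which the generators
emulate.

### Published-count fixtures

Supplementary tables behind several published summary numbers are not
deposited in machine-readable form, so deterministic synthetic stand-ins
realize the printed counts exactly and the package's operations recompute
the summaries from them: a greedy largest-margin-first set system for the
five-herb Venn (sizes 149/146/120/146/142, union 156, common core 116), an
even-quota strided bipartite graph for the 13,914-edge compound–target
network (6 + 276 + 156 nodes) and the 516-pair target–function network
(145 targets, 8 modules), and a descriptor table reproducing per-herb
retention 88/98/7/15/54/67 of 688 (the per-herb *input* split is not
published, so the 359 removed compounds are spread evenly across herbs).
These fixtures pin identities arbitrarily; only the set/graph arithmetic is
meaningful.

## Problem sizes and numerical choices

Tests and the acceptance script run the screening stages at the default
generator scale (5 targets × 2 ligands, 40 compounds, 10 seeds — about
4,000 optimised superpositions), which keeps full-suite wall time at a few
minutes while still exercising every optimiser branch. Rounding for
reports is half-up (`decimal`), raw values are kept internally. Tie-breaks
are lexicographic everywhere ordering matters. Degenerate inputs
(single-atom molecules, empty association maps, unannotated targets, empty
enrichment after the p-cut) are handled explicitly rather than erroring
mid-pipeline; genuinely invalid inputs (empty library, threshold outside
(0, 1], >6 Venn sets) raise typed errors.

## Known limitations

Single conformer per compound; rigid alignment only; shape-only similarity
(no feature/colour channel); flat term sets (no GO topology); no
multiple-testing correction by default; identifier matching is plain
symbol equality. The pipeline's published-scale arithmetic is reproduced on
fixtures, not on the original proprietary inputs, which are not deposited.
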