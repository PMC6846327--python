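# Methods

## Problem and model

The pipeline assesses missense substitutions on a single protein (the
610-residue menin isoform is the motivating case) by their predicted effect
on fold stability.  An external empirical force field (FoldX or equivalent)
supplies one ΔΔG observation per structure chain per substitution; the
pipeline's contribution is everything around those observations: group
labelling, ensemble aggregation, solvent-accessibility context, and
classification evaluation.

A variant's assessment is the arithmetic mean ΔΔG over all chains resolving
its position (the median is available as an option), with the sample SD and
chain count reported alongside.  Variants resolved by no structure are
omitted rather than scored.  The conventional "strongly destabilizing" call
uses ΔΔG > 3 kcal/mol, with a more conservative call at > 4 kcal/mol; both
are strict inequalities here, configurable, with boundary cases logged.
The force field's quoted uncertainty (±0.8 kcal/mol) is surfaced as a fixed
annotation and deliberately not propagated statistically — the downstream
use is a coarse threshold, not an error-weighted estimate.

## Variant layer

Group labels derive from database membership booleans carried in the input
TSV: disease-mutation-only → pathogenic; population-database-only → benign;
both → uncertain; neither → unlabeled.  An optional `group` column
overrides the derived label, which is how novel clinical variants (absent
from every database) are tagged.  The 615-residue minor isoform's five
extra residues are taken to occupy positions 149–153 (inserted after
residue 148); the register is configurable because the insertion point is a
convention, and positions inside it raise a no-equivalent error rather than
being silently shifted.  Nucleotide-level records encoding the same protein
change are merged: allele frequencies are summed over the merged alleles,
REVEL scores averaged, and a reference-residue disagreement at a position
is an error.  When merged records disagree on group label the most severe
label is kept (pathogenic > uncertain > novel > benign > unlabeled) with a
warning; the alternative — recomputing from merged membership — would
require carrying membership through the merge for a case that clean inputs
never produce.

## Structures and superposition

PDB parsing is delegated to Bio.PDB and converted into lightweight
containers carrying van der Waals radii (C 1.70, N 1.55, O 1.52, S 1.80,
H 1.20 Å; overridable).  Waters and HETATM records are excluded, only the
first MODEL is read, the highest-occupancy alternate location is kept (tie
→ first in file), and elements are inferred from atom names when the
element column is blank.  Superposition is the Kabsch SVD construction on
Cα atoms paired by residue number, with the reflection corrected to a
proper rotation; point sets that are coincident or collinear (smallest
meaningful singular value below 1e-8 of the largest) raise a degeneracy
error rather than returning an arbitrary transform.

## Solvent accessibility

Accessibility is computed by Shrake–Rupley sampling rather than DSSP's
implementation: each atom's solvent-expanded sphere (radius + 1.4 Å probe)
is covered with a deterministic golden-spiral point set (960 points/atom by
default) and a point counts as exposed when outside every other atom's
expanded sphere.  The choice is deliberate: a sampled SASA is verifiable
against closed forms (isolated sphere, two-sphere spherical caps, both held
to 1% in the tests), and the downstream consumer is a coarse RSA < 0.2
burial threshold that is insensitive to the small systematic differences
between SASA implementations.  Hydrogens are ignored by default since
crystal structures rarely resolve them.

Because the point set is fixed, a naive implementation would give slightly
different areas for the same structure in different orientations.  By
default coordinates are therefore first expressed in the structure's own
principal-axis frame (covariance eigenvectors, signs fixed by the first
clearly off-plane atom so the frame co-rotates with the data), making
results rigid-motion invariant for generic structures.  `orient=False`
keeps the raw laboratory frame; in that mode adding atoms can only remove
exposed sample points, so occlusion monotonicity and the "binding can only
occlude" ΔRSA ≤ 0 property hold exactly, and complex-vs-isolated
comparisons should use it so both runs see an identical grid.

RSA is the mean absolute residue area across the representative structures
divided by the residue type's theoretical maximum area (Tien scale,
transcribed into `MAX_ASA_TIEN`); averaging precedes normalization.  RSA
may exceed 1.0 and is reported uncapped.  Burial is RSA < 0.2, strict.

## Evaluation layer

The positive class is "pathogenic" and higher scores mean more pathogenic;
inverted scorers must be negated by the caller.  The ROC curve steps
through all distinct score values with ties grouped into diagonal segments,
so the trapezoidal AUC equals Mann–Whitney pair concordance with ties
counted half — an identity the tests enforce exactly against exhaustive
pair enumeration, with scikit-learn as a second, independent check.  The
ΔΔG threshold in the combined rule stays strict while the REVEL cutoff
(default 0.7) is inclusive; the default combination is conjunctive ("and"),
since requiring both calls is the variant that raises PPV, with "or"
available for sensitivity analyses.  A missing REVEL score falls back to
the ΔΔG call with a warning.  The default t test is the pooled (Student)
variant to match the conventional label, with Welch available because
group SDs of ΔΔG differ markedly in practice.  Quartiles use linear
interpolation between order statistics (numpy default, "type 7"); no
convention is canonical, so this one is simply documented.

## Synthetic cohorts

The generator's defaults are the emulated study conditions: 161 variants
per group; latent ΔΔG ~ N(5.06, 4.25²) kcal/mol for pathogenic and
N(1.13, 1.46²) for benign; each covering chain observes latent +
N(0, 0.8²); 95% of variants are covered by all 31 chains and the remainder
by one.  Positions are drawn uniformly along the protein with the reference
residue a fixed property of the position, so a realistic handful of
positions carries both a benign and a pathogenic variant (multiallelic
sites).  Pathogenic-hosting positions draw RSA from Beta(2, 8) with
probability 0.863 and from Uniform(0, 1) otherwise; benign-only positions
are uniform.  Note the mixture weight is the probability of drawing from
the burial-skewed component, not the realized RSA < 0.2 fraction — Beta(2,
8) has only about half its mass below 0.2, so the generator produces a
strongly burial-skewed pathogenic group (realized buried fraction ≈ 0.47 vs
≈ 0.2 for benign) without reproducing the real cohort's 86.3% figure, which
requires the real structures.  The REVEL-like score is a logistic transform
of the standardized latent ΔΔG plus N(0, 0.15) noise clipped to [0, 1] —
purely a fixture for exercising the combined rule and ROC comparison.
Benign allele frequencies decay log-linearly with latent ΔΔG so the
frequency-vs-ΔΔG report is populated; pathogenic variants carry none (by
construction they are absent from population databases).

What the generator does *not* emulate: the visibly non-Gaussian shape of
real ΔΔG distributions (only the first two moments are matched), any
spatial correlation between burial and ΔΔG beyond group membership, and
real coverage heterogeneity (the real ensemble spans 1–31 chains, not just
{1, 31}).  Passing tests therefore demonstrate correct bookkeeping and the
qualitative group separation, not force-field accuracy on real structures.

Toy structures are ideal α-helices (1.5 Å rise, 100°/residue, 2.3 Å Cα
radius) with one pseudo side-chain carbon per residue; with two chains the
helix axes sit 8 Å apart with side chains facing, a spacing chosen so the
side-chain shells occlude each other and the complex is guaranteed to bury
surface relative to the isolated chains.

## Problem sizes and numerical choices

The test suite runs everything at toy scale: 12–25-residue helices for
geometry, 161/161 cohorts for pipeline runs, 2×10⁴–10⁵-variant cohorts for
closed-form rate checks, and 200 replicate cohorts in the acceptance
script.  SASA quadrature at 960 points/atom converges to <1% against 3840
points on these fixtures.  All randomness flows through
`numpy.random.default_rng` seeded per run; replicate seeds derive from a
`SeedSequence` of the base seed.

## Known limitations

- The stability backend is an interface: the package parses force-field
  output (generic TSV and FoldX `Dif` tables) but never runs the physics.
- DSSP-computed accessibility will differ in detail from the sampled SASA;
  consumers should not mix RSA values from the two sources in one cohort.
- Insertion codes are parsed but rejected by ensemble coverage and RSA
  profiling, which key residues by integer position.
- The principal-axis canonicalization guarantees rigid-motion invariance
  only for structures with a non-degenerate inertia spectrum; exactly
  symmetric point sets fall back to the laboratory frame.
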