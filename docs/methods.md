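# Methods

## Distance model

Pairwise divergence uses the Kimura two-parameter model,
d = −½ ln(1 − 2P − Q) − ¼ ln(1 − 2Q), with P the transition and Q the
transversion difference proportion over the compared sites. Identical
sequences return an exact 0 (no log evaluation), and pairs with
1 − 2P − Q ≤ 0 or 1 − 2Q ≤ 0 are *saturated*: at matrix level they are
flagged undefined (NaN) rather than aborting the run, so one degenerate
pair cannot sink an analysis. Downstream stages either refuse to use
undefined pairs (naming them) or, on request, exclude the affected samples
with a warning.

Site masking defaults to **complete deletion**: one shared mask of columns
where every sample has an unambiguous A/C/G/T. This reproduces the
"positions in the final dataset" semantics of standard barcode divergence
tables and makes all pairs commensurable. **Pairwise deletion** (per-pair
masks) is an option; the two can differ noticeably when missingness is
uneven, which is why both are exposed rather than silently choosing.
IUPAC ambiguity codes, N and `-` are all treated as missing data in every
counting step — a deliberate ancient-DNA stance: a damaged or uncertain
base should neither create nor support a difference.

Reports print divergence × 100 rounded to two decimals; all comparisons
against thresholds use the unrounded fraction.

## Threshold grouping

A partition at threshold *t* is the set of connected components of the
graph with an edge wherever d < *t* (**single linkage**). Single linkage
was chosen as the default because pairwise "compared against all others"
grouping tables, and descriptions of loose groups with multiple
cross-member interactions, imply chaining semantics; complete linkage
(every within-group pair below *t*) is provided for sensitivity analysis.
Thresholds are strict: "<0.8%" means d < 0.008 exactly, so a pair at
exactly the cut-off does not group. Nested thresholds necessarily yield
nested partitions (single-linkage components are monotone in the edge set);
the test suite asserts this refinement property on random matrices.

Concordance against reference taxon labels counts a taxon split across
groups as a false negative, a group containing two or more taxa as a false
positive, and calls a taxon concordant when its members share a group
containing no other taxon.

## Tree

The displayed tree is **neighbor joining on the K2P matrix**, not a
maximum-likelihood tree: in this workflow the tree is a visualization of
the distance structure, while the delimitation inference itself is carried
by the threshold grouping. NJ keeps the stack small, exactly testable
(additive matrices must be reproduced perfectly), and deterministic: ties
in the selection criterion are broken by the lowest pair of node-creation
indices, and negative branch-length estimates are clamped to zero and
counted on the tree object. Bootstrap support resamples the kept columns
with replacement (default 500 replicates), recomputes matrix and tree, and
reports the percentage of replicates containing each original bipartition;
replicate streams are spawned per replicate from the single user seed, so
supports do not depend on sample order. Newick output carries branch
lengths and integer support labels.

## Diagnostic SNPs

An informative site is a **strict fixed difference**: every unambiguous
observation in group A is one base, every unambiguous observation in group
B a different base, with at least `min_per_group` observations each.
Ambiguous bases never count as support even when compatible with the fixed
allele (Y over a fixed C is missing, not a confirmation) — conservative
given that C→T deamination damage produces exactly the C/T and G/A
patterns these markers show; that caveat applies to the 557 C/T marker and
to three of the four COI sites. A tolerance parameter (allowing one
discordant sample) exists but is off by default. Multi-group designs are
decomposed into one-vs-rest scans. Polarity (which allele is derived) is
metadata only; nothing here computes it, since that would require an
outgroup analysis out of scope for the package.

## Eggshell association

The association test is an **exact one-sided binomial sign test**: under
the null each of the *k* extreme-thickness eggshells carries the focal
class with probability ½, and p = P(X ≥ k_matching), X ~ Binomial(k, ½).
With all extremes matching, p = 0.5^k — 0.0039 for k = 8, ~7.5 × 10⁻⁹ for
k = 27. The equal-probability null was adopted because it is the simplest
test reproducing both published probabilities; a hypergeometric variant
conditioning on the observed class frequencies is provided as an option
and yields smaller p-values. Thickness ties that span the k-th selection
boundary abort with guidance instead of silently choosing: inclusion of a
tied sample changes p by a factor of two, so the decision belongs to the
analyst (a doubtful record can simply be excluded from the input).

Morphometric verdicts compare each available measurement to the published
subspecies ranges with **inclusive boundaries** (a 225 mm femur is within
150–225); "within" requires all available measurements inside the range,
and "above" dominates when measurements disagree in direction, since an
oversize bone rules the subspecies out regardless.

## Synthetic data

The generator is first-class code, not a fixture: it produces the
statistical structure every stage assumes, at configurable strength.

Sequences evolve down a fixed split ((FarNorth, Central), FarSouth) under
the two-parameter substitution process with transition/transversion rate
ratio κ (default 2, an unremarkable mitochondrial value). Each branch is
applied via the model's exact closed-form substitution probabilities at the
branch's expected divergence (p_ts = ¼ + ¼e^{−4d/(κ+2)} − ½e^{−2d(κ+1)/(κ+2)},
p_tv = ¼ − ¼e^{−4d/(κ+2)} per target), so realized divergences are exactly
calibrated to the configured heights — simpler and more testable than
event-by-event simulation. Default branch heights put the Far North / far
south expectation at ~2% (beyond the 1.6% cut-off), Far North / Central at
~1.1% (between 0.8% and 1.25%) and within-population divergence at 0.3%.
The default sample sizes (2 Far North, 29 central, 6 far south; 37 total,
624 bp at reference 6996) echo the shape of the real COI dataset; the
far-south count is a free choice since no published figure fixes it.
Missingness (default 2% of cells to N) is applied last. Helper
constructors cover three recurring designs: `symmetric_population_config`
(every inter-population divergence equal — used for parameter-recovery
checks), `implant_only_config` (all heights zero, so implanted sites are
the only differences — used to verify that SNP scans recover exactly the
implanted positions with no false positives), and `control_region_config`
(the 27 bp fragment at reference 554 carrying 557 C/T).

Phenotypes: thickness ~ Normal(class mean, sd) truncated at zero, defaults
1.15/0.90 mm (sd 0.10) for class I/II — values chosen to straddle the
observed thick/thin split; bone lengths uniform within the class's
subspecies limits, with a configurable outlier fraction drawn above them.
`eggshell_study_fixture` reproduces the 35-shell design (8 thin class II,
27 thick class I) with guaranteed strict separation so the sign test is
tie-free.

What the generator does **not** emulate: within-population coalescent
genealogies (samples are conditionally independent given their population
ancestor), gene flow or hybridisation (though the real genus likely
hybridised — a natural extension), damage-biased missingness, and
alignment error. Passing tests therefore demonstrate correctness of the
computations under clean population structure, not robustness to those
real-data complications.

## Problem sizes and numerical choices

Tests run the simulator at the default 624 bp with 12–37 samples, 50–100
bootstrap replicates, 200-replicate false-positive counts and 2000
random-label calibration draws; the full suite completes in a few seconds.
Distances are exact to the closed form (oracle agreement to 1e−12 is
asserted); the only tolerance-bearing quantities are simulation
calibration checks, which use standard-error-based bands. Fixed seeds make
every simulated assertion reproducible. The acceptance script's outputs
depend only on the fixture's label structure, not on the seed.

## Known limitations

- Single-linkage chaining can merge populations through one intermediate
  sample; that is the intended semantics, but complete linkage should be
  consulted when a grouping looks fragile.
- The K2P saturation domain means highly divergent pairs (outgroups) can
  be undefined; they are flagged, not imputed.
- The alignment is assumed gapless relative to the reference, as for
  amplicons of fixed reference spans; reference indels are not modelled,
  and `-` is per-sample missing data.
- The sign test treats extreme-set membership as fixed and classes as the
  random element; it is not a test of the thickness distributions
  themselves.
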