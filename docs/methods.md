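# Methods

This note documents the models, parameter choices and numerical
conventions behind `strainmosaic`, and what the simulation-based tests
do and do not establish about real data.

## The WSS model and its assumptions

The window-based SNV similarity treats each (sample, species) as a
single consensus strain: at every reference position with sufficient
evidence, the sample carries either the reference base or one
alternate base. Mixed infections (two strains of one species in one
sample) are outside the model; the consensus caller will either report
the dominant strain or, when no allele reaches the consensus fraction,
leave positions uncalled.

Per window, similarity is concordant/union over variant sites: the
union is every position called variant in at least one sample, and a
site is concordant only when both samples call the identical alternate
base. Windows whose union is empty score 1.0 — two samples that both
match the reference are indistinguishable there, and penalising or
skipping such windows would make the score depend on reference choice
in regions without variation. The exact normalisation is the one
genuinely open design choice in the score; it is isolated in
`wss.window_similarity` plus the `empty_union_policy` parameter
("one", the default, or "drop"), and both variants are unit-tested, so
swapping the convention is a one-line change.

The per-species score is the **unweighted arithmetic mean** of
retained-window similarities, scaled to 0–100. Weighting windows by
their union size was considered and rejected: it would let a single
high-diversity window dominate and would make scores less comparable
across species with different SNV densities, which matters because
cut-offs are per species but scores share one scale.

## Filters and boundary conventions

All thresholds sit at the filter defaults and all comparisons are
chosen so the boundary value itself *passes*:

| filter | rule | boundary behaviour |
|---|---|---|
| read identity | (aligned − NM)/aligned ≥ 0.90 | 0.90 retained |
| multi-mapping | secondary/supplementary flag set → drop | — |
| sample breadth | fraction of positions with depth ≥ 1, both samples ≥ 0.30 | 0.30 passes |
| sample mean depth | total depth / reference length, both samples ≥ 3.5 | 3.5 passes |
| window depth | drop iff > 50% of bases below depth 5 in either sample | exactly 50% retains |
| call vs cut-off | related iff score > cut-off | tie → unrelated |

Mean depth is computed over the whole reference, not covered positions
only — the stricter deterministic reading. The sample-level exclusion
is fail-if-either (a pair with one bad sample is not scored), the
stricter of the two readings of a conjunctive exclusion sentence, and
the window rule likewise drops a window unusable in either sample,
because similarity is intrinsically pairwise. Terminal windows shorter
than 1000 bp are kept and filtered against their own length.
Reference positions with base N are never callable and so never enter
any union.

The consensus caller (depth ≥ 5, alternate fraction ≥ 0.8, both
configurable) is a deliberately naive stand-in for a full
variant-calling workflow; the VCF reader exists precisely so outputs
of external multi-sample callers can be consumed instead. The
allele-fraction comparison uses a 1e-12 tolerance so that exact
rational boundaries (4/5 against 0.8) are not lost to floating-point
representation.

## Cut-off calibration

Training data are labelled pair scores: related = the same individual
re-sampled at separate times, unrelated = different individuals. When
the two distributions separate, the cut-off is the midpoint between
max(unrelated) and min(related) — the unique-by-construction choice
that classifies all training pairs correctly with the largest margin.
When they overlap, the cut-off maximises Youden's J (TPR − FPR, with
"related" predicted above the threshold) over the observed scores plus
one candidate below all of them; ties go to the higher threshold,
favouring specificity, and the training error is reported with a
warning. One class empty means no cut-off: the species is excluded
from classification rather than guessed, and downstream pattern logic
treats its pairs as no-calls. The package ships a cut-offs TSV format
so externally established per-species values can be dropped in
unchanged.

## Cohort designs and pattern reduction

Comparisons never cross families: a mother is compared only with her
own infant's samples (days 4, 7, 21 and infancy, as available), a
pregnant woman's early gestational bin (days 1–100) only with her own
later bins (101–150, 151–200, 201–300; boundaries inclusive), a donor
only with its dam and litter. Gestational "merging" is implemented as
pileup-level pooling — elementwise summation of allele counts and
depth before profiling — which is equivalent to concatenating the
reads of the pooled collection days.

Pattern reduction ignores no-calls rather than counting them as
unrelated: a species without coverage or cut-off at some time point
carries no evidence either way. Per species and family, the
mother–infant call vector reduces to shared-at-all-time-points /
mixed / never-shared / insufficient; a donor/dam/F1 triple reduces to
donor-and-dam-related, dam-only, donor-only, all-unrelated or
insufficient; and the family-level summary is only-related / mosaic /
only-unrelated. The decision tables are total over the 3⁴ and 3³
possible call vectors and are verified exhaustively against
independent oracle tables.

## Synthetic data: what it emulates, what it does not

The simulator defines the conditions under which the pipeline is
validated:

* **References** are i.i.d. base sequences at a target GC fraction
  (default 0.5); lengths of 10 kb (10 windows) are used throughout the
  test suite — large enough to exercise windowing and QC, small
  enough that a full 15-family cohort runs in seconds.
* **Strains** carry Binomial(L, d) substitutions at uniform positions.
  Unrelated strains are drawn independently at d = 0.5% from the
  reference (hence ≈ 1% from each other); related pairs share the
  identical strain genome with drift 0 by default (the
  related/unrelated dichotomy assumes strain persistence), with
  optional drift for within-host evolution.
* **Sequencing** is per-position Poisson depth (default 20×) with a
  uniform base-error rate (default 0.1%), and coverage dropout placed
  as contiguous zero-depth blocks (default 500 bp) because real
  coverage gaps are contiguous — this is what makes the breadth QC
  test meaningful. Calibration uses 20 related + 20 unrelated pairs,
  mirroring a same-individual-resequenced design.
* **Alignments** are ungapped, fixed-length reads with edit distance
  computed against the reference (so strain SNVs count toward NM, as
  an aligner would report); multi-mapping is emulated by flagging a
  fraction of records secondary, since the filter inspects flags, not
  mapping itself.
* **Abundance tables** come from log-normal compositions with
  group-specific offsets, multinomially sequenced; effect 0 gives
  exchangeable samples (a proper null for the permutation test).

Not emulated: indels and structural variants, read quality scores,
host contamination, within-sample strain mixtures, and real
between-species SNV-density variation. Passing tests therefore show
that the scoring, filtering, calibration and pattern machinery is
correct under the stated noise model — not that the default cut-offs
or thresholds are optimal for any particular real dataset, where
cut-offs should be calibrated from real labelled pairs or supplied
from established values.

All generator randomness flows from one integer seed through
`numpy.random.SeedSequence` spawning (one child per reference, lineage
and sample), so whole cohorts are byte-reproducible from one number.

## Community statistics

Counts are Hellinger-transformed (√ of relative abundance), then
Bray–Curtis dissimilarities feed PERMANOVA, UPGMA and NMDS.
PERMANOVA is one-way, computed directly from the distance matrix via
Anderson's decomposition (see the module docstring for the formulas),
with the (1+b)/(1+m) p-value convention so p is never 0; the default
999 permutations suit screening, 9999 resolve p down to 10⁻⁴, and an
exact-enumeration mode covers designs of ≤ 8 samples. Degenerate
perfect separation (within-group sums of squares exactly 0) is
reported as F = ∞ and handled consistently in permutations. The
implementation is cross-checked in the tests against
scikit-bio's PERMANOVA (pseudo-F agreement to 1e-9).

UPGMA uses scipy's average linkage on lexicographically pre-sorted
labels (deterministic tie-breaking) and reports ultrametric node
heights — half the linkage distance — plus a Newick serialisation with
branch lengths; a naive O(n³) re-implementation serves as the test
oracle. NMDS runs SMACOF iterative majorization with monotone
regression (non-metric), one restart initialised from the classical
scaling solution and seven random restarts by default, keeping the
configuration with the lowest Kruskal stress-1; stress-1 is computed
via isotonic regression of embedded distances on observed
dissimilarities, independent of the optimiser's internal stress.

## Problem sizes used in validation

The shipped test suite and acceptance script use: 3–10 kb references,
100–200 randomized score comparisons against a brute-force oracle, 20
calibration replicates of 80 pairs each, one 15-family × 3-species
cohort (75 samples), 1000 null abundance tables at 999 permutations,
and one 25-sample 5-group PERMANOVA at 9999 permutations. These sizes
were chosen as the smallest at which every filter, boundary and
stochastic property is genuinely exercised; all scale linearly if
enlarged.

## Known limitations

* The consensus caller is per-sample and naive; joint multi-sample
  calling (as an external tool would do) can rescue low-depth sites
  the naive caller leaves uncalled.
* The pileup builder assumes ungapped alignments (full-length match
  records); gapped real-world SAM records should be profiled upstream
  and ingested via VCF.
* WSS compares consensus profiles, so a strain replacement below the
  consensus fraction is invisible until it becomes dominant.
* PERMANOVA is unrestricted one-way; stratified or multi-factor
  designs are out of scope.
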