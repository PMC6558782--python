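# Methods

This note documents the models, parameters, and numerical choices behind
`mapanchor`, and what its synthetic validation does and does not show about
real data.

## The problem

A draft plant genome exists as unordered, unoriented scaffolds.  An F2
population derived from two heterozygous parents has been genotyped at SNP
markers with known scaffold coordinates.  The task is to (i) build a
genetic linkage map from the informative markers, (ii) use it to assign,
order, and orient scaffolds into chromosome pseudomolecules, and (iii)
lift transcripts, SNPs, and SSR loci onto the resulting chromosome
coordinate system, with per-chromosome accounting.

## Segregation filtering

Parental genotype configurations are classified by the CP-model
nomenclature.  With outbred heterozygous parents, eight polymorphic
configurations occur; only **aa×bb** (both parents homozygous, different
alleles) gives the fully informative 1:2:1 codominant F2 ratio, and only
those markers are mapped.  The retention rules, in order:

1. pattern = aa×bb;
2. allele sanity: no observed progeny call carries an allele outside
   {a, b}, and calls are plain ACGT (non-ACGT IUPAC codes survive parsing
   but fail here);
3. missing fraction ≤ 0.30 — removal is strict (`> 30%` is removed,
   29.7% is kept);
4. 1:2:1 Pearson χ² (2 df) on the non-missing counts, removal only at
   *P* < 0.001.

The order matters: the distortion test is only defined for clean aa×bb
markers, and missingness affects its power.  Verdicts record the reason,
χ² statistic, p-value, and missing fraction per marker, and partition the
input exactly.

**Bin collapsing.**  Markers with zero observed recombinants — identical
calls at every commonly observed individual — collapse into a bin whose
representative is the member with the smallest (scaffold, position).  A bin
is only formed when ≥ 50% of individuals are commonly observed, which
prevents spurious bins between sparsely observed markers.  Greedy
assignment against representatives in sorted order makes collapsing
idempotent.

## Linkage mapping

**Pairwise r̂.**  For each marker pair the 3×3 joint genotype table over
commonly observed individuals (≥ 10 required) is fit by EM: the only
ambiguous class is the double heterozygote, whose expected recombinant
gamete count is 2r²/((1−r)²+r²); the M-step divides expected recombinant
gametes by 2n.  Initialization r = 0.25, convergence |Δr| < 1e−8, at most
2000 iterations, r̂ clamped to [0, 0.5].  LOD = log₁₀ L(r̂) − log₁₀ L(0.5).
All pairs are computed at once via indicator-matrix products.

**Grouping.**  Single-linkage closure of edges with LOD ≥ T and r̂ < 0.45.
The default T is *not* the conventional 3: testing m(m−1)/2 pairs at
P(LOD ≥ 3) ≈ 10⁻⁴ yields several spurious cross-chromosome edges once a
few hundred markers are mapped, and single linkage amplifies any one of
them into a fused group.  The default is therefore
T = max(3, log₁₀(#pairs) + 1), which holds the expected spurious-edge
count near 0.1 genome-wide.  The cost is an occasional *split* chromosome
(a genuine weak junction falling below T); splits are nearly harmless for
anchoring — each fragment still orders and orients its scaffolds —
whereas fusions are destructive.  For the same reason no threshold
scanning toward a target group count is performed: with noisy data the
weakest genuine junction can be weaker than the strongest spurious edge,
so an exact chromosome-count guarantee is not attainable by thresholded
single linkage at all; the suite asserts group *purity* instead, and exact
counts only on noiseless data.

**Ordering.**  Greedy chain extension from the highest-LOD pair, then
2-opt moves minimizing the sum of adjacent Kosambi distances, then a
multipoint refinement: positions x minimizing
Σ w_ij (x_j − x_i − δ_ij)² over all pairs with r̂ < 0.4, weights
w = 1/Var(d̂) by the delta method (Var(d̂) ≈ d′(r̂)²·r̂(1−r̂)/2n, the common
factor n dropped), signed distances δ from the current order; re-sort by
fitted x and iterate to a fixed point.  The refinement uses every flanking
marker to vote on close-pair order, which a purely adjacent-distance
objective decides from too little information.  Reported cM positions
remain **cumulative adjacent Kosambi distances** — deterministic and
directly oracle-checkable — with the multipoint fit used only to choose
the order.  Group orientation is normalized (smallest marker id in the
first half), and positions are invariant to input marker order.

**Error masking.**  After a first-pass order, a call disagreeing with both
observed chain neighbours while they agree with each other implies a
double crossover in the flanking interval.  When the per-gamete
probability of that event, r₁·r₂, is below 0.005 — the scale of plausible
per-call genotyping-error rates — an error is the likelier explanation;
the call is set missing and the map re-estimated once.  At wide spacings
the gate leaves genuine double crossovers alone.  This is the standard
singleton-correction step of linkage-map software; on error-free data it
costs a small downward length bias (genuine tight doubles are rare but
nonzero) which the tests account for.

**Map function.**  Kosambi, d = 25·ln((1+2r)/(1−2r)) cM, with the exact
inverse.  The simulator draws crossovers from a Poisson process (Haldane,
no interference) while the mapper uses Kosambi, mirroring how Kosambi is
routinely applied to real data whose interference is unknown.  The
mismatch compresses long gaps (≈ −6% at 8-cM marker spacing, < −1% at
dense spacing) and is intentional; length-recovery tests compare against
Σ kosambi(r_Haldane(gap)), the quantity the mapper actually estimates.

## Anchoring

Markers are placed on scaffolds by exact matching of a 101-bp flank
(both strands) against all scaffolds; markers hitting ≥ 2 scaffolds, ≥ 2
sites, or nothing are discarded with a logged reason.  A tabular import
path accepts precomputed alignments for real data, where a local aligner
would replace exact matching.

Each scaffold is assigned to the linkage group containing the majority of
its mapped markers; ties or zero mapped markers leave it unplaced.  Within
a chromosome, scaffolds sort by the arithmetic mean cM of their markers
(ties lexicographic).  Orientation counts concordant vs discordant marker
pairs between physical (bp) and genetic (cM) order, ignoring pairs tied in
either coordinate: a strict majority decides '+' or '−'; a tie — including
the zero-usable-pair cases of a single marker or fully co-binned markers —
defaults to '+' with `orientation_known=False`.  A two-marker scaffold is
decided by its single informative pair: the decision rule is "whichever
count is greater", and one pair constitutes a majority.  Orientation of a
scaffold whose markers never recombine is information-free; the default
is an explicit abstention, not an inference.

Pseudomolecules concatenate the ordered, oriented scaffolds with 100 N
between neighbours (AGP gap type U, evidence "map"; the spacer is a
convention, exposed as a flag) and are described by AGP v2.1 rows that
tile [1, length] exactly.  Whole-chromosome reversal is unresolvable from
map data; all truth comparisons are defined up to it.

## Liftover

Coordinates are 1-based inclusive throughout (BED exports are 0-based
half-open).  For a feature [s, e] on a scaffold of length L placed at
offset O:

* orientation '+': [O+s−1, O+e−1], strand kept;
* orientation '−': [O+L−e, O+L−s], strand flipped.

The transform preserves length, is injective per scaffold, and has an
exact inverse.  Transcripts are placed by exact substring search (both
strands; multiple hits keep the first by coordinate, flagged ambiguous;
splice-aware alignment is out of scope and served by the import path).
SSR loci are in-silico PCR hits: both primers matching exactly on the same
strand with outer-end-to-outer-end amplicon **strictly** < 400 bp; all
loci of a multi-locus pair are found, and the feature table keeps the
first with an ambiguity flag so counts stay deterministic.

## Reporting conventions

Lengths print as Mb rounded half away from zero to 1 decimal.  Transcript
density per Mb is computed **from the displayed Mb value** (350/7.1 →
49.3), matching how such tables are normally assembled.  Percentages are
computed to 2 decimals and then floored at 1 decimal — this reproduces
the printed convention in which 89.7499% displays as 89.7 — so recomputed
percentages match displayed ones exactly.  Density tracks count features
by their start position in fixed windows (default 1 Mb, last window
truncated), with transcript tracks split by chromosome strand.

## The simulator and what passing tests mean

Defaults: 14 chromosomes of 500 kb (a deliberate desk-scale stand-in for
a 341.9-Mb genome), 12 scaffolds per chromosome (168 total, near the 170
of the motivating assembly), 4 markers per scaffold, 111 individuals,
150 cM per chromosome (the real linkage groups span 62–209 cM), 5%
missing calls, 1% genotyping errors, 10% distorted markers (resampled
from a 9:5:2 ratio, chosen to trip the *P* < 0.001 filter essentially
always at n = 111), 10% non-aa×bb parental patterns, 30 transcripts
(0.3–8 kb) and 20 SSR primer pairs planted within scaffold boundaries,
uniform A/C/G/T base composition.

Features of real data the generator does **not** model: read-level
sequencing noise, spliced transcripts, repetitive sequence (random
sequence makes exact matching nearly always unique, which flatters the
placement steps), GC composition, crossover interference, and
non-uniform marker ascertainment.  Passing recovery tests therefore
demonstrates the correctness of the *coordinate algebra, filters,
estimators, and ordering logic* under realistic genetic noise — not
robustness to alignment ambiguity in repeat-rich genomes, which the
import paths delegate to external aligners.

Recovery is scored against truth up to whole-chromosome reversal, with
two orientation metrics: strict (abstentions count as wrong when the
default misses) and decided-only.  At n = 500 noiseless, assignment and
ordering are perfect and every decided orientation is correct; the one or
two abstaining scaffolds per genome are those whose markers drew zero
recombinants.  At n = 111 with 1% error and 5% missing, ≥ 90% of
scaffolds are correctly ordered and oriented under strict scoring
(measured ≈ 92–93% aggregated over 20 seeds).

## Numerical and degenerate-input choices

* EM: init 0.25, tol 1e−8, ≤ 2000 iterations; pairs with < 10 common
  individuals are errors (single-pair API) or NaN (matrix API).
* r̂ ≥ 0.499 is clamped before Kosambi when a finite ordering distance is
  needed; such pairs never end up adjacent in a group.
* 2-opt accepts only improvements > 1e−12; all tie-breaks are by marker
  or scaffold id, making every stage deterministic and independent of
  input row order.
* Empty retained marker sets yield an empty map with a warning; empty
  feature inputs yield empty tables with zero counts.
* Scaffold cutting uses a reduced-interval uniform draw, which cannot
  produce a piece under the 1000-bp minimum.
* All randomness flows from a single integer seed through one
  `numpy.random.Generator`; identical seeds give byte-identical artifact
  trees.

## Known limitations

* Two-point mapping only: no multipoint likelihood for *positions* (the
  multipoint fit refines order only), no interference modeling.
* Thresholded single-linkage grouping can split a chromosome with a weak
  junction; it is tuned to never fuse rather than never split.
* Orientation of short or marker-poor scaffolds is frequently undecidable
  at n = 111; they default to '+' and are flagged, matching the
  positive-by-default convention of the anchoring protocol.
* The e-PCR and transcript mappers require exact matches; primer or
  transcript variants against a diverged reference need the external
  alignment import path.
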