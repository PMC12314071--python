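# Methods

## Scoring model and exact occurrence p-values

A motif is an L×4 matrix of per-position base counts or probabilities.
Probabilities are recognised by rows summing to 1 (within 1e-3) and are
rescaled to pseudo-counts of 100 before regularisation, because motif
collections mix count-based and probability-based sources; a matrix with
some rows of each kind is rejected.  Counts are regularised with a
pseudocount distributed by the background,

    p[i, b] = (n[i, b] + c · bg[b]) / (Σ_b n[i, b] + c),

with c = 0.1 by default (the standard default of occurrence scanners),
and scored in bits as log2(p/bg).  The background defaults to uniform
(0.25 each); a 0-order background estimated from the scanned sequences is
available.  Minus-strand windows are scored with the reverse-complemented
matrix and share the forward null distribution, which is exact for any
strand-symmetric background and is the convention of standard scanners.

The occurrence p-value P(S ≥ s) for a random background window is
computed exactly for a discretised score: per-position log-odds are
rounded to integer multiples of the granularity (default 1/1000 bit) and
the distribution of their sum is built by position-wise convolution of
the at-most-four-point per-position distributions.  Scanning uses the
same integer tables, so the p-value attached to a hit is the exact tail
mass of the discretised score at the hit's own bin — the bin containing
the score is always included, so p is never understated relative to the
discretised model.  Discretisation perturbs a window's score by at most
L·g/2 bits; the test suite verifies that p-values and hit sets agree with
exhaustive 4^L enumeration up to that band for L ≤ 8, and that empirical
hit rates on 100 kb of i.i.d. background match the threshold within three
Monte-Carlo standard errors at p ≤ 1e-2 and 1e-3.  Float-score queries
are floored onto the bin grid and clamped at the attainable support, so
P(S ≥ min) = 1 and P(S > max) = 0 exactly.

Overlapping occurrences of the same motif are all reported (no greedy
masking): occurrence counts are therefore upper-bound-style counts, which
matches how motif landscapes are usually summarised ("at least N
occurrences").

## Coordinates and regions

Gene models anchor three positions per gene: the TSS (transcript 5'
end), the translational start (first CDS base in transcript orientation)
and the 3'UTR end (transcript 3' end), taken from GFF3.  Where a gene has
several mRNAs the longest is used (configurable); annotation sets rarely
state which isoform anchored a published screen, so this choice is the
package's own documented default.

Internal arithmetic is 0-based half-open; every file-facing coordinate is
1-based inclusive (BED stays 0-based half-open per its standard, and DHS
intervals are strand-less).  Promoter positions are signed offsets from
the translational start with no position 0: +1 is the A of ATG, −1 the
base immediately upstream.  This skip-zero convention is the one used in
promoter deletion-series work; it is centralised in two inverse functions
and property-tested as a bijection, because an off-by-one here corrupts
every downstream report.

Two regions drive the screen:

* core promoter: TSS−200 through the base *before* the ATG ("to the
  translational start site" is read as exclusive of the ATG base itself —
  a documented choice);
* CRM search space: TSS−2000 through the 3'UTR end, intersected with the
  DHS track; overlapping DHS intervals are merged first, and the result
  may be empty.

## Core-promoter elements

The published Y-patch weight matrix is not redistributable, so the
Y-patch model is pluggable: supply a PWM, or use one of two built-ins.
The default is a synthetic pyrimidine-patch PWM (12 positions, C and T at
0.45 each after pseudocount); under a uniform background its p < 4e-4
acceptance set is exactly the all-pyrimidine 12-mers (mass 0.5^12 ≈
2.44e-4), a clean operational definition of "pyrimidine patch".  The
fallback rule mode declares any run covered by length-8 windows with
pyrimidine fraction ≥ 0.8 and at least one C, merged over overlaps.
Replication of any published screen is conditional on supplying the
original matrix.  Y-patch detection is orientation-constrained (forward
strand of the gene only) with p strictly below 4e-4, and the per-gene
count collapses overlapping hits greedily from the left (deterministic
and order-independent).

TATA variants are exact hexamer matches (default TATAAA and ATTAAA, as
published variant strings are exact) with an optional PWM mode; reported
positions refer to the 5' base of the hexamer, since conventions differ
on whether an element's position means its 5' end or centre.  MTE, BREu
and DCE-S-I are scanned from a user-supplied POLII library in gene
orientation.

## The co-occurrence screen

Hits are scanned at the loose 1e-3 threshold and then filtered by strict
per-family cutoffs: WRKY and G2-like at p < 1e-3; MYBR_B, DOF, IDD and
DPBF at p < 1e-4.  A CRM call exists iff one passing hit per family can
be selected such that (max stop − min start + 1) ≤ 300 bp and all six lie
within a single contiguous accessible interval.  Two deliberate readings
are built in:

* the 300-bp span rule is applied jointly to all six families (a CRM is
  one compact physical module), although the defining sentence could be
  read as constraining only the four strict families; the literal
  alternative is a parameter;
* no bridging across DHS gaps — six hits scattered over two accessible
  islands are not one module.

The caller anchors candidate windows at each hit (leftmost-start
anchoring), takes per-family earliest-ending hits to obtain the minimal
span per anchor, and reduces overlapping candidates to the minimal-span
call per locus (ties to the leftmost).  Only the Y-patch is
orientation-constrained; CRM family hits count on either strand.
Supporting evidence records the lowest-p hit per family.

Enrichment of screen flags against expression classes uses Fisher's
exact two-sided test with the sample odds ratio ad/bc; degenerate tables
(zero cells making the OR undefined or infinite) are flagged rather than
silently patched.

## Expression filters

Filters are pure functions of their tables and strict exactly as their
definitions read: TPM = 1.0 is not "TPM > 1", log2FC = 2.0 is not
"> 2".  The specificity filter requires both an adjusted-p column and an
FDR column because the two derive from different upstream fitters and
are applied jointly; missing values fail (conservative).  Differential
statistics are consumed, never computed — the count-model fits belong to
dedicated tools upstream.  Co-expression ranking is Pearson correlation
on log2(TPM+1), descending, ties broken by gene id; zero-variance
targets are rejected.

## Reporter quantification

Duplicate MUG reactions are fitted by OLS over all 20 cycles (no
lag-phase trimming by default; a trim is configurable), converted to
nmol 4-MU through the same-plate standard curve, averaged across
duplicates and divided by mg protein.  LUC/GUS uses the GUS rate per
second, as transactivation ratios are conventionally printed; MUG rates
are per minute; the conversion lives in one place.  Pairwise group tests
are two-sided Wilcoxon rank-sum (exact null when the combined n ≤ 20 and
no ties, normal approximation with continuity correction otherwise) or
t-tests, Benjamini–Hochberg corrected over the pairwise family.  The
compact letter display uses insert-and-absorb; the sharing-a-letter
relation exactly reproduces the thresholded adjusted-p matrix (tested),
with letter order following group input order.  No outlier exclusion is
applied anywhere.

## What the synthetic data does and does not emulate

The generator plants family consensus words of a synthetic sharp
(97:1-count) motif library into i.i.d. background at 40% GC, genes of
2–6 kb with 150–400 bp 5'UTRs on alternating strands, one gene per
contig with 2.5 kb flanks.  One contig per gene keeps each gene's
2-kb regulatory span free of its neighbours' planted elements, so truth
tables stay exact; multi-gene chromosomes are not emulated.  The
nine-base consensus length for the strict families is chosen so that
under a uniform background only the exact consensus word passes p < 1e-4
(single-mismatch words of a sharp symmetric 9-mer carry p ≈ 1.07e-4):
chance co-occurrence of a missing sixth family inside a five-family
gene's accessible window then has probability ~2×10⁻³ per gene, which is
what makes "zero false positives among ≤5-family genes" a reproducible
expectation rather than a coin flip.  Category fractions default to
40% both / 15% CRM-only / 15% Y-patch-only / 10% five-family /
20% background, and the five-family negative controls also carry a
planted Y-patch so the six-family requirement itself is what blocks the
call.  DHS coverage modes: cover the plants (with a 20-bp margin),
exclude them (negative control), or whole-contig.

Expression tables follow the 7-stage, 3–4-replicate, three-cell-type
design; bundle-sheath-specific genes draw log2FC(BS/M) from
Normal(3, 0.5) truncated above 2 with sub-threshold p and FDR, and
non-members violate exactly one condition in rotation, including the
exact-boundary cases.  Kinetics are linear with Gaussian read noise
(default sd 20 AU against a curve slope of 800 AU/nmol).

Real data differ in ways the simulation deliberately ignores: motif
instances are degenerate rather than consensus-exact, backgrounds are
not i.i.d. (a first-order chain is available to stress this), DHS
boundaries are soft, expression classes are not generated by the filter
being tested, and plate-reader kinetics saturate.  Passing tests
therefore demonstrate correctness of the computation, not performance on
rice data; the published genome-wide counts additionally depend on
version-pinned external resources (genome release, DHS set, motif
collection, study RNA-seq) that this package does not download.

## Problem sizes and numerical choices

The default test and acceptance runs use 100-gene genomes, 100 kb
calibration backgrounds, 20 random PWMs for the enumeration oracle, and
1000-replicate null simulations for the Wilcoxon size check — sizes at
which every check is exact or adequately powered while the whole suite
runs in seconds.  Granularity 1/1000 bit; all randomness flows from one
seed through named per-stage sub-streams, so enlarging one simulation
never perturbs another; identical inputs produce byte-identical outputs
(tested).  Degenerate inputs (N-containing windows, empty DHS, stages
with fewer than three samples, singleton comparison groups,
zero-variance targets, zero GUS rates) are skipped, warned about, or
rejected as documented on each function rather than silently absorbed.

## Known limitations

Single-isoform anchoring per gene; 0-order backgrounds only; no q-values
(the screen is defined on p-value thresholds); no motif discovery; no
TSS inference from read data (TSSs come from the annotation); enrichment
assumes a fixed universe of screened genes; the compact letter display
is deterministic but not guaranteed minimal in letter count for
pathological significance graphs.
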