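# Methods

## Breeding-scheme model

The simulator models a haploid fungal breeding program. Individuals are
haplotypes: per-marker parental-origin vectors over a `GenomeMap` of
linkage groups, each with a physical length (bp) and a genetic length
(Morgans). A cross forms a transient diploid whose meiotic gametes are
drawn under the Haldane model: the crossover count per linkage group is
Poisson with mean equal to the genetic length, breakpoints are uniform
in genetic position, there is no interference, and the starting parent
of each group is a fair coin flip. The recombination fraction between
loci d Morgans apart therefore converges to r = ½(1 − e^(−2d)), which
serves as a closed-form oracle in the tests. Marker genetic positions
assume a uniform recombination rate along each group (genetic position
proportional to physical position); nothing downstream depends on this
beyond the marker spacing in Morgans.

A breeding line starts from an all-donor × all-recurrent cross; each
subsequent cross pairs the selected progeny with the all-recurrent
parent. "n backcrosses" counts **total crosses**, so the unselected
donor fraction after n rounds is 0.5ⁿ (ten rounds → 0.5¹⁰; with 9,127
genes, 9 expected donor genes). Selection is rejection sampling of
gametes: the surviving gamete must carry the donor allele at the
fertility locus FS (fertile ⇔ donor FS, by definition of the phenotype)
and satisfy the mating-type rule (default: donor MAT1-1 every round;
`final_mat_allele` can switch the last round, producing lines of the
opposite mating type). Rejection sampling is capped (default 10,000
gametes/round) and errors beyond the cap, bounding runtime.

The association panel performs one further cross of a fertile line to
the recurrent parent and bins gametes by fertility until the configured
panel (default 20 fertile + 20 sterile) is filled. Because binning stops
when the slower bin fills, the binned draw counts are biased estimators
of the segregation ratio; the unconditional 1:1 check always uses fresh
unconditioned gamete draws.

### Default map

Seven linkage groups (the *T. reesei* karyotype), 1.0 Morgan and 500 kb
each, 1,000 evenly spaced markers per group, 9,127 genes tiled in
proportion to physical length, FS mid-way along group 6 and MAT mid-way
along group 3 (unlinked, mirroring a scaffold-6 fertility locus and an
independent mating-type locus). The dense 0.1-cM marker spacing emulates
genotyping lines by whole-genome SNP catalogs (hundreds of thousands of
SNPs genome-wide), where marker resolution is far finer than the
recombination scale; window-based block detection is only meaningful in
that regime. All of this is configurable through `SimConfig`.

## SNP coding effects

A SNP is classified against a gene model as noncoding (inside the span,
outside every CDS segment), synonymous or nonsynonymous by rebuilding
the codon containing the site from the concatenated CDS
(reverse-complemented for minus-strand genes), substituting the
alternate allele and translating both codons with the standard genetic
code. Stop gain/loss counts as nonsynonymous (the analyses use a binary
split). Multiple SNPs in one codon are classified independently against
the reference codon, as per-site annotators do; haplotype-aware codon
reconstruction is out of scope. Genes whose total CDS length is not a
multiple of 3 are flagged non-annotatable and excluded from effect calls
but retained for interval analyses. A SNP overlapping two genes is
counted in both, with the number of such SNPs reported. The classifier
is validated against an independent brute-force oracle that mutates the
full genomic sequence and translates the whole protein.

## Region detection

*Nonsynonymous clusters*: a maximal run of positionally consecutive
genes, each carrying ≥ 10 nonsynonymous SNPs, is a region when it holds
≥ 5 qualifying genes. The criterion is read as **per-gene** ≥ 10
(consistent with the per-gene burden analysis that precedes it);
"close vicinity" is operationalized as positional adjacency with a
configurable gap allowance (default 0 interposed below-threshold genes).
A cumulative mode (windowed sum instead of per-gene threshold) is
provided for sensitivity analysis. Both thresholds are configurable
because the original criterion is ambiguous on this point.

*Donor blocks*: sliding windows of 25 consecutive markers are flagged
when the donor fraction among non-missing calls is ≥ 0.9; overlapping or
adjacent flagged windows merge into maximal blocks. Windows with < 50%
informative calls are skipped; missing calls never enter denominators.
This density logic matches detecting retained regions by locally
increased SNP abundance; an HMM would add unsupported structure. The
detector is calibrated for blocks of at least twice the window: those
are recovered essentially always, with boundaries within one window of
truth. Donor segments much shorter than the window can escape
detection — after 10 rounds of backcrossing roughly 2–3% of lines carry
an FS segment that short at default settings — so the cross-line
consensus of *detected* blocks contains the FS interval in ~93% of
3-line experiments, whereas the consensus of *true* donor intervals
contains it always (selection guarantees donor FS in every line).

*Consensus*: per linkage group, the interval intersection of each line's
merged blocks, annotated with overlapping genes. The operation is
associative and order-independent.

## Inheritance statistics

Expected retention is 0.5ⁿ of the genome and round(0.5ⁿ·G) of G genes
(nearest integer, so 8.91 → 9). Segregation against 1:1 uses the exact
binomial test, two-sided by minimum-likelihood summation (alternatives
such as tail doubling differ; this convention is asserted against an
enumeration oracle). Marker–trait association uses the two-sided
Fisher exact test on the donor/recurrent × fertile/sterile table —
exact is preferred over chi-square at n = 40 — with Bonferroni
correction over the tested marker family (17 markers in the emulated
design) and complete-case handling of missing calls. Note that a
perfectly co-segregating 20+20 marker has p = 2/C(40,20) ≈ 1.45 × 10⁻¹¹:
the mirrored table is equally improbable, so both extremes enter the
two-sided sum. The candidate locus is the longest run of adjacent
markers significant after correction (ties broken by smallest p); on
simulated panels it contains the true FS marker in ≥ 95% of replicates
and significant markers are confined to the FS linkage group.

## Profile analysis

One-way fixed-effects ANOVA is computed from the sums-of-squares
definitions, F = MS_between/MS_within on (k−1, N−k) df; it matches
`scipy.stats.f_oneway` and, for two groups, the pooled-variance t-test
(F = t²). Degenerate inputs are explicit: all values identical → F = 0,
p = 1; zero within-group variance with unequal means → p = 0 with a
degeneracy flag. Only one-way ANOVA is implemented; batch covariates are
out of scope.

Fold change is the ratio of linear-scale group means (the scale of
normalized intensities; a log-scale option exists). The 2-fold and
5-fold filters at P < 0.01 flag disjoint up/down sets; rows with a zero
denominator mean are excluded and tallied. On null matrices the flag
rate at P < 0.01 calibrates to ~1%.

Hierarchical clustering is agglomerative with 1 − Pearson distance and
average linkage by default (the classic expression-pattern
configuration), cut to exactly k clusters. Determinism contract: output
is deterministic for a given input order; ties follow scipy's stable
agglomeration order. Zero-variance rows have no defined correlation and
are assigned to the nearest cluster centroid (Euclidean) after the cut
rather than crashing the distance computation. One caveat the tests make
explicit: a "flat" regulation archetype has no pattern *shape*, so
correlation distance cannot isolate it — its correlations with anything
are noise. Recovery of the three-archetype structure
(up-in-background-A / flat / up-in-background-B) therefore uses
Euclidean distance, which is also the natural choice for
turbidity/growth magnitude profiles; correlation distance cleanly
separates anticorrelated patterns of any magnitude.

Relative growth is reported as mean ratio × 100 ± SD: replicate-paired
ratios (sample SD, ddof = 1) for equal replicate counts, otherwise the
ratio of means with SD from a seeded 1,000-resample bootstrap (the
original ±SD computation for unequal designs is underdetermined; this is
the declared choice). Category enrichment is the one-sided
hypergeometric upper tail, reported raw by default (as functional-
category enrichments classically are), with an optional Bonferroni flag.

## Synthetic data: what it emulates and what it does not

The generators cover (a) a biallelic parental SNP catalog over a
multi-group haploid genome, (b) recurrent backcrossing with two-locus
selection, (c) fertile/sterile genotyped panels, (d) coding catalogs
with planted synonymous/nonsynonymous/noncoding SNPs (synonymous planted
at third positions of 4-fold degenerate codons, nonsynonymous at second
positions — always amino-acid-changing under the standard code — on both
strands, with and without introns), and (e) profile matrices with
planted archetypes and group differences. Every generator writes truth
records, so recovery is scored exactly, and every draw flows through one
seeded `numpy` generator: identical configs give byte-identical outputs.

Real data differ in ways the generators deliberately ignore: crossover
interference, segmental aneuploidy and ascospore inviability, uneven
marker/SNP density, genotyping error, overlapping gene models beyond
the simple tiled layout, microarray normalization artifacts, and
correlated expression noise. Passing tests demonstrate correctness of
the algorithms under the stated model, not robustness to those
real-data effects.

## Problem sizes

Defaults were chosen so the full suite and the acceptance script run in
minutes on one CPU: Haldane recovery uses 60,000–100,000 gametes per
distance, retention means use 150–200 replicate lines at reduced map
size, locus recovery uses 200 full-size panels, and null calibrations
use 8,000–10,000 rows/replicates. All sizes are ordinary function
arguments and scale up freely.
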