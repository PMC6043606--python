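# Methods

## The inference problem

Several diploid isolates are resequenced against a single haploid,
majority-rules reference. A sexually recombining isolate is a random draw
from its population: against a reference that is itself one haplotype of
that population, its genome shows heterozygous positions (allele balance
R ≈ 0.5) and homozygous non-reference positions (R ≈ 1) in the
Hardy-Weinberg ratio 2:1, and pairs of such isolates are mosaics of shared
and unshared haplotype tracts. A clonal family descended from one founder
instead shows: almost no homozygous non-reference positions (the reference
derives from the clonal lineage itself), near-total SNP sharing among
members, near-zero crossover signal, and large homozygous blocks with
identical boundaries in every member — the footprint of a single
loss-of-heterozygosity (LoH) event in the founder. Every module here
quantifies one of those contrasts.

## Allele balance

R = nc/(nc+rc) uses only the most common non-reference nucleotide, which
suppresses most sequencing error (two distinct non-reference alleles at one
position are overwhelmingly technical; positions where the second
non-reference count exceeds max(1, 0.2·nc) are flagged ambiguous).
Positions are classified hom-ref / het / hom-nonref by the bands
R < 0.2 / 0.2–0.8 / > 0.8; the bands separate the three modes at ≥ 20×
depth and ≤ 1% error and are configurable. "Extreme read coverage" is not
defined sharply anywhere we know of; we exclude positions outside
[0.25×, 2×] the genome-wide median depth, configurable.

Mapping bias — aligners keep reads matching the reference more often —
multiplies the sampling probability of non-reference reads by b ≤ 1, so the
het mode sits at b/(1+b) instead of 0.5. Since this package consumes count
tables rather than raw reads, the remedy offered is analytic: estimate b
from the median of het-range R (robust to the 1/depth lattice of R values,
where a histogram mode is not) and invert r → r/(b + r − br). The original
remedy in read-level pipelines is stricter base-quality filtering; the two
pursue the same goal (centre the het mode at 0.5) by different means.

The single-genotype check requires the bias-corrected het-range mean within
0.05 of 0.5 and a unimodal het-range histogram (smoothed, 30 bins on
0.1–0.9; peaks above 40% of the maximum separated by a dip below half the
smaller peak count as distinct modes). A 50:50 mixture of two genotypes
moves sites het in only one component to R ≈ 0.25/0.75 and is read as
"mixed"; fewer than 100 het sites is "indeterminate".

Relative copy number of a region (e.g. an rDNA array) is the ratio of
median depths, region over genome. Hemizygous intervals are non-overlapping
5 Kb windows whose median depth falls in [0.35, 0.65] × the genome median
and which contain no het call, merged when adjacent.

## Hardy-Weinberg diagnostics

With the reference a random haplotype, a site at minor-allele frequency q
is het with probability 2pq and hom-nonref with probability pq (= q²·p +
p²·q), hence E[het] = 2·E[hom-nonref] for any allele-frequency spectrum.
Three tests follow:

1. **Ratio test** — exact two-sided binomial test that the het fraction of
   het + hom-nonref positions is 2/3.
2. **Sharing bound** — the probability that a het site is het in each of n
   independent HWE isolates is at most (1/2)^n, because 2pq ≤ 1/2 with the
   maximum at p = 1/2 (verified by grid search in the tests).
3. **Unlinked sharing test** — sample one het site per chromosome (removing
   linkage between tested sites), count how many are het in all other
   isolates, and compute the exact binomial upper tail at the (1/2)^n
   bound. "Shared" means het-in-all-others, matching the bound's
   derivation.

The combined verdict labels an isolate H-like (sexual) when the
hom-nonref/het ratio is within ±25% of 1/2 and the sharing test does not
reject, L-like (clonal) when the hom-nonref deficit is at least 10-fold and
the sharing test rejects, and indeterminate on any conflict — conflicting
evidence is surfaced, never resolved silently. The 10-fold and ±25%
defaults reflect the order-of-magnitude separation the two regimes produce;
the rejection α must be attainable given the number of chromosomes (with 4
unlinked sites the smallest possible tail is (1/16)⁴ ≈ 1.5e-5).

## SNP deserts

Model SNPs as independent per-bp events at the isolate's genome-wide rate p
(total SNPs ÷ callable length; known reference gaps should be excluded from
both). The distance from a position to the k-th SNP downstream is negative
binomial (p, k); we work with the equivalent exact binomial tail
P[Bin(L, p) ≤ k−1] to avoid the failures/successes convention ambiguity,
with no continuous approximation. The threshold L* is the smallest L with
that tail ≤ α (bisection on the exact CDF); defaults k = 5, α = 1e-4,
merge gap 100 bp.

Candidate deserts are the maximal intervals containing fewer than k SNPs,
delimited by SNPs, with the chromosome start acting as a virtual boundary
(the 5' end is not treated specially beyond that). Near the 3' end, where
only j < k SNPs remain downstream of an anchor, the observable quantity is
the distance to the j-th (last) SNP, so the candidate runs from the anchor
to the last SNP and is tested against L_j computed with parameter j; with
j = 0 nothing downstream is observable and no desert is declared — a
SNP-free chromosome end (or chromosome) yields no call. Intervals longer
than their threshold are merged when overlapping or within 100 bp,
iterated to a fixpoint. A consequence worth knowing: a desert's reported
boundaries extend to the k-th flanking SNP on each side, i.e. up to k−1
SNPs lie inside a called desert and boundaries sit a few inter-SNP
spacings outside a true SNP-free block.

Each desert is annotated with density n/L ± 2σ, σ = sqrt(p(1−p)/L).
Cross-isolate boundary clustering groups desert starts (ends) agreeing
within a tolerance (default 0 bp, "exact"). The age profile compares
per-desert densities of deserts ≥ 50 Kb by a chi-square homogeneity test
against a single shared rate, and reports fold-depletion as flank density
over pooled desert density, the flank being all non-desert sequence;
similar densities across deserts indicate simultaneous origin (one
inbreeding event) rather than the age spectrum gene conversion or
selective sweeps would leave.

## Refinement, crossovers, cladogram

**Refinement** adds, never removes: wherever any isolate has a raw call,
every other isolate with depth ≥ 10 and the *same* alternate allele at
≥ 20% of reads gains a rescued het call; covered isolates without support
are recorded hom-ref, the rest missing. The exact criteria of the original
pipelines vary, so all thresholds are configuration; the defaults separate
1% sequencing error from true heterozygotes at ≥ 10×. Multi-allelic
positions stay as separate (position, alt) records. Refinement is
idempotent.

**Crossover density** is a reconstruction, declared as such: no standard
estimator exists for this setting. Informative sites (het in ≥ 1 isolate of
a pair, genotyped in both) are marked concordant/discordant; runs shorter
than 10 informative sites are absorbed as noise (private mutations,
genotyping error appear as isolated discordant sites); surviving run
transitions count as crossovers; density divides by the assayed span
(first to last informative site per chromosome, summed). The absolute
numbers depend on the minimum run length; the order-of-magnitude contrast
between clonal pairs (~0) and sexually related pairs does not, and only
that contrast should be interpreted.

**Cladogram.** Top-down recursive bipartitioning: every split of a node's
isolates is scored S(A) + S(B) − X(A, B), where S(·) is the number of SNP
positions present in all members of a side *when the side has at least two
members* (a single isolate exhibits no within-subtree sharing and
contributes 0 — without this convention the score degenerately favours
peeling off whichever isolate has the most SNPs), and X counts positions
present in at least one member of each side but not in all of either. Ties
break to the lexicographically smallest partition and are flagged on the
node. Internal branch lengths are SNPs shared by all leaves below;
terminal branches are private SNP counts. Exhaustive scoring is 2^(n−1)−1
bipartitions per node — instant for cohort sizes this method is meant for
(≤ ~15). The score is pluggable for experimentation.

**Divergence clock.** years = private_SNPs / (ploidy × genome_size × μ ×
(365.25/division_interval_days)). The diploid target (ploidy 2) is used
because private SNPs are heterozygous point mutations on either homolog.
Defaults μ = 1e-9 per bp per division, one division per 2 days, 32 Mb.

## Competition simulator

A deliberately minimal discrete-generation model; the claims it supports
are qualitative (who dominates, whether a lineage survives its allele's
success), so transparency was preferred over guessing unpublished detail.
One generation = one mitotic division (2 days). State is a census of
(strategy, genotype-at-one-tracked-locus, lineage) classes capped at N by
multinomial resampling (the drift source). Asexual classes double every
generation. Facultative classes double except during meiotic episodes:
every T generations (default 365 ≈ 2 years) the whole genotype group
pauses for d generations (default 2), then its members are replaced by
Hardy-Weinberg offspring of its own allele pool and lose their mitotic
lineage identity. Homozygous-recessive (aa) groups use interval T×f,
f ≥ 1 — the advantageous-recessive model: fitness expressed as rarer sex.

Known consequences of these choices: (i) with d = 0 and a neutral locus
the model reduces exactly to Wright-Fisher drift of lineage frequencies
(fixation probability = initial frequency; verified to ±2.5 SE over 500
replicates); (ii) because episodes are population-synchronous, the asexual
advantage arrives in factor-2^d jumps every T generations rather than as a
smooth selection coefficient d·ln2/T, so an established clone fixes within
roughly 10³–10⁴ generations (≈ a decade at N = 5000) — comfortably inside
"within a few centuries" — while a clone starting from a single cell is
usually lost to drift before its first episode; (iii) a facultative focal
lineage loses its identity at its own first meiosis, so "displacement of
the original background" is partly structural and partly drift. The
reassembly scenario tracks the allele and the lineage separately: with
f ≫ 1 the allele fixes while the founding lineage is displaced by
recombinant aa backgrounds; the obligate variant of the same configuration
keeps the focal lineage's genotype identity to fixation. Summaries report
fixation probability and median fixation time with bootstrap CIs; censored
replicates are reported separately and excluded from the median.

## Synthetic data: what it does and does not emulate

The generator realises a site panel once per population (positions, minor
allele frequencies from a uniform or neutral 1/q spectrum — the wild
spectrum is unknown, so it is a knob, and the 2:1 law holds for any
choice), fixes the reference allele per site as one random haplotype, and
draws isolates' genotypes independently under HWE. Clonal founders are
constructed so that one of their haplotypes *is* the reference haplotype:
the reference of such a study is assembled from the clonal lineage itself,
which is what makes clonal isolates nearly free of hom-nonref positions;
descendants inherit the founder plus Poisson-distributed private het
mutations at uniform positions (collisions redrawn) and never recombine.
Pileups draw Poisson depth (halved in hemizygous blocks, scaled in
copy-number blocks), sample haplotypes with mapping bias b (het
non-reference read fraction b/(1+b)), and flip bases uniformly at the error
rate. Base identities are a deterministic function of position so all
isolates' pileups agree on ref/alt alleles.

Not emulated: read-level artifacts (indels, soft-clipping, mapping to
repeats), linkage disequilibrium between panel sites, structural variation
beyond hom-ref LoH blocks, gene conversion, and within-population
relatedness between "sexual" isolates (they are independent HWE draws, so
concordance between them carries no haplotype tracts; tests of the
crossover estimator therefore plant tract mosaics explicitly). Passing
tests demonstrate correctness of the statistics under the model's
assumptions, not robustness to every real-data artifact.

Default desk genome: 4 chromosomes × 1 Mb; analyses at paper scale (32 Mb,
~180 K SNPs) enter only as closed-form inputs. Positions are 1-based
internally; BED output is 0-based half-open. All randomness flows through
integer seeds; fixed seeds give bit-identical outputs.

## Numerical notes

Binomial tails are exact (scipy), never normal-approximated; the desert
threshold uses bisection on the exact CDF; the unlinked sharing test is
checked against explicit 2^n outcome enumeration in the tests; interval
merging iterates to a fixpoint; degenerate inputs (zero depth, empty
tracks, empty subsets, zero rates) raise or warn explicitly rather than
propagating NaNs silently.
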