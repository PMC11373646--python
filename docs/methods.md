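# Methods

This note documents the models, estimators, defaults and numerical
choices behind `panelkin`, and what the synthetic-data generator does and
does not emulate.

## Genotype representation

Biallelic SNP calls are dense int8 codes: HOMREF=0, HET=1, HOMALT=2,
MISSING=−1 — equivalently, alternate-allele dosage with a missing
sentinel. Hotspot variant-caller tables map "Absent" → HOMREF: the
category records that the *variant* allele is absent, which for a called
sample means homozygous reference. This is stated prominently because it
is the one conversion users routinely get wrong. Genepop I/O is fixed to
the two-digit dialect with 01 = reference and 02 = alternate allele;
allele order within a genotype is not meaningful ("0201" ≡ "0102").
Positions are 1-based everywhere except BED export (0-based half-open).

## QC and filtering

Technical-replicate concordance uses pairs in which both members have a
genotyping rate ≥ 0.5, compares loci typed in both, and classifies
discordances into the three unordered genotype-pair categories. The
summary is the unweighted mean ± sample s.d. of per-pair concordances
(each pair counts equally, rather than pooling genotypes) — matching how
repeatability is conventionally reported for these panels. For downstream
analysis the replicate with the highest genotyping rate is kept, ties
broken by lexicographically first sample id.

The missingness filter keeps samples, then loci, with strictly less than
30% missing calls by default; locus missingness is computed over the
samples retained by the first pass. The order is an explicit parameter
because it is not exchangeable: dropping bad samples first can rescue loci
that a loci-first pass would discard, and the tests pin the implemented
order. Boundary cases (exactly 30%) are removed, following the strict
"less than" reading. Loci whose observed calls imply a single allele are
monomorphic and dropped; all-missing loci count as monomorphic (no
observed alleles — the degenerate case is resolved toward removal).
Negative-control wells are flagged when mean amplicon depth exceeds 40×
(strictly greater).

## Per-locus statistics

`p_alt = (2·n_HOMALT + n_HET) / (2·n_typed)`, `h_obs = n_HET / n_typed`,
`h_exp = 2p(1−p)` with no small-sample correction (the selection pipeline
this mirrors used the uncorrected form, and ranking is unaffected by a
monotone correction). The MAF floor removes loci with `maf < 0.01`.

F_ST is Weir & Cockerham's (1984) θ from the a/b/c variance components;
per-locus values use all populations with at least two typed individuals,
and multilocus pairwise values are the ratio of sums (Σa / Σ(a+b+c)) over
loci. Confidence intervals are percentile bootstrap over loci, 1000
replicates by default, seeded. Populations qualify for pairwise F_ST with
more than 15 retained individuals. The per-locus estimator is invariant to
ref/alt relabeling; loci with zero total variance are undefined (NaN)
rather than zero.

Hardy–Weinberg proportions use the exact biallelic test with full
enumeration over heterozygote configurations (log-factorial arithmetic,
two-sided: total probability of configurations no more likely than the
observed one). Deviations at p < 0.05, uncorrected, are *flagged only* —
in amplicon panels HWP departures are often the footprint of null alleles
or family structure and deserve inspection, not silent removal.
Monomorphic samples return p = 1 by convention.

A private allele is one observed (≥ 1 copy) in exactly one genetic
grouping; the report lists the locus, the allele, the grouping and the
copy count within it.

## Relatedness and structure

Pairwise relatedness uses the Ritland (1996) moment estimator scaled to
the relatedness (not kinship) scale:

    r_l = 2 [ Σ_a S_xa S_ya / p_a − 1 ] / (A_l − 1)

with S the half-counts of each allele in a genotype and A_l = 2 alleles;
multilocus r averages r_l with weights A_l − 1 (uniform for SNPs) over
loci typed in both individuals. Loci monomorphic in the frequency table
are skipped; a pair with no usable shared locus is reported as undefined.
Negative estimates are a normal property of the estimator. Frequencies
default to the analysed dataset itself; when samples contain many close
relatives this biases r downward, which is why the first-degree purge
works on a threshold calibrated within known families (default 0.26, the
kind of value obtained as the average minimum within-full-sib-family
relatedness) rather than on the theoretical 0.5.

The purge is iterative elimination: while any within-population pair
exceeds the threshold, remove the individual in the most offending pairs
(ties: lower genotyping rate, then lexicographically first id). This is
greedy and order-deterministic; it does not attempt a minimum vertex
cover, matching the simple elimination used in practice.

PCA operates on dosages with missing values imputed to the locus mean and
columns centred, via SVD. Each component is oriented so its
largest-magnitude loading is positive, making signs reproducible across
runs and BLAS implementations.

## Kinship likelihoods

The κ decomposition and transition kernel are described in the README.
Numerical choices: natural-log units throughout (the assignment cutoffs 5
and 10 are interpreted in these units); the genotyping-error model is the
minimal symmetric per-genotype miscall (rate ε, default 0.005, each wrong
genotype ε/2, independent across individuals and loci) — richer
allele-level error models exist, but this is the smallest model that makes
Mendelian exclusions finite and it calibrates well against the simulated
miscall process. Loci with undefined or fixed frequencies, or missing in
either individual, contribute zero to logl. With ε = 0 an exclusion drives
logl to −inf, reported as-is.

Relationship logl distributions are plain Monte-Carlo (default 10,000
pairs per relationship, seeded): genotype pairs are drawn locus-by-locus
from the observed-genotype joint (error kernel included) and scored with
the same PO-vs-U tables used for real data. Tail rates below ~1/n_sim are
only upper-bounded, not resolved; no importance sampling is attempted.
Duplicate detection reports sample pairs with ≥ 100 shared typed loci and
concordance ≥ 0.95.

## Parentage pipeline

Candidates are all genotyped parent-generation individuals; sex is not
used, and the caller is responsible for excluding third generations
(grandparents can otherwise absorb assignments). All pairs with
`logl > 5` are retained, however many per offspring. Trios require
*exactly two* retained candidates, both ≥ 10 — an offspring with three or
more retained candidates is deliberately not a trio, since its surplus
assignment is itself a red flag. Parent pairs supported by ≥ 2 trios are
confirmed, and only confirmed trios feed the incompatibility tally.
Mendelian compatibility is a precomputed 27-entry table from gamete
enumeration; any missing genotype skips the locus for that trio (counted
in neither numerator nor denominator).

Loci with ≥ 4 incompatible trio offspring are flagged for removal (a
secondary watch list at ≥ 2 is also available). After removal, assignment
re-runs and is scored against the pedigree: possible assignments are
(offspring × genotyped true parent) slots; completeness is
100·correct/possible; the false-positive percentage divides by all
assignments made (correct + FP), the denominator that makes the two
published-style summaries internally consistent. Pedigree conflicts are
surfaced in the per-family table (expected versus assigned), never
auto-corrected.

## Synthetic-data generator

The generator defines the study conditions for every stochastic test.
Ancestral alternate-allele frequencies are drawn from U(0.1, 0.5) by
default (a post-MAF-filter panel profile); per-population frequencies
follow Balding–Nichols, Beta(p(1−F)/F, (1−p)(1−F)/F), with F = 0 handled
as a point mass. Founders are drawn in HWE as haplotype pairs; offspring
receive one uniformly chosen allele per parent per locus, independently
across loci. Null alleles are planted on founder haplotypes at a chosen
fraction of loci (default scenario: 10% of loci, null frequency 0.25) and
inherited; a heterozygous carrier is observed as a homozygote of its
visible allele and a null homozygote as MISSING — the standard null
phenomenology, and the mechanism that produces trio incompatibilities.
Miscalls are symmetric per-genotype (ε/2 to each wrong genotype), then
missingness is applied, then replicates are re-observed independently
from the same truth, giving the closed-form expected replicate
concordance (1−ε)² + 2(ε/2)². All randomness flows from one seed through
named substreams, so identical specs give identical bundles.

The default breeding-program scenario — 18 broodstock (9 dams × 9 sires)
in 15 partial-factorial crosses, 7 offspring per cross, 300 loci,
ε = 0.005 — mirrors the family structure and panel size of a typical
shellfish parentage run and takes well under a second, so the end-to-end
recovery tests run it across ten seeds.

What the generator does **not** emulate: linkage (loci are independent;
real panels average ~50 amplicons per chromosome, so sib-pair logl
variance is somewhat underestimated), locus-specific depth and dropout
profiles, population-specific null-allele sharing, ascertainment bias in
marker discovery, and sweepstakes reproductive success. Passing tests
therefore demonstrate the correctness and calibration of the algorithms
under idealized inheritance and error, not field performance on any
particular population.

## Known limitations

* Biallelic SNPs only; multi-allelic loci and microhaplotypes are out of
  scope.
* The error model is per-genotype, not per-allele; allele-specific
  dropout other than the explicit null-allele mechanism is not modelled.
* The marker-selection H_OBS cap (0.5) and top-N sizes are panel-design
  conventions, configurable but not optimized here.
* Assignment treats candidate parents symmetrically; dam/sire roles in
  reports follow the pedigree, not the genetics.
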