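# Methods

This note documents the models, default parameters and numerical choices
behind each stage of `panelforge`, and what the synthetic-data generator
does and does not emulate.

## Identity power

Per-locus probability of identity for unrelated individuals and for full
siblings uses the standard biallelic closed forms (Paetkau/Waits
conventions):

    P_ID(p)    = p^4 + q^4 + (2pq)^2
    P_IDsib(p) = 1/4 + (1/2) S2 + (1/2) S2^2 - (1/4) S4,
                 S2 = p^2 + q^2,  S4 = p^4 + q^4

Both are verified in the test suite against brute-force enumeration: all
ordered genotype pairs under HWE for P_ID, and exhaustive enumeration over
parental matings with Mendelian offspring distributions for P_IDsib.
Cumulative curves multiply per-locus values with loci ranked most
informative first (ascending per-locus P_ID; for biallelic loci the same
ranking orders P_IDsib). Accumulation is done in log space — beyond a few
hundred loci the direct product underflows doubles. The minimum panel size
is the smallest n whose cumulative value is *strictly below* the threshold;
the threshold defaults to the reciprocal of the relevant sample count
(0.007 in the bundled examples, i.e. a ~140-sample survey). Ranking can be
switched to input order for externally ordered panels.

## MAF bins and the frequency generator

Candidate loci are drawn uniformly within named minor-allele-frequency
bins: low = [0.00, 0.10], moderate = [0.20, 0.30], high = [0.40, 0.49]. A
`proportional` bin mixes the three ranges; its weights default to equal
thirds because no empirical genome-wide MAF histogram is bundled, and they
are configurable for users who have one.

## Dyad simulation and kinship classification

Relationship categories carry their single-locus identity-by-descent (IBD)
distributions — PO (0,1,0), FS (1/4,1/2,1/4), HS (1/2,1/2,0), FC
(3/4,1/4,0), UR (1,0,0) — and expected kinship coefficients 0.25, 0.25,
0.125, 0.0625, 0. A dyad is simulated by drawing individual 1 from HWE,
drawing the IBD state k per locus, copying k alleles into individual 2 and
filling the rest from the population. Loci are unlinked and independent,
which matches the marginal IBD distribution exactly but ignores the
chromosome-scale IBD correlation real full sibs exhibit; this only affects
the variance of multilocus statistics, not their means. The simulator
records the true IBD states so tests can check realized sharing against
the category distribution.

Kinship is estimated with the Loiselle estimator (see below) against the
panel's true frequencies. Classification fits a normal approximation
(mean, SD) per category on an independent training simulation of the same
size (training seed = seed + 1) and assigns each test dyad by maximum
likelihood; ties break toward the less related category (UR < FC < HS < FS
< PO). This supervised-ML design was chosen because distribution-overlap
assignment rules in the literature do not fully specify how a dyad is
allocated; a normal approximation is accurate here because multilocus
kinship estimates are averages over hundreds of loci. PO and FS share the
same expected kinship and differ only in estimator variance, so their
mutual confusion is the irreducible hard case — the test suite asserts it
is the largest off-diagonal of the misclassification matrix.

The sensitivity analysis evaluates panel sizes n ∈ {50, 100, 200, 400}
per MAF bin, averaging accuracies over 4 independently drawn frequency
panels (replicates). Tests and the bundled analyses use 10,000 dyads per
category, a scale at which the standard error of an accuracy is ~0.5% and
the ordinal comparisons of interest are stable while the whole grid runs
in about a minute. One caveat documented here because it is scientifically
real: with weakly informative (low-MAF) panels every estimate shrinks
toward zero and the classifier degenerates to calling everything
unrelated, which *inflates* UR accuracy. Comparisons of per-category
accuracy between MAF bins are therefore made on the related categories
(and on the category-mean), not on UR.

## Sex loci

Sex-differentiated loci are constructed with the female allele frequency f
~ U(0, 1 − d) and male frequency f + d, so the per-sex differential is
exactly d by construction; d = 1 yields fixed differences (gametolog-like
markers), intermediate d models partial sex linkage. Genotypes are HWE
within sex. The returned per-sex frequency table holds *realized* sample
frequencies, which is what a screening step would actually observe.
Screening flags loci with |p_m − p_f| ≥ cutoff (default 0.20).

Sex assignment is a supervised two-class naive Bayes over genotype classes:
per-sex class frequencies are estimated from known-sex training samples
with a pseudocount of 0.5 per class, priors are equal, and the posterior is
the product over called sex loci. A sample is called when the winning
posterior reaches the cutoff (default 0.9); a sample with no called sex
locus is always `unassigned`, never guessed. A supervised caller was chosen
over unsupervised clustering because validation cohorts have known sexes
and HWE cannot be assumed at gametolog-like loci.

## Amplicon read simulation

Per sample and locus, depth ~ NegativeBinomial(mean = tier.mean_depth,
size = tier.depth_dispersion, default 5), zeroed with probability
`dropout_prob`; negative-binomial depth was chosen over Poisson to mimic
the strongly overdispersed per-locus depths of real multiplexed amplicon
libraries. Each on-target read is forward primer + allele probe + random
filler to the read length (default 75 bp single-end); heterozygotes emit
allele 2 with probability `allele2_bias` (default 0.5). Substitution errors
are applied per base at `error_rate`; off-target reads are uniform random
sequence appended so the on-target share equals `on_target_fraction` in
expectation. The four bundled quality tiers (tissue, hair, colon feces,
field feces) form a monotone quality gradient — mean depths 149/177/119/96,
dropout 3/5/10/14%, on-target 90/60/50/45%, error 0.2–0.5% — chosen to
emulate the tissue > hair > colon > field contrast typical of noninvasive
sampling.

Not emulated: PCR chemistry (primer thermodynamics, chimeras), paired-end
reads, quality-score structure (dummy qualities are written), contaminant
DNA from non-target species, and index hopping. Passing tests therefore
demonstrate correctness of the statistical machinery under a clean
generative model, not robustness to every artifact of real libraries. The
simulator's emission ledger (per-locus pre-error allele counts) is the
oracle for genotyper count tests.

## Genotyping

Matching is exact substring search, the convention of amplicon genotypers:
a read belongs to a locus iff it contains the forward primer; allele counts
additionally require the allele probe (searched in read orientation only —
panels must supply probes in read orientation). Calls use the allele-count
ratio r = count_a1 / max(count_a2, 0.1): hom1 if r ≥ 10, hom2 if r ≤ 0.1,
het if r ∈ [0.2, 5], otherwise missing; depth < 10 is missing. All
thresholds are configurable and logged in the report parameters; the 0.1
denominator floor (so count_a2 = 0 gives r = 10·count_a1) avoids division
by zero while preserving the hom1 decision. Technical runs of the same
sample are merged by summing counts *before* calling, so loci undercovered
in each run alone can still clear the depth gate.

Panel-health diagnostics flag, never drop: overrepresented primers (share
of pooled reads above 10× the uniform share by default) and primer-dimer
artifacts (reads containing ≥ 2 distinct panel primers in either
orientation and no probe). Curating the panel in response is a human
decision.

## QC conventions

Filters: samples first, then loci, both at "> max_missing" strict (a
sample at exactly 50% missing is retained). Discordance compares unordered
genotypes at loci called in both pair members — het vs hom is discordant
even when an allele is shared; missing-vs-called cells are excluded, not
counted as mismatches. The headline rate pools counts across pairs (total
discordant / total comparable); per-pair rates are also emitted because the
two conventions differ when pairs have unequal overlap.

## Unique-genotype clustering

Pairwise match decisions require at least `min_overlap` co-called loci
(default 50) and a mismatch rate ≤ `match_tolerance` (default 0.02).
The 2% default is deliberately conservative relative to measured
noninvasive replicate discordance well under 1%: it merges degraded
recaptures while remaining far below the ~30–50% mismatch rate of distinct
individuals under a high-MAF panel. Matching samples merge by
single-linkage (so chains of degraded samples still coalesce); a greedy
complete-linkage alternative is exposed for users worried about chaining.
The cluster count is the unique-genotype census; the locus set's empirical
cumulative P_ID/P_IDsib is attached for interpretability.

## Loiselle kinship

With x = dosage/2 and reference allele-2 frequency p per locus,

    F_ij = [ Σ_l 2 (x_il − p_l)(x_jl − p_l) + bias_l ] / Σ_l 2 p_l (1 − p_l)

summed over loci called in both individuals (the factor 2 covers both
alleles of a biallelic locus, whose deviation products are identical).
When reference frequencies are estimated from the analyzed samples
themselves — the default, as population programs do — the per-locus
small-sample term bias_l = 2 p(1−p)/(2 n_l − 1) (n_l individuals called at
locus l, hence 2 n_l gene copies) cancels the negative covariance induced
by centering on the sample's own frequency estimate; with external
frequencies the term is zero. Monomorphic and frequency-less loci are
skipped; pairs with no shared informative loci get NaN. The diagonal is
not reported: self-"kinship" under this centered-product form is not the
(1 + F)/2 quantity a reader might expect, and reporting it invites
misreading.

## Determinism and problem sizes

Every generator takes an explicit integer seed; derived seeds come from
`numpy.random.SeedSequence` so stages are independently reproducible, and
the pipeline manifest records all stage seeds plus output checksums. The
bundled analyses and tests run at desk scale — 10,000 dyads per category
for the sensitivity grid, 1,000 dyads for parameter recovery, cohorts of
100 for sexing — sizes at which every assertion's sampling error is an
order of magnitude below the effect it checks while the full suite stays
fast.

## Known limitations

* Unlinked-locus dyad simulation understates multilocus kinship variance
  for close relatives (no linkage).
* Exact substring matching cannot tolerate primer-region sequencing
  errors; a read with an error inside the primer or probe is simply not
  counted (visible as slightly reduced measured on-target fractions under
  nonzero error rates). Fuzzy matching is out of scope.
* The sex caller is supervised; it cannot be used without known-sex
  training individuals.
* Multi-allelic loci and indels are out of scope throughout (VCF import
  skips them with a count).
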