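# Methods

This note records the statistical models implemented in mhapkit, the
assumptions they make, the defaults and why they were chosen, and the
boundaries of what the synthetic-data tests can demonstrate.

## Genotype calling (`mhapkit.calling`)

A microhaplotype genotype at one locus is called from the read depths of
the haplotypes observed in an individual's amplicon:

1. total depth < `min_depth` (default **20** reads) → missing;
2. haplotypes are ranked by depth, ties broken lexicographically so the
   call is deterministic;
3. if the third-ranked haplotype carries ≥ `min_ratio` of the reads the
   individual shows more than two credible haplotypes: the call is missing
   and the individual counts toward the locus's multi-haplotype fraction
   (a contamination / paralog symptom surfaced as QC rather than silently
   dropped);
4. otherwise, if the second-ranked haplotype carries ≥ `min_ratio`
   (default **0.30**) of the reads, the call is a heterozygote of the top
   two; otherwise a homozygote of the top haplotype.

The balance rule is deliberately asymmetric: it is a criterion for
*accepting a heterozygote*, so a minor haplotype that fails it yields a
homozygote call for the major haplotype rather than a missing genotype.
This keeps loci at the depth floor usable while still protecting against
index-hopping and low-level contamination.

**Hardy–Weinberg exact test.**  Multiallelic, Monte Carlo: the statistic is
the conditional probability of the observed genotype-count configuration
given the allele pool (Levene's distribution, computed in log space with
`gammaln`); the p-value is the fraction of `hwe_reps` (default **10 000**)
random re-pairings of the pool whose configuration probability is at most
the observed one, with the observed configuration counted once so that
p ∈ (0, 1].  The statistic is discrete: for low-diversity loci (biallelic,
small n) there is an atom at p = 1 whenever the observed configuration is
the modal one, so the null distribution is uniform only approximately and
conservatively.  The uniformity property test therefore uses 4-allele loci
at n = 100, where the configuration space is fine enough for a
Kolmogorov–Smirnov check at α = 0.001.  Loci with fewer than 5 genotypes
are reported as not tested (NaN).  A locus is flagged HWE_FAIL when
p < `hwe_alpha` (default **0.01**) in at least two collections —
operationalizing "clear" violation as replication across collections.

**Null-allele screen.**  The statistic is max(0, 1 − H_obs/H_exp) per locus
and collection: the apparent proportion of heterozygotes miscalled as
homozygotes, which a segregating null allele inflates.  A locus is flagged
when the statistic exceeds `null_allele_threshold` (default **0.2**) in any
collection with ≥ 20 genotyped fish.  This is a deliberate simplification
of full binomial-likelihood miscall-rate estimation from read-depth data:
it uses only called genotypes, so it cannot separate null alleles from
other sources of heterozygote deficit (e.g. Wahlund effect within a
collection).

## Summaries and FST (`mhapkit.popgen`)

Expected heterozygosity is 1 − Σ p̂² from the raw allele-frequency
estimates (no small-sample correction), averaged over loci; observed
heterozygosity is the heterozygote fraction.  The subsample-standardized
statistics N̄_A,ss and P̄_poly,ss downsample every collection, per locus,
to the smallest number of genotyped fish at that locus in any collection,
without replacement, averaging `subsample_reps` (default **1000**) draws.
When all collections have equal counts the subsample is the whole sample
and the statistics are exact for any seed.  The per-locus RNG is seeded as
`seed + locus_index` so results are reproducible and independent of locus
evaluation order.

Pairwise FST is Weir & Cockerham's θ in its multiallelic form: variance
components a, b, c per locus *and allele*, combined as a **ratio of sums**
over all loci and alleles — not a mean of per-locus ratios — which is the
standard weighting and is what keeps low-information loci from dominating.
Negative estimates are reported as-is (they are informative about sampling
noise near θ = 0).  Loci with fewer than two genotyped fish in either
collection are skipped for that pair; a pair with no usable locus is NaN
with a warning.  Markers in the run-timing, sex and species-diagnostic
categories are excluded by default, mirroring their exclusion from GSI;
the summary statistics accept any marker filter the caller applies first.

## GSI self-assignment (`mhapkit.gsi`)

The per-locus likelihood of an unordered genotype (i, j) in a candidate
collection with allele counts y and Dirichlet prior λ is the two-draw
posterior predictive

    P = m · (y_i + λ_i)/(Y + Λ) · (y_j + λ_j + δ_ij)/(Y + Λ + 1),

m = 2 for heterozygotes, δ_ij = 1 for homozygotes.  The default prior is
λ_a = 1/K_l per allele (K_l alleles at locus l), with a unit prior
available.  Alleles never observed in a collection retain prior mass, so no
genotype has zero likelihood and logs never diverge.

Loci are treated as statistically independent within collections — the
reason the mutually linked run-timing block is excluded from GSI — and
missing loci are skipped, so fish are compared across different locus sets;
scaled likelihoods remain comparable because each fish is normalized over
collections.  Leave-one-out removes the focal fish's two gene copies from
its own collection's counts before scoring, eliminating the upward bias of
in-sample self-assignment; the package retains a `leave_one_out=False` mode
purely to quantify that inflation.  Argmax ties (vanishingly rare with
continuous likelihoods) are broken by lexicographic group name.

## Close-kin power (`mhapkit.kin`)

Relationships are parameterized by Cotterman kappas; HS and AN share
(½, ½, 0) and are distinguishable only through linkage.  Per-locus joint
genotype tables are built exactly (outer products, a transmission matrix
for the one-IBD term, and a diagonal for two-IBD), then pre- and
post-multiplied by the TGIE error matrix
E[t, o] = (1−ε)·1[o=t] + ε·P_HWE(o) with ε default **0.01** per locus.
Each conditional table sums to 1 to 1e-9 by construction, which the tests
enumerate for 2–6 allele loci.

Simulators are mechanical, not table-lookups, so they provide an
independent route against the analytic tables: the unlinked simulator draws
latent IBD states i.i.d. from the kappas; the linked simulator gene-drops
founder haplotypes (assembled under linkage equilibrium) through explicit
pedigrees — PO: parent and own child; FS: two shared parents; HS: one
shared parent; AN: grandparent couple → two full sibs, one sib's child
versus the other sib — with recombination between map-adjacent loci by the
Haldane function on a 1 cM/Mb default map (overridable via `pos_cM`).
Unplaced markers are their own linkage groups (free recombination).  The
pair statistic Λ is always computed with the per-locus (linkage-free)
likelihood tables, mirroring how the estimation model would score real
pairs; linkage only changes the *distribution* of Λ for FS/HS/AN, not for
PO (one allele IBD everywhere regardless of recombination) or U
(independent individuals).

**Importance sampling.**  The threshold η(φ) is the φ-quantile of Λ under
the numerator relationship simulated *with* linkage (φ = tolerated FNR);
the unrelated-pair FPR P_U(Λ ≥ η) is estimated from unlinked draws of the
numerator relationship weighted by exp(−Λ), which is exactly the U/num
likelihood ratio because U-pair loci are independent.  The estimator is
unbiased with a computable Monte-Carlo SE and resolves rates far below
1/n_reps.  FPR is monotone non-increasing in φ: tolerating more false
negatives raises the threshold.  Weights are clipped at exp(700) to avoid
overflow in the (already FPR ≈ 1) regime of very low thresholds.

**Plain Monte Carlo** handles kin-vs-kin errors, where importance sampling
is unavailable; the binomial SE makes rates below ~10⁻³ unreliable at the
default 100 000 replicates, and results are reported with their SEs so the
caller can judge.

**Most-heterozygous-SNP projection.**  `reduce_to_top_snp` projects each
amplicon to the variant position with the highest expected heterozygosity
pooled over all collections (ties → the leftmost position), re-coding
genotypes to the base at that position.  Comparing Λ-distribution
separation before and after projection quantifies the power gained by
scoring amplicons as full microhaplotypes.

## Marker screens (`mhapkit.screens`)

The run-timing diplotype call requires all eight block markers typed;
concordance is strict — all homozygous-early, all homozygous-late, or all
heterozygous — and *any* other pattern is RECOMBINANT, because such fish
are removed from run-timing-stratified analyses.  The late-fall screen
consumes a precomputed association table; the association study itself is
out of scope, the peak is a user-supplied interval, and "near fixation" is
operationalized as a maximum group allele frequency ≥ 0.95 (configurable).
All numeric thresholds of the screen are keyword arguments, and the
selection is monotone: relaxing any threshold never removes a selected SNP.

## Synthetic data (`mhapkit.sim`)

The generator is a hierarchical two-level F-model: per-locus base
frequencies from a symmetric Dirichlet (α = 1.5, floored at 0.02 and
renormalized to avoid degenerate downstream Dirichlet parameters), unit
frequencies from Dirichlet(p₀(1−F_unit)/F_unit), collection frequencies
from Dirichlet(p_unit(1−F_coll)/F_coll), genotypes in HWE, missingness
MCAR per collection.  Defaults mirror a California-salmon-style baseline:
17 collections in 7 reporting units (sizes 4/2/2/1/3/4/1, two units being
single phenotypically distinct collections), 96 fish per collection, 200
loci with 2–5 alleles concentrated at 2–4, per-unit divergences
(0.05, 0.06, 0.05, **0.50**, 0.03, 0.02, 0.04) — the fourth unit plays the
strongly bottlenecked population, pushing its pairwise FST toward ~0.3
while within-unit pairs sit near F_coll = 0.015 — and per-collection
missingness spanning 0.008–0.338 with the extreme on the bottlenecked
collection.  Read counts are negative-binomial totals (default mean 80,
dispersion 5) split binomially at heterozygotes around an allele balance
of 0.5 ± `balance_sd`, with an optional background-haplotype injection for
exercising the multi-haplotype QC path.  The run-timing block simulator
emits intact early/late haplotype blocks with an optional single crossover
per haplotype at rate `recomb_rate`.

What the generator does **not** emulate: locus-correlated missingness
(real missingness concentrates in degraded samples and hard-to-amplify
loci; MCAR is the documented simplification), correlated divergence among
units (all units drift independently from one ancestral pool, so there is
no isolation-by-distance or shared-lineage structure), linkage
disequilibrium within collections (founder haplotypes are in linkage
equilibrium, consistent with the GSI model's assumption), and selection or
run-timing phenotypes.  Passing tests therefore demonstrate estimator
correctness under the model's own assumptions, not robustness to real-data
artifacts such as allele dropout bias, batch effects, or mixed-stock
contamination.

## Problem sizes and numerical choices

The test suite runs the statistical checks at deliberately compact sizes —
50 000 replicates for distributional (KS) contracts, 20 000–40 000 for
variance comparisons, 500 loci for p-value uniformity, 20 replicate
baselines for FST parameter recovery — chosen so the full suite completes
in well under a minute per module while keeping Monte-Carlo standard errors
an order of magnitude below the tested effect sizes.  The acceptance script
uses the full default baseline (≈ 326 000 genotypes) and 50 000 kin-power
replicates.  Tolerances: exact identities at 1e-9 (likelihood
normalization, scaled-likelihood sums, FST oracle agreement); Monte-Carlo
comparisons at 3 standard errors; KS tests at α = 0.001.

## Known limitations

* Parent-offspring **trio** error rates are not implemented; there is no
  established method for multiallelic trio error estimation, and pair PO
  power is the operative bound.
* The null-allele screen is a heterozygote-deficit heuristic, not a
  read-level miscall model.
* Kin-power simulations use complete genotypes; an observed-missingness
  mask can be emulated by subsetting the panel but is not applied by
  default.
* Half-sibling discrimination is intrinsically weak at panel sizes of a
  few hundred markers; the package reports the rates honestly rather than
  extrapolating beyond Monte-Carlo resolution.
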