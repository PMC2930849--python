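# Methods

`sibscan` implements a genomewide allele-sharing linkage analysis of
exceptional human longevity in nuclear sibships with untyped parents,
together with a synthetic-data generator that reproduces the study
design end to end. This note records the models, the defaults and why
they are what they are, and what the simulation experiments do and do
not establish.

## Phenotype: expected age at death and nested age categories

The analyzed phenotype is the *expected age at death* (EAD). For a
deceased subject it is the actual age at death; for a living subject it
is the age at last contact plus the sex- and age-specific remaining life
expectancy from a cohort life table (ages truncated to whole years for
the lookup, the standard life-table convention). About 70% of a
longevity cohort is alive at last contact, so using the raw age at last
contact would systematically understate the phenotype of interest.

Ten nested categories impose sex-specific minimum EADs — males
90, 91, 92, 93, 94, 95, 96, 98, 99, 100 and females 95–104 in one-year
steps — spanning the upper 5% to the upper 0.2% tail of the birth
cohort. Trimming at category *k* removes non-qualifying subjects with
the sibship-preserving rule: a sibling **pair** is removed whole as soon
as either member fails, while sibships of three or more shed only the
failing members. A sibship reduced below two qualifying members is
dropped entirely; a singleton carries no allele-sharing information, so
this extension of the pair rule is forced. Trimming is idempotent and
category memberships are nested by construction.

Subgroups: `Previous`/`New` are recruitment-wave metadata columns; `MC`
(male-containing) vs `FO` (female-only) is evaluated on the sibship's
qualifying members, by default at the loosest category (a switch
re-evaluates it per category; the original definition is ambiguous and
both behaviors are exposed).

## The built-in life table and death-age baseline

Death ages follow a Gompertz law S(t) = exp(−c(e^{t/s}−1)) with shared
shape s = 13.7 years and sex-specific rates solved so that the upper 5%
tail sits at age 90 (males) and 95 (females). The shape was fit so the
male tail also passes through 0.2% at age 100 — i.e. both anchor rows of
the category table are population quantiles of the baseline. The
built-in life table is derived from the same law by numerical
integration of e(a) = ∫ₐ S dt / S(a) (trapezoid on a 0.05-year grid, up
to age 140), which makes the generator and the phenotype module exactly
self-consistent; a real historical cohort table in TSV (sex, age,
expectancy) can be substituted anywhere a table is accepted.

## The cohort generator

Sibships have 2–5 genotyped siblings (default mix 218:50:9:2 over sizes
2–5, the composition of a 279-family longevity cohort), two untyped
founders, and a small fraction (2.5%) contain a half-sibling pair,
modeled with a third founder. Sexes are drawn with 28% males. Subject
death ages are

  T = Gompertz baseline + Z_f (+ effect_years if susceptible at the trait locus),

where Z_f ~ Normal(0, frailty_sd²) is shared by the whole sibship. The
frailty term is the unlinked familial component of longevity —
polygenes and shared environment — and it is what makes siblings of the
long-lived long-lived themselves. Its default, 7 years, was calibrated
so that a simulated 279-sibship cohort reproduces the published
per-category retention profile of such cohorts (about 12% of sibships
surviving to the strictest category, mean EAD ≈ 101, mean age at last
contact ≈ 98–99); without it, retention collapses roughly 25-fold over
the ten categories, the decay implied by the population tails alone.

Recruitment requires every sibling's death age to exceed the
sex-specific floor (90/95, the loosest category cutoffs). Under the
null with no frailty this is exact inverse-CDF conditional sampling;
with frailty or a planted locus it is batched rejection sampling, which
is the exact ascertainment law: families with high frailty or shared
longevity alleles are recruited disproportionately often. Death ages
are capped at 122 years, the ceiling of verified human lifespans.
Censoring: each subject is alive at last contact with probability 0.7;
the age at last contact is the death age minus an Exponential(mean 2.5
years) recall gap, so EAD (which adds back the life-table expectancy)
remains positively correlated with the latent death age.

Genotypes are gene-dropped: founder haplotypes are drawn from panel
allele frequencies (or from a small latent-haplotype pool inside
designated LD blocks — two complementary core haplotypes plus 3% allele
jitter, which guarantees within-block r² well above the 0.16 clustering
threshold), then transmitted through independent two-state Markov
meiosis chains with Haldane switch probabilities (no interference,
sex-averaged map). When a sibship was accepted conditional on its
trait-locus configuration, the chains are generated outward from the
trait marker conditioned on the accepted transmission bits — the exact
conditional law of a reversible chain. `degrade` adds missingness and
random allele-substitution errors, and can return the planted masks as
ground truth for error-detection experiments.

The generator does **not** model population stratification, genotype
intensities, sex-specific maps, mutation, or realistic demography; LD
exists only inside planted blocks. Passing tests on these cohorts
therefore demonstrate correctness of the machinery under the stated
design, not robustness to stratification or other real-data pathologies
the study handled by design choices upstream of this pipeline.

## QC

Samples below a 95% call rate are flagged first; sibships reduced below
two members drop out. Marker filters then remove the union of: markers
on an unassigned chromosome, markers failing the exact conditional
Hardy–Weinberg test at P < 10⁻³ in one randomly chosen subject per
sibship (one-per-family is the only selection that guarantees
unrelatedness; drawn once under a fixed seed), and markers below a 90%
call rate. The HWE test conditions on the allele count and sums the
probabilities of all heterozygote counts no more probable than the one
observed; it is exact at the small minor-allele counts where the filter
binds, and is verified against full rational-arithmetic enumeration for
every table with n ≤ 50.

Relationship concordance classifies within-sibship pairs from
identity-by-state counts via method-of-moments IBD estimates (expected
IBS-given-IBD integrated over the panel's allele frequencies). Fixed
classification bands on the estimated kinship proportion π̂ (≥0.8
duplicate/MZ, 0.35–0.8 full sib, 0.15–0.35 half sib, else unrelated)
are documented constants, not estimates; pairs are flagged, never
removed automatically. Classification needs genome-scale data: realized
sib sharing over a few hundred cM has a standard deviation large enough
to cross the bands, so short test genomes mis-classify a minority of
true sibs — a property of the statistic, not of the implementation.

## LD clustering

Pairwise r² is computed from EM haplotype frequencies (fixed uniform
start, relative log-likelihood tolerance 10⁻⁸, ≤500 iterations —
deterministic given the data) on the unrelated subset, within a sliding
window of 10 markers or 500 kb, whichever is larger. Pairs with
r² strictly above 0.16 are merged together with all map-intervening
markers; overlapping merges chain. Each multi-marker cluster becomes a
multiallelic pseudo-marker at the mean cM of its members with zero
internal recombination and EM haplotype frequencies over its (≤6)
markers. In the linkage engine the cluster alphabet is pruned to the
eight most frequent haplotypes above 10⁻³ (renormalized); a sibling
whose member genotypes are incompatible with the pruned alphabet is
treated as untyped at that cluster rather than zeroing the family's
likelihood. The pipeline wrapper splits chained clusters larger than
the cap into contiguous chunks — small unrelated samples yield noisy r²
that occasionally chains long runs — while the lower-level fitting
function keeps a hard error so the cap is never exceeded silently.

## Multipoint linkage

The hidden state at a locus is the inheritance vector: one bit per
meiosis (two per child; a third founder serves half-sib structures).
Emissions marginalize founder alleles over population frequencies —
supplied panel frequencies by default, or sample-estimated ones, which
give nearly indistinguishable scans. A forward–backward pass per
chromosome over marker/cluster positions (Haldane map function) yields
vector posteriors; sibships sharing a pedigree structure are processed
as one numpy batch, which is what makes thousand-replicate
gene-dropping runs tractable. Posteriors match exhaustive enumeration
over vector paths × founder assignments to 10⁻⁹ on small instances.

**Allele sharing.** S_all is computed per vector by enumerating, over
all ways of picking one allele from each affected sibling, the product
of factorials of the founder-allele multiplicities, scaled by 2^(−a).
Null mean and SD come from exact enumeration over the uniform vector
distribution (sibpair values are exactly {1, 1.25, 1.5} with moments
1.25 and √0.03125). Per family the posterior is collapsed onto the few
distinct normalized scores, so the Kong–Cox likelihood

  LOD(t) = Σ_f log₁₀ ( E_post[e^{δZ_f}] / E_0[e^{δZ_f}] )

is evaluated cheaply on a coarse δ grid (step 0.05 on [0, 3]) and
refined by vectorized golden-section search to 10⁻⁶. The statistic is
one-sided (δ ≥ 0; LOD = 0 at δ̂ = 0); a signed variant used in
diagnostics allows δ < 0. The upper bound δ_max = 3 is far beyond any
fitted value (published excess-sharing estimates are ≤ 0.64); the
exponential model needs no positivity constraint. The fixed-position
null distribution matches the ½χ²₁ asymptotics: P(LOD > 0.59) ≈ 0.05
over 2000 simulated replicates. An NPL-style normalized mean score is
emitted alongside for reference.

**Parametric models.** For trait prevalence K (the category's
birth-cohort tail fraction), penetrance is 1 for susceptible genotypes
and K/10 for phenocopies, and the disease allele frequency solves
K = P_sus + (1 − P_sus)·K/10 in closed form (dominant:
q = 1 − √(1 − P_sus); recessive: q = √P_sus; the implied prevalence
reproduces K to 10⁻¹⁰). P(all sibs affected | vector) is computed by
the same founder-marginalization engine with the penetrance matrix as
emission; parents are phenotype-unknown. The conventional parametric
LOD sums per-family log₁₀ likelihood ratios; the heterogeneity LOD
maximizes Σ_f log₁₀(α·LR_f + 1 − α) over α on a 0.01 grid with one
parabolic refinement (hLOD ≥ max(0, LOD); hLOD at α = 1 equals the
parametric LOD).

**Error wiping.** For each call, the posterior probability that it is
erroneous is computed under a per-call error prior of 0.005 by comparing
the sibship likelihood with the call observed vs uninformative,
conditioning on the leave-one-locus-out vector distribution — the
multipoint evidence that exposes close double crossovers. Calls with
posterior > 0.99 are set to missing; passes repeat to a fixpoint, so
wiping is idempotent. Mendelian checks are impossible with untyped
parents. The conservative threshold has a quantitative consequence: an
isolated double crossover across 1-cM flanks caps the likelihood ratio
near 1/θ² ≈ 10⁴, just below the ≈2×10⁴ the 0.99 posterior demands, so
high sensitivity requires sub-cM spacing or multi-marker conflicts. The
sensitivity experiment therefore uses a 0.25-cM map of informative
quintet sibships (recall ≈ 0.77 at family × marker resolution, with
conflicts sometimes attributed to a sibling of the erroneous call);
both the threshold and prior are configurable.

## Empirical significance

Null replicates preserve the observed pedigrees, map, allele and
cluster-haplotype frequencies, missing-call pattern, and the observed
category memberships (each replicate is trimmed through the same
successive categories). Founder haplotypes are drawn at the drop-unit
level (singleton markers and whole clusters, zero recombination within
a cluster) and transmitted with Haldane recombination; draws are
batched over replicates in chunks of 50 to bound memory.

Each replicate set is scanned under every category. The empirical P
value for an observed peak is P = (r+1)/(n+1), where r counts distinct
(replicate, location) events meeting the observed LOD across all
categories — a replicate exceeding it in several categories at the same
location counts once. "Same location" means peak maxima within 30 cM on
one chromosome; the original radius is undocumented, 30 cM spans the
published peak widths, and the parameter is configurable. The combined
P value counts replicates harbouring two or more distinct qualifying
locations. The one-sided 95% Clopper–Pearson upper limit is computed on
the adjusted count (r+1 events in n+1 trials) — the only one of the
four natural conventions (one/two-sided × raw/adjusted) that reproduces
all three published worked examples, verified against exact binomial
tail evaluation before being frozen. Genomewide thresholds at level α
are the (1−α) quantile of the per-replicate genomewide maximum,
averaged over categories (per-category threshold) or taken over each
replicate's maximum across all categories (overall threshold). The
fixed single-scan screen LOD = 3.6 is a configuration constant, not
derived.

The full-fidelity threshold replication (279 sibships with the
published size mix, ~2000 markers at mean MAF 0.27 over a 3500-cM
genome, 200 replicates × 10 categories) runs for hours on one CPU and
ships as `examples/full_threshold_replication.py`; the test suite runs
a one-chromosome, 50-sibship, 40-replicate version that checks the
structural property (the overall threshold exceeds the per-category
threshold, and a one-chromosome scan sits below the genomewide 3.9).

## Simulation experiment sizes and what they show

* Null calibration: 2000 replicates × 60 sibpairs at a 9-marker,
  40-cM map; fixed mid-map position.
* Planted-locus recovery: 300 sibships, 160 markers over two 120-cM
  chromosomes, effect 15 years, 20 seeds per mode. The locus is planted
  as the sole familial component so the experiment isolates mapping
  accuracy; dominant architectures use a rare allele (q ≈ 0.11), since
  a common dominant allele makes nearly half the cohort susceptible and
  carries little sharing information. With the default 7-year familial
  background on top, the same effect yields peak LODs of ~1–3 and
  localization succeeds mainly at the stricter age cutoffs — the power
  loss that motivates the multi-category design, and the reason real
  scans of this design report peaks rather than certainties.
* LD inflation guard: with cluster definitions estimated once from 400
  unrelated diplotypes, the 95th percentile of the null genomewide
  maximum with clustering does not exceed the unclustered one over 40
  replicates.

## Numerical conventions

Haldane map function θ = (1 − e^{−2d/100})/2 for d in cM; strictly
increasing cM enforced per chromosome (ties broken at 10⁻⁹ cM in the
panel simulator). HMM scaling per locus; posterior normalization
verified to 10⁻⁹. EM from a fixed uniform start (random restarts agree
in log-likelihood to 10⁻⁶ on identifiable instances). All randomness
derives from one integer seed through named per-stage substreams;
identical seed and configuration give byte-identical outputs (replicate
streams are reproducible for a fixed replicate count, since draws are
batched per chunk). Genotypes are int8 codes 0/1/2 (copies of allele
"A", the allele whose frequency the panel records) with −1 for missing;
PED files encode allele "A" as 1.

## Known limitations

Exact inheritance-vector enumeration limits sibship size (V = 4^n
states; n ≤ 5 is instant, and the design never needs more). Pairwise
r² within a bounded window cannot merge markers further apart than the
window. The moment-based IBD classifier assumes markers in linkage
equilibrium and is noisy below a few hundred markers. The
delta/alpha maximizers assume a unimodal profile (true in practice for
these likelihoods; the coarse grid guards against local optima). The
error-detection model treats an erroneous call as uninformative rather
than modeling the substitution kernel, which slightly understates
evidence for errors that remain Mendelian-consistent.
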