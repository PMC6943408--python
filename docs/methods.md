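# Methods

This note documents the models implemented in `mosscrust`, the design of
the synthetic-data generator, and every numerical convention a user might
need to interpret or reproduce the outputs. It states no empirical result
that the test suite or `scripts/acceptance.py` does not itself compute.

## Survey dominance

For a quadrat survey with presence records (site, quadrat, species), the
four dominance indices are

* species frequency = 100 · S_N / (total quadrats),
* S_N / S, S_N / N_a, N_a / T_a,

with S_N the number of distinct quadrats holding species N, S the total
number of *samples collected* (a mixed ratio: the survey this models
collected 675 samples over 185 quadrats, and its published table is
consistent only with this reading), N_a the number of sites holding the
species, and T_a the total sites. All arithmetic is done at full
precision; rounding (1 d.p. for frequency, 3 d.p. for ratios) happens
only at the presentation layer. A species observed in zero sites reports
S_N/N_a as missing. Candidate dominants are the union of the top-k
species by frequency and the species above a coverage cut; coverage has
no formula in the source methodology and is accepted as an externally
measured column.

Two internal inconsistencies of the published top-20 table are carried
as printed and flagged rather than repaired: the S_N/N_a column total is
printed as 49.865 although its entries sum to 56.501, and row 1 pairs a
frequency of 39.5 with S_N/S = 0.118, which no single quadrat count can
produce (39.5% of 185 quadrats is ≈73, and 73/675 = 0.108).

## Drought-resistance evaluation

Membrane permeability is the electrolyte-leakage percentage
100 · EC1/EC2; EC1 > EC2 is physically suspect and warned about.
Replicate-level physiology is averaged per species before scoring.

The membership (subordinate function) transform is min-max
normalization per index across species, reflected for harmful indexes:
beneficial Z = (x − min)/(max − min), harmful Z = (max − x)/(max − min).
Directionality is Pro/SOD/POD beneficial and MP/MDA harmful — the
published membership table is only internally consistent under this map
(a species with the *best* membrane score ranks mid-table overall). A
constant index column has no min-max normalization; it raises a
`DegenerateIndexError` unless the caller maps it to 0.5. Every
non-constant column attains both 0 and 1 by construction.

The comprehensive score is the arithmetic mean of the five memberships;
rank 1 is the largest score; exact ties share the smallest applicable
rank, are flagged, and break deterministically by species id.
Classification thresholds default to high ≥ 0.55 and low ≤ 0.42 (closed
boundaries), which reproduce the published grouping of the seven
candidate mosses.

Grey relational analysis uses Deng's formulation with the comprehensive
score as the reference sequence: Δ_i(k) = |x0(k) − xi(k)|, coefficient
ξ = (Δ_min + ρΔ_max)/(Δ + ρΔ_max) with global extrema, grade = mean ξ
over species, ρ = 0.5 (the standard convention; exposed as a parameter).
Grades live in (ρ/(1+ρ), 1]; a grade of 1 occurs iff the sequences
coincide. The source study's printed "correlation coefficients" (0.2523,
0.2039) lie *below* Deng's analytic lower bound 1/3 at ρ = 0.5, so they
cannot be standard Deng grades of the printed memberships; whatever its
software computed is not reconstructible, and those printed values are
not treated as a correctness target.

## Community analyses

* **Alpha diversity.** Chao1 uses the bias-corrected form
  S_obs + F1(F1−1)/(2(F2+1)) (finite at F2 = 0); Shannon uses the
  natural log; Good's coverage is 1 − F1/N; Faith PD is the branch
  length spanning the observed leaves and the root. All four delegate to
  scikit-bio.
* **Distances.** Bray-Curtis on raw counts (scale-dependent by
  definition); unweighted UniFrac on presence/absence (count ≥ 1, no
  rarefaction by default). A tree whose root has more than two children
  is resolved with zero-length internal branches — this leaves every
  branch-length metric numerically unchanged, whereas rerooting (e.g.
  midpoint) would alter UniFrac on such trees.
* **NMDS** minimizes Kruskal stress-1 by SMACOF with monotone (isotonic)
  regression on ranks, 20 seeded restarts, 500 iterations, tolerance
  1e-6; the reported configuration is the restart with the lowest
  stress-1, recomputed from the final embedding.
* **UPGMA** is size-weighted average-linkage agglomeration (scipy);
  merge heights are non-decreasing and the Newick output halves each
  merge height into ultrametric branch lengths.
* **Venn decomposition** classifies each OTU by its exact set of groups
  (present = count > 0 in ≥ 1 sample of the group) over all 2^g − 1
  regions; the core is the all-groups region. The core count is
  monotone non-increasing as groups are added.
* **Dominant taxa** at a rank are those with mean relative abundance
  strictly above the threshold (default 1%); unassigned lineages pool
  as "unclassified".

## Hypothesis testing

**PERMANOVA** follows the adonis decomposition: G = −½ J D² J
(Gower centering), sequential (Type I) sums of squares over user-ordered
terms (treatment-coded factors, raw covariates, elementwise-product
interactions), pseudo-F against the residual, and p from free
permutation of sample labels with the add-one estimator
(1 + #{F* ≥ F})/(1 + n_perm); 999 permutations by default. Term R²
values plus the residual sum to exactly 1. An `exact=True` mode
enumerates all n! permutations for n ≤ 9 and returns the exact tail
proportion. Aliased terms raise an error naming the offender. Note that
a published per-factor table whose R² values sum above 1 is a set of
*marginal* (single-factor) fits; the analysis driver reproduces that
layout with one single-term model per factor, while the sequential
decomposition is used wherever additivity matters.

**LEfSe-style biomarkers.** Abundances are aggregated per taxonomic
level (phylum…genus) on the relative scale × 1e6. Each non-constant
taxon is screened by Kruskal-Wallis across classes (p < 0.05); survivors
get an effect size: because the one-component discriminant of a single
taxon is the taxon axis itself, the score is log10 of the largest
between-class separation of class means on the per-million scale,
averaged over 30 seeded within-class bootstrap resamples, and the
enriched class is the one with the largest mean. Reported biomarkers
pass both p < α and score > 2.0. Two simplifications relative to the
original formulation: the subclass (within-class Wilcoxon) stage is
omitted — the modelled design has no subclasses — and the
all-features-jointly LDA is replaced by the per-taxon discriminant just
described. No multiple-testing correction is applied beyond the stated
per-taxon thresholds (an FDR flag would be a departure from the source
convention and is deliberately absent).

**RDA/CCA.** The choice follows the gradient-length rule: CCA when the
DCA axis-1 gradient length is ≥ 3.5 SD (closed boundary), else RDA. The
gradient length is computed from correspondence-analysis axis 1 with
Hill-style scaling — sample scores are rescaled so the abundance-weighted
mean within-species variance of sample scores (the mean species
tolerance) is 1, and the length is the resulting score range in SD
units. This is the textbook definition of "gradient length in SD units
of species turnover" but *not* decorana's detrending-by-segments with
nonlinear rescaling; absolute lengths can differ from decorana's on the
same data, a known limitation. RDA runs on Hellinger-transformed
abundances, CCA on chi-square-weighted abundances (both via scikit-bio
for axes and eigenvalues; features never observed are dropped as they
carry no inertia). Per-covariate marginal R² is the constrained-inertia
fraction of a one-covariate fit, with permutation p (999 default) by
permuting the covariate. Nearly collinear covariate sets trigger a
warning naming the columns; zero-variance covariates are an error.

**Spearman heatmaps** correlate the top-50 genera (or a supplied
biomarker list) with each factor; p-values use the exact permutation
null for n ≤ 10 untied samples and the t-approximation otherwise; stars
follow the usual convention (* 0.01 < p ≤ 0.05, ** 0.001 < p ≤ 0.01,
*** p ≤ 0.001); rows and columns are ordered by average-linkage
clustering of the correlation matrix; constant genera report missing
correlations.

## Guild annotation

Rules map a taxon name at a stated rank to a guild with a confidence in
{possible, probable, highly probable}. Matching is case-insensitive and
exact (no regex); the deepest-rank match wins; rules below the caller's
minimum confidence are ignored; conflicting same-rank rules resolve to
the first listed, with a warning. Profiles are per-sample guild relative
abundances summing to 1, with an option to drop the unassigned residual
and renormalize (ratios among assigned guilds are preserved).
Single-guild assignment is the default; the rule table format allows a
taxon to appear in several rows, in which case first-listed precedence
applies.

## Co-occurrence networks

The top-50 genera by total abundance (ties broken lexicographically;
unclassified lineages pool by their deepest assigned name) enter a
Spearman correlation matrix; an edge is kept iff p ≤ 0.01 and |ρ| > 0.6
(|ρ| because the modelled study reports both strong positive and strong
negative correlations under "R > 0.6"), with the sign recorded. Constant
genera are excluded from correlation but remain as isolated nodes.
Average path length and diameter are computed on the largest connected
component with unweighted edges; transitivity is the global
3 × triangles / connected triples; communities come from deterministic
greedy modularity maximization on the unsigned skeleton (negative edges
participate as plain edges — signed community detection is out of
scope); major modules have > 10 nodes; keystone taxa are the top-3 by
betweenness (ties by degree, then name). Two equal disconnected blocks
bound modularity at exactly 0.5, so "modularity > 0.5" requires
additional small components — real co-occurrence networks, and the
generator, both have them.

## The synthetic-data generator

The generator reproduces the *statistical design* of the field study so
downstream stages can be tested for truth recovery. One master seed fans
out to fixed per-stage child generators, so each stage is independently
reproducible; every generator is byte-deterministic under a fixed seed.

**Survey.** Bernoulli occupancy per quadrat with per-species (optionally
per-site) probabilities; defaults: 14 sites, 185 quadrats spread as
evenly as possible, a 30-species pool with geometric-decay occupancy
(0.45 · 0.87^i) giving a strict expected-count ranking recorded as
truth. Coverage is a noisy monotone function of expected occupancy.

**Physiology.** Seven species with equally spaced "quality"; each of the
five indexes interpolates a realistic best→worst range (MP 20–80%,
Pro 1.5–0.1 mg/g, MDA 2–10 nmol/g, SOD 300–100 U/g, POD 250–50 U/g) by
quality, with replicate noise sized so adjacent species means are
2 replicate-SDs apart (typical assay CVs are well below between-species
separation). Which species holds which rank is a seeded permutation,
recorded as truth.

**Microbiome.** 18 samples (Hyp/Hyo × Ve/Se/Sl × 3), 2 892 OTUs in 534
genera (the study's bacterial counts), mean library ≈ 56 700 reads
(lognormal, CV 0.2), Dirichlet-multinomial with concentration
p · 300. Log-relative-abundance construction per sample:

* a light-tailed base composition (log-normal, σ = 1);
* centered sparse species and class shift vectors (support: a random
  half of the features; scales: species 2.2, class 1.0 log units) —
  species stronger than class, mirroring the modelled study's reported
  effect ordering, with the species > class R² ordering holding in ≈98%
  of simulations;
* 20 planted biomarker OTUs in dedicated singleton genera at moderate
  base abundance, shifted ±log(fold)/2 between the two species
  (default fold 100, alternating the enriched species); these features
  are excluded from the random shift supports so the planted fold is
  exact, and fold = 1 plants nothing;
* two 12-genus co-abundance modules among the top-abundance genera:
  each module has a latent factor (bounded uniform, unit SD, factors
  orthogonalized in-sample since they are independent by design) with
  sign-balanced ±1.2 loadings, centered by the members'
  abundance-weighted mean so the block has no common-mode mass shift —
  unbalanced exponential loadings would leak through compositional
  closure and correlate every other taxon; plus six satellite
  co-abundance pairs (loading 1.5) emulating the small components of
  real co-occurrence networks;
* module, pair and covariate-coupled taxa get 20× lower Dirichlet
  overdispersion, modelling tightly host-associated taxa whose planted
  structure is not drowned by sampling noise;
* covariates: drought indexes with species-dependent means (SOD
  292.03/229.18, Pro 1.42/1.16 for Hyp/Hyo — the modelled study's
  reported means — plus plausible POD/MP/MDA values) and climate
  variables with class-dependent means (rain, temperature, sunshine,
  elevation for a Guizhou-like gradient); three designated genera are
  coupled to Pro, SOD and POD at 1 log-unit per covariate SD;
* a random-coalescent bifurcating tree with exponential branch lengths
  over all OTUs.

Named conditions freeze the configurations the calibration and recovery
studies use: `null_community_config` silences *every* channel tying
counts to the design labels (shifts, biomarker fold, covariate
coupling), making labels exchangeable for type-I-error calibration;
`planted_module_config` keeps only the modules and satellites (fold = 1:
twenty 100-fold species-bimodal genera would otherwise form their own
major co-occurrence module).

**Guild rules.** A configured fraction (default 0.7) of observed genera
is mapped to guild labels drawn from the bacterial
(photoautotrophy, chemoheterotrophy, nitrate reduction, methanotrophy,
human pathogens) or fungal (plant pathogen, saprotroph subtypes,
endophyte, ectomycorrhizal, animal pathogen, fungal parasite) label
sets with random confidence levels; the genus→guild truth map is
recorded.

**What the generator does not emulate.** Phylogenetic signal in the
effects (shifts are independent of the tree), realistic heavy-tailed
rank-abundance curves, zero-inflation beyond the Dirichlet-multinomial,
taxonomic correlation between biomarkers (planted as singleton genera),
sequencing error and chimeras, spatial autocorrelation among sites, and
the actual taxa of the deposited sequencing data. Passing recovery tests
therefore shows the *pipeline* is correct and calibrated under the
modelled design, not that the study's exact published community values
(its Table-4 R² magnitudes, its 137/50 edge counts, modularity 0.67,
path length 2.248) are reproduced — those require the deposited reads
and are explicitly not targets.

## Problem sizes and runtime conventions

Calibration and recovery studies use the design-scale generator
(18 samples × 2 892 OTUs): 200 simulations × 999 permutations for the
PERMANOVA null, 100 simulations for effect ordering and for the LEfSe
null (50 in the acceptance script), 5 for biomarker recall, 100 for
drought-ranking recovery — sizes at which each study completes in
seconds to a couple of minutes on one core while leaving binomial noise
well inside the acceptance margins. Unit tests run a reduced generator
(400 OTUs, 120 genera) whose statistical structure is unchanged.

## Known limitations

* The grey-relation grades of the source study's software are not
  reproducible (below Deng's bound; see above).
* The DCA gradient length approximates decorana (no detrending by
  segments); only the RDA/CCA selection rule is relied on.
* The modelled study applies CCA to its fungal community at gradient
  length 0.661, contradicting its own stated rule; the implementation
  follows the stated rule and exposes `method=` as an override.
* Exact Spearman permutation p-values are limited to n ≤ 10 untied
  samples (n! enumeration); larger n uses the t-approximation.
* PERMANOVA's free permutation assumes exchangeable samples; the 3-rep
  nested structure of composite samples is not modelled as a blocking
  factor.
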