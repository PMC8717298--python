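# Methods

This note records the models and procedures `phylodom` implements, the
defaults and why they were chosen, what the synthetic generator does and
does not emulate, and the numerical conventions in corner cases.

## Dominance metrics and partitioning

Per site, a species' *cover* is its mean percent cover over **all** plots
(zeros included), *frequency* the fraction of plots occupied, and *cover-PO*
its mean cover where present; cover = frequency × cover-PO holds exactly by
construction. Cover within a plot may exceed 100% in total because canopies
overlap. Species with zero cover in every plot of a site are treated as
absent from that site.

Species are ranked descending on the chosen metric, with deterministic tie
breaks (frequency, then cover-PO, both descending, then name ascending) —
a reproducibility choice, since any rule is defensible for exact ties. With
k = 3 the ranking splits dominant / intermediate / nondominant; when the
species count is not divisible by 3 the remainder goes to the intermediate
group so the two compared extremes stay equal-sized (with k = 2 the
remainder goes to the nondominant group). Only the two extreme groups enter
the dispersion analysis.

## Dispersion null model and SES

The null reassigns the site's species to the partitions uniformly at random
without replacement, preserving the group sizes — equivalent to shuffling
tree tips without weights. Abundance weights are deliberately not used in
the sampling: abundance already defined the partitions. Each of the
`n_iter = 999` iterations contributes a random-dominant and a
random-nondominant value; pooled with the two observed values this gives
2·999 + 2 = 2000 values whose mean and SD standardize **both** partitions
(`pool="both"`). A per-partition pooling variant (`pool="per-partition"`,
999 + 1 values each) is available; the pooled default makes D_SES and
ND_SES directly comparable since they share the reference distribution.
Δ_SES = D_SES − ND_SES is exact by construction.

Local classification uses ±1.96·s with s = 1 for a single partition's SES.
For the disparity we use s = √2, the SD of a difference of two independent
unit-variance scores; the multiplier is an argument, so a stricter s = 2
convention is one keyword away. Global tests: Shapiro–Wilk at α = 0.05
gates between a KS goodness-of-fit test against N(0, √expected variance)
(expected variance 1 for D/ND, 2 for Δ) plus a two-sided χ² variance test,
and a two-sided Wilcoxon signed-rank test against 0; a one-sample t-test is
always reported alongside the normal branch for transparency. Fewer than 8
sites is an error — the tests are unreliable below that.

Degenerate inputs: a site whose null pool has zero variance (e.g. an
equal-branch star tree, or a trait with one value) gets no SES and is
excluded from that combination with a recorded reason; likewise partitions
with fewer than 2 usable species after trait missingness.

Trait dispersion uses |xᵢ − xⱼ| distances after a per-trait transform:
log10 for the right-skewed size traits (seed mass, plant height), identity
for the ratio-like traits (LDMC, leaf N). Transforms are configurable;
coverage fractions are reported because trait tables are rarely complete.

## Phylogenetic beta diversity

Each site × partition is represented by the branch set of the minimal
root-connected subtree of its species on the megatree; including the root
path keeps single-species partitions well-defined and makes summed branch
lengths equal Faith's PD. With a the shared branch length and b, c the
unique lengths, SOR = (b+c)/(2a+b+c), SIM = min(b,c)/(a+min(b,c)),
SNE = SOR − SIM; the multisite versions use Σ min, Σ max of the pairwise
unique fractions and ΣPDᵢ − PD(union), and reduce exactly to the pairwise
formulas for two sites. The pairwise index is reported as the mean over all
site pairs.

The null shuffles species among the three partitions within each site.  By
default the shuffle preserves each site's observed group sizes, keeping the
null comparable to the equal-thirds design; a multinomial
(`size_preserving=False`) variant draws labels with equal probability.  The
three partitions' null values are pooled (3 × 499 = 1497) and compared with
each observed value by a two-sided add-one empirical p,
2·min(P(null ≤ obs), P(null ≥ obs)) capped at 1. With equal group sizes the
three partitions' null distributions coincide; with a remainder the
intermediate group is slightly larger and its null shifts measurably (the
multisite indices have tiny sampling SDs), which is why the pooled reference
is built from all three — the same convention the observed values are
judged against.

## Lineage and genus scans

The occurrence unit is species × site: each species counts once per site it
occupies, toward every branch on its root path. Under no
phylogeny–dominance association each occurrence lands in each of the three
partitions with probability 1/3, so each branch × partition count is tested
with an exact two-sided binomial test (minimum-likelihood summation; scipy's
`binomtest`). Branches need ≥10 occurrences to be tested; genera are always
reported. No multiple-testing correction is applied by default — the scan is
exploratory and raw p-values are reported — but a Benjamini–Hochberg column
is available (`bh_correct=True`). The exact test is mildly conservative at
these counts; the calibration suite measures its realized type-I rate at
~4.5–5% on neutral simulations.

## Driver models

Ordinary least squares throughout, no site weights. Backward-stepwise AIC:
start from the full model, drop the predictor whose removal lowers AIC the
most, stop when no removal lowers AIC; ties break alphabetically, so the
path is deterministic and invariant to column order. Rank-deficient designs
are rejected with the offending columns named. Listwise deletion is applied
per response with the dropped count reported.

The d-separation test of an independence claim fits
`response ~ predictor + graminoid_prevalence` and reports the predictor's
partial coefficient test; a large p supports the claim that the predictor's
association with the response is mediated by prevalence. Only the
single-mediator claims are implemented — multi-equation structural models
are out of scope. Grouped ΔR² refits the final model without each
category's retained variables (location / climate / management / topology /
biomass, re-groupable via a dict); under collinearity the ΔR² values need
not sum to the full R², and this is not asserted anywhere.

## Tree utilities

* **Grafting**: a species with ≥2 congeners in the tree becomes a pendant at
  the congeners' MRCA with pendant length equal to the mean tip depth below
  that node; a single congener's terminal edge is split at its midpoint;
  otherwise the species drops to its family's MRCA; species with neither are
  reported ungraftable and excluded. These placements keep an ultrametric
  tree ultrametric (tested) and are idempotent for present species.
* **Faith's PD** includes the path to the root — the common convention, and
  the one that makes branch-set sums equal PD.
* **Gamma** (Pybus–Harvey) requires ≥3 tips and ultrametricity within
  1e-6 × depth (grafted trees can drift slightly); polytomies contribute
  zero-length internode intervals.
* **Colless** resolves polytomies as maximally unbalanced caterpillars
  (children in descending subtree size) — deterministic, no RNG in a summary
  statistic; Sackin is the plain sum of tip depths in edges.
* Pruning suppresses degree-2 nodes, summing branch lengths, and preserves
  all pairwise cophenetic distances among retained tips (tested to 1e-9).

## Synthetic generator

The generator emulates the survey design the pipeline targets: ≥30 1 m²
quadrats per site, site richness 20–60 from a 200-species pool, per-plot
functional-group biomass, and site covariates spanning field-realistic
ranges (graminoid prevalence 0.14–1 of live biomass, mean annual
temperature −8–27 °C, annual precipitation 216–2224 mm — the ranges a
global grassland survey reports). Trees are birth–death simulations under
the general sampling approach (which keeps the pure-birth gamma statistic
unbiased), with maximal clades of ≤5 tips sharing a genus and ≤25 tips a
family so taxonomy maps are derivable.

Each site's high-cover tier has size ⌈richness/3⌉, aligning the generator's
"true dominants" with the k = 3 partition. Cover-PO tiers are lognormal
with well-separated means (high tier ~25%, background ~4%) and occupancy is
Bernoulli per plot (high tier 0.6–0.95, background 0.1–0.6), so realized
cover ≈ frequency × cover-PO with clean tier recovery; plot-level noise is
lognormal with mean-preserving correction. The scenarios differ only in who
gets the high tier: a focal clade (~30% of the pool, operationally "the
graminoids"), a greedy-maximin-dispersed set, or a uniform random set.
Graminoid biomass share is set exactly to a per-site prevalence target;
with `prevalence_coupling=True` that prevalence also sets the fraction of
the high tier drawn from the focal clade, planting a true
prevalence → clustering effect for the driver stage to recover. Traits are
Brownian on the tree (two traits exponentiated to log-scale), with higher
missingness for nondominant species to emulate database sampling bias.

What the generator does **not** emulate: spatial structure within and among
plots, temporal dynamics, observer error in cover estimation, uneven plot
counts, non-random species pools across regions (region labels are drawn
independently of the phylogeny), and realistic covariate–climate
correlation structure. Passing recovery tests therefore shows the
*statistical machinery* is correct and calibrated, not that field data will
show any particular effect size.

## Problem sizes and calibration bands

The test and acceptance runs use: 999 dispersion shuffles and 499 beta
shuffles (the analysis defaults); 50-site runs for the directional
scenarios; 300 sites for the neutral band, because the per-site disparity
SD is ≈1.5 and the mean's band of ±0.2 needs SE ≈ 0.09; 2000 sites for the
SES moment calibration; two 100-site neutral metacommunities (≥2000 tested
branch × partition rows) for the scan's type-I rate; and 300–400 replicates
for the d-separation type-I rate. Seeds are fixed in tests; every
stochastic stage is byte-reproducible given a seed.

## Known limitations

* The backward-stepwise path is greedy; it is checked against an exhaustive
  subset search on well-conditioned designs but is not guaranteed to find
  the global AIC optimum under strong collinearity.
* The exact binomial scan ignores the weak negative dependence induced by
  fixed within-site group sizes, making it slightly conservative.
* Family-level graft placement (pendant at the family MRCA) is one of
  several defensible conventions; alternatives shift deep-node distances
  for grafted species.
* The d-separation stage tests one mediator at a time; claims requiring
  simultaneous adjustment for several variables are not covered.
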