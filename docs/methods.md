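# Methods

## Pipeline

The analysis starts from four aligned objects: an sOTU count table (samples x
features), a SILVA-style ranked taxonomy per feature, per-sample metadata
(country, household, sample type), and a rooted phylogeny whose tips are the
feature identifiers. Stages run in a fixed order, enforced by the
orchestrator:

1. **Organelle filter** — features whose lineage contains "mitochondria" or
   "chloroplast" (case-insensitive, any rank) are dropped; the per-sample
   fraction of sequences removed is reported. A sample emptied by this filter
   is an error, not a silent drop.
2. **Low-count filter** — features with grand total < 10 or present in fewer
   than 2 samples are dropped. Presence means count > 0; no minimum-fraction
   rule is applied.
3. **Shallow-sample exclusion** — samples with fewer total reads than the
   rarefaction depth (default 10,000) are excluded and listed. The surviving
   samples keep their *unrarefied* counts for the compositional branch;
   rarefied counts are used only by the diversity branch.
4. **Diversity** — alpha metrics (observed features, Shannon base 2, Faith's
   PD including the root path) are averaged over repeated independent
   rarefactions (default 10 iterations at depth 10,000; multivariate
   hypergeometric subsampling, i.e. without replacement). Beta metrics
   (Jaccard on presence/absence, Bray-Curtis, unweighted UniFrac, and the
   non-normalized weighted UniFrac) are computed on a single rarefied table;
   ordination is classical PCoA.
5. **Genus-level collapse (L6)** — features are summed over their lineage
   prefix through rank 6. The group key keeps the full prefix, so two
   identically named genera in different families never merge, and a feature
   unassigned at genus collapses under its deepest assigned rank (typically
   the family), which is also its display name.
6. **Relative abundance, abundance filter, CLR** — rows are closed to 1;
   the abundance filter keeps taxa with mean > 1% or max > 5% (strict
   comparisons, per the wording "higher than"/"exceeding") and deliberately
   does **not** renormalize, so the filtered table is an open composition;
   the CLR transform subtracts the per-sample mean log.
7. **Core criteria** — F1/F2/F3 are evaluated on the *full* L6 relative
   table (before the 1%/5% filter). Rationale: the number of taxa passing F2
   must equal the abundance-filter output, which is only true when the
   criteria see the unfiltered table. "All consumers" in F3 means all
   households present in the analyzed sample set, including single-sample
   households.
8. **Group analyses** — cell means per (country, sample type) with absent
   cells omitted (never zero-filled); Euclidean complete-linkage clustering
   of rows and columns with optional column standardization
   (scale → distance → cluster); PCA of the CLR table by SVD; one-way
   PERMANOVA on distance matrices; per-taxon permutation F-tests across
   countries within each sample type with BH-FDR; and the mixed model
   `response ~ country + sample_type + (1 | household)` fitted by REML
   (statsmodels MixedLM), reporting the household variance component as a
   share of (household + residual) variance and estimated marginal means
   computed over observed design cells with equal weights.

The per-taxon permutation screening is a declared substitute for 50-50 MANOVA
with rotation tests (an external method this package does not reimplement);
its outputs carry `method="permutation_F"`, and its country-effect variance
share (multivariate among-group sum of squares over total) is analogous to,
but not identical with, a 50-50 MANOVA decomposition.

## Key parameters

| parameter | default | unit | rationale |
|---|---|---|---|
| rarefaction depth | 10,000 | reads | retains diversity while excluding only the shallowest samples |
| rarefaction iterations | 10 | – | averages out subsampling noise in alpha metrics |
| low-count thresholds | total ≥ 10, ≥ 2 samples | reads / samples | removes denoising artifacts and singleton-sample features |
| abundance filter | mean > 1% or max > 5% | relative abundance | separates consistently abundant taxa and sporadic bloomers from the tail |
| core criteria | F1 1%, F2 1%/5%, F3 = all households | – | the three-way prevalence/abundance definition |
| CLR zero replacement | δ = half the smallest nonzero value, table-wide | relative abundance | simple, reproducible; applied only when zeros exist |
| Shannon base | 2 | bits | common amplicon-workflow convention; base is a parameter |
| permutations (PERMANOVA/screening) | 999 | – | p resolution 0.001 with the add-one estimator |
| screening cell minimum | 5 | samples | country x sample-type cells below this are excluded |

Numerical conventions: permutation p-values use the add-one estimator
(p = (1 + #{F* ≥ F}) / (1 + n_perm)), so p is never 0; PCoA retains negative
eigenvalues in the report but excludes them from axes and from the
proportion-explained denominator; PCA/PCoA axis signs are fixed by making the
largest-magnitude loading positive; clustering ties are broken by sorting
labels lexicographically before linkage; display rounding is half-up at two
significant figures for percentages, computation always on unrounded values.

## Synthetic study generator

The generator emulates a five-country household survey: 15 households per
country, up to 7 sample types per household drawn with type-specific
inclusion probabilities (matched to the observed per-type sample counts of a
~300-sample study), one country contributing no cleaning utensils (the
missing-cell motif), and log-normal sequencing depths (median 50,000,
log-sd 0.7, so ~1% of samples fall below the 10,000 rarefaction depth).

Community model, per sample: taxon log-abundance = baseline + country effect
+ sample-type effect + household intercept + per-sample noise, all Gaussian;
composition = softmax; counts ~ Dirichlet-multinomial at the sample's depth.
Planted structure with known truth:

- **8 core taxa** — high baseline (log-mean 3.0), colonizing every household;
- **5 bloom taxa** — one sample each with a planted spike of 6–20%, sporadic
  trace presence elsewhere (so the single-sample filter does not erase them);
  they must land in the F2-only Venn region;
- **4 rare "pathogen-like" taxa** — present in ~3% of samples at 0.05–0.3%
  abundance, with one designated sample dominated at 43%;
- **background taxa** — log-normal baselines plus *household occupancy*: each
  background taxon colonizes a household with probability 0.8. Without
  occupancy, any taxon above ~0.5% mean abundance would be detected in every
  household at depth 10,000 and near-universal occurrence would carry no
  signal; patchy colonization is what makes F3 informative in real surveys.
- **2 organelle features** — a fixed composition fraction per sample type
  (10% on cutting boards, 2% elsewhere), exercising the organelle filter.

The Dirichlet concentration is 500: low enough for visible overdispersion,
high enough that a resident taxon at ≥ 1% abundance has negligible
per-sample dropout at depth 10,000 (alpha = 5). Sample-to-sample spikes are
carried by the log-scale noise and the planted motifs rather than by
near-zero Dirichlet alphas, which would make *every* low-abundance taxon
drop in and out of samples and contradict the premise that the planted core
is ubiquitous.

What the generator does **not** emulate: realistic phylogenies (the tree is
a random sequential coalescent with Exp(1) branch lengths — valid topology
and branch lengths, nothing more), taxonomy-classifier error, chimeras,
cross-sample contamination, or correlated taxon dynamics. A green
planted-core recovery test therefore establishes that the pipeline's
filtering and criteria arithmetic is correct under a plausible
abundance/occupancy model — not that the thresholds are optimal for any
particular real survey.

## Known limitations

- F3 has no detection-floor option; a single read in one sample of a
  household counts as occurrence there.
- The mixed model assumes Gaussian responses; relative abundances of core
  taxa are analyzed untransformed or CLR-transformed at the caller's choice.
- The country-screening variance share is not comparable across packages
  that decompose variance via 50-50 MANOVA.
- Weighted UniFrac is reported non-normalized by default (a normalized
  variant is available); its values are not bounded by 1.
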