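# Methods

## The problem setting

Upper-genital-tract specimens (endometrium, fallopian tube, ovary) carry
bacterial loads within one or two orders of magnitude of the DNA introduced
by reagents and handling. Any 16S profile from such a specimen is a mixture
of genuine community and kitome, in proportions set by the specimen's true
biomass. The package therefore treats three measurements as one problem:
absolute load (qPCR), contaminant identification (negative controls), and
composition (read counts), and only then asks the comparative questions —
continuum along the tract, community types, diversity, and differential
abundance between benign and cancer groups.

## Contamination model and the prevalence test

The generator and the decontamination stage share one model: each specimen
contributes a constant mass of contaminant DNA `c0` and a variable mass of
genuine DNA equal to its true load `L`, so the expected contaminant read
fraction is `c0 / (c0 + L)`. Negative controls (`L = 0`) contain contaminant
reads only. This is what makes a prevalence test sensible: contaminants are
present in (nearly) all controls and predominantly in low-biomass specimens,
while genuine taxa are absent from controls.

`score_contaminants` builds, per taxon, the 2x2 presence/absence (count >= 1;
no higher presence floor) by class (true sample vs pooled control) table and
computes a one-sided p for over-representation in controls: Fisher's exact
test when any expected cell is below 5 (the classical small-count rule),
otherwise a Pearson chi-square halved to the control-enriched side. A taxon
is flagged when p < 0.5; a taxon absent from every control is never flagged.
The one-sided alternative is deliberate — a two-sided test would flag
biological taxa *depleted* in controls, which is every genuine taxon. All
four control types (air, knife, extraction kit, sequencing kit) are pooled
for the test; per-type presence counts are reported for audit only.

The low-information filters then keep taxa with at least 5 counts in at
least ceil(10% of samples) samples and drop the 5% of survivors with the
smallest inter-quartile range of counts (ties broken by taxon id). The IQR
rule is interpreted as *removing* the lowest-variance fraction — the
variance-filter semantics of the common marker-gene analysis platforms; the
fraction is configurable because the alternative reading (keeping taxa whose
IQR exceeds 5% of the count range) is defensible too.

## Quantification

The standard curve is OLS of Ct on log10(copies per reaction) over a
ten-fold dilution series (>= 3 levels required; the fit warns below
r² = 0.98 or outside 90-110% efficiency, with efficiency = 10^(-1/slope)-1).
Copies per reaction invert the curve; total copies scale by
extract volume / loaded volume (50 uL / 5 uL = x10). A sample is called
above background when total copies exceed 700 — strictly, a recorded choice
since "at 700" does not state the boundary — and the call is reported as a
fraction per (site, group) stratum. Standards are supplied in copies; a
helper converts genome equivalents of the *E. coli* standard (7 16S copies
per genome) when needed. Loads are not normalised to per-species 16S copy
number, so "copies" overstate cell counts for multi-operon taxa uniformly
across groups. Cytokine plates are corrected per well by the ratio of the
well's total protein to a reference well's, multiplying the raw pg/mL.

## Continuum statistics

A taxon is "present" at a site when its relative abundance is at least 0.5%
(inclusive). For each patient with two or more matched sites the pipeline
reports per-pair S1, S2, shared count c and `DSC = 2c/(S1+S2)` (0 for two
empty sets, with a warning, to keep medians defined), exclusive Venn region
counts over all sites (they sum to the union size), and a full-continuum
flag: the single most abundant taxon of each lower-tract site is present at
every matched upper-tract site. Taxon identity is the species label when the
taxonomy provides one, else the OTU id. Paired within-organ similarity is
the squared Pearson correlation of fraction vectors over the union of taxa
nonzero in either sample (Spearman available); fewer than 3 such taxa gives
a missing value.

## Community typing and frequency tests

Counts are rarefied per anatomical site to the lowest read count among
samples with at least 500 reads (shallower samples are dropped, mirroring
low-read exclusions), by multivariate hypergeometric draws — exact sampling
without replacement, so column sums hit the depth exactly and no count grows.
Ward-linkage clustering on Euclidean distances between genus-level fraction
vectors provides the exploratory dendrogram; the reported labels come from
the deterministic rules, in precedence order: Lactobacillus >= 75%;
Gardnerella >= 50% with Lactobacillus the second genus; Streptococcus >= 36%
(vaginal sites only); otherwise high-diversity/other. The garbled published
condition for the Gardnerella/Lactobacillus type ("Lactobacillus > > 40%")
is resolved as "Lactobacillus ranks second", the only reading consistent
with fractions summing to 1 when Gardnerella holds >= 50%; the rule trace
records which threshold fired. Group-by-type tables are tested with the
Pearson chi-squared statistic without continuity correction — the form that
reproduces the published table p-values from their printed counts — and 2x2
demographic tables with Fisher's exact test reporting the sample
cross-product odds ratio ad/bc (again matching the printed values; exact CI
methods are not reproduced).

## Diversity and group comparison

Shannon entropy uses natural logarithms (a base option exists). Bray-Curtis
on per-sample fractions is `1 - sum(min(p_i, p_j))`, returned as a
scikit-bio `DistanceMatrix`; empty samples sit at distance 1 from everything.
Two-group scalars use Mann-Whitney (exact when sample sizes are small and
ties absent, normal approximation otherwise), more groups Kruskal-Wallis
with tie correction; Dunn's z-based post-hoc comparisons use pooled
mid-ranks with tie correction and Bonferroni adjustment over the pairs
tested. PERMANOVA computes the pseudo-F from among/within sums of squared
distances and estimates p as `(1 + #{F_perm >= F_obs}) / (1 + n_perm)` over
seeded label permutations (default 999). The implementation is local so the
permutation stream is explicit and reproducible; the test suite cross-checks
the statistic against scikit-bio's and the p-value against exhaustive
enumeration at n = 6.

## LEfSe-style differential abundance

Features are relative abundances scaled by 1e6 (the convention that makes a
log10 score of 2 mean a 100-per-million class difference). Per feature:
Kruskal-Wallis across the two classes at alpha 0.05; an optional subclass
consistency check (pairwise sign agreement between subclasses across
classes); then an effect size from 30 bootstrap rounds of 2/3 stratified
subsampling, each contributing the class difference of the feature's
one-dimensional discriminant mean, averaged and reported as
log10(|difference|). Significant = passes all gates with score > 2. Exactly
two classes are supported; subclasses default to none.

This recipe screens per feature without multiplicity control, exactly like
the published procedure. The consequence — measured by the acceptance suite,
not assumed — is that on permuted class labels the chance that *some*
feature is called significant is close to 1 - 0.95^m for the m features
abundant enough to clear the score cutoff (~0.9 here with ~45 such genera).
Users should read LEfSe outputs as ranked candidates, not error-controlled
discoveries; the recovery test (spiked Lactobacillus depletion and anaerobe
enrichment found in 100/100 seeds) shows the power side of that trade.

## The synthetic cohort

The generator draws, per patient, a lower-genital-tract composition from a
Dirichlet over 60 named genital/gut taxa; the benign prior concentrates ~60%
of its mass on four Lactobacillus species, and the cancer prior divides the
Lactobacillus weights by 10 and multiplies a six-taxon anaerobe set
(Porphyromonas, Prevotella, Peptoniphilus, Anaerococcus, Fusobacterium,
Bacteroides) by 5. The prior's total concentration (~5) is set so that
dominance-skewed states — Lactobacillus-dominant at >= 75%, occasional
Gardnerella- or Streptococcus-led samples, and high-diversity communities —
all occur, as in real vaginal ecosystems. Each upper-tract site mixes the
patient's lower-tract composition with weight w (default 0.6) into an
independent site-specific draw; the rectum is an independent gut-weighted
draw, giving the low vagina-rectum sharedness seen in practice. True loads
are log-normal per site (total extract copies; endometrium median ~10^3, so
roughly 60% of benign endometrial samples clear the 700-copy cutoff;
vagina/cervix/rectum 10^5-10^6.5), with the cancer group shifted down 1.5
log10 in the vagina, cervix and rectum. Contamination follows the mixture
model with c0 = 300 copies, which keeps negative controls below the
background cutoff and makes contaminant read share range from ~25% in the
endometrium to ~0.1% in the vagina. Counts are multinomial at depth 2000;
controls (per type: air, knife, extraction, sequencing) draw from the
contaminant pool only. One explicit RNG stream per dataset.

What the generator does **not** emulate: sequencing error and chimeras,
batch-specific kitomes (one contaminant composition per dataset),
per-species 16S copy-number variation, patient covariates (age, BMI,
menopause), and community-state mixtures richer than a single Dirichlet per
group (Gardnerella/Streptococcus-led states are rarer than in real cohorts).
Passing tests therefore demonstrate correctness of the statistical machinery
and recoverability of the planted structure — not that real cohorts will
show effects of these sizes.

## Numerical choices and degenerate inputs

- Presence means count >= 1; prevalence thresholds are inclusive ("at
  least").
- The 700-copy call is strict (>); fractions are monotone non-increasing in
  the cutoff.
- Sorensen of two empty sets is 0 (warned); `DSC = 2J/(1+J)` with Jaccard J
  is verified as an identity in the tests.
- Zero-read samples become zero columns in relative-abundance tables
  (warned) and sit at Bray-Curtis distance 1.
- Chi-squared drops all-zero category columns first; a table left with one
  column returns statistic 0, p 1.
- Fisher's OR with a zero cross-product denominator is reported as inf (or 0)
  with a note rather than raising.
- Rarefaction with `depth="min"` excludes samples under the 500-read floor
  before taking the minimum; exactly-at-depth samples pass through unchanged.
- Decontamination first, then the OTU filters, then per-site rarefaction,
  then normalisation — the order is fixed and recorded here because the
  alternative (rarefy first) changes presence patterns the prevalence test
  sees.
- Pipeline thresholds live in one flat `PipelineConfig`; defaults are the
  operating values quoted throughout, so every analysis stage can be audited
  from a single document.

## Problem sizes

The default analysis cohort is 24 benign and 37 cancer patients across eight
sites (496 samples) at depth 2000. The test suite's simulations use 40-100
samples per dataset, 100 seeds for the LEfSe recovery rate, 200 label
permutations for its null rate, and 500-1000 replicates for the type-I-error
calibrations, with PERMANOVA at 199 permutations inside those loops and 999
elsewhere.
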