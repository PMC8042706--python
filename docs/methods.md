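# Methods

## The question the pipeline answers

After a whole genome duplication (WGD), every gene briefly exists in two
copies (ohnologs). Over tens of millions of years one copy may keep the
ancestral expression level while the other drifts, is pushed down toward
pseudogenization, or gains a new (possibly tissue-specific) expression
level. `ohnoshift` implements a comparative pipeline that asks, for each
orthogroup across a clade of WGD-descendant species plus outgroups,
whether expression in the duplicated lineage has shifted to a new
optimum — and then characterizes the symmetry, genomic context, and
functional associations of those shifts. Because the pipeline is
exercised on synthetic cohorts with planted truth, every step can be
validated end-to-end.

## The phylogenetic Ornstein-Uhlenbeck model

Per gene, log2 expression evolves on the species tree as an
Ornstein-Uhlenbeck (OU) process with optimum θ, pull strength α (units:
1/time, with the tree's branch lengths defining time), and drift
variance rate σ². At stationarity, species separated by patristic
distance d have

    Cov(i, j) = (σ² / 2α) · exp(−α d).

Biological replicates within a species scatter around the species mean
with variance β·σ²/(2α); β is the dimensionless within-/between-species
variance ratio. The root state is drawn from the stationary
distribution at the base optimum, which is what yields the exp(−αd)
covariance above.

The shift test paints the tree with two regimes: the WGD-descendant
clade (stem branch included — an interpretation choice; the crown-only
variant would weaken attraction further) gets its own optimum θ_shift,
the rest keeps θ_base. Tip expectations follow the Hansen weighting: a
branch segment under optimum θ_r occupying [s₀, s₁] of the root-to-tip
path of total depth T contributes θ_r·(e^{−α(T−s₁)} − e^{−α(T−s₀)}).
The null model has a single optimum. Both models are fit by maximum
likelihood per gene, and

    LRT = 2 (log L_alt − log L_null),   clamped at 0,

is referred to the upper tail of χ² with one degree of freedom;
LRT > 3.8415 (the 95% quantile) is called significant, and the sign of
θ̂_shift − θ̂_base gives the shift direction. The χ²₁ reference (rather
than the boundary mixture ½δ₀ + ½χ²₁) is the convention this package
follows for the test; the clamp makes the test mildly conservative at
the boundary and the free nuisance estimation makes it anticonservative
overall (see Limitations).

### Fitting

For fixed (α, β) the optima and the stationary variance have closed-form
generalized-least-squares solutions, so the likelihood is profiled and
numerical optimization runs over (log α, log β) only, by bounded
L-BFGS-B from three deterministic starts (α at {0.25, 1, 4}/root-depth,
β from a one-way within/between variance decomposition) plus seeded
random starts, five in total. Bounds: α ∈ [10⁻³, 5·10²]/root-depth,
β ∈ [10⁻⁴, 10⁴]. The profiled variance is floored at 10⁻¹² so constant
input (a gene with identical values everywhere) yields a finite
likelihood and θ̂ equal to that constant. A Cholesky failure marks the
fit non-converged and the gene is excluded downstream with a reason.

### Test units

Singleton trees are tested once. Ohnolog trees are tested once per
duplicate clade, with the other clade removed; both units share the
outgroup expression unchanged. The species tree is pruned to the
species with data in the unit (patristic distances preserved, unary
nodes collapsed); units with fewer than three species are returned
untested — the model is unidentifiable below that.

## Upstream filters

Gene trees arrive pre-split into monophyletic clades with
`SPECIES|geneid` tip labels. A tree is rejected when it has more than
two maximal ingroup clades, when an ingroup clade still contains one
species twice after one split at the duplication node, or when an
outgroup species appears twice; otherwise it is a singleton (one clade)
or ohnolog (two clades), complete iff every expected ingroup species is
present in every clade. Expression-based exclusions then drop trees
whose duplicate clade is entirely unexpressed (all replicates at TPM 0;
the threshold is configurable), whose sister-outgroup anchor (pike
role) is missing/unexpressed, or whose distant-outgroup anchors
(zebrafish/medaka roles) are both missing/unexpressed. Rooting is taken
as given; re-rooting is not attempted.

## Normalization

TMM (trimmed mean of M-values) is re-implemented on TPM directly:
M = log2(test/ref), A = ½·log2(test·ref), genes with a zero in either
column dropped, the central 40% of the M-distribution and central 90%
of the A-distribution retained by ranks (average ranks on ties), and
the factor is 2 to the precision-weighted mean of surviving M-values
(inverse asymptotic binomial variance weights from the column totals).
Fewer than 10 surviving genes triggers an untrimmed fallback with a
warning. The reference column is the one whose upper quartile is
closest to the mean upper quartile.

Stage 1 normalizes replicates within each species, with factors
geometric-mean-centered to 1 per species. Stage 2 builds a species ×
singleton-orthogroup matrix of replicate means (ohnologs never enter),
computes one TMM factor per species on composition-normalized columns
with the column total carried in the divisor — this makes a global
rescaling of one species cancel exactly, up to the geometric-mean
centering across species that preserves the overall scale — and divides
every replicate of the species by its factor. Finally values are
transformed as log2(TPM + 0.01). A state machine (raw →
within-normalized → between-normalized → logged) refuses re-running or
skipping stages.

## Pair classification and tissue statistics

Each copy's call reduces to up/down (significant) or cons; the
unordered pair gives six categories: cons+cons, up+cons, down+cons,
up+up, down+down, up+down (up+down kept distinct from the asymmetric
categories). Pair asymmetry is |mean log2 difference between copies|
pooled over all ingroup samples of species carrying both copies.
Against an independent tissue atlas, concordance counts the non-focal
tissues in which the shifted copy is strictly lower/higher than its
partner (ties count in neither). Tissue specificity uses
τ = Σ(1 − xᵢ/max)/(N−1) on linear values (a log variant is available),
and the focal-tissue (liver-role) filter keeps genes with focal
expression ≥ 0.9 of their row maximum and τ > 0.6 (a quantile-based
variant of the level rule is available by flag).

## Genomic context

All intervals are 0-based half-open; overlap is strand-blind and needs
≥ 1 shared base. Promoters are strand-aware TSS windows (defaults
−2000/+200 for TE load; the window is a parameter because bound-TFBS
analyses conventionally use −3000/+200), clipped to the chromosome. TE
load is the fraction of the promoter covered by merged TE intervals.
The liver-network cascade over up+cons pairs with a tissue-specific up
copy: per motif keep the top 4 candidate TFs at E < 1e−10 and alignment
length > 100; keep TFs bound in ≥ 20 target promoters; keep
liver-specific TFs; then one TF per motif (largest |LRT| — "strongest
shift" operationalized as the LRT, configurable), merge motifs whose
target sets overlap > 80% (overlap coefficient), collapse multi-motif
TFs, and rank by up-shift bias (bound up-copies − bound cons-copies,
ties by total targets) keeping the top 9 for display. Every stage's
surviving TF set is retained for audit, and an empty stage is labelled.

## Association tests

Paired Wilcoxon signed-rank: exact by full sign-assignment enumeration
(dynamic programming over doubled average ranks) up to n = 25, normal
approximation with tie and continuity corrections above. Fisher's exact
test via the hypergeometric distribution (two-sided: tables no more
probable than observed). Pathway enrichment is a one-sided
hypergeometric over-representation test per term with all tested
ohnolog orthogroups as background. Complex-label homogeneity uses
10,000 label permutations with the (b+1)/(n+1) empirical-p estimator
(never exactly zero; conservative). Fractionation bias is a per-block
two-sided exact binomial test of loss counts against Binomial(n, ½) —
the block-level statistic is this package's declared choice, isolated
behind one function. Spearman correlation uses average ranks, exact
permutation p at n ≤ 10, t-approximation above. No multiple-testing
correction is applied unless configured; raw p-values are reported.

## The synthetic cohort

The generator emulates the study design, not read-level data: a 7-taxon
ultrametric species tree (root depth 1.0; four ingroup species, crown
at 0.8 with the WGD dated at 0.7 on the stem branch that begins at 0.5
where the sister outgroup splits; two distant outgroups joining evenly
toward the root — scales echoing the real chronogram, fixed by
convention), 120 singleton + 220 ohnolog orthogroups (~65% ohnolog
share, scaled down ~30× from the study for desk runtime), 25% partial
trees (1 to n−1 tips deleted from one copy, never breaking monophyly),
four replicates per species. Expression: species means drawn from the
OU multivariate normal on the *gene* tree with the planted regime
painting (α = 2, σ² = 1, β = 0.3 per unit root depth, so α·T = 2 and
stationary SD = 0.5 log2 units); replicates add N(0, β·σ²/2α); output
back-transformed to TPM via 2^x − 0.01 floored at 0 (floor events
counted in the truth record). Planted pair categories: 8% up+cons, 20%
down+cons, 3% up+up, 6% down+down, 3% up+down (40% of pairs shifted,
down-dominant); singletons: 11% up, 9% down. Shift magnitude Δθ = 1.5
log2 units — a free parameter, since real shift magnitudes are not
identified; sensitivity to it is what the power curves measure. A
quarter of shifts are tissue-specific in the atlas (focal-only, with a
squared multiplier so the atlas sees them clearly); the rest move the
focal tissue and, concordantly, 77% of the other 14 tissues. Ohnolog
copies share their orthogroup's ancestral atlas profile. Planted
context signal: down-shifted copies carry 2.5× the TE insertion rate;
up-shifted copies gain extra bound liver-TF sites, TE-overlapping with
a TC1-Mariner bias; one pathway is enriched among down-shifted pairs;
protein complexes are drawn label-homogeneous 70% of the time.
Randomness is a single seed with deterministic per-stage sub-streams,
so identical configs reproduce byte-identically.

What the generator does *not* emulate: mapping/quantification noise,
gene-length effects, correlated expression between orthogroups,
assembly errors, real TE sequence content, or footprint-score noise.
Passing recovery tests therefore demonstrates the statistical chain is
correct under its own model, not that the model is adequate for any
particular real dataset.

## Problem sizes

The validation harness runs 100 random-tree likelihood-oracle cases,
500 null genes for calibration, 200 genes per shift size for power, and
one full default cohort (340 trees, ~560 clade tests) — sizes chosen so
the whole suite completes in minutes on one CPU while keeping
Monte-Carlo error a few percent.

## Limitations

- **Small-sample behaviour of the shift test.** With seven species the
  likelihood is nearly flat in α (phylogenetic half-life is barely
  identified), and per-gene free ML of (α, β, σ²) in both models makes
  the χ²₁ LRT anticonservative: measured type-I error is ≈ 0.19–0.22 at
  the nominal 0.05, entirely attributable to nuisance re-estimation
  (fixing the true α, β gives 0.048, and the likelihood itself matches
  direct MVN evaluation to 10⁻¹⁴). For the same reason θ̂_shift is
  attenuated toward the clade sample mean (median error ≈ −0.6 at
  Δθ = 2) although the *direction* is essentially always right. These
  are properties of the procedure itself at this taxon count, not of
  the implementation; consumers should treat per-gene "significant"
  calls as an enriched-but-contaminated set and category counts as
  biased toward shifted categories. A parametric bootstrap would
  calibrate the test but is out of scope.
- Between-species TMM assumes singleton orthogroups are mostly
  non-divergent; with few singletons the trim can leave under 10 genes
  and fall back to the untrimmed mean (warned).
- Gene trees are used with their given rooting; reconciliation and
  re-rooting are upstream concerns.
- The fractionation-block statistic is a declared stand-in (exact
  binomial per block); block definitions come from the caller.
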