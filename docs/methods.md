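# Methods

This note documents the models, defaults, and numerical choices behind
`planktonscape`, and what the synthetic-data tests do and do not establish
about real surveys.

## Study design and data model

The unit of analysis is an OTU count table (taxa × samples) from a
spatially and seasonally replicated survey: 6 sites along a ~50 km
reservoir transect × 3 seasons (summer, summer–autumn transition, autumn)
× 3 replicates = 54 samples, with per-sample metadata (site, season,
replicate, coordinates) and ten measured environmental variables (WT °C,
pH, DO mg/L, Secchi depth SD m, Chl a mg/m³, TN, TP, NH₄⁺-N, COD_Cr,
COD_Mn mg/L). Counts are validated as nonnegative integers; composition
summaries use read-count proportions (the proportion basis is configurable
but read counts are the default, since OTU-count proportions discard
abundance information).

## Synthetic survey generator

The generator exists so that every estimator can be tested by parameter
recovery against known ground truth. It emulates:

- **Regional pool**: relative abundances drawn lognormal(μ=0, σ=2) over
  2,000 OTUs and normalized — a long-tailed species-abundance distribution
  typical of amplicon surveys.
- **Neutral assembly**: each sample's composition is Dirichlet with
  concentration `N_T·m·p` (default depth N_T = 20,000 reads, migration rate
  m = 0.1), then reads are multinomial. The Dirichlet-multinomial is the
  finite-sample analogue of the Sloan beta prediction, so the neutral-model
  fit inverts it exactly; recovery of m is a true inverse test.
- **Niche filtering**: per-OTU optima on a standardized latent
  environmental axis; sampling weights `p·exp(−s·(optimum − env)²)` with
  default strength s = 2, i.e. a niche breadth of half an environmental
  standard deviation — strong but realistic filtering.
- **Environmental structure**: a latent trophic axis with a fixed, evenly
  spaced site gradient (reservoirs carry a persistent riverine-inlet-to-dam
  trophic gradient; a random gradient would make the deterministic ground
  truth a seed lottery) plus random seasonal offsets. Nutrients, Chl a and
  oxygen demand load positively on the axis, transparency and DO
  negatively, and water temperature carries an explicit seasonal cycle — so
  TLI regressions have recoverable signs and season ANOVA has power at the
  defaults and nominal size when the effect is zeroed.
- **Dispersal limitation** (optional, `decay_rate` > 0 per km): per-OTU
  log-abundance perturbations across sites with correlation
  `exp(−decay_rate·d_km)`, producing distance decay of similarity.

Not emulated: phylogenetic structure among OTUs, sequencing error,
compositional artefacts of relative-abundance correlation, temporal
autocorrelation beyond categorical seasons, and a diversity–trophic-state
coupling (the TLI–diversity regression sign is therefore not a planted
truth here, unlike the TLI–environment signs). Passing recovery tests
demonstrates estimator correctness under the stated generative model, not
robustness to those real-data features.

## Diversity and group tests

Shannon uses natural logarithms; Margalef is `(S−1)/ln N` (the standard
definition; a typeset source that prints it without the fraction bar is
not a usable index since `(S−1)·ln N` grows with depth). Alpha indices
consume raw counts; Bray-Curtis is computed on relative abundances by
default because library sizes may differ. NMDS wraps nonmetric MDS with
one classical-scaling start plus random restarts (default 4) and reports
Kruskal stress-1 recomputed by isotonic regression; the metric start keeps
stress nonincreasing in the embedding dimension. The beta-diversity group
test is PERMANOVA (pseudo-F on squared distances, p = (1 + #{F* ≥ F})/(1 +
n_perm), 999 permutations default) — the source analysis names only the
p-values, so the test is labeled in output and ANOSIM could be substituted
without changing interfaces. Group comparisons of scalar quantities use
classical one-way ANOVA.

## Trophic level index

Sub-indices are the standard Chinese lake/reservoir log-linear forms, e.g.
`TLI(Chl a) = 10(2.5 + 1.086 ln Chl a)`; weights are squared correlations
with Chl a renormalized to sum to one (national survey values r = 1, 0.84,
0.82, −0.83, 0.83 by default). COD_Cr does not enter the TLI. TLI is
computed per sample and averaged per site (aggregation order is not fixed
by convention; a per-site-mean-concentration mode is available and the two
agree on homogeneous sites). Grading: < 30 oligotrophic, [30, 50)
mesotrophic, > 50 eutrophic with light/middle/hyper sub-bands at 60 and
70. The value 50 itself falls between the published bands; it is assigned
to mesotrophic and flagged as a boundary case.

## Spatial analyses

Geographic distances are great-circle (haversine, R = 6371.0088 km);
environmental distances are Euclidean on z-scored variables (all ten by
default — the variable set is configurable since conventions differ).
Distance-decay is OLS of dissimilarity on distance over the n(n−1)/2
unique pairs; because pairs sharing a sample are dependent, significance
comes from simultaneous row/column permutations (two-sided on the slope),
not from the OLS t-test. The similarity-decay slope is reported as the
exact negation of the dissimilarity slope. Mantel tests (Pearson or
Spearman) permute one matrix's rows and columns simultaneously; two-sided
by default. Group-wise Mantel panels subset samples by site or season
before testing.

## Ordination

The DCA step drives only the linear-vs-unimodal decision (threshold 3 SD
units). It uses reciprocal averaging to convergence, detrending by 26
segments on the second axis, and no nonlinear rescaling; the axis-1 length
is the range of sample scores (on the species-score scale) divided by the
mean within-sample dispersion of species scores — an approximation to
classic SD turnover units that agrees with vegan's `decorana` to well
within the decision tolerance on strong-gradient, noisy, and
niche-filtered fixtures (8.74 vs 8.85, 1.45 vs 1.05, 6.59 vs 6.78). Two
samples with complete turnover give an infinite length, correctly forcing
the unimodal choice.

RDA Hellinger-transforms the community matrix (linear ordination of raw
counts is not defensible; chord and none are available), column-centers
it, projects onto standardized predictors by least squares, and
eigen-decomposes the fitted values. Axis percentages are shares of the
*constrained* variance; constrained + residual equals total variance to
1e-9. On a fixed fixture the eigenvalues match vegan's `rda` to seven
decimals. Overall significance permutes community rows; marginal
per-variable tests permute reduced-model residuals (Freedman-Lane), both
with pseudo-F = (SS_constrained/q)/(SS_residual/(n−q−1)). When the DCA
length is ≥ 3 the pipeline reports the unimodal recommendation and skips
RDA (CCA is out of scope); the standalone `ordination.rda` function
remains callable for either outcome.

## Co-occurrence networks

The correlation method and thresholds are field-modal defaults (Spearman,
|ρ| ≥ 0.6, Benjamini-Hochberg FDR α = 0.05 across all tested pairs) and
are recorded in output metadata; they are configurable because no single
convention exists. Networks are built per site with seasons pooled.
Topology: average degree 2E/N, density 2E/(N(N−1)), diameter and average
path length on the largest connected component (unweighted), mean local
clustering with degree-<2 nodes contributing zero, Newman modularity of
the Louvain partition (seeded for determinism). Zi is the within-module
degree z-score (sd = 0 modules give Zi = 0); Pi = 1 − Σ_s(k_is/k_i)²;
roles use the conventional (2.5, 0.62) thresholds with exact threshold
hits assigned to the lower category and flagged, since the convention uses
strict inequalities on both sides. Key species are all non-peripheral
nodes ranked by Pi then Zi. Every metric is cross-checked against naive
brute-force reimplementations (explicit Floyd-Warshall, triangle counting,
Q summation) on random graphs. Note that modularity is bounded above by 1;
topology tables from other toolchains occasionally print "modularity"
values far above 1, which cannot be Newman Q and are not reproduced here.

## Assembly inference

The Sloan neutral model uses detection limit d = 1/N_T (one read, the
standard convention; configurable) and estimates m by bounded scalar
minimization of the squared frequency error on a log scale, m ∈ (1e-6, 1].
The 95% envelope is the Wilson score interval around the predicted
frequency at n = n_samples — smoother near f = 0/1 than Clopper-Pearson —
and partitions OTUs into above/within/below. The modified stochasticity
ratio uses `MST_ij = D_ij/Ē_ij` when observed dissimilarity is below the
null mean and `(1−D_ij)/(1−Ē_ij)` otherwise (the published
stochasticity-ratio framework; the formula is echoed in output metadata
for auditability since citations of the quantity often omit it). The
default null redraws each sample's library multinomially from the pooled
regional relative abundances (100 iterations default), preserving library
sizes and the regional abundance distribution; a richness-preserving
variant guarantees one read per occupied OTU so realized richness is
exact. Pairs with degenerate null means (0 or 1) are excluded with a
warning. Fits are produced pooled and per site.

## Problem sizes and determinism

Recovery and calibration checks run at the survey's own scale — 54
samples × 2,000 OTUs, 20 seeded replicates per condition, 100 null
iterations for MST, and 500 small-n null simulations per permutation test
— sizes at which each property is statistically decisive while the whole
suite stays desk-scale. Every stochastic routine takes an explicit seed
and identical configuration yields bit-identical output; the pipeline
report embeds a config hash for provenance.

## Known limitations

- DCA lengths are approximate (no nonlinear rescaling); only the threshold
  decision should be consumed.
- Spearman co-occurrence on relative abundances carries compositional
  bias; SparCC-style methods are out of scope.
- The NCM assumes equal-ish library sizes (N_T enters as the mean); highly
  uneven libraries would blur the beta prediction.
- MST classification at the 0.5 threshold is a convention, not a
  hypothesis test; borderline means warrant null-iteration sensitivity
  checks.
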