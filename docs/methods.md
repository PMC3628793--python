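# Methods

This note documents the statistical machinery implemented in
`pcpspath`, the choices made where the design was genuinely open, and
what the synthetic-data experiments do and do not demonstrate.

## Data model

All analyses operate on four validated inputs: a site × species
incidence matrix **W** (sites are biogeographic units such as
ecoregions), a species → IUCN category table (LC, NT, VU, EN, CR, EW,
EX), a rooted phylogeny whose branch lengths are all set to 1 on
ingestion, and a per-site attribute table (latitude, longitude, area,
nine climate variables each summarized as mean and range, and six
anthropogenic-biome cover proportions: urban, villages, croplands,
rangelands, seminatural, wild). Taxa missing from the threat table are
treated as Least Concern with a warning, so partial assessments remain
usable; taxa absent from every site are dropped with a warning; species
absent from the tree are a hard error rather than silently imputed.

## Diversity and threat scenarios

Richness is the row sum of **W**; a species is *endemic* when its
column sum is 1, and its single site gets the credit. Threat scenarios
pool categories cumulatively — urgent {CR, EW, EX} ⊂ moderate (+EN) ⊂
inclusive (+VU) — so per-site counts are monotone across scenarios by
construction; the pipeline asserts this nestedness on every run. Global
scenario totals count distinct taxa of **W** only: species assessed but
absent from the composition matrix do not contribute.

## Phylogenetic fuzzy-weighting and PCPS

Node-count distances **D** (edges on the tip-to-tip path of the
unit-branch-length tree) are converted to similarities by the scaled
complement **S** = 1 − **D**/max(**D**); scaling by the maximum
guarantees similarities in [0, 1] with the most distant pair at
exactly 0. An alternative fixed scale can be supplied through
`similarity_complement(D, scale=...)`.
Column-standardizing **S** gives the belonging matrix **Q**
(q<sub>ij</sub> = s<sub>ij</sub>/Σ<sub>k</sub>s<sub>kj</sub>; columns sum
to 1), and the phylogeny-weighted composition is **P** = **W Q**ᵀ.
Because **Q** is column-stochastic, row sums of **P** equal row sums of
**W** exactly (asserted to 1e−12 in the tests); each presence is
redistributed toward phylogenetic neighbours without creating or
destroying richness.

Sites are ordinated by principal coordinates analysis of square-rooted
Bray–Curtis dissimilarities between rows of **P**: Gower double-centering
of −½d², eigendecomposition, scores = eigenvector × √eigenvalue for
positive eigenvalues. Negative eigenvalues (non-Euclidean input; rare
under the square-root transform) are reported and their axes discarded
with a warning; a Lingoes correction is available via
`PCPSOrdination(correction="lingoes")`. Axis orientation is fixed by
making the largest-|score| site positive, so reports are reproducible.
The first three PCPS are retained for modelling by default
(`n_axes=3`), configurable by count. Fuzzy-weighting operates at
whatever taxon level the tree's tips provide; an optional
genus-aggregation step (`genus_aggregate=True`) sums species columns per
clade first. Per-taxon and per-clade Pearson correlations with each axis
support clade–gradient diagnostics; constant columns are reported as
r = 0 with a `degenerate` flag.

## Climate axes

Each of the nine climate variables is decomposed per site into mean and
range (max − min), giving 18 columns on incomparable scales, then
reduced by correlation-matrix PCA (variables z-scored). Loadings are
variable–axis Pearson correlations, so each variable's squared loadings
sum to 1 across all axes (asserted). Axis signs are fixed so the
dominant variable of each axis loads positively. Two axes are retained
by default. Constant columns are dropped with a warning; fewer than
three sites is an error.

## Path analysis

**Residualization.** Every variable entering the causal model — the
response included — is first replaced by its residual from an OLS on
intercept + latitude + longitude + area, so the model describes
geography- and area-free variation. Residuals are exactly orthogonal to
the geography columns (checked to 1e−8). Collinear geography is a hard
error.

**Causal ranks.** Climate axes are exogenous (rank 0); anthrome covers
and PCPS axes rank 1; richness and endemism rank 2; the scenario threat
count is the response (rank 3). Edges may only point from lower to
higher rank; no same-rank edges (in particular none between richness and
endemism; this is configurable by editing the rank map).

**Selection.** Candidate predictors are screened by exhaustive
best-subset AIC with the Gaussian-OLS form
`AIC = n ln(RSS/n) + 2(k+2)`, where k counts predictors and the +2
covers intercept and error variance. The null model competes. Ties
within 1e−9 prefer fewer predictors, then lexicographic variable order;
an essentially perfect fit returns −∞ with a warning. Singular candidate
subsets are skipped (the six anthrome proportions sum to 1, so their
full subset is always collinear after residualization). Subsets are
enumerated exhaustively up to 20 candidates; group-wise pre-selection
(climate, anthromes, PCPS, each selected separately against the
response) keeps candidate sets small, and the union of group winners
plus richness and endemism enters the model build. Small-sample AICc is
available (`aicc=True`) but off by default.

**Model build.** Breadth-first from the response: the response's
predictors are selected among all admissible retained variables of
strictly lower rank; each selected endogenous predictor is then resolved
against its own admissible set; termination follows because ranks
strictly decrease. The result is a DAG by construction.

**Coefficients and p-values.** One multiple OLS per endogenous node of
the z-scored node on its z-scored parents gives standardized path
coefficients; for a single parent, β equals the Pearson correlation
(asserted to 1e−10). P-values come from a randomization test: each
node's values are permuted across sites (999 permutations by default;
at least 99 enforced), its parent regression refit, and the two-tailed
p-value computed as (1 + #{|β*| ≥ |β|})/(n_perm + 1). We permute the
endogenous node itself, not predictors or residuals; permutations are
vectorized through the pseudoinverse of the fixed design, and the
generator is seeded, so identical seeds give bitwise-identical p-values.
Under an independence null the empirical type-I error at α = 0.05 is
the attainable level 9/200 = 0.045 with 199 permutations, verified by
simulation in the acceptance suite. Non-significant selected edges are
retained and flagged, not pruned.

**Effects.** Direct effect = coefficient of the single edge into the
response (0 if absent); indirect effect = sum over all directed paths of
length ≥ 2 of the product of coefficients (exhaustive path enumeration
via networkx); total = direct + indirect.

## Synthetic worlds

The generator emulates the ingredients of a continental threatened
species analysis with known ground truth:

- **Phylogeny.** Pure-birth (uniform leaf-splitting) topology, unit
  branch lengths; tips in leaf order partitioned into contiguous genera.
- **Sites and climate.** Latitudes on a jittered grid spanning ±55°;
  areas log-normal. Nine latent climate variables combine a latitudinal
  gradient (`climate_gradient_strength`, default 1), an independent
  continentality factor and site noise; per-site subsamples (8 by
  default) yield means and ranges, with within-site spread growing
  toward the poles.
- **Niches and ranges.** Species niche optima evolve by Brownian motion
  on the tree (`phylo_signal`); half the optimum variance sits on the
  deepest split by default (`deep_split=0.5`), mimicking a deep clade
  divergence in climate affinity. Expected range size is log-uniform
  from a quarter-site to half the landscape and itself evolves on the
  tree, so narrow-ranged species form clades; narrow-ranged species are
  also climate specialists (niche breadth shrinks with prevalence).
  Occurrence probabilities are Gaussian kernels of site climate around
  each optimum; widespread species are rescaled by a log-normal per-site
  suitability (so richness varies strongly and is not a deterministic
  function of climate), while narrow-ranged species are concentrated by
  a suitability-coupled log-normal hotspot factor emulating
  topographic microendemism. Empty rows/columns are re-drawn (bounded);
  a species whose occupancy probability is negligible everywhere is
  anchored at one site drawn in proportion to its profile.
- **Land use.** Six Dirichlet cover proportions per site, with the
  villages (and, more weakly, croplands) concentration tilted upward and
  the wild concentration downward in warm, low-seasonality climates with
  strength `landuse_coupling`. Covers sum to 1 exactly.
- **Threat.** A latent score per species,
  `b_endemic·1[range = 1] + b_village·(mean village cover over occupied
  sites) + b_richness·z(mean richness over occupied sites) + N(0, 1)`,
  is cut at strictly increasing thresholds into LC < NT < VU < EN < CR
  (EW/EX unused by default). The strong-effect defaults are
  `b_endemic = 10`, `b_village = 26`, `b_richness = 1.2` with thresholds
  (7.4, 8.2, 9.0, 9.8), chosen so that category frequencies, endemism
  hotspots and scenario structure resemble a real continental amphibian
  assemblage while giving endemism the dominant standardized effect.
  The large magnitude of `b_village` reflects the scale of its
  covariate: village cover is a proportion with a site standard
  deviation near 0.2, so the latent shift per standard deviation is
  comparable to the other effects.

The whole world is a pure function of `(WorldConfig, seed)`;
regeneration is bitwise identical. Default sizes (120 sites × 400
species) keep a full pipeline run around a second; the recovery
experiments run at 500 × 1500.

**What the generator does not emulate:** spatially contiguous ranges
(occupancy is climate- and suitability-driven, not neighbourhood-
constrained), speciation/extinction dynamics, observation error in
range maps, correlated threat assessments within clades beyond what the
range-size channel induces, and real Earth geometry. Passing recovery
tests therefore show that the pipeline can rediscover site-level causal
structure of this kind at continental sample sizes — not that the
method is robust to spatial autocorrelation or biased sampling.

## Validation experiments and a known limitation

The acceptance suite runs the full pipeline on 100 strong-effect worlds
and asks whether each scenario's final model contains positive,
significant (α = 0.05) direct edges endemism→threat, villages→threat
and richness→threat, and whether endemism carries the largest |β| into
the response. At the frozen conditions the endemism and villages edges
are recovered in ≳ 93% of runs and endemism is the largest coefficient
in a majority, but joint recovery of all three edges settles near
75–82% per scenario, with the richness edge the binding one.

The mechanism is a property of the ordination worth knowing about:
because **P** conserves row sums and the scaled-complement similarities
have a high baseline (every taxon shares some similarity with every
other), the relative composition of **P** varies only a few percent
across sites, so Bray–Curtis distances between rows of **P** are
dominated by richness differences and the first PCPS axis is nearly a
monotone transform of site richness (|r| ≈ 0.9 in these worlds). In the
path model this makes PCPS1 and richness near-collinear: best-subset
AIC occasionally substitutes PCPS1 for richness or keeps both, and in
the latter case the permutation null for either coefficient widens with
the collinearity, costing significance. Raising the richness share of
the response variance restores the richness edge but then richness, not
endemism, carries the largest coefficient. We kept the generator
faithful to the system being emulated (endemism-dominant threat
structure) rather than optimizing the joint recovery rate.

## Numerical choices

- OLS everywhere via `numpy.linalg.lstsq`; rank-deficient designs raise.
- Eigendecompositions via `scipy.linalg.eigh` (symmetric); eigenvalues
  clipped at 0 where mathematically non-negative.
- PCoA eigenvalue sign tolerance: 1e−10 relative to the largest
  magnitude.
- Permutation indices generated by `argsort` of uniform draws, giving a
  single batched permutation matrix per node.
- Permutation exceedance comparison uses a 1e−12 slack so that exact
  ties (e.g. a perfect fit) count as exceedances.
- All seeds flow through `numpy.random.SeedSequence` spawning, recorded
  in the run manifest.
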