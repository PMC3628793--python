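# pcpspath

Phylogenetic fuzzy-weighting, PCPS ordination and hierarchical path
analysis for the macroecology of threatened species.

## The problem

Why are threatened species where they are? At the scale of biogeographic
units (e.g. ecoregions), the number of threatened amphibians per unit
could be driven directly by human land use, or indirectly by climate
acting through species richness, endemism and the phylogenetic
composition of assemblages. `pcpspath` implements an analysis chain that
disentangles these direct and indirect effects:

1. **Diversity and threat scenarios.** From a site × species incidence
   matrix **W** and IUCN Red List categories, compute per-site richness,
   endemism (species confined to a single site) and threatened-species
   counts under three nested scenarios: *urgent* = {CR, EW, EX},
   *moderate* = urgent ∪ {EN}, *inclusive* = moderate ∪ {VU}.
2. **Phylogenetic structure (PCPS).** Node-count distances **D** on a
   unit-branch-length phylogeny become similarities
   **S** = 1 − **D**/max(**D**); column-standardizing **S** gives the
   belonging matrix **Q** (columns sum to 1), and **P** = **W Q**ᵀ is the
   phylogeny-weighted composition — each presence is redistributed
   toward close relatives while row sums (richness) are preserved
   exactly. A principal coordinates analysis of square-rooted
   Bray–Curtis dissimilarities between rows of **P** yields Principal
   Coordinates of Phylogenetic Structure (PCPS); the leading axis
   captures the deepest phylogenetic gradients across sites.
3. **Climate axes.** Nine environmental variables, each summarized per
   site as mean and range (18 columns), are reduced by correlation-matrix
   PCA to two climate axes; loadings are variable–axis Pearson
   correlations.
4. **Path analysis.** Every variable is residualized on latitude,
   longitude and area; variables carry a causal rank (climate exogenous;
   land-use covers and PCPS next; richness and endemism; threat count as
   response). Predictors are chosen by exhaustive best-subset AIC
   (`AIC = n ln(RSS/n) + 2(k+2)`), first within variable groups, then
   iteratively from the response backwards. Path coefficients are
   standardized regression coefficients (β); their p-values come from a
   randomization test that permutes each endogenous node across sites;
   total effects decompose into direct (single edge) and indirect (sum
   over multi-edge paths of the product of β).

A fully synthetic world generator with known causal structure (Yule
phylogeny, Brownian niche evolution, Dirichlet land-use covers coupled
to climate, threshold-based IUCN categories with known coefficients for
endemism, village cover and richness) makes the whole chain testable
end-to-end as a parameter-recovery experiment.

## Worked example

```python
import numpy as np
import pcpspath as pp

world = pp.generate_world(pp.WorldConfig(n_sites=120, n_species=400,
                                         n_genera=40), seed=11)
result = pp.run_pipeline(world.W, world.phylogeny, world.attributes,
                         world.threats, n_perm=999, seed=11)

print("species totals per scenario:", result.diversity.attrs["global_totals"])
print("PCPS variance fractions:", np.round(result.pcps.variance_fractions_[:3], 3))
urgent = result.scenario_models["urgent"]
print(urgent.edges_.round(3).to_string(index=False))
```

prints

```
species totals per scenario: {'urgent': 139, 'moderate': 166, 'inclusive': 180}
PCPS variance fractions: [0.436 0.2   0.084]
  parent         child   beta  p_value  significant
endemism threat_urgent  0.611    0.001         True
  pcps_1 threat_urgent  0.387    0.166        False
  pcps_3 threat_urgent  0.116    0.374        False
richness threat_urgent  0.640    0.062        False
villages threat_urgent  0.167    0.060        False
  pcps_1      endemism -0.368    0.001         True
  pcps_2      endemism  0.229    0.014         True
  pcps_3      endemism -0.284    0.002         True
  pcps_1      richness -0.865    0.001         True
  pcps_2      richness  0.239    0.007         True
  pcps_3      richness -0.336    0.001         True
```

Reading the output: 139 of the 400 simulated species fall in the urgent
scenario (CR here; the generator produces no EW/EX by default). The
first PCPS axis concentrates ~44% of the variation in phylogeny-weighted
composition. In the urgent-scenario path model, endemism carries a
strong, significant direct effect on the number of threatened species
(β = 0.61, permutation p = 0.001), while the phylogenetic axes act
mostly indirectly through richness and endemism (e.g. the strong
pcps_1 → richness link, β = −0.87). `result.scenario_models[s].effects_`
holds the direct/indirect/total decomposition per variable.

The same pipeline runs from the shell:

```bash
pcpspath simulate --seed 11 --out-dir world/
pcpspath run --seed 11 --out-dir results/        # all three scenarios
pcpspath pcps --composition world/composition.csv --tree world/tree.nwk
```

Each run writes per-scenario edge lists, effect decompositions, DOT
graphs and a JSON manifest with content digests, so identical inputs and
seeds reproduce identical outputs bit for bit.

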