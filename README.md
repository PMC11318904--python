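# commphylo

Community phylogenetics along environmental gradients: do co-occurring
species share more (or less) evolutionary history than a random draw from
the regional pool, and what does that say about how communities assemble?

The package implements the full analysis chain used in elevational-gradient
studies of diverse taxa (the motivating system is Geometridae moth
communities at eight sites from 200 to 3700 m a.s.l. on Mt. Wilhelm, Papua
New Guinea):

- **Alpha structure.** Per-site mean pairwise distance (MPD), mean
  nearest-taxon distance (MNTD) and Faith's phylogenetic diversity (PD),
  standardized against a taxon-label-shuffling null into
  NRI = −SES(MPD), NTI = −SES(MNTD) and SES.PD, with |index| ≥ 1.96 flagged
  as significant clustering/overdispersion. An exhaustive-enumeration null
  is available for small trees.
- **Beta structure.** PhyloSor phylogenetic dissimilarity and species
  Sorensen dissimilarity, each decomposed Baselga-style into turnover
  (β_sim) and nestedness (β_sne) with β_sor = β_sim + β_sne exactly;
  COMDIST (mean between-community cophenetic distance) and a UPGMA
  dendrogram of sites.
- **Predictor modelling.** Gaussian-ML OLS over all predictor subsets,
  ranked by small-sample AICc with Akaike weights
  (logLik = −(n/2)(log 2π + log(RSS/n) + 1), k counts the residual
  variance); second-order polynomial fits; Pearson and seed-reproducible
  Mantel permutation tests.
- **Synthetic data.** Yule/birth–death trees plus gradient community
  matrices with known assembly structure (random, clade-filtered,
  overdispersed, nested-attrition, range-turnover) and predictor tables
  (temperature falling 0.54 °C per 100 m from 27.4 °C at 200 m), so every
  statistic can be checked for calibration and power without any downloads.
- **Pipeline.** One config (YAML or `RunConfig`) runs
  interpolate → alpha → beta → model ranking → Mantel and writes a fully
  reproducible text bundle; also exposed as a thin `commphylo` CLI
  (`simulate`, `alpha`, `beta`, `regress`, `mantel`, `run`).

## Worked example

The published per-site index table for the Mt. Wilhelm transect ships with
the package; ranking all eight predictor-subset models for SES.PD:

```python
from commphylo import candidate_rankings, mt_wilhelm_indices, pearson

table = mt_wilhelm_indices()
ranking = candidate_rankings(
    table, ["ses_pd"], ["plant_richness", "predator_abundance", "temperature"]
)
print(ranking[["model", "loglik", "aicc", "delta_aicc", "weight"]].round(3))
```

prints

```
                                            model  loglik   aicc  delta_aicc  weight
                                             Null -16.192 38.785       0.000   0.536
                                      temperature -14.097 40.195       1.410   0.265
                                   plant_richness -15.136 42.272       3.488   0.094
                               predator_abundance -15.210 42.419       3.634   0.087
                 predator_abundance + temperature -12.270 45.873       7.089   0.015
                     plant_richness + temperature -14.019 49.370      10.586   0.003
              plant_richness + predator_abundance -14.958 51.250      12.465   0.001
plant_richness + predator_abundance + temperature -10.744 61.489      22.704   0.000
```

With only eight sites no predictor earns its parameters: the intercept-only
model carries most of the Akaike weight, and only temperature comes within
ΔAICc < 2 of it. The two tip-level indices mirror each other,
`pearson(table["nti"], table["ses_pd"])` → r = −0.969, p = 7.5e-05: sites
whose species are terminally clustered also carry less branch length than
expected for their richness.

The `examples/` directory holds one short narrative script per capability
(alpha structure under filtering, turnover-vs-nestedness decomposition,
model ranking, full pipeline); each prints what it computes and what the
numbers mean.

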