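# permamicro

Analysis pipeline for paired warming/control soil-microbiome experiments,
covering both sides of the microbial carbon budget: the catabolic side
(respiration, carbon use efficiency, co-occurrence network complexity,
carbohydrate-active-enzyme gene enrichment) and the anabolic side
(growth, turnover, necromass carbon, mineral-associated organic carbon).
It is written for microbial ecologists who have count tables, incubation
records and soil chemistry from a blocked warming experiment — or who want
a fully synthetic, ground-truthed replica of such a study to validate
methods against.

## What it computes

**Microbial physiology from ¹⁸O-labelled-water incubations.** DNA produced
over a 24 h incubation follows from the heavy-oxygen excess of the DNA
extract, DNA_produced = O_total · (O_excess/100) · (100/O_label) ·
(100/31.21); growth is G = (C_mic/DNA_mic) · DNA_produced/(w·t), with
biomass C from fumigation-extraction (flush/0.45); respiration R comes from
headspace CO₂ against blank vials via the ideal gas law. From these:
CUE = G/(G+R), turnover T_m = G/C_mic·24, and mass-specific rates
G_m = 1000·G/C_mic, R_m = 1000·R/C_mic.

**Necromass C from amino sugars.** Bacterial necromass C = 45·MurA; fungal
necromass C = (GluN/179.17 − 2·MurA/251.23)·179.17·9; total necromass and
its share of soil organic carbon, with paired contrasts.

**Co-occurrence networks.** Pearson correlations of log₁₀ relative
abundances (prevalence-filtered, rarefied), thresholded where the
eigenvalue nearest-neighbour spacing distribution turns Poisson (random-
matrix-theory criterion); topology (n, L, avgK, clustering), greedy
modules, relative modularity against degree-preserving rewired nulls,
Zi–Pi node roles and keystones, and module-eigengene–environment
correlations.

**Gene-family enrichment.** Length-normalised relative abundance
RA_i = (r_i/L_i)/Σ_j(r_j/L_j), aggregation to CAZy families/classes or KO
sets, and LEfSe-style scoring (Kruskal–Wallis screen, bootstrap linear-
discriminant effect size on ppm scale, |LDA| > 2 and unadjusted p < 0.05).

**Community and carbon-pool statistics.** Richness and Shannon diversity,
Bray–Curtis distances, PERMANOVA/ANOSIM/MRPP permutation tests (free or
block-stratified), RDA variation partitioning with Ezekiel-adjusted R²,
SOM-fractionation bookkeeping (POC / heavy POC / MAOC proportions, mass and
C recovery) and the heterotrophic-respiration warming effect.

**Synthetic experiment generator.** A 10-block paired design with known
ground truth for every quantity above, built by inverting each estimator so
that the pipeline on noiseless data recovers the truths exactly. See
`docs/methods.md` for the model and its defaults.

## Worked example

Run the whole chain on the default synthetic experiment:

```
permamicro run --out run1/
permamicro report run1/
```

which prints (abridged):

```
## Physiology (paired contrasts)
- G_m: control 0.1985 vs warming 0.1974 (p = 0.957)
- R_m: control 0.276 vs warming 0.3951 (p = 0.0086)
- CUE: control 0.418 vs warming 0.3345 (p = 0.00058)

## Necromass
- prop_of_soc: control 0.2793 vs warming 0.3161 (p = 0.0051)

## Networks
- control: threshold 0.69, n = 65, L = 308, avgK = 9.48, RM = 1.010, keystones = 1.54%
- warming: threshold 0.69, n = 47, L = 388, avgK = 16.51, RM = 0.981, keystones = 8.51%

## Enrichment
- 30 families enriched under warming, 13 under control

## Community and carbon pools
- MAOC proportion: control 0.663 vs warming 0.697 (p = 0.0258)
- R_h warming effect: 41.1% (p = 7.42e-07)
```

Reading this: mass-specific growth is unchanged by warming while
respiration rises, so carbon use efficiency falls from 0.42 to 0.33 —
microbes route less of their carbon intake into biomass under warming. The
warming network is denser (avgK 16.5 vs 9.5) with more keystone nodes.
Thirty CAZy families are warming-enriched. Meanwhile necromass accumulates
(28% → 32% of SOC) and the mineral-associated pool grows (66% → 70%), while
heterotrophic respiration is 41% higher. The generator's configured truths
for this run are CUE 0.41/0.34, necromass share 0.28/0.31, MAOC share
0.65/0.71 and an R_h effect of +41% — the pipeline recovers each within its
sampling error at 10 blocks.

Individual stages run standalone (`permamicro simulate|physiology|
necromass|network|enrich|stats --help`), reading and writing tab-delimited
text tables; `run1/manifest.json` records config, per-stage seeds, file
digests and timings, and re-running with the same config reproduces the
digests byte-for-byte.

Library use mirrors the CLI:

```python
from permamicro import datagen, physiology

experiment, truth = datagen.generate_experiment(datagen.GeneratorConfig(seed=7))
table, contrasts = physiology.physiology_table(experiment)
print(contrasts["CUE"].mean_control, contrasts["CUE"].p)
```

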