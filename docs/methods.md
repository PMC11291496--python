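# Methods

`permamicro` implements the computational chain of a paired in-situ
warming/control soil experiment: microbial physiology from heavy-oxygen-water
incubations, necromass carbon from amino-sugar biomarkers, co-occurrence
networks thresholded by random-matrix theory, gene-family differential
abundance, permutation multivariate community statistics, and carbon-pool
bookkeeping. A synthetic-data generator emulates the full study with known
ground truth so every stage is testable without any field data.

## Study design

The emulated design is 10 spatial blocks, each holding one ambient-control
and one passively warmed plot (open-top chamber), sampled in one year:
20 samples in total. Warming raises topsoil temperature by a configurable
offset constrained to 0.8–2.2 °C. All paired contrasts are two-sided paired
t-tests on block-aligned arrays, `t = mean(d) / (sd(d)/sqrt(n))`, `df = n−1`.

## Physiology (¹⁸O-DNA method)

Growth is measured substrate-independently: soil incubated 24 h at 15 °C
with water enriched to 20 at% ¹⁸O incorporates the label into newly
synthesised DNA. The chain is

- `DNA_produced = O_total · (O_excess/100) · (100/O_label) · (100/31.21)` —
  31.21 is the mass % of oxygen in an average DNA molecule; `O_excess` is
  the at% ¹⁸O surplus of the labelled DNA extract over the mean of the
  natural-abundance replicates, floored at zero when negative (small-signal
  noise, flagged not fatal);
- `G = (C_mic/DNA_mic) · DNA_produced / (w·t)` (µg C g⁻¹ h⁻¹), where
  `C_mic` is fumigation-extraction biomass C (flush / 0.45) and `DNA_mic`
  the soil DNA yield;
- respiration `R` from the headspace CO₂ build-up over an empty blank vial,
  converted with the ideal gas law at the incubation temperature with
  headspace volume taken as the vial volume (the ~0.3 g soil plug is
  neglected); carbon mass uses 12.011 g mol⁻¹;
- `CUE = G/(G+R)`; turnover `T_m = G/C_mic · 24` (day⁻¹); mass-specific
  rates `G_m, R_m = 1000·G/C_mic, 1000·R/C_mic` with the *initial* biomass
  as denominator (the end-of-incubation pool is not observed).

## Necromass (amino sugars)

Muramic acid (MurA) is unique to bacterial cell walls; glucosamine (GluN) is
shared. With contents in µg g⁻¹ dry soil:

- bacterial C = `45 · MurA`
- fungal C = `(GluN/179.17 − 2·MurA/251.23) · 179.17 · 9`, evaluated in the
  algebraically simplified form `(GluN − 2·MurA·179.17/251.23) · 9` so the
  MurA-free case is exact in floating point; negative values (bacterial GluN
  exceeding total GluN) are floored at zero and flagged;
- total = bacterial + fungal; the SOC share converts SOC from g C kg⁻¹ to
  µg g⁻¹ with the single factor 1000 held in one module constant.

Internal-standard quantification uses
`content = (peak/IS_peak) · IS_mass · response_factor / soil_mass`, with a
default response factor of 1.0 per analyte (no published GC response
factors; a calibration table can be supplied).

## Co-occurrence networks

Per treatment arm, only ASVs present in every retained sample enter the
correlation step (so the log₁₀ of relative abundance needs no pseudocount);
Pearson correlations are taken across samples on the rarefied table.
Rarefaction is a per-sample multivariate hypergeometric draw (without
replacement) to the minimum sample depth, with an explicit seed.

The edge threshold is chosen by random-matrix theory: scanning s from 0.30
upward in steps of 0.01, entries with |r| < s are zeroed, fully isolated
rows dropped, and the eigenvalue nearest-neighbour spacing distribution
(NNSD) tested against the exponential. The selected threshold is the first s
whose NNSD conforms to Poisson (chi-square p > 0.05) and stays Poisson for
three consecutive steps. Numerical choices:

- degenerate eigenvalues (within 1e−8) are collapsed before unfolding —
  thresholded matrices carry large spikes (isolated rows at exactly 1) that
  hold no spacing information;
- unfolding is local: each spacing is divided by the mean spacing of an
  11-point moving window (window parameter 5), which removes the global
  density profile without assuming a functional form;
- the chi-square histogram uses bins of 0.1 on [0, 3] with an open tail and
  rightward merging to ≥ 5 expected counts per cell. On simulated ensembles
  this classifier prefers the Wigner surmise on ≥ 90% of GOE draws and
  accepts Poisson on ≥ 90% of independent-block spectra.

Modules come from greedy modularity maximisation with deterministic
node-id tie-breaking; relative modularity is
`RM = (M − mean(M_null))/mean(M_null)` over degree-preserving rewired nulls
(10·L double-edge swaps each, default 100 nulls). Node roles use the
standard Zi–Pi taxonomy: `Zi` the within-module degree z-score (0 when the
module sd is 0), `Pi = 1 − Σ_m (k_im/k_i)²`, hubs at Zi > 2.5 and
connectors at Pi > 0.62; keystones are all non-peripheral nodes. A uniform
threshold across arms (the max of the per-arm RMT thresholds) is the
default in the pipeline, mirroring how paired networks are usually compared.

Module eigengenes are the first principal component of the standardized
log₁₀ member abundances (half-count pseudocount against rarefaction zeros),
sign-oriented to correlate positively with the mean member profile, and
correlated with each environmental covariate (Pearson, two-sided).

## Gene-family enrichment

Per-gene relative abundance is length-normalised:
`RA_i = (r_i/L_i) / Σ_j (r_j/L_j)`. Aggregation sums RA over genes sharing a
family/class/KO label; unannotated genes stay in the denominator but in no
label, so label totals are sub-additive.

Differential families follow the LEfSe recipe for a two-group design
without subclasses (the subclass Wilcoxon stage is skipped — there are no
subclasses in a paired two-arm design): Kruskal–Wallis screen at p < 0.05
(with two groups this is equivalent to the rank-sum test; KW is kept for
fidelity to the cited method), then an effect size from bootstrap-averaged
(30 rounds, 2/3 subsampling) group-mean differences along the discriminant
axis on abundances scaled to parts-per-million; with one family at a time
the discriminant axis coincides with the family axis, so the effect is the
ppm mean difference. Scores are signed log₁₀ magnitudes with the
conventional |LDA| > 2 cut-off; p-values are deliberately unadjusted, with
an optional Benjamini–Hochberg flag (off by default).

## Multivariate statistics and carbon pools

Bray–Curtis dissimilarity feeds three permutation tests sharing one
convention, `p = (1 + #{perm ≥ obs}) / (1 + n_perm)`, 999 permutations by
default, seeded:

- PERMANOVA: one-factor pseudo-F from the within/total squared-distance
  decomposition; an exact mode enumerates all distinct assignments at small n;
- ANOSIM: `R = (mean between-rank − mean within-rank) / (N(N−1)/4)`;
- MRPP: δ the group-size-weighted mean within-group distance, with
  chance-corrected agreement `A = 1 − δ/E[δ]`.

Permutations are unrestricted by default; `strata` permutes within blocks
for the paired layout (the default is a documented choice, not a claim
about the original analysis). Under the generator's null all three tests
hold their 5% level within ±2% over 200 simulations.

Variation partitioning runs redundancy analysis on centred responses with
Ezekiel-adjusted R², partitioned between the plant and soil covariate sets
by inclusion–exclusion; slightly negative components are reported as
computed. Carbon pools: per-sample fraction C stock = fraction mass ×
fraction C concentration; proportions are relative to summed recovered C
(robust to < 100% recovery; a bulk-SOC denominator is the documented
alternative); the heterotrophic-respiration warming effect is
`(mean_W − mean_C)/mean_C · 100` on per-sample seasonal means.

## Synthetic-data generator

Every observable is produced by inverting the estimator that will consume
it, so the forward pipeline on noiseless data recovers each stored truth
exactly — the central identity test. Defaults are the study conditions:
true CUE 0.41 (control) vs 0.34 (warming), necromass/SOC 0.28 vs 0.31,
MAOC/SOC 0.65 vs 0.71, R_h +41%, 30 warming- vs 13 control-enriched
families at fold change 3, warming ΔT within 0.8–2.2 °C, 10 blocks.

- **Block effects** are one shared log-normal multiplier per block applied
  to both arm members (growth, biomass, respiration baseline), which is what
  makes paired tests strictly more powerful than unpaired here. Between-plot
  variance components are not published; they are calibrated only to
  reproduce the stated means ± SE at n = 10.
- **Incubations**: true G is drawn per sample (same distribution in both
  arms — growth is not a warming response here), CUE is exactly the
  treatment value, R follows. Observables are back-calculated through the
  inverse of the physiology equations (50 ml vial, 300 mg soil, 24 h, 15 °C, blank at
  5 ppm, O_total 25 µg, C_mic:DNA_mic = 25). `cv_noise` (default 0.1) is
  the end-to-end relative error of each measurement chain, entering once
  through the CO₂ difference and once through the ¹⁸O excess as mean-one
  log-normal factors.
- **Communities**: log-normal latent abundances with planted modules of 12
  ASVs sharing a latent factor (loading 0.95, idiosyncratic sd 0.25, latent
  within-module correlation ≈ 0.93 — high module coherence is required for
  edges to survive Pearson estimation at n = 10); warming multiplies
  planted-factor variance by 2 so warming networks are denser; the first
  prokaryotic module tracks standardized soil temperature so an eigengene
  has a recoverable driver. Counts are multinomial at a per-sample depth
  (configured depth 5000 minus a random loss up to 10%); a high-baseline
  core set guarantees prevalence-filter survivors.
- **Genes**: 60 CAZy families × 3 genes with lengths uniform on
  [600, 3000] bp (making length normalisation non-trivial) plus an
  unannotated background pool carrying 90× the CAZy intensity — CAZy genes
  are a ~1% sliver of a real catalog, and without the background the
  compositional shift from boosting 30 families falsely marks the untouched
  families as control-enriched. Reads are Poisson around expectations at
  depth 10⁶ (rounded expectations at zero noise).
- **Amino sugars** invert the necromass equations from the configured SOC
  share with a 1:2 bacterial:fungal split; **fractions** invert the MAOC
  share with mass recovery drawn in [0.94, 0.99] and C recovery in
  [0.97, 0.995] (noisy stocks are rescaled to preserve the drawn recovery);
  **R_h** is a twice-monthly May–October series with a mid-season peak and a
  multiplicative warming effect, so the ratio of seasonal means is exact at
  zero noise.

What the generator does *not* emulate: phylogenetic correlation among taxa,
compositional correlation artefacts beyond the multinomial, temporal
autocorrelation in R_h, measurement-instrument drift, or any real
taxonomy. Passing recovery tests therefore demonstrates correctness of the
estimator chain under the stated noise model, not robustness to every
pathology of field data.

## Problem sizes and determinism

Default problem sizes (150 + 80 ASVs, depth 5000, 480 genes at depth 10⁶,
200-feature spectra for classifier validation, 199–999 permutations,
100–200 simulation replicates in calibration tests) were chosen so the full
suite and pipeline run in well under an hour on one core while keeping every
statistical check adequately powered. All randomness flows from explicit
seeds: the pipeline derives per-stage seeds from one global seed via
hashing, so stages rerun standalone reproduce their outputs byte-for-byte.

## Known limitations

- The RMT scan conventions (step 0.01, three-step persistence, chi-square
  binning) are de facto community conventions; other pipelines may select
  slightly different thresholds on the same matrix.
- LEfSe scores are comparable in rank and threshold behaviour to the
  original tool, not bit-identical (bootstrap scheme and internal
  normalisation differ between versions of the reference implementation).
- With n = 10 samples per arm, Pearson correlation estimates are noisy
  (sd ≈ 0.3 under the null); network edge lists at such n are indicative,
  and ~3–7% of background pairs can exceed typical thresholds by chance.
- Whether rarefaction preceded or followed removal of non-target ASVs is
  ambiguous in the field protocol this emulates; the pipeline filters
  first, then rarefies, and records both depths.
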