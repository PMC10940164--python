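# erphagyquant

Quantitative analysis of how sequential loss of ER-phagy receptors remodels
the endoplasmic-reticulum proteome.

ER-phagy receptors (FAM134A/B/C, TEX264, CCPG1, ...) link ER membrane to the
autophagy machinery and target ER content for lysosomal degradation. An
*allelic series* of knockouts — WT → DKO → TKO → QKO → PKO, each genotype
adding one more receptor deletion — combined with multiplexed isobaric (TMT)
proteomics lets one ask which receptor step is responsible for the
accumulation or depletion of each ER protein. `erphagyquant` implements the
full quantitative pipeline:

- **PSM-level TMT processing** — quality filtering of peptide-spectrum
  matches (summed reporter signal-to-noise > 200, isolation purity > 0.5),
  per-channel sum-normalization to the median channel total, and protein
  rollup by summing constituent PSM intensities.
- **Differential abundance** — WT-centred log2 intensities, pooled-variance
  two-sided Student's t-tests per protein, Benjamini–Hochberg FDR control.
- **The allelic-series linear model** — each sample is coded with cumulative
  0/1 indicators x_k (1 iff its genotype contains the k-th sequential
  deletion), giving the staircase design WT=(0,0,0,0), DKO=(1,0,0,0),
  TKO=(1,1,0,0), QKO=(1,1,1,0), PKO=(1,1,1,1) and the per-protein model

  &nbsp;&nbsp;&nbsp;&nbsp;y = β₀ + β₁x₁ + β₂x₂ + β₃x₃ + β₄x₄ + ε

  on WT-centred log2 intensities (centring drives β₀ to zero). Each βₖ is the
  mean log2 fold change contributed by the k-th deletion step — β₃, for
  example, is the average fold change from the triple to the quadruple
  knockout — with t-based p-values BH-adjusted per step across proteins.
- **Compartment statistics** — ER compartment annotations (ER-associated /
  ER-membrane / ER-lumen, TM-segment counts from `_n` name suffixes), a
  randomized-selection null (100 random same-size protein sets, two-sided
  Kolmogorov–Smirnov per iteration), one-sided Wilcoxon signed-rank of β
  versus zero with Bonferroni correction, and paired two-sided Wilcoxon
  between genotypes.
- **Keima flux** — ratiometric autophagic-flux readout from gated
  flow-cytometry events: mean(561 nm acidic) / mean(445 nm neutral),
  normalized to a matched bafilomycin-A1 (BAFA) control.
- **A ground-truth simulator** of the whole experiment (truth tables, protein
  matrices, PSM tables, annotations, flow events), so every stage is testable
  with known parameters.

The model-facing classes follow scikit-learn conventions
(`PsmQcFilter`, `ChannelSumNormalizer`, `ProteinRollup`,
`ReferenceLog2Centerer` transformers and the `AllelicSeriesModel` estimator
with fitted `beta_`, `se_`, `pvalues_`, `padj_`, `significant_` attributes);
module-level functions wrap them for one-line use.

## Worked example

```python
import erphagyquant as eq

cfg = eq.SimConfig(n_proteins=500, replicates_per_genotype=3, seed=42)
sim = eq.simulate_experiment(cfg)

pq = eq.quantify(sim["psms"], sim["design"])          # filter -> normalize -> rollup
centred = eq.log2_transform_and_center(pq)            # WT-centred log2 matrix
model = eq.fit_all(centred, pq.design)                # allelic-series fit

print(model.beta_.loc["FAM134A"].round(2))
print("significant:", model.significant_.loc["FAM134A"].tolist())

ann = eq.parse_annotations(eq.truth_to_annotation(sim["truth"]))
print(eq.summarize_beta(model, ann, by="er_class").round(3))
```

```
WT->DKO    -2.58
DKO->TKO   -0.20
TKO->QKO    0.23
QKO->PKO   -0.39
Name: FAM134A, dtype: float64
significant: [True, False, False, False]
               WT->DKO  DKO->TKO  TKO->QKO  QKO->PKO  n_proteins
er_class
ER-associated   -0.022     0.005     0.036    -0.075          44
ER-lumen        -0.064     0.035     0.019     0.020          65
ER-membrane     -0.014    -0.076    -0.021    -0.115         113
none            -0.055    -0.029     0.011    -0.103         272
```

The simulated FAM134A is knocked out at the first step (true step effect
−2.5 log2 units): the fit recovers a strongly negative, significant β^WT→DKO
of −2.58 and near-zero, non-significant coefficients at the later steps —
the protein stays deleted, so no further step changes its abundance. The
compartment table shows mean β per step with group sizes.

The same pipeline is available from the shell:

```sh
erphagyquant simulate --config cfg.yaml --out sim/ --seed 42
erphagyquant quant --psms sim/psms.tsv --design sim/design.tsv --out sim/matrix.tsv
erphagyquant fit allelic --matrix sim/matrix.tsv --design sim/design.tsv --out sim/fits.tsv
erphagyquant stats ks --fits sim/fits.tsv --annotations sim/annotations.tsv --out sim/ks.tsv
erphagyquant flux --events events.csv --pairings pairings.tsv --out flux.tsv
```

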