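# qsip18o

Quantitative stable isotope probing (qSIP) with heavy water (H₂¹⁸O): estimate
taxon-specific microbial growth from shifts in DNA buoyant density.

## What this package does

When a soil (or other) community is incubated with ¹⁸O-enriched water,
actively growing bacteria synthesize DNA that incorporates ¹⁸O and therefore
bands at a higher density in a CsCl ultracentrifugation gradient. Sequencing
the 16S rRNA gene in each density fraction and scaling the read counts by
per-fraction qPCR totals gives each taxon a weighted-average density (WAD) in
every tube. Comparing a taxon's WAD between ¹⁸O- and ¹⁶O-amended tubes yields
its ¹⁸O **atom percent excess (APE)** — an integrated measure of new DNA
synthesis — and, under a linear-growth assumption, an absolute growth rate.

The model, for taxon *i* with unlabeled WAD *W*<sub>light</sub> and labeled
WAD *W*<sub>lab</sub>:

- GC content from the unlabeled baseline: *G* = (*W*<sub>light</sub> − 1.646057) / 0.083506
- unlabeled molecular weight: *M*<sub>light</sub> = 0.496 *G* + 307.691
- labeled molecular weight: *M*<sub>lab</sub> = *M*<sub>light</sub> · *W*<sub>lab</sub>/*W*<sub>light</sub>
- atom fraction excess: *A* = (*M*<sub>lab</sub> − *M*<sub>light</sub>) / 12.07747 · (1 − 0.002000429); APE = 100 *A*
- growth: *b*ᵢ = (*N*<sub>TOTAL</sub> − *N*<sub>LIGHT</sub>) / *t*, with
  *N*<sub>LIGHT</sub> = *N*<sub>TOTAL</sub> (1 − *A*/*A*<sub>sat</sub>) and
  *A*<sub>sat</sub> the enrichment of the incubation water (0.7876) minus
  natural abundance.

Around that core the package provides:

- **Replicate-presence filtering** (a taxon is kept for a treatment only if
  recovered from all replicates) and a **replicate-level bootstrap** (1000
  iterations, 90% percentile CI) for each taxon's APE; taxa whose lower CI
  bound clears zero are classified as actively growing.
- **Treatment comparisons**: per-taxon APE ratios between conditions,
  phylum-level means tested against 1 with Wilcoxon signed-rank tests and
  Benjamini–Hochberg correction.
- **Community metrics**: Inverse Simpson diversity of total vs
  qSIP-filtered (actively growing) communities, gross growth summed by
  phylum, and a growth-efficiency proxy (gross growth / CO₂ efflux) with
  percent reductions between moisture regimes.
- A **forward simulator** of the full experiment (fungal inoculum × moisture
  design, 54 tubes, 22 fractions/tube, Gaussian density bands, qPCR and
  sequencing noise) with a ground-truth ledger, so every inference stage can
  be validated end to end.

## Worked example

```sh
cat > design.yaml <<EOF
design:
  n_taxa: 120
run:
  n_boot: 1000
  seed: 7
EOF
qsip simulate -c design.yaml -o data --seed 7
qsip run -c design.yaml -i data -o results --seed 7
qsip report results
```

`simulate` writes the five input tables (`fractions.tsv`, `samples.tsv`,
`counts.tsv`, `taxonomy.tsv`, `co2.tsv`) plus the ground-truth ledger
`truth.tsv`; `run` writes the result tables and a run manifest; `report`
renders `summary.txt` and figures. The summary for the command above begins:

```
qSIP run summary
================

ASV-treatment estimates: 697 (303 active, lower 90% CI > 0)

Median APE of active taxa per treatment:
  R_irregularis|limited                  22.67 APE  (n=51)
  R_irregularis|replete                  31.71 APE  (n=60)
  S_bescii|limited                       18.09 APE  (n=53)
  S_bescii|replete                       24.93 APE  (n=38)
  uninoculated|limited                    9.11 APE  (n=45)
  uninoculated|replete                   22.49 APE  (n=56)
```

Reading this: each treatment's number is the median ¹⁸O APE over its actively
growing taxa — the simulated design suppresses growth potential under water
limitation in uninoculated soil (9.11 vs 22.49 APE) while fungal-inoculated
treatments are much less affected, and the per-treatment growth-efficiency
values in the rest of the summary follow the same pattern.

The same workflow is available as library calls
(`qsip18o.generate_experiment`, `qsip18o.run_pipeline`,
`qsip18o.truth_recovery_report`) for programmatic use.

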