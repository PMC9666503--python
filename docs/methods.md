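# Methods

## The qSIP model

DNA buoyant density in a CsCl gradient increases with both GC content and
heavy-isotope incorporation. The model therefore uses each taxon's
*unlabeled* weighted-average density (WAD) as its own baseline: with
densities in g mL⁻¹,

```
G        = (W_light − 1.646057) / 0.083506          GC fraction
M_light  = 0.496 · G + 307.691                      g mol⁻¹ per nucleotide
M_lab    = M_light · (W_lab / W_light)
A        = (M_lab − M_light) / 12.07747 · (1 − 0.002000429)
APE      = 100 · A
```

The four calibration constants (GC–density line, GC–molecular-weight line,
maximum per-nucleotide mass gain at full ¹⁸O substitution, natural ¹⁸O
abundance) are the published qSIP calibration for ¹⁸O and are exposed in the
`qsip` config section; only ¹⁸O defaults ship.

A taxon's WAD in a tube is the copy-weighted mean density over the tube's
*sequenced* fractions, where per-fraction copies are read proportions scaled
by the fraction's total 16S qPCR count. `N_TOTAL` for the tube is the sum of
those copies. Using only sequenced fractions keeps WAD and `N_TOTAL` on the
same support.

Growth assumes a linear form: newly synthesized DNA carries the ¹⁸O
enrichment of the incubation water (atom fraction 0.7876 here), so the new
fraction of the pool is `p_new = A / A_sat` with
`A_sat = 0.7876 − 0.002000429 = 0.785600`, and

```
N_LIGHT = N_TOTAL · (1 − p_new)
b       = (N_TOTAL − N_LIGHT) / t          copies g⁻¹ day⁻¹,  t = 7 d
cells_b = b / 6                            cells g⁻¹ day⁻¹ (6 gene copies/cell)
```

Negative A (noise when a taxon's labeled WAD falls below its baseline) is
deliberately not clamped: clamping would bias the bootstrap distributions,
and significance is delegated to the CI-based activity filter.
`N_TOTAL` is taken per replicate as the mean of the replicate's two T7 tube
totals (¹⁶O and ¹⁸O); T0 totals are carried through the outputs for turnover
interpretation but do not enter `b`, which the linear-growth equation defines
from end-of-assay quantities only.

## Uncertainty and activity classification

Replicate tubes (n = 3 per treatment and isotope) are the independent units,
so the bootstrap resamples replicate-level WADs: each of the 1000 iterations
draws 3 unlabeled and 3 labeled WADs with replacement, averages each side and
converts the pair to APE. The point estimate is the median of the draws; the
90% CI the 5th/95th percentiles (linear interpolation). A taxon is "actively
growing" when its lower bound is strictly above zero. Upstream of this, an
ASV is retained for a treatment only if it was recovered (≥1 read, any
sequenced fraction, either T7 isotope) from every replicate.

Known calibration limits of this estimator, quantified by the package's own
validation run (`scripts/acceptance.py`): with only three replicates per
side, the percentile bootstrap is anti-conservative. Under an all-inactive
null the activity call fires for roughly 10–14% of taxa rather than the
nominal one-sided 5% — for any continuous replicate noise the strict
`ci_low > 0` rule with 3+3 resampling has a floor near 12% — and empirical
coverage of the nominal 90% CI is near 72% rather than 90%. A further
contribution comes from the sequencing window: only fractions above the
DNA-concentration cutoff are observed, which truncates taxon bands
asymmetrically and biases APE slightly upward when the labeled community
shifts. These are properties of the estimator design (replicate-level
resampling, percentile CI, per-tube sequencing cutoff), not of its
implementation; they should be kept in mind when interpreting "active"
fractions from real 3-replicate experiments.

## Treatment comparisons

For taxa active under both of two conditions, the APE ratio (condition a /
condition b) measures differential growth potential. Ratios are averaged
*unweighted* within phylum; each phylum's ratios are tested against 1 with a
two-sided Wilcoxon signed-rank test (exact null distribution when n < 25
with no ties; normal approximation with tie correction otherwise; zero
differences dropped, all-zero sets give p = 1 by convention).
Benjamini–Hochberg correction runs across the phyla of one comparison family
(one pairwise treatment comparison), and significance is adjusted p < 0.05.
Reporting is restricted to the ten most abundant phyla, ranked by total read
count (configurable).

## Community metrics

Diversity uses the Inverse Simpson index `D = 1/Σ p_i²` on copy-scaled
abundances pooled per tube over sequenced fractions, computed for the total
community and for the qSIP-filtered ("active") community after
renormalization; values are per tube (sample), then summarized per
treatment. No rarefaction is applied. Gross growth per group is `Σ b_i · t`
over member ASVs — new gene copies per gram over the assay, keeping the
linear-growth convention — and the growth-efficiency proxy divides a
treatment's gross growth by its mean CO₂ efflux. Units are carried as a
composite string (copies g⁻¹ per µg CO₂ mg⁻¹ soil C) rather than converted
to biomass C. Percent reduction between moisture regimes is
`100·(1 − eff_limited/eff_replete)`.

## The simulator

`generate_experiment` emulates the full assay design: 3 fungal inoculum
levels × 2 moisture regimes × 3 replicates, each contributing T0 ¹⁶O, T7 ¹⁶O
and T7 ¹⁸O tubes (54 in the default design), 22 fractions per tube.

Ground truth per taxon: GC ~ U(0.3, 0.7); per treatment an activity flag
(default P(active) = 0.4) and, for active taxa, APE ~ U(0, 65 × treatment
scale) — inactive taxa have APE exactly 0. Abundances are Dirichlet(0.5) at
the base with lognormal treatment-level shifts (σ = 0.5) and per-replicate
multipliers (σ = 0.3). The default treatment APE scales encode the
study-shaped pattern the package is meant to exercise — strong suppression
under water limitation in uninoculated soil (scale 0.45 vs 1.0), mild
suppression with fungal inocula — and the default CO₂ means put the
S. bescii treatments highest. These are realistic choices for a soil
incubation, fixed once; the paper-style per-treatment values are not
measurable from a simulation and the acceptance metrics treat them as the
study conditions.

Physics: each taxon's DNA bands as a Gaussian in density (σ = 0.005 g mL⁻¹).
In a labeled tube the taxon is a two-component mixture — old DNA at the
unlabeled center, new DNA (fraction `p_new`) at the fully water-labeled
center — which makes the mass-weighted density shift reproduce the true APE
exactly under the inference model while keeping partial labeling physically
explicit. The collected gradient spans 1.620–1.800 g mL⁻¹ partitioned into
22 uniform bins (fraction 1 densest); mass outside the gradient is truncated
with a warning. Per-fraction DNA concentration (5 µg per tube, 40 µL
resuspension) and qPCR totals get lognormal noise (CV 0.05 and 0.15);
fractions above 1.0 ng µL⁻¹ are "sequenced" and receive multinomial read
counts at depth 10,000. These defaults give 6–11 sequenced fractions per
tube, as in the assay the design emulates. With `noise: false` the simulator
emits expectations instead of draws, making pipeline estimates exact up to
density-bin discretization (≈10⁻³ APE points).

Not emulated: chimeras and primer/amplification bias, phylogenetic
correlation of GC or activity, relic/extracellular DNA pools, non-uniform
fraction spacing, and taxon-specific 16S copy numbers. Passing recovery
tests therefore demonstrates correctness of the inference chain under the
stated noise model, not robustness to those real-data artifacts.

## Numerical and interface choices

- Fraction 1 = densest (physical collection order from the tube bottom); a
  `density_orientation: light_first` config flag renumbers both fractions
  and counts on input.
- All-zero read vectors yield all-zero copies; taxa with zero copies in a
  tube have undefined (absent) WAD and are skipped with a reason code when a
  whole side is missing.
- qPCR totals are interpreted as copies per g dry soil per fraction; the
  config records the basis string, since relative scaling cancels in WAD
  but not in `b`.
- GC outside [0, 1] and `p_new > 1` (super-saturated) produce warnings, not
  errors; values are retained.
- Bootstrap determinism: one seeded generator drives the estimate table in
  sorted (treatment, ASV) order; the experiment simulator derives one named
  substream per tube from the master seed, so single tubes are reproducible
  in isolation.
- The validation run uses 300 taxa and 1000 bootstrap iterations — large
  enough for stable error quantiles while keeping the whole run inside a
  few seconds.

## Known limitations

Beyond the bootstrap calibration and simulator-scope caveats above: the
growth model is linear by construction (no exponential variant); growth
estimates inherit the assumption of six 16S copies per cell; CO₂ efflux is a
treatment-level input, so efficiency carries no taxon-level resolution; and
the BIOM reader supports the JSON (v1) serialization only.
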