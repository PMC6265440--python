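# Methods

## The analysis model

`sipnet` implements the downstream analysis of a DNA-SIP rhizosphere
experiment. The measured objects are (i) CsCl gradient fraction
profiles per sample (buoyant density, fluorometric DNA quantity, δ¹³C),
(ii) sample × OTU count tables with ranked taxonomy and sample metadata
(plant species, nutrient-use strategy, compartment, replicate), and
(iii) per-sample activity measurements (SIR, DEA, root exudation rate).

The analysis assumes that ¹³C-labeled DNA of active exudate consumers
bands at higher buoyant density than unlabeled DNA, so that a "heavy"
fraction near 1.66 g ml⁻¹ and a "light" fraction near 1.62 g ml⁻¹
represent exudate consumers and SOM degraders respectively. Fraction
selection takes the fraction closest to the target density and fails
beyond a tolerance of 0.005 g ml⁻¹ — half the spacing of a 10-fraction
gradient spanning 1.58–1.70 g ml⁻¹. Peak location compares densities at
instrument precision (3 decimals) and breaks ties toward the higher
density. Enrichment calls use δ¹³C > baseline + margin with baseline
−28.7‰ (natural abundance) and a default margin of 5‰, which keeps
unplanted bulk soil (≈ −24.3‰) below the call; the margin is
configurable because classification in a SIP design properly rests on
density, not on a δ¹³C cutoff.

## Table processing rules

- Rare-OTU filter: an OTU is kept iff its total count strictly exceeds
  0.005% of the grand total across all samples. The threshold is global
  (not per sample); a per-sample variant is available via a flag. The
  filter is idempotent: removing rare OTUs lowers the grand total and
  hence the absolute threshold, so survivors survive re-application.
- Prevalence filter (pre-network): keep OTUs detected in strictly more
  than 25% of samples. Both filters use strict inequalities.
- Rarefaction: multivariate-hypergeometric subsampling without
  replacement to exactly the target depth (2,744 reads by default);
  samples below depth are dropped with a logged warning, never padded.
- Proportions: per-sample rows sum to 1 (relative abundance);
  per-OTU columns sum to 1 (repartition profiles, making an OTU's
  absolute abundance irrelevant to co-occurrence).
- Replicate aggregation sums by default (preserving the count nature of
  the table); mean is offered for sensitivity analysis.
- Core microbiota: presence = count ≥ 1 after rarefaction; the
  ubiquity threshold is inclusive (an OTU in exactly `threshold × n`
  samples is in the core), swept from 50% to 100% in 5% steps.
- Specificity ratios divide a phylum's relative abundance in one plant
  by its cross-plant mean, so each phylum's ratios average to 1; logs
  are base 10 (a display convention; configurable), and a zero ratio is
  reported as undefined rather than pseudocounted (a pseudocount flag
  exists). An OTU-count variant of the numerator is available, since
  "abundance" can be read either way.

## Ordination and group separation

PCoA double-centers −½D² (Gower centering) and eigendecomposes.
Negative eigenvalues — which arise because Bray–Curtis is not
Euclidean-embeddable — are reported in the spectrum for diagnostics but
contribute no coordinates and are excluded from the
proportion-explained denominator; no Cailliez/Lingoes correction is
applied by default. For Euclidean-embeddable input the embedding
reproduces the distances to numerical precision, which the tests check
at 1e-8.

Group separation uses a PERMANOVA-style pseudo-F on the distance
matrix: F = (SS_among/(a−1)) / (SS_within/(N−a)) with sums of squared
distances partitioned by group, compared against random label
permutations. The p-value uses the add-one estimator
(1 + #{F* ≥ F})/(1 + n_perm), so p = 0 is unattainable and the minimum
is 1/(n_perm+1). All permutations are driven by an explicit seed; there
is no hidden global random state.

## Co-occurrence networks

Edges connect OTU pairs whose per-OTU repartition profiles have
Bray–Curtis dissimilarity ≤ 0.12 — small distance means similar
repartition, i.e. co-occurrence. The alternative reading (similarity
≥ 0.12) would connect nearly every pair and is available as a flag, as
is per-sample normalization. Before inference, triplicates are summed
into one pseudo-sample per plant × fraction, so profiles run over
plants and compartments rather than replicate pots. Bulk-soil samples
are excluded from the RAS network by default.

Node preference coordinates are
x = (%E−%C)/(%E+%C) and y = (%H−%L)/(%H+%L), where the class
percentages are the OTU's **mean per-sample relative abundance** within
each class (exploitative/conservative samples for x, heavy/light for
y). The class-mean form is used rather than pooled raw read counts
because the design is unbalanced (4 exploitative vs 2 conservative
species): pooling would place every preference-free OTU at x ≈ +1/3,
whereas class means keep it at 0, and the two forms coincide under
balanced classes with equal depths. A coordinate whose denominator is
zero is undefined, kept as an explicit missing attribute (never 0), and
survives GraphML round-trips as such.

Graph statistics: mean degree is exactly 2E/N; the clustering
coefficient averages local transitivity over all nodes with degree-<2
nodes contributing 0 (exclusion selectable); the characteristic path
length averages shortest paths over connected ordered pairs only, with
the number of disconnected pairs reported.

## Activity statistics

The activity model is log(activity) = intercept + slope·exudation + ε,
fitted by least squares with the natural log (the base shifts slope and
intercept, never r). Pearson r is computed between log-activity and
exudation with the two-sided t-based p. Zero activities are rejected
before the transform, naming the offending samples. Because a single
correlation may be quoted jointly for SIR and DEA, both a per-activity
and a pooled (stacked) mode are provided. Group summaries report mean
and SE = sd/√n, with single-sample groups flagged rather than given a
fabricated SE.

## The synthetic generator

The generator emulates the study design: 6 species (BE, AO, DG, TF
exploitative; FP, SC conservative) × compartments light/heavy/root × 3
replicates, plus 3 bulk-soil controls (57 samples). Each OTU receives:

- a baseline abundance from a lognormal (σ = 1.5), giving the heavy
  tail typical of amplicon tables;
- a guild — exudate consumer (30%), SOM degrader (30%), generalist
  (25%), root specialist (15%) — that sets multiplicative compartment
  effects: consumers ×`enrichment_effect` in heavy (√fold in root),
  SOM degraders ×fold in light and bulk, root specialists ×fold in
  root. Bulk soil shares the light-fraction (SOM) profile with no
  exudate signal, mirroring its role as a no-plant control;
- a continuous strategy preference in [−1, 1]; samples of a strategy
  multiply the OTU by `strategy_effect^±pref`.

Counts are Gamma-mixed Poisson around depth × designed proportion.
Total mixing variance (`dispersion`, default 0.3) splits into a
component shared by all members of a guild within a sample
(`guild_correlation` = 0.8) and an OTU-specific residual. The shared
component is what makes same-guild OTUs co-fluctuate, so the
co-occurrence stage has genuine signal to find; with independent noise
only, no OTU pair would pass a 0.12 dissimilarity threshold. Per-sample
depths are Poisson around `mean_depth` = 5000, comfortably above the
2,744 rarefaction depth for most samples. Defaults
`enrichment_effect` = 8 and `strategy_effect` = 4 represent a strong
SIP labeling contrast and a clear but not absolute host preference.

Exudation rates are drawn per species, uniform over the configured
range with conservative species confined to the lower half (exploitative
species exude more); SIR and DEA follow the log-linear law with noise
σ = 0.3 on the log scale (DEA offset −0.5 so the two activities differ
in level but share the slope). Gradient profiles are 10 fractions on a
fixed density grid with a Gaussian DNA peak centered at 1.622 g ml⁻¹
and a δ¹³C peak centered at 1.655 g ml⁻¹ whose height scales with the
species' labeling level (itself mapped from exudation); measurement
noise is 1 fluorometric unit (DNA) and 0.4‰ (δ¹³C).

Everything derives from one master seed; the four stage streams (OTU
identities, counts, activities, gradients) use fixed spawn keys, so the
same config and seed reproduce every artifact byte-for-byte.

What the generator does **not** emulate: read-level error and chimera
structure, phylogenetic correlation among OTUs, compositional coupling
beyond the multinomial-like constraint, soil chemistry, and
between-replicate environmental gradients. Passing tests therefore
demonstrate that the analysis recovers the designed structure from
overdispersed counts at realistic depth — not that it would resolve
every feature of field data.

## Numerical choices and degenerate inputs

- Density comparisons round to 3 decimals; peak ties break upward.
- Ubiquity and prevalence thresholds guard float comparisons with a
  1e-9 epsilon so that 3-of-4 counts as exactly 0.75.
- Bray–Curtis on two all-zero vectors, flat gradient channels, empty
  samples, single-sample PCoA, single-member PERMANOVA groups, and
  constant regressors all raise typed errors rather than returning
  NaN.
- The unique-OTU percentage rounds half-up to an integer percent.
- Pipeline problem sizes: the bundled configs run 300 OTUs × 57
  samples at depth 5,000 with 999 permutations — large enough for
  stable network and test statistics while keeping a full run in
  seconds.

## Pipeline configuration

`sipnet run --config run.yaml` accepts:

```yaml
seed: 1                    # master seed, mandatory
output_dir: out            # where artifacts and manifest.json go
synthetic:                 # generate data (any SimConfig field), or:
  n_otus: 300
# inputs:
#   otu_table_prefix: data/otu_table   # .counts/.taxonomy/.samples TSVs
#   activity: data/activity.tsv
light_density: 1.62        # defaults shown
heavy_density: 1.66
min_abundance: 5.0e-5      # the 0.005% filter
min_prevalence: 0.25
network_threshold: 0.12
rarefaction_depth: 2744
n_perm: 999
stages: [data, gradient, filter, rarefy, diversity, core, network, activity]
```

Omitted stages are recorded as `skipped` in the manifest; the manifest
also stores a SHA-256 hash of the config and per-stage record counts,
and is byte-identical across runs of the same config and seed.

## Known limitations

- The 0.12 edge threshold is a fixed rule, not a null-model-calibrated
  significance test (no SparCC/SPIEC-EASI-style inference); spurious
  edges at low prevalence are possible and the prevalence filter is the
  only guard.
- The permutation test is a generic distance-based group-separation
  engine; it is not claimed to match any particular software's exact
  p-values, only its statistic is cross-checked against an independent
  implementation.
- BIOM support covers the dense JSON 1.0 variant only (sufficient for
  round-tripping this package's tables).
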