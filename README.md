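# sipnet

Analysis toolkit for DNA stable-isotope-probing (DNA-SIP) studies of
rhizosphere microbiota — who is active, on which carbon source, and under
which plant.

In a DNA-SIP experiment, plants are grown under a ¹³CO₂ atmosphere so
that organisms assimilating fresh root exudates build ¹³C into their
DNA. CsCl density-gradient ultracentrifugation then separates a "heavy"
DNA pool (exudate consumers, buoyant density ≈ 1.66 g ml⁻¹) from a
"light" pool (soil-organic-matter degraders, ≈ 1.62 g ml⁻¹), and 16S
amplicon sequencing of each fraction — plus root tissue and unplanted
bulk soil — yields sample × OTU count tables. `sipnet` covers the
downstream analysis chain for such data:

- **gradient** — model fraction profiles (density, DNA quantity, δ¹³C),
  select the light/heavy fractions, locate channel peaks, call ¹³C
  enrichment against the −28.7‰ natural-abundance baseline;
- **otu** — count-table container with taxonomy and sample metadata;
  the 0.005% relative-abundance filter, the >25% prevalence filter,
  seeded rarefaction (without replacement), rarefaction curves,
  proportion normalization, replicate and taxonomy aggregation;
- **diversity** — observed richness, inverse Simpson `1/Σpᵢ²`,
  Bray–Curtis dissimilarity `Σ|uᵢ−vᵢ|/Σ(uᵢ+vᵢ)`, principal coordinates
  analysis (Gower centering), and a seeded PERMANOVA-style permutation
  test of group separation;
- **core** — core microbiota by ubiquity threshold (100% of samples by
  default, swept 50→100% in 5% steps), Venn partitioning of per-group
  cores, and per-phylum plant-specificity ratios
  (abundance / cross-plant mean, log-scaled);
- **network** — co-occurrence inference: per-OTU repartition profiles →
  all-pairs Bray–Curtis → edge where dissimilarity ≤ 0.12, with each
  node placed at preference coordinates
  `x = (%E−%C)/(%E+%C)` (exploitative vs conservative plants) and
  `y = (%H−%L)/(%H+%L)` (heavy vs light fraction), plus mean degree
  `2E/N`, clustering coefficient and characteristic path length;
- **activity** — log-linear correlation of substrate-induced
  respiration (SIR) and denitrifying enzyme activity (DEA) with root
  exudation rate;
- **synthetic** — a seeded generator that emulates the full study
  design (6 grass species on an exploitative↔conservative nutrient-use
  gradient × light/heavy/root compartments × 3 replicates + bulk-soil
  controls) with known OTU guilds, strategy preferences and activity
  parameters, so every stage is testable against ground truth.

## Worked example

Generate a synthetic experiment, build the root-adhering-soil (RAS)
network from the light+heavy fractions, and correlate denitrification
with exudation:

```
$ sipnet simulate --seed 1 --out demo
wrote 57 samples x 300 OTUs to demo

$ sipnet network --table demo/otu_table --compartments light,heavy --out demo/ras.graphml
{
 "n_nodes": 296,
 "n_edges": 913,
 "mean_degree": 6.169,
 "clustering_coefficient": 0.393,
 "characteristic_path_length": 5.295
}

$ sipnet activity --activity-table demo/activity.tsv --response dea
{
 "r": 0.8674,
 "p": 3e-06,
 "slope": 0.282502,
 "intercept": 0.44112,
 "n": 18
}

$ sipnet gradient --profile demo/gradient_TF.tsv
{
 "light": {"density": 1.62, "delta13C": -25.9812},
 "heavy": {"density": 1.66, "delta13C": 22.4499},
 "dna_peak_density": 1.62,
 "delta13C_peak_density": 1.66
}
```

Reading the output: the RAS network's 296 OTUs are connected by 913
edges (mean degree 6.17 = 2·913/296), and the graph is strongly
clustered (0.39) — OTUs sharing a guild co-fluctuate and form modules.
DEA rises log-linearly with exudation (r = 0.87 over 18 samples; the
fitted slope 0.28 recovers the generator's true slope 0.25 within its
standard error). The TF gradient shows total DNA peaking at
1.62 g ml⁻¹ while δ¹³C peaks at 1.66 g ml⁻¹: heavily labeled DNA from a
high-exudation species, so its heavy fraction (δ¹³C ≈ +22‰, far above
the −28.7‰ baseline) is called enriched.

The full pipeline — gradient selection, 0.005% abundance filter,
rarefaction to 2,744 reads, diversity + PCoA + permutation tests, core
partitioning, both networks, and activity correlation, with a
reproducible JSON manifest — runs from a YAML config:

```
sipnet run --config run.yaml     # see docs/methods.md for the config keys
```

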