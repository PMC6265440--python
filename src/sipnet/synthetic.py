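"""Seeded synthetic DNA-SIP datasets with known ground truth.

The generator emulates the structure of a ¹³CO₂-labeling rhizosphere
experiment on grassland soil: six plant species (four exploitative, two
conservative nutrient-use strategies) × three DNA compartments per plant
(light fraction ≈ SOM degraders, heavy fraction ≈ ¹³C-exudate consumers,
root tissue) × three replicates, plus unplanted bulk-soil controls.

Each OTU is assigned a functional guild and a continuous plant-strategy
preference; these determine multiplicative effects on its expected
proportion per sample class. Counts are drawn from a Gamma-mixed Poisson
(negative-binomial-like) model to mimic OTU-table overdispersion. The
activity table follows log(activity) = intercept + slope·exudation + ε,
and each species gets a CsCl gradient profile whose DNA peak sits at
1.62–1.63 g ml⁻¹ and whose δ¹³C peak sits at 1.64–1.67 g ml⁻¹, scaled by
the species' labeling level.

A single master seed drives everything; stage streams are derived by
fixed spawn keys so partial reruns stay reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .gradient import GradientFraction, GradientProfile, NATURAL_ABUNDANCE_D13C
from .otu import OtuTable

GUILDS = ("exudate_consumer", "som_degrader", "generalist", "root_specialist")

DEFAULT_SPECIES_STRATEGIES: dict[str, str] = {
    # four exploitative, two conservative grasses
    "BE": "exploitative",
    "AO": "exploitative",
    "DG": "exploitative",
    "TF": "exploitative",
    "FP": "conservative",
    "SC": "conservative",
}

_PHYLA = (
    "Proteobacteria",
    "Actinobacteria",
    "Bacteroidetes",
    "Firmicutes",
    "Acidobacteria",
    "Verrucomicrobia",
    "Chloroflexi",
    "Nitrospirae",
    "Planctomycetes",
    "Gemmatimonadetes",
)

_COMPARTMENTS = ("light", "heavy", "root")


@dataclass
class SimConfig:
    """Parameters of the synthetic experiment.

    Effects are multiplicative folds: ``enrichment_effect`` elevates
    exudate consumers in heavy vs light fractions (1 = no SIP signal);
    ``strategy_effect`` elevates strategy-preferring OTUs in samples of
    the matching plant strategy. ``dispersion`` is the total Gamma
    mixing variance of the count model (0 = pure Poisson);
    ``guild_correlation`` is the share of that variance that members of
    the same guild experience jointly within a sample (co-response),
    which is what gives co-occurring OTUs correlated repartition
    profiles.
    """

    n_species: int = 6
    strategy_map: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_SPECIES_STRATEGIES)
    )
    n_replicates: int = 3
    n_otus: int = 300
    n_phyla: int = 8
    guild_fractions: dict[str, float] = field(
        default_factory=lambda: {
            "exudate_consumer": 0.30,
            "som_degrader": 0.30,
            "generalist": 0.25,
            "root_specialist": 0.15,
        }
    )
    mean_depth: int = 5000
    dispersion: float = 0.3
    guild_correlation: float = 0.8
    enrichment_effect: float = 8.0
    strategy_effect: float = 4.0
    exudation_range: tuple[float, float] = (1.0, 10.0)
    activity_slope: float = 0.25
    activity_intercept: float = 1.0
    activity_noise_sd: float = 0.3
    include_bulk: bool = True
    seed: int = 0

    def validate(self) -> None:
        if set(self.guild_fractions) - set(GUILDS):
            raise ConfigurationError(f"unknown guilds {set(self.guild_fractions) - set(GUILDS)}")
        if abs(sum(self.guild_fractions.values()) - 1.0) > 1e-9:
            raise ConfigurationError("guild_fractions must sum to 1")
        if any(v < 0 for v in self.guild_fractions.values()):
            raise ConfigurationError("guild_fractions must be non-negative")
        if self.enrichment_effect <= 0 or self.strategy_effect <= 0:
            raise ConfigurationError("effect folds must be > 0")
        if not 0.0 <= self.guild_correlation <= 1.0:
            raise ConfigurationError("guild_correlation must be in [0, 1]")
        if self.n_replicates < 1:
            raise ConfigurationError("n_replicates must be >= 1")
        if len(self.strategy_map) != self.n_species:
            raise ConfigurationError(
                f"strategy_map has {len(self.strategy_map)} species, expected {self.n_species}"
            )
        if set(self.strategy_map.values()) - {"exploitative", "conservative"}:
            raise ConfigurationError("strategies must be exploitative or conservative")
        lo, hi = self.exudation_range
        if not lo < hi:
            raise ConfigurationError("exudation_range must be (min, max) with min < max")


@dataclass
class GroundTruth:
    """What the generator knows that the analysis must recover."""

    otu_guild: dict[str, str]
    otu_strategy_pref: dict[str, float]  # preference in [-1, 1]
    true_activity_params: tuple[float, float]  # (slope, intercept)
    otu_baseline: dict[str, float] = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        return {
            "otu_guild": self.otu_guild,
            "otu_strategy_pref": {k: float(v) for k, v in self.otu_strategy_pref.items()},
            "true_activity_params": [float(v) for v in self.true_activity_params],
            "otu_baseline": {k: float(v) for k, v in self.otu_baseline.items()},
        }


def _rng(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(stream,)))


def _guild_multiplier(guild: str, compartment: str, fold: float) -> float:
    """Expected fold of a guild in a compartment relative to baseline.

    Bulk soil shares the SOM-degrader profile of the light fraction (no
    exudate signal); root tissue favours root specialists and, more
    weakly, exudate consumers.
    """
    if guild == "exudate_consumer":
        return {"light": 1.0, "bulk": 1.0, "heavy": fold, "root": float(np.sqrt(fold))}[compartment]
    if guild == "som_degrader":
        return {"light": fold, "bulk": fold, "heavy": 1.0, "root": 1.0}[compartment]
    if guild == "root_specialist":
        return fold if compartment == "root" else 1.0
    return 1.0  # generalist


def designed_proportions(cfg: SimConfig, truth: GroundTruth) -> pd.DataFrame:
    """Expected OTU proportions per (compartment, strategy) sample class.

    These are the noise-free design targets the count model samples
    around; with both effects at 1 every class row is identical.
    """
    otus = list(truth.otu_guild)
    baseline = np.array([truth.otu_baseline[o] for o in otus])
    prefs = np.array([truth.otu_strategy_pref[o] for o in otus])
    guilds = [truth.otu_guild[o] for o in otus]
    rows = {}
    classes = [(c, s) for c in _COMPARTMENTS for s in ("exploitative", "conservative")]
    if cfg.include_bulk:
        classes.append(("bulk", "none"))
    for compartment, strategy in classes:
        g_mult = np.array(
            [_guild_multiplier(g, compartment, cfg.enrichment_effect) for g in guilds]
        )
        if strategy == "exploitative":
            s_mult = cfg.strategy_effect**prefs
        elif strategy == "conservative":
            s_mult = cfg.strategy_effect ** (-prefs)
        else:
            s_mult = np.ones_like(prefs)
        weights = baseline * g_mult * s_mult
        rows[(compartment, strategy)] = weights / weights.sum()
    out = pd.DataFrame(rows).T
    out.columns = otus
    return out


def generate_dataset(
    config: SimConfig,
) -> tuple[OtuTable, pd.DataFrame, dict[str, GradientProfile], GroundTruth]:
    """Generate the full synthetic experiment.

    Returns the OTU table (all species × compartments × replicates plus
    bulk controls), the per-sample activity table, one gradient profile
    per species, and the ground truth. Identical config and seed give
    identical output.
    """
    config.validate()
    seed = config.seed

    # --- stream 0: OTU identities, guilds, preferences, baselines -----
    rng = _rng(seed, 0)
    otus = [f"OTU_{i + 1:04d}" for i in range(config.n_otus)]
    n_phyla = min(config.n_phyla, len(_PHYLA))
    phylum_weights = rng.dirichlet(np.ones(n_phyla) * 1.5)
    phyla = rng.choice(_PHYLA[:n_phyla], size=config.n_otus, p=phylum_weights)
    taxonomy = pd.Series([f"Bacteria;{p}" for p in phyla], index=otus)

    guild_names = list(config.guild_fractions)
    guild_p = np.array([config.guild_fractions[g] for g in guild_names])
    guilds = rng.choice(guild_names, size=config.n_otus, p=guild_p)
    prefs = rng.uniform(-1.0, 1.0, size=config.n_otus)
    baseline = rng.lognormal(mean=0.0, sigma=1.5, size=config.n_otus)
    truth = GroundTruth(
        otu_guild=dict(zip(otus, (str(g) for g in guilds))),
        otu_strategy_pref=dict(zip(otus, prefs)),
        true_activity_params=(config.activity_slope, config.activity_intercept),
        otu_baseline=dict(zip(otus, baseline)),
    )
    design = designed_proportions(config, truth)

    # --- stream 1: counts --------------------------------------------
    rng_counts = _rng(seed, 1)
    sample_rows = []
    meta_rows = []
    species_list = list(config.strategy_map)
    for species in species_list:
        strategy = config.strategy_map[species]
        for compartment in _COMPARTMENTS:
            for rep in range(1, config.n_replicates + 1):
                sample_rows.append((f"{species}_{compartment}_r{rep}", compartment, strategy, species, rep))
    if config.include_bulk:
        for rep in range(1, config.n_replicates + 1):
            sample_rows.append((f"BS_bulk_r{rep}", "bulk", "none", "BS", rep))

    # Gamma-mixed Poisson: the mixing variance splits into a component
    # shared by all OTUs of a guild within a sample (co-response) and an
    # OTU-specific residual, so same-guild OTUs co-fluctuate.
    disp_shared = config.dispersion * config.guild_correlation
    disp_cell = config.dispersion * (1.0 - config.guild_correlation)
    guild_of = np.asarray(guilds)
    counts = np.zeros((len(sample_rows), config.n_otus), dtype=np.int64)
    for i, (sample_id, compartment, strategy, species, rep) in enumerate(sample_rows):
        p = design.loc[(compartment, strategy)].to_numpy()
        depth = rng_counts.poisson(config.mean_depth)
        mu = depth * p
        if disp_shared > 0:
            shared = {
                g: rng_counts.gamma(1.0 / disp_shared, disp_shared)
                for g in guild_names
            }
            mu = mu * np.array([shared[g] for g in guild_of])
        if disp_cell > 0:
            mu = rng_counts.gamma(1.0 / disp_cell, mu * disp_cell)
        counts[i] = rng_counts.poisson(mu)
        meta_rows.append(
            {"species": species, "strategy": strategy, "compartment": compartment, "replicate": rep}
        )
    sample_ids = [r[0] for r in sample_rows]
    table = OtuTable(
        counts=pd.DataFrame(counts, index=sample_ids, columns=otus),
        taxonomy=taxonomy,
        sample_meta=pd.DataFrame(meta_rows, index=sample_ids),
    )

    # --- stream 2: activities ----------------------------------------
    rng_act = _rng(seed, 2)
    lo, hi = config.exudation_range
    mid = (lo + hi) / 2
    exudation_by_species = {}
    for species in species_list:
        if config.strategy_map[species] == "conservative":
            exudation_by_species[species] = rng_act.uniform(lo, mid)
        else:
            exudation_by_species[species] = rng_act.uniform(lo, hi)
    act_rows = []
    act_ids = []
    for species in species_list:
        for rep in range(1, config.n_replicates + 1):
            ex = exudation_by_species[species]
            log_sir = config.activity_intercept + config.activity_slope * ex + rng_act.normal(0, config.activity_noise_sd)
            log_dea = (
                config.activity_intercept - 0.5
                + config.activity_slope * ex
                + rng_act.normal(0, config.activity_noise_sd)
            )
            act_ids.append(f"{species}_ras_r{rep}")
            act_rows.append(
                {
                    "species": species,
                    "strategy": config.strategy_map[species],
                    "sir": float(np.exp(log_sir)),
                    "dea": float(np.exp(log_dea)),
                    "exudation": float(ex),
                }
            )
    activity = pd.DataFrame(act_rows, index=act_ids)

    # --- stream 3: gradient profiles ---------------------------------
    rng_grad = _rng(seed, 3)
    child_seeds = rng_grad.integers(0, 2**31 - 1, size=len(species_list))
    profiles = {}
    for k, species in enumerate(species_list):
        ex = exudation_by_species[species]
        labeling = 0.05 + 0.90 * (ex - lo) / (hi - lo)
        profiles[species] = generate_gradient_profile(labeling, seed=int(child_seeds[k]), label=species)
    return table, activity, profiles, truth


# ---------------------------------------------------------------------
# Gradient profile synthesis
# ---------------------------------------------------------------------

_GRADIENT_DENSITIES = np.round(np.linspace(1.58, 1.70, 10), 3)
_DNA_PEAK_CENTER = 1.622  # g/ml, within the observed 1.62-1.63 band
_D13C_PEAK_CENTER = 1.655  # g/ml, within the observed 1.64-1.67 band
_DNA_AMPLITUDE = 100.0  # fluorometric units
_D13C_AMPLITUDE = 80.0  # permil above baseline at full labeling
_DNA_NOISE_SD = 1.0
_D13C_NOISE_SD = 0.4


def generate_gradient_profile(
    labeling_atom_pct: float, seed: int, label: str = ""
) -> GradientProfile:
    """Synthesize a 10-fraction CsCl gradient profile.

    The DNA channel is unimodal with its maximum in 1.62–1.63 g ml⁻¹;
    the δ¹³C channel rises above the −28.7‰ natural-abundance baseline
    in proportion to ``labeling_atom_pct`` with its maximum in
    1.64–1.67 g ml⁻¹. At labeling 0 every fraction sits at baseline
    within measurement noise.
    """
    if not 0.0 <= labeling_atom_pct <= 1.0:
        raise ValueError(f"labeling_atom_pct must be in [0, 1], got {labeling_atom_pct}")
    rng = np.random.default_rng(seed)
    d = _GRADIENT_DENSITIES
    dna = _DNA_AMPLITUDE * np.exp(-(((d - _DNA_PEAK_CENTER) / 0.018) ** 2))
    dna = np.clip(dna + rng.normal(0, _DNA_NOISE_SD, size=d.size), 0, None)
    delta = (
        NATURAL_ABUNDANCE_D13C
        + labeling_atom_pct * _D13C_AMPLITUDE * np.exp(-(((d - _D13C_PEAK_CENTER) / 0.02) ** 2))
        + rng.normal(0, _D13C_NOISE_SD, size=d.size)
    )
    fractions = [
        GradientFraction(
            index=i + 1,
            buoyant_density=float(d[i]),
            dna_quantity=float(dna[i]),
            delta13C=float(delta[i]),
        )
        for i in range(d.size)
    ]
    return GradientProfile(fractions=fractions, label=label)
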