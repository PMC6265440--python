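"""End-to-end orchestration of the SIP analysis from a YAML config.

Stage order mirrors the analysis: data (synthetic generation or file
ingest) → gradient fraction selection → abundance filter → rarefaction →
diversity + ordination → core/Venn/specificity → co-occurrence networks
→ activity correlation. Every run writes its artifacts plus a JSON
manifest holding the config hash, the master seed, and per-stage record
counts; the manifest is byte-identical across runs of the same config
and seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import activity as activity_mod
from . import core as core_mod
from . import diversity as div
from . import io as sio
from . import network as net_mod
from . import otu as otu_mod
from .exceptions import ConfigurationError, PipelineStageError
from .gradient import peak_density, select_fraction
from .otu import OtuTable, SampleGroup
from .synthetic import SimConfig, generate_dataset

logger = logging.getLogger(__name__)

ALL_STAGES = (
    "data",
    "gradient",
    "filter",
    "rarefy",
    "diversity",
    "core",
    "network",
    "activity",
)

DEFAULTS: dict[str, Any] = {
    "light_density": 1.62,
    "heavy_density": 1.66,
    "min_abundance": 5e-5,  # the 0.005% rare-OTU filter
    "min_prevalence": 0.25,
    "network_threshold": 0.12,
    "rarefaction_depth": 2744,
    "n_perm": 999,
}


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    seed: int
    output_dir: Path
    synthetic: SimConfig | None = None
    input_prefix: Path | None = None
    activity_path: Path | None = None
    stages: tuple[str, ...] = ALL_STAGES
    params: dict[str, Any] = field(default_factory=lambda: dict(DEFAULTS))
    raw: dict[str, Any] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            with open(path, encoding="utf-8") as fh:
                doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigurationError(f"malformed YAML config: {exc}") from exc
        if not isinstance(doc, dict):
            raise ConfigurationError("config must be a YAML mapping")
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict[str, Any]) -> "RunConfig":
        if "seed" not in doc:
            raise ConfigurationError("config requires a 'seed'")
        seed = int(doc["seed"])
        out_dir = Path(doc.get("output_dir", "sipnet_out"))
        params = dict(DEFAULTS)
        for key in params:
            if key in doc:
                params[key] = doc[key]
        if not 0 <= params["min_prevalence"] < 1:
            raise ConfigurationError("min_prevalence must be in [0, 1)")
        if not 0 <= params["network_threshold"] <= 1:
            raise ConfigurationError("network_threshold must be in [0, 1]")
        if params["rarefaction_depth"] < 1:
            raise ConfigurationError("rarefaction_depth must be >= 1")
        stages = tuple(doc.get("stages", ALL_STAGES))
        unknown = set(stages) - set(ALL_STAGES)
        if unknown:
            raise ConfigurationError(f"unknown stages {sorted(unknown)}")
        synthetic = None
        input_prefix = None
        activity_path = None
        if "synthetic" in doc:
            syn = dict(doc["synthetic"] or {})
            syn.setdefault("seed", seed)
            if "exudation_range" in syn:
                syn["exudation_range"] = tuple(syn["exudation_range"])
            try:
                synthetic = SimConfig(**syn)
            except TypeError as exc:
                raise ConfigurationError(f"bad synthetic block: {exc}") from exc
            synthetic.validate()
        elif "inputs" in doc:
            inputs = doc["inputs"]
            input_prefix = Path(inputs["otu_table_prefix"])
            if "activity" in inputs:
                activity_path = Path(inputs["activity"])
        else:
            raise ConfigurationError("config needs a 'synthetic' or 'inputs' block")
        return cls(
            seed=seed,
            output_dir=out_dir,
            synthetic=synthetic,
            input_prefix=input_prefix,
            activity_path=activity_path,
            stages=stages,
            params=params,
            raw=doc,
        )

    def config_hash(self) -> str:
        canonical = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()


def _json_default(o: Any) -> Any:
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages and return the manifest dict.

    Any stage failure aborts with :class:`PipelineStageError` naming the
    stage; the partially written manifest on disk is flagged stale.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
        "stale": True,  # flipped to False once all stages finish
    }
    manifest_path = out / "manifest.json"

    def record(stage: str, status: str, **counts: Any) -> None:
        manifest["stages"][stage] = {"status": status, **counts}
        with open(manifest_path, "w", encoding="utf-8") as fh:
            json.dump(manifest, fh, indent=1, sort_keys=True, default=_json_default)
            fh.write("\n")

    enabled = set(config.stages)
    for stage in ALL_STAGES:
        if stage not in enabled:
            record(stage, "skipped")

    state: dict[str, Any] = {}
    for stage in ALL_STAGES:
        if stage not in enabled:
            continue
        t0 = time.perf_counter()
        try:
            counts = _STAGE_FUNCS[stage](config, state, out)
        except Exception as exc:  # noqa: BLE001 - rewrap with stage name
            record(stage, "failed", error=str(exc))
            raise PipelineStageError(stage, exc) from exc
        logger.info("stage %s finished in %.2fs: %s", stage, time.perf_counter() - t0, counts)
        record(stage, "completed", **counts)
    manifest["stale"] = False
    with open(manifest_path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    return manifest


# ---------------------------------------------------------------------
# Stage implementations
# ---------------------------------------------------------------------

def _stage_data(config: RunConfig, state: dict, out: Path) -> dict:
    if config.synthetic is not None:
        table, act, profiles, truth = generate_dataset(config.synthetic)
        state.update(table=table, activity=act, profiles=profiles, truth=truth)
        sio.write_otu_table_tsv(table, out / "otu_table")
        sio.write_biom_json(table, out / "otu_table.biom.json")
        sio.write_activity_tsv(act, out / "activity.tsv")
        for species, profile in profiles.items():
            sio.write_gradient_tsv(profile, out / f"gradient_{species}.tsv")
        with open(out / "ground_truth.json", "w", encoding="utf-8") as fh:
            json.dump(truth.to_json_dict(), fh, indent=1, sort_keys=True)
            fh.write("\n")
    else:
        table = sio.read_otu_table_tsv(config.input_prefix)
        state.update(table=table, profiles={}, truth=None)
        if config.activity_path is not None:
            state["activity"] = sio.read_activity_tsv(config.activity_path)
    table = state["table"]
    return {"n_samples": table.n_samples, "n_otus": table.n_otus}


def _stage_gradient(config: RunConfig, state: dict, out: Path) -> dict:
    profiles = state.get("profiles", {})
    rows = []
    for species, profile in sorted(profiles.items()):
        light = select_fraction(profile, config.params["light_density"], tolerance=0.01)
        heavy = select_fraction(profile, config.params["heavy_density"], tolerance=0.01)
        rows.append(
            {
                "species": species,
                "light_density": light.buoyant_density,
                "heavy_density": heavy.buoyant_density,
                "heavy_delta13C": heavy.delta13C,
                "dna_peak_density": peak_density(profile, "dna"),
                "delta13C_peak_density": peak_density(profile, "delta13C"),
            }
        )
    if rows:
        pd.DataFrame(rows).to_csv(out / "gradient_selection.tsv", sep="\t", index=False, float_format="%.6g")
    return {"n_profiles": len(rows)}


def _stage_filter(config: RunConfig, state: dict, out: Path) -> dict:
    table = otu_mod.filter_by_relative_abundance(state["table"], config.params["min_abundance"])
    state["table"] = table
    return {"n_samples": table.n_samples, "n_otus": table.n_otus}


def _stage_rarefy(config: RunConfig, state: dict, out: Path) -> dict:
    table = otu_mod.rarefy(state["table"], int(config.params["rarefaction_depth"]), seed=config.seed)
    state["table"] = table
    sio.write_counts_tsv(table, out / "rarefied.counts.tsv")
    return {"n_samples": table.n_samples, "n_otus": table.n_otus, "depth": int(config.params["rarefaction_depth"])}


def _stage_diversity(config: RunConfig, state: dict, out: Path) -> dict:
    table: OtuTable = state["table"]
    alpha = pd.DataFrame(
        {
            "observed_richness": [
                div.observed_richness(table.counts.loc[s]) for s in table.sample_ids
            ],
            "inverse_simpson": [
                div.inverse_simpson(table.counts.loc[s]) for s in table.sample_ids
            ],
        },
        index=table.sample_ids,
    )
    alpha.index.name = "#SampleID"
    alpha.to_csv(out / "alpha_diversity.tsv", sep="\t", float_format="%.6g")
    rel = table.counts.div(table.counts.sum(axis=1), axis=0)
    labels, dm = div.bray_curtis_matrix(rel)
    sio.write_distance_matrix_tsv(labels, dm, out / "bray_curtis.tsv")
    ordination = div.pcoa(labels, dm)
    ordination.coordinates.to_csv(out / "pcoa_coordinates.tsv", sep="\t", float_format="%.8g")
    counts: dict[str, Any] = {"n_samples": len(labels), "n_axes": ordination.coordinates.shape[1]}
    # group separation: heavy vs light fractions of the root-adhering soil
    ras = table.samples_where(compartment={"light", "heavy"})
    if len(ras) >= 4:
        idx = [labels.index(s) for s in ras]
        sub_dm = dm[np.ix_(idx, idx)]
        groups = table.sample_meta.loc[ras, "compartment"].to_numpy()
        f, p = div.permutation_group_test(
            ras, sub_dm, groups, n_perm=int(config.params["n_perm"]), seed=config.seed
        )
        counts["heavy_vs_light_pseudo_F"] = round(f, 6)
        counts["heavy_vs_light_p"] = round(p, 6)
    summary = {
        "eigenvalues": [float(v) for v in ordination.eigenvalues],
        "proportion_explained": [float(v) for v in ordination.proportion_explained],
    }
    with open(out / "pcoa_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=1)
        fh.write("\n")
    state["distance"] = (labels, dm)
    return counts


def _stage_core(config: RunConfig, state: dict, out: Path) -> dict:
    table: OtuTable = state["table"]
    results: dict[str, Any] = {}
    n_regions = 0
    for compartment in ("light", "heavy", "root"):
        ids = table.samples_where(compartment=compartment)
        if not ids:
            continue
        sub = table.subset_samples(ids)
        cores = {}
        for species in sorted(sub.sample_meta["species"].unique()):
            group = SampleGroup(species, frozenset(sub.samples_where(species=species)))
            cores[species] = core_mod.core_otus(sub, group, ubiquity=1.0)
        if len(cores) >= 2:
            strategies = table.sample_meta.set_index("species")["strategy"].to_dict()
            for strat in ("exploitative", "conservative"):
                members = {sp: c for sp, c in cores.items() if strategies.get(sp) == strat}
                if len(members) < 2:
                    continue
                part = core_mod.venn_partition(members)
                results[f"{compartment}_{strat}"] = {
                    "union": part.union_size,
                    "shared_by_all": part.shared_by_all(),
                    "unique": {sp: part.unique_to(sp) for sp in members},
                }
                n_regions += len(part.region_counts)
        sweep_group = SampleGroup(compartment, frozenset(ids))
        results[f"{compartment}_ubiquity_sweep"] = [
            [t, n] for t, n in core_mod.ubiquity_sweep(sub, sweep_group)
        ]
    with open(out / "core_partition.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=1, sort_keys=True, default=_json_default)
        fh.write("\n")
    try:
        spec = core_mod.phylum_specificity(table, "heavy")
        spec.log_ratios.to_csv(out / "phylum_specificity_heavy.tsv", sep="\t", float_format="%.6g")
    except ValueError:
        pass
    return {"n_venn_regions": n_regions, "n_result_blocks": len(results)}


def _stage_network(config: RunConfig, state: dict, out: Path) -> dict:
    table: OtuTable = state["table"]
    counts: dict[str, Any] = {}
    for name, compartments in (("ras", ("light", "heavy")), ("root", ("root",))):
        ids = table.samples_where(compartment=set(compartments))
        if not ids:
            continue
        # regroup triplicates into one pseudo-sample per plant x fraction
        agg = otu_mod.regroup_triplicates(table.subset_samples(ids))
        net = net_mod.build_network(
            agg,
            min_prevalence=config.params["min_prevalence"],
            threshold=config.params["network_threshold"],
            position_table=table,
        )
        stats = net_mod.network_stats(net)
        net_mod.export_graphml(net, out / f"network_{name}.graphml")
        net_mod.edge_table(net).to_csv(out / f"network_{name}.edges.tsv", sep="\t", index=False, float_format="%.8g")
        net_mod.node_table(net).to_csv(out / f"network_{name}.nodes.tsv", sep="\t", index=False, float_format="%.8g")
        counts[f"{name}_nodes"] = stats.n_nodes
        counts[f"{name}_edges"] = stats.n_edges
        counts[f"{name}_mean_degree"] = round(stats.mean_degree, 6)
        counts[f"{name}_clustering"] = round(stats.clustering_coefficient, 6)
        if np.isfinite(stats.characteristic_path_length):
            counts[f"{name}_path_length"] = round(stats.characteristic_path_length, 6)
    return counts


def _stage_activity(config: RunConfig, state: dict, out: Path) -> dict:
    act = state.get("activity")
    if act is None:
        return {"n_samples": 0}
    results = {}
    for col in ("sir", "dea"):
        res = activity_mod.log_linear_correlation(act[col], act["exudation"])
        results[col] = {
            "r": round(res.r, 6),
            "p": round(res.p, 8),
            "slope": round(res.slope, 6),
            "intercept": round(res.intercept, 6),
            "n": res.n,
        }
    pooled = activity_mod.pooled_log_linear_correlation(
        {"sir": act["sir"], "dea": act["dea"]}, act["exudation"]
    )
    results["pooled"] = {"r": round(pooled.r, 6), "p": round(pooled.p, 8), "n": pooled.n}
    with open(out / "activity_correlation.json", "w", encoding="utf-8") as fh:
        json.dump(results, fh, indent=1, sort_keys=True)
        fh.write("\n")
    summary = activity_mod.group_summary(act, by="strategy")
    summary.to_csv(out / "activity_by_strategy.tsv", sep="\t", float_format="%.6g")
    return {"n_samples": len(act), "sir_r": results["sir"]["r"], "dea_r": results["dea"]["r"]}


_STAGE_FUNCS = {
    "data": _stage_data,
    "gradient": _stage_gradient,
    "filter": _stage_filter,
    "rarefy": _stage_rarefy,
    "diversity": _stage_diversity,
    "core": _stage_core,
    "network": _stage_network,
    "activity": _stage_activity,
}
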