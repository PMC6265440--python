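"""Core-microbiota determination, Venn partitioning, and phylum
specificity ratios.

The core microbiota of a sample group is the set of OTUs present (count
≥ 1, normally after rarefaction) in at least a given fraction of the
group's samples — 100% by default, swept from 50% to 100% in 5% steps to
show how the core shrinks with stricter ubiquity. Cores from several
groups are compared as a Venn partition (every non-empty membership
region counted). Phylum specificity expresses how over- or
under-represented a phylum is in one plant relative to the cross-plant
mean, reported as a ratio and its log.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .otu import OtuTable, SampleGroup, aggregate_taxonomy

logger = logging.getLogger(__name__)

_EPS = 1e-9  # guards float threshold comparisons like 3/4 vs 0.75

DEFAULT_SWEEP = tuple(round(0.50 + 0.05 * i, 2) for i in range(11))  # 0.50 … 1.00


@dataclass
class CorePartition:
    """Venn partition of per-group OTU sets.

    ``region_counts`` maps a frozenset of group names (the groups an OTU
    belongs to) to the number of OTUs exactly in those groups; regions
    are disjoint and sum to the union size.
    """

    group_sets: dict[str, frozenset[str]]
    region_counts: dict[frozenset[str], int]
    ubiquity_threshold: float = 1.0

    @property
    def union_size(self) -> int:
        out: set[str] = set()
        for s in self.group_sets.values():
            out |= s
        return len(out)

    def shared_by_all(self) -> int:
        return self.region_counts.get(frozenset(self.group_sets), 0)

    def unique_to(self, name: str) -> int:
        return self.region_counts.get(frozenset({name}), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"region": "&".join(sorted(k)), "n_groups": len(k), "count": v}
            for k, v in sorted(
                self.region_counts.items(), key=lambda kv: (len(kv[0]), sorted(kv[0]))
            )
        ]
        return pd.DataFrame(rows, columns=["region", "n_groups", "count"])


def core_otus(
    table: OtuTable, samples: SampleGroup, ubiquity: float = 1.0
) -> frozenset[str]:
    """OTUs present in at least ``ubiquity`` of the group's samples.

    Presence means count ≥ 1; the threshold is inclusive, so an OTU
    present in exactly ``ubiquity × n`` samples belongs to the core.
    """
    ids = [s for s in table.sample_ids if s in samples.sample_ids]
    if not ids:
        raise ValueError(f"group {samples.name!r} has no samples in the table")
    present = (table.counts.loc[ids] > 0).sum(axis=0)
    need = ubiquity * len(ids) - _EPS
    return frozenset(present.index[present >= need])


def ubiquity_sweep(
    table: OtuTable,
    samples: SampleGroup,
    thresholds: Sequence[float] = DEFAULT_SWEEP,
) -> list[tuple[float, int]]:
    """Core size as a function of the ubiquity threshold (non-increasing)."""
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    if any(t < 0 or t > 1 for t in thresholds):
        raise ValueError("thresholds must lie in [0, 1]")
    return [(t, len(core_otus(table, samples, ubiquity=t))) for t in thresholds]


def venn_partition(
    sets: Mapping[str, frozenset[str] | set[str]],
    ubiquity_threshold: float = 1.0,
) -> CorePartition:
    """Count OTUs in every membership region of 2–6 named sets."""
    if not 2 <= len(sets) <= 6:
        raise ValueError(f"Venn partition supports 2-6 sets, got {len(sets)}")
    group_sets = {name: frozenset(s) for name, s in sets.items()}
    membership: dict[str, frozenset[str]] = {}
    for name, s in group_sets.items():
        for otu in s:
            membership[otu] = membership.get(otu, frozenset()) | {name}
    region_counts: dict[frozenset[str], int] = {}
    for region in membership.values():
        region_counts[region] = region_counts.get(region, 0) + 1
    return CorePartition(
        group_sets=group_sets,
        region_counts=region_counts,
        ubiquity_threshold=ubiquity_threshold,
    )


def unique_fraction_percent(unique_count: int, total_count: int) -> int:
    """Percentage of a group's OTUs that are unique to it, as an integer.

    ``100 × unique / total`` rounded half-up (so 0.5 rounds to 1).
    """
    if total_count <= 0:
        raise ValueError("total_count must be > 0")
    if not 0 <= unique_count <= total_count:
        raise ValueError("unique_count must lie in [0, total_count]")
    return int(math.floor(100 * unique_count / total_count + 0.5))


@dataclass
class SpecificityProfile:
    """Per-phylum, per-plant abundance ratios against the cross-plant mean.

    ``ratios``: phyla × plants, each row averaging to 1 by construction.
    ``log_ratios``: elementwise log of the ratios; entries where the
    ratio is 0 are NaN and flagged in ``undefined_log``.
    """

    ratios: pd.DataFrame
    log_ratios: pd.DataFrame
    undefined_log: pd.DataFrame  # boolean mask, True where log is undefined
    log_base: float = 10.0


def phylum_specificity(
    table: OtuTable,
    compartment: str,
    rank: str = "phylum",
    log_base: float = 10.0,
    use_otu_counts: bool = False,
) -> SpecificityProfile:
    """Plant-specificity ratios of taxa within one compartment.

    For each taxon at ``rank``, computes its relative abundance in every
    plant's samples of the compartment, divides by the mean over plants,
    and reports the ratio and its log (base 10 by default; the base only
    shifts the log scale). ``use_otu_counts=True`` replaces relative
    abundance with the number of distinct OTUs of the taxon, an
    alternative reading of "abundance in each phylum". Taxa absent from
    every plant are dropped with a warning; a zero ratio has an undefined
    log (no pseudocount is applied).
    """
    ids = table.samples_where(compartment=compartment)
    sub = table.subset_samples(ids)
    plants = sorted(sub.sample_meta["species"].unique())
    if len(plants) < 2:
        raise ValueError("phylum specificity needs >= 2 plants in the compartment")
    per_plant = {}
    for plant in plants:
        block = sub.subset_samples(sub.samples_where(species=plant))
        taxa_counts = aggregate_taxonomy(block, rank).sum(axis=0)
        if use_otu_counts:
            labels = block.rank_labels(rank)
            observed = block.counts.sum(axis=0) > 0
            per_plant[plant] = labels[observed].value_counts().astype(float)
        else:
            total = taxa_counts.sum()
            per_plant[plant] = taxa_counts / total if total > 0 else taxa_counts
    abundance = pd.DataFrame(per_plant).fillna(0.0)  # taxa × plants
    means = abundance.mean(axis=1)
    absent = means[means == 0].index
    if len(absent):
        logger.warning("dropping %d taxa absent from every plant", len(absent))
        abundance = abundance.drop(index=absent)
        means = means.drop(index=absent)
    ratios = abundance.div(means, axis=0)
    undefined = ratios == 0
    with np.errstate(divide="ignore"):
        log_ratios = np.log(ratios) / np.log(log_base)
    log_ratios = log_ratios.where(~undefined)
    return SpecificityProfile(
        ratios=ratios,
        log_ratios=log_ratios,
        undefined_log=undefined,
        log_base=log_base,
    )
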