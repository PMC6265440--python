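"""Sample × OTU count table with taxonomy and sample metadata.

The table is the central container of the pipeline: non-negative integer
counts indexed by (sample, OTU), a semicolon-ranked lineage per OTU, and
per-sample metadata (plant species, nutrient-use strategy, compartment,
replicate). All filtering, rarefaction, normalization, and aggregation
rules operate on copies; nothing mutates in place, and any sample or OTU
that an operation drops is reported through the module logger.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyInputError, GroupingError

logger = logging.getLogger(__name__)

#: Lineage ranks recognised in taxonomy strings, outermost first.
RANKS = ("domain", "phylum", "class", "order", "family", "genus")

UNCLASSIFIED = "unclassified"

STRATEGIES = ("exploitative", "conservative", "none")
COMPARTMENTS = ("light", "heavy", "root", "bulk")


@dataclass
class SampleGroup:
    """A named, non-empty set of sample ids."""

    name: str
    sample_ids: frozenset[str]

    def __post_init__(self) -> None:
        self.sample_ids = frozenset(self.sample_ids)
        if not self.sample_ids:
            raise ValueError(f"sample group {self.name!r} is empty")


@dataclass
class OtuTable:
    """Counts (samples in rows, OTUs in columns) + taxonomy + metadata.

    Parameters
    ----------
    counts
        DataFrame of non-negative counts, index = sample ids,
        columns = OTU ids. Stored as int64 when integral.
    taxonomy
        Series mapping otu_id -> semicolon-ranked lineage string
        (``domain;phylum;class;order;family;genus``, any suffix may be
        missing). OTUs absent from the mapping are filled with
        ``unclassified``.
    sample_meta
        DataFrame indexed by sample id with columns ``species``,
        ``strategy`` (exploitative/conservative/none), ``compartment``
        (light/heavy/root/bulk) and ``replicate``.
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    sample_meta: pd.DataFrame

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        self.taxonomy = self.taxonomy.reindex(self.counts.columns).fillna(UNCLASSIFIED)
        missing = set(self.counts.index) - set(self.sample_meta.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)}")
        self.sample_meta = self.sample_meta.loc[self.counts.index]

    # -- basic views ---------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_samples(self) -> int:
        return self.counts.shape[0]

    @property
    def n_otus(self) -> int:
        return self.counts.shape[1]

    def rank_labels(self, rank: str) -> pd.Series:
        """Per-OTU label at a lineage rank; missing levels -> unclassified."""
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        pos = RANKS.index(rank)

        def _level(lineage: str) -> str:
            parts = [p.strip() for p in str(lineage).split(";")]
            if pos < len(parts) and parts[pos]:
                return parts[pos]
            return UNCLASSIFIED

        return self.taxonomy.map(_level)

    def subset_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        ids = [s for s in self.sample_ids if s in set(sample_ids)]
        return OtuTable(
            counts=self.counts.loc[ids].copy(),
            taxonomy=self.taxonomy.copy(),
            sample_meta=self.sample_meta.loc[ids].copy(),
        )

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        ids = [o for o in self.otu_ids if o in set(otu_ids)]
        return OtuTable(
            counts=self.counts[ids].copy(),
            taxonomy=self.taxonomy.loc[ids].copy(),
            sample_meta=self.sample_meta.copy(),
        )

    def samples_where(self, **conditions: object) -> list[str]:
        """Sample ids whose metadata match all keyword conditions.

        A condition value may be a scalar or a collection of accepted
        values, e.g. ``samples_where(compartment={"light", "heavy"})``.
        """
        mask = pd.Series(True, index=self.sample_meta.index)
        for col, want in conditions.items():
            if isinstance(want, (set, frozenset, list, tuple)):
                mask &= self.sample_meta[col].isin(list(want))
            else:
                mask &= self.sample_meta[col] == want
        return list(self.sample_meta.index[mask])


# ---------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------

def filter_by_relative_abundance(
    table: OtuTable,
    min_fraction: float = 5e-5,
    per_sample: bool = False,
) -> OtuTable:
    """Drop rare OTUs below a relative-abundance threshold.

    An OTU is retained iff its total count across all samples strictly
    exceeds ``min_fraction`` × grand total (default 0.005%, the
    conventional post-clustering rare-OTU filter). With
    ``per_sample=True`` an OTU is retained if it exceeds the threshold
    within at least one sample.
    """
    grand_total = int(table.counts.to_numpy().sum())
    if grand_total == 0:
        raise EmptyInputError("cannot abundance-filter a table with zero total count")
    if per_sample:
        sample_totals = table.counts.sum(axis=1)
        frac = table.counts.div(sample_totals.replace(0, np.nan), axis=0)
        keep = (frac > min_fraction).any(axis=0)
    else:
        keep = table.counts.sum(axis=0) > min_fraction * grand_total
    dropped = int((~keep).sum())
    if dropped:
        logger.info("abundance filter removed %d of %d OTUs", dropped, table.n_otus)
    return table.subset_otus(list(table.counts.columns[keep]))


def prevalence_filter(table: OtuTable, min_prevalence: float = 0.25) -> OtuTable:
    """Keep OTUs detected in strictly more than ``min_prevalence`` of samples.

    Prevalence counts samples with a nonzero count. The default (> 25%)
    is the selection applied before network inference.
    """
    if table.n_samples == 0:
        raise EmptyInputError("cannot prevalence-filter an empty table")
    present = (table.counts > 0).sum(axis=0)
    keep = present > min_prevalence * table.n_samples
    dropped = int((~keep).sum())
    if dropped:
        logger.info("prevalence filter removed %d of %d OTUs", dropped, table.n_otus)
    return table.subset_otus(list(table.counts.columns[keep]))


# ---------------------------------------------------------------------
# Rarefaction
# ---------------------------------------------------------------------

def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` total reads are dropped (with a
    logged warning), not padded. Reproducible for a fixed seed.
    """
    if depth <= 0:
        raise ValueError(f"rarefaction depth must be >= 1, got {depth}")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    kept_rows: list[str] = []
    new_rows: list[np.ndarray] = []
    for sample_id in table.sample_ids:
        total = int(totals[sample_id])
        if total < depth:
            logger.warning(
                "sample %s has %d reads < depth %d; dropped", sample_id, total, depth
            )
            continue
        vec = table.counts.loc[sample_id].to_numpy(dtype=np.int64)
        if total == depth:
            new = vec
        else:
            new = rng.multivariate_hypergeometric(vec, depth)
        kept_rows.append(sample_id)
        new_rows.append(np.asarray(new, dtype=np.int64))
    if not kept_rows:
        raise EmptyInputError(f"no sample has >= {depth} reads")
    counts = pd.DataFrame(
        np.vstack(new_rows), index=kept_rows, columns=table.counts.columns
    )
    return OtuTable(
        counts=counts,
        taxonomy=table.taxonomy.copy(),
        sample_meta=table.sample_meta.loc[kept_rows].copy(),
    )


def rarefaction_curve(
    table: OtuTable,
    sample_id: str,
    depths: Sequence[int],
    reps: int,
    seed: int,
) -> list[tuple[int, float]]:
    """Mean observed richness of one sample at increasing subsampling depths.

    For each depth, draws ``reps`` without-replacement subsamples and
    averages the number of OTUs observed. Depths must be ascending and
    not exceed the sample's total read count.
    """
    vec = table.counts.loc[sample_id].to_numpy(dtype=np.int64)
    total = int(vec.sum())
    if list(depths) != sorted(depths):
        raise ValueError("depths must be sorted ascending")
    if any(d > total for d in depths):
        raise ValueError(f"depth exceeds sample total {total}")
    rng = np.random.default_rng(seed)
    out: list[tuple[int, float]] = []
    for depth in depths:
        if depth == total:
            out.append((depth, float((vec > 0).sum())))
            continue
        draws = rng.multivariate_hypergeometric(vec, depth, size=reps)
        out.append((depth, float((draws > 0).sum(axis=1).mean())))
    return out


# ---------------------------------------------------------------------
# Normalization and aggregation
# ---------------------------------------------------------------------

def to_proportions(
    table: OtuTable, axis: Literal["per_sample", "per_otu"]
) -> pd.DataFrame:
    """Convert counts to proportions along samples or OTUs.

    ``per_sample``: each sample row sums to 1 (relative abundance).
    ``per_otu``: each OTU's across-sample repartition profile sums to 1,
    so an OTU's absolute abundance no longer matters — only where its
    reads fall. All-zero vectors along the chosen axis are dropped with a
    warning.
    """
    counts = table.counts.astype(float)
    if axis == "per_sample":
        totals = counts.sum(axis=1)
        empty = totals[totals == 0].index
        if len(empty):
            logger.warning("dropping %d all-zero samples", len(empty))
            counts = counts.drop(index=empty)
            totals = totals.drop(index=empty)
        return counts.div(totals, axis=0)
    if axis == "per_otu":
        totals = counts.sum(axis=0)
        empty = totals[totals == 0].index
        if len(empty):
            logger.warning("dropping %d all-zero OTUs", len(empty))
            counts = counts.drop(columns=empty)
            totals = totals.drop(index=empty)
        return counts.div(totals, axis=1)
    raise ValueError(f"axis must be 'per_sample' or 'per_otu', got {axis!r}")


def aggregate_replicates(
    table: OtuTable,
    groups: Sequence[SampleGroup],
    method: Literal["sum", "mean"] = "sum",
) -> OtuTable:
    """Collapse replicate samples into one pseudo-sample per group.

    Groups must be disjoint and reference existing samples. The default
    (sum) preserves the count nature of the table; mean is offered for
    sensitivity analysis.
    """
    seen: set[str] = set()
    for g in groups:
        unknown = g.sample_ids - set(table.sample_ids)
        if unknown:
            raise GroupingError(f"group {g.name!r} references unknown samples {sorted(unknown)}")
        overlap = g.sample_ids & seen
        if overlap:
            raise GroupingError(f"sample(s) {sorted(overlap)} appear in multiple groups")
        seen |= g.sample_ids
    rows = []
    meta_rows = []
    for g in groups:
        ids = [s for s in table.sample_ids if s in g.sample_ids]
        block = table.counts.loc[ids]
        rows.append(block.sum(axis=0) if method == "sum" else block.mean(axis=0))
        # representative metadata: shared values kept, conflicting ones blanked
        meta = table.sample_meta.loc[ids]
        rep = {
            col: (meta[col].iloc[0] if meta[col].nunique() == 1 else "")
            for col in meta.columns
        }
        meta_rows.append(rep)
    counts = pd.DataFrame(rows, index=[g.name for g in groups])
    sample_meta = pd.DataFrame(meta_rows, index=[g.name for g in groups])
    return OtuTable(counts=counts, taxonomy=table.taxonomy.copy(), sample_meta=sample_meta)


def regroup_triplicates(table: OtuTable) -> OtuTable:
    """Collapse replicates into one summed pseudo-sample per plant × compartment.

    This is the regrouping applied before co-occurrence inference, so the
    repartition profiles run over plants and fractions rather than
    individual replicate pots.
    """
    groups = [
        SampleGroup(f"{sp}_{comp}", frozenset(ids))
        for (sp, comp), ids in sorted(
            table.sample_meta.groupby(["species", "compartment"]).groups.items()
        )
    ]
    return aggregate_replicates(table, groups, method="sum")


def aggregate_taxonomy(table: OtuTable, rank: str) -> pd.DataFrame:
    """Sum counts over OTUs sharing a lineage label at ``rank``.

    Returns a samples × taxa DataFrame; OTUs without an assignment at the
    rank are pooled under ``unclassified``. Total reads are conserved.
    """
    labels = table.rank_labels(rank)
    return table.counts.T.groupby(labels).sum().T
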