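"""Count-table preprocessing: organelle and low-count filtering, genus-level
collapse, relative abundance, rarefaction, abundance filtering and the CLR
transform.

The canonical order, enforced by the pipeline orchestrator, is:
organelle filter -> low-count filter -> shallow-sample exclusion (rarefaction
depth) -> taxonomic collapse -> relative abundance -> abundance filter -> CLR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .tables_io import RANKS, UNASSIGNED, FeatureTable, TaxonomyMap

ORGANELLE_MARKERS = ("mitochondria", "chloroplast")


class RelativeAbundanceTable:
    """Real-valued table, samples x features, values in [0, 1].

    A *closed* table (the default) has rows summing to 1; tables produced by
    the abundance filter are open (rows sum to <1) because removed features'
    mass is deliberately not redistributed.
    """

    def __init__(self, data: pd.DataFrame, closed: bool = True):
        values = data.to_numpy(dtype=float)
        if values.size and ((values < 0).any() or (values > 1 + 1e-12).any()):
            raise ValueError("relative abundances must lie in [0, 1]")
        if closed and values.size:
            sums = values.sum(axis=1)
            bad = np.abs(sums - 1.0) > 1e-9
            if bad.any():
                raise ValueError(f"sample rows do not sum to 1: {list(data.index[bad])[:5]}")
        self.data = data.astype(float)
        self.closed = closed

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    def __repr__(self) -> str:
        kind = "closed" if self.closed else "open"
        return f"RelativeAbundanceTable({self.data.shape[0]} x {self.data.shape[1]}, {kind})"


class CLRTable:
    """Centered log-ratio transformed table; each sample row sums to 0."""

    def __init__(self, data: pd.DataFrame):
        values = data.to_numpy(dtype=float)
        if values.size:
            sums = values.sum(axis=1)
            if (np.abs(sums) > 1e-9 * max(1.0, np.abs(values).max())).any():
                raise ValueError("CLR rows must sum to 0")
        self.data = data.astype(float)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass(frozen=True)
class OrganelleReport:
    removed_features: list[str]
    removed_fraction: pd.Series  # per sample, fraction of sequences removed


def is_organelle(lineage) -> bool:
    return any(m in label.lower() for label in lineage for m in ORGANELLE_MARKERS)


def filter_organelles(
    table: FeatureTable, tax: TaxonomyMap, keep_unknown: bool = False
) -> tuple[FeatureTable, OrganelleReport]:
    """Drop features of mitochondrial/chloroplast origin; report per-sample loss."""
    missing = [f for f in table.feature_ids if f not in tax]
    if missing and not keep_unknown:
        raise ValueError(f"feature(s) without lineage: {missing[:5]}")
    organelle = [
        f for f in table.feature_ids if f in tax and is_organelle(tax.lineage(f))
    ]
    totals = table.sample_totals().astype(float)
    removed = table.data[organelle].sum(axis=1).astype(float)
    with np.errstate(invalid="ignore"):
        fraction = (removed / totals).fillna(0.0)
    kept = table.data.drop(columns=organelle)
    emptied = kept.index[(kept.sum(axis=1) == 0) & (totals > 0)].tolist()
    if emptied:
        raise ValueError(f"sample(s) emptied by organelle removal: {emptied}")
    return FeatureTable(kept), OrganelleReport(organelle, fraction)


def filter_low_count(
    table: FeatureTable, min_total: int = 10, min_samples: int = 2
) -> FeatureTable:
    """Drop features with grand total < min_total or present in < min_samples samples."""
    if min_total < 0 or min_samples < 0:
        raise ValueError("thresholds must be non-negative")
    totals = table.feature_totals()
    prevalence = (table.data > 0).sum(axis=0)
    keep = (totals >= min_total) & (prevalence >= min_samples)
    return FeatureTable(table.data.loc[:, keep])


def collapse_label(lineage, level: int) -> str:
    """Join the lineage prefix through `level`; uniqueness key for collapsing."""
    return ";".join(lineage[:level])


def display_name(label: str) -> str:
    """Deepest assigned rank of a collapsed label (family name when genus is unassigned)."""
    parts = [p for p in label.split(";") if p != UNASSIGNED]
    return parts[-1] if parts else UNASSIGNED


def collapse_taxonomy(
    table: FeatureTable, tax: TaxonomyMap, level: int = 6
) -> FeatureTable:
    """Sum features sharing the same lineage prefix through `level` (L6 = genus).

    Labels keep the full prefix so same-named genera in different families stay
    distinct; `display_name` recovers the deepest assigned rank for reporting.
    """
    if not 1 <= level <= len(RANKS):
        raise ValueError(f"level must be in 1..{len(RANKS)}")
    labels = [collapse_label(tax.lineage(f), level) for f in table.feature_ids]
    collapsed = table.data.T.groupby(pd.Index(labels, name="taxon"), sort=True).sum().T
    return FeatureTable(collapsed)


def to_relative(table: FeatureTable) -> RelativeAbundanceTable:
    totals = table.sample_totals()
    empty = totals.index[totals == 0].tolist()
    if empty:
        raise ValueError(f"zero-total sample(s): {empty}")
    return RelativeAbundanceTable(table.data.div(totals, axis=0))


def rarefy(
    table: FeatureTable, depth: int, seed: int | np.random.Generator
) -> tuple[FeatureTable, list[str]]:
    """Subsample each sample to exactly `depth` counts without replacement.

    Samples shallower than `depth` are excluded and listed. Sampling is
    multivariate hypergeometric, deterministic for a given seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    totals = table.sample_totals()
    excluded = totals.index[totals < depth].tolist()
    retained = totals.index[totals >= depth]
    if len(retained) == 0:
        raise ValueError(f"no samples retained at depth {depth}")
    rows = [
        rng.multivariate_hypergeometric(table.data.loc[s].to_numpy(), depth)
        for s in retained
    ]
    rarefied = pd.DataFrame(rows, index=retained, columns=table.data.columns)
    return FeatureTable(rarefied), excluded


def exclude_shallow(table: FeatureTable, depth: int) -> tuple[FeatureTable, list[str]]:
    """Drop samples below the rarefaction depth without subsampling the rest."""
    totals = table.sample_totals()
    excluded = totals.index[totals < depth].tolist()
    kept = table.data.loc[totals >= depth]
    if kept.shape[0] == 0:
        raise ValueError(f"no samples retained at depth {depth}")
    return FeatureTable(kept), excluded


def abundance_filter(
    relab: RelativeAbundanceTable,
    mean_thresh: float = 0.01,
    max_thresh: float = 0.05,
) -> RelativeAbundanceTable:
    """Keep features whose mean relative abundance exceeds `mean_thresh` or whose
    maximum in any sample exceeds `max_thresh` (strict comparisons). Remaining
    values are NOT renormalized, so the output is an open composition."""
    for t in (mean_thresh, max_thresh):
        if not 0 <= t <= 1:
            raise ValueError("thresholds must lie in [0, 1]")
    means = relab.data.mean(axis=0)
    maxes = relab.data.max(axis=0)
    keep = (means > mean_thresh) | (maxes > max_thresh)
    kept = relab.data.loc[:, keep]
    closed = relab.closed and bool(keep.all())
    return RelativeAbundanceTable(kept, closed=closed)


def clr_transform(
    relab: RelativeAbundanceTable, pseudocount: float | None = None
) -> CLRTable:
    """Centered log-ratio transform.

    Zeros make log-ratios undefined; when the table contains any, a pseudocount
    delta (default: half the smallest nonzero relative abundance in the whole
    table) is added to every cell and rows are re-closed before taking logs.
    Tables without zeros are transformed as-is.
    """
    if relab.data.shape[1] < 2:
        raise ValueError("CLR is undefined for a single-feature table")
    values = relab.data.to_numpy(dtype=float)
    if (values == 0).any():
        if pseudocount is None:
            nonzero = values[values > 0]
            if nonzero.size == 0:
                raise ValueError("table is all zeros")
            pseudocount = float(nonzero.min()) / 2.0
        values = values + pseudocount
    values = values / values.sum(axis=1, keepdims=True)
    logs = np.log(values)
    clr = logs - logs.mean(axis=1, keepdims=True)
    return CLRTable(pd.DataFrame(clr, index=relab.data.index, columns=relab.data.columns))
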