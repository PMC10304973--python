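"""Three-criterion core-microbiota definition, Venn partitioning, and
occurrence/abundance summaries.

A taxon belongs to the core when it simultaneously passes:

* F1 (mean):     arithmetic mean relative abundance across all samples > 1%
* F2 (mean-max): mean > 1% OR maximum in at least one sample > 5%
* F3 (occurrence): present (> 0) in at least one sample of EVERY household

F1's condition implies F2's disjunction whenever F1's threshold is at least
F2's mean threshold, so the F1-only and F1&F3-without-F2 Venn regions are
structurally empty; this is asserted on every evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._utils import display_percent
from .preprocess import RelativeAbundanceTable
from .tables_io import FeatureTable, SampleMetadata

VENN_REGIONS = ("F1", "F2", "F3", "F1&F2", "F1&F3", "F2&F3", "F1&F2&F3")


@dataclass(frozen=True)
class CoreCriteria:
    """Thresholds of the three criteria; defaults are the 1%/5% convention."""

    f1_mean_thresh: float = 0.01
    f2_mean_thresh: float = 0.01
    f2_max_thresh: float = 0.05
    f3_group: str = "household"

    def __post_init__(self):
        for t in (self.f1_mean_thresh, self.f2_mean_thresh, self.f2_max_thresh):
            if not 0 <= t <= 1:
                raise ValueError("criteria thresholds must lie in [0, 1]")


@dataclass(frozen=True)
class CoreResult:
    table: pd.DataFrame = field(repr=False)  # per taxon: stats, flags, venn_region
    criteria: CoreCriteria = field(default_factory=CoreCriteria)

    @property
    def core_taxa(self) -> list[str]:
        flags = self.table
        return list(flags.index[flags["passes_F1"] & flags["passes_F2"] & flags["passes_F3"]])

    def passing(self, criterion: str) -> list[str]:
        return list(self.table.index[self.table[f"passes_{criterion}"]])


def _venn_label(f1: bool, f2: bool, f3: bool) -> str:
    parts = [name for name, flag in zip(("F1", "F2", "F3"), (f1, f2, f3)) if flag]
    return "&".join(parts)


def evaluate_criteria(
    relab: RelativeAbundanceTable,
    meta: SampleMetadata,
    criteria: CoreCriteria = CoreCriteria(),
) -> CoreResult:
    """Evaluate F1/F2/F3 per taxon on a relative-abundance table."""
    frame = meta.require_samples(relab.sample_ids)
    groups = frame[criteria.f3_group]
    counts_per_group = groups.value_counts()
    if (counts_per_group == 0).any():
        raise ValueError("grouping level with zero samples")

    values = relab.data
    means = values.mean(axis=0)
    maxes = values.max(axis=0)
    present = values > 0
    pct_samples = 100.0 * present.sum(axis=0) / values.shape[0]

    # F3: for every household, present in >= 1 of its samples
    present_by_group = present.groupby(groups, observed=True).any()
    f3 = present_by_group.all(axis=0)

    f1 = means > criteria.f1_mean_thresh
    f2 = (means > criteria.f2_mean_thresh) | (maxes > criteria.f2_max_thresh)

    if criteria.f1_mean_thresh >= criteria.f2_mean_thresh and not (f1 <= f2).all():
        raise AssertionError("invariant violated: F1 must imply F2")

    table = pd.DataFrame(
        {
            "mean_relab": means,
            "max_relab": maxes,
            "pct_samples_present": pct_samples,
            "passes_F1": f1,
            "passes_F2": f2,
            "passes_F3": f3,
        }
    )
    table["venn_region"] = [
        _venn_label(a, b, c)
        for a, b, c in zip(table["passes_F1"], table["passes_F2"], table["passes_F3"])
    ]
    return CoreResult(table, criteria)


def venn_partition(result: CoreResult) -> dict[str, int]:
    """Counts of taxa in each exclusive region of the F1/F2/F3 Venn diagram."""
    counts = {region: 0 for region in VENN_REGIONS}
    labels = result.table.loc[result.table["venn_region"] != "", "venn_region"]
    for label in labels:
        counts[label] += 1
    crit = result.criteria
    if crit.f1_mean_thresh >= crit.f2_mean_thresh:
        assert counts["F1"] == 0 and counts["F1&F3"] == 0, (
            "structurally empty Venn regions are populated"
        )
    return counts


def core_summary(result: CoreResult) -> pd.DataFrame:
    """Core taxa with mean relative abundance (%) and % of samples present,
    sorted by descending mean abundance."""
    core = result.table.loc[result.core_taxa, ["mean_relab", "pct_samples_present"]].copy()
    core["mean_relab_pct"] = 100.0 * core.pop("mean_relab")
    core = core[["mean_relab_pct", "pct_samples_present"]]
    return core.sort_values("mean_relab_pct", ascending=False, kind="stable")


@dataclass(frozen=True)
class OccurrenceSummary:
    table: pd.DataFrame = field(repr=False)
    per_country: pd.DataFrame = field(repr=False)  # MultiIndex (taxon, country)
    n_samples: int = 0
    n_households: int = 0

    def display(self) -> pd.DataFrame:
        """Printed-table view: two-significant-figure half-up rounding and
        per-country households/samples occurrence pairs."""
        rows = {}
        for taxon in self.table.index:
            row = self.table.loc[taxon]
            entry = {
                "mean_relab_pct": display_percent(row["mean_relab_pct"]),
                "max_relab_pct": display_percent(row["max_relab_pct"]),
                "pct_samples": display_percent(row["pct_samples"]),
                "pct_households": display_percent(row["pct_households"]),
            }
            for country, sub in self.per_country.loc[taxon].iterrows():
                nh, ns = int(sub["n_households_present"]), int(sub["n_samples_present"])
                entry[country] = f"{nh}/{ns}" if ns else "0"
            rows[taxon] = entry
        return pd.DataFrame.from_dict(rows, orient="index")


def taxon_occurrence_summary(
    table: FeatureTable | RelativeAbundanceTable,
    meta: SampleMetadata,
    taxa: list[str] | None = None,
) -> OccurrenceSummary:
    """Occurrence/abundance accounting per taxon, overall and per country.

    Presence is any value > 0 (no detection floor). Relative abundances are
    computed from counts when a count table is given.
    """
    if isinstance(table, FeatureTable):
        from .preprocess import to_relative

        relab = to_relative(table)
    else:
        relab = table
    if taxa is None:
        taxa = relab.feature_ids
    unknown = [t for t in taxa if t not in relab.data.columns]
    if unknown:
        raise KeyError(f"unknown taxa: {unknown}")
    frame = meta.require_samples(relab.sample_ids)
    values = relab.data[taxa]
    present = values > 0

    n_samples = values.shape[0]
    n_households = frame["household"].nunique()

    overall = pd.DataFrame(
        {
            "mean_relab_pct": 100.0 * values.mean(axis=0),
            "max_relab_pct": 100.0 * values.max(axis=0),
            "pct_samples": 100.0 * present.sum(axis=0) / n_samples,
        }
    )
    hh_present = present.groupby(frame["household"], observed=True).any()
    overall["pct_households"] = 100.0 * hh_present.sum(axis=0) / n_households

    country_of_household = frame.groupby("household", observed=True)["country"].first()
    records = []
    for country in sorted(frame["country"].unique()):
        in_country = frame["country"] == country
        hh_in_country = country_of_household.index[country_of_household == country]
        for taxon in taxa:
            records.append(
                {
                    "taxon": taxon,
                    "country": country,
                    "n_households_present": int(
                        hh_present.loc[hh_in_country, taxon].sum()
                    ),
                    "n_samples_present": int(present.loc[in_country, taxon].sum()),
                    "n_households_total": int(len(hh_in_country)),
                    "n_samples_total": int(in_country.sum()),
                }
            )
    per_country = pd.DataFrame.from_records(records).set_index(["taxon", "country"])

    # row consistency: country presences must add up to the global presences
    sums = per_country.groupby(level="taxon").sum()
    for taxon in taxa:
        assert sums.loc[taxon, "n_samples_present"] == int(present[taxon].sum())
        assert sums.loc[taxon, "n_households_present"] == int(hh_present[taxon].sum())

    return OccurrenceSummary(overall, per_country, n_samples, n_households)
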