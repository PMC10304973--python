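"""Data model and TSV/Newick IO for household-microbiome survey objects.

The pipeline operates on four aligned objects: an sOTU count table
(samples x features), a ranked taxonomy per feature, per-sample metadata
(country, household, sample type), and a rooted phylogeny whose tips are
feature identifiers. Everything downstream (filtering, diversity, core
criteria) consumes these containers, so their invariants are enforced here
once, at construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

from ._utils import round_half_up

RANKS = ("domain", "phylum", "class", "order", "family", "genus", "species")
UNASSIGNED = "unassigned"

SAMPLE_TYPES = (
    "sponge",
    "cloth",
    "sink",
    "cutting_board",
    "tap_handle",
    "countertop",
    "handles",
)
CLEANING_UTENSILS = frozenset({"sponge", "cloth"})


def sample_category(sample_type: str) -> str:
    """cleaning_utensil for sponges and cloths, surface for everything else."""
    if sample_type not in SAMPLE_TYPES:
        raise ValueError(f"unknown sample type: {sample_type!r}")
    return "cleaning_utensil" if sample_type in CLEANING_UTENSILS else "surface"


class FeatureTable:
    """Integer count matrix, samples x features, with unique ordered identifiers."""

    def __init__(self, data: pd.DataFrame):
        if data.index.has_duplicates:
            dups = data.index[data.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample identifiers: {dups}")
        if data.columns.has_duplicates:
            dups = data.columns[data.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature identifiers: {dups}")
        values = data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            if not np.allclose(values, np.round(values)):
                raise ValueError("counts must be integers")
            values = np.round(values).astype(np.int64)
        if values.size and (values < 0).any():
            raise ValueError("counts must be non-negative")
        self.data = pd.DataFrame(
            values.astype(np.int64, copy=False), index=data.index, columns=data.columns
        )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape

    def sample_totals(self) -> pd.Series:
        return self.data.sum(axis=1)

    def feature_totals(self) -> pd.Series:
        return self.data.sum(axis=0)

    def total(self) -> int:
        return int(self.data.to_numpy().sum())

    def __eq__(self, other) -> bool:
        return isinstance(other, FeatureTable) and self.data.equals(other.data)

    def __repr__(self) -> str:
        return f"FeatureTable({self.shape[0]} samples x {self.shape[1]} features)"


class TaxonomyMap:
    """feature id -> canonical 7-rank lineage (absent ranks explicit 'unassigned')."""

    def __init__(self, lineages: pd.DataFrame, confidence: pd.Series | None = None):
        if list(lineages.columns) != list(RANKS):
            raise ValueError(f"lineage frame must have columns {RANKS}")
        if lineages.index.has_duplicates:
            dups = lineages.index[lineages.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate feature identifiers in taxonomy: {dups}")
        self.lineages = lineages.astype(str)
        self.confidence = confidence

    @classmethod
    def from_strings(cls, mapping: dict[str, str], separator: str = ";") -> "TaxonomyMap":
        rows = {fid: parse_lineage(s, separator) for fid, s in mapping.items()}
        frame = pd.DataFrame.from_dict(rows, orient="index", columns=list(RANKS))
        return cls(frame)

    def lineage(self, feature_id: str) -> tuple[str, ...]:
        try:
            return tuple(self.lineages.loc[feature_id])
        except KeyError:
            raise KeyError(f"feature id not in taxonomy: {feature_id!r}") from None

    def __contains__(self, feature_id: str) -> bool:
        return feature_id in self.lineages.index

    def __len__(self) -> int:
        return len(self.lineages)


@dataclass(frozen=True)
class SampleMetadata:
    """Per-sample design variables; `category` is derived from sample_type."""

    frame: pd.DataFrame = field(repr=False)

    REQUIRED = ("country", "household", "sample_type")

    def __post_init__(self):
        frame = self.frame
        missing = [c for c in self.REQUIRED if c not in frame.columns]
        if missing:
            raise ValueError(f"metadata missing required column(s): {missing}")
        if frame.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in metadata")
        bad = sorted(set(frame["sample_type"]) - set(SAMPLE_TYPES))
        if bad:
            raise ValueError(f"unknown sample type(s): {bad}")
        # a household belongs to exactly one country
        span = frame.groupby("household", observed=True)["country"].nunique()
        crossing = span[span > 1].index.tolist()
        if crossing:
            raise ValueError(f"household(s) span multiple countries: {crossing}")
        frame = frame.copy()
        frame["category"] = frame["sample_type"].map(sample_category)
        object.__setattr__(self, "frame", frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def require_samples(self, sample_ids) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise KeyError(f"samples without metadata: {missing[:5]}")
        return self.frame.loc[list(sample_ids)]

    def households(self) -> list[str]:
        return sorted(self.frame["household"].unique())


@dataclass(frozen=True)
class DatasetSummary:
    n_samples: int
    n_features: int
    total_sequences: int
    mean_per_sample: float
    min_per_sample: int
    max_per_sample: int
    mean_per_feature: float

    def rounded(self) -> dict:
        """Printed-report view: means half-up rounded to integers."""
        return {
            "n_samples": self.n_samples,
            "n_features": self.n_features,
            "total_sequences": self.total_sequences,
            "mean_per_sample": round_half_up(self.mean_per_sample),
            "min_per_sample": self.min_per_sample,
            "max_per_sample": self.max_per_sample,
            "mean_per_feature": round_half_up(self.mean_per_feature),
        }


def parse_lineage(lineage: str, separator: str = ";") -> tuple[str, ...]:
    """Split a SILVA-style lineage string into the canonical 7 ranks.

    Rank prefixes ("d__", "p__", ...) are stripped; empty or placeholder
    labels and missing deeper ranks become explicit 'unassigned'.
    """
    labels = []
    for part in str(lineage).split(separator):
        label = part.strip()
        if len(label) >= 3 and label[1:3] == "__":
            label = label[3:].strip()
        if label == "" or label.lower() in {"unassigned", "unclassified", "na"}:
            label = UNASSIGNED
        labels.append(label)
    labels = labels[: len(RANKS)]
    labels += [UNASSIGNED] * (len(RANKS) - len(labels))
    # a lineage like "d__Bacteria;__;__" keeps the explicit placeholders
    return tuple(labels)


# ---------------------------------------------------------------------------
# readers / writers (UTF-8, tab-delimited, LF)
# ---------------------------------------------------------------------------


def read_feature_table(path, orientation: str = "features") -> FeatureTable:
    """Read a TSV count table.

    orientation='features' expects features as rows (QIIME-style export, with a
    tolerated '#OTU ID' header); orientation='samples' expects samples as rows.
    The returned table is always samples x features.
    """
    if orientation not in {"features", "samples"}:
        raise ValueError("orientation must be 'features' or 'samples'")
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    # QIIME exports sometimes start with "# Constructed from biom file"
    while lines and lines[0].startswith("#") and "\t" not in lines[0]:
        lines.pop(0)
    if not lines:
        raise ValueError("no samples: empty table file")
    header = lines[0].split("\t")
    body = lines[1:]
    if not body:
        raise ValueError("no samples: table has a header but no data rows")
    row_ids, rows = [], []
    for line in body:
        cells = line.split("\t")
        row_ids.append(cells[0])
        parsed = []
        for col_name, cell in zip(header[1:], cells[1:]):
            try:
                value = int(cell)
                if value < 0:
                    raise ValueError
            except ValueError:
                raise ValueError(
                    f"malformed count at row {cells[0]!r}, column {col_name!r}: {cell!r}"
                ) from None
            parsed.append(value)
        if len(parsed) != len(header) - 1:
            raise ValueError(f"row {cells[0]!r} has {len(parsed)} cells, expected {len(header) - 1}")
        rows.append(parsed)
    frame = pd.DataFrame(rows, index=row_ids, columns=header[1:], dtype=np.int64)
    if orientation == "features":
        frame = frame.T
    return FeatureTable(frame)


def write_feature_table(table: FeatureTable, path, orientation: str = "features") -> None:
    if orientation not in {"features", "samples"}:
        raise ValueError("orientation must be 'features' or 'samples'")
    frame = table.data.T if orientation == "features" else table.data
    label = "#OTU ID" if orientation == "features" else "#SampleID"
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        frame.to_csv(fh, sep="\t", index_label=label, lineterminator="\n")


def read_taxonomy(
    path,
    feature_col: str = "Feature ID",
    lineage_col: str = "Taxon",
    confidence_col: str | None = "Confidence",
    separator: str = ";",
) -> TaxonomyMap:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    for col in (feature_col, lineage_col):
        if col not in frame.columns:
            raise ValueError(f"taxonomy file lacks column {col!r}")
    if frame[feature_col].duplicated().any():
        dups = frame[feature_col][frame[feature_col].duplicated()].tolist()
        raise ValueError(f"duplicate feature id rows in taxonomy: {dups}")
    lineages = pd.DataFrame(
        [parse_lineage(s, separator) for s in frame[lineage_col]],
        index=frame[feature_col],
        columns=list(RANKS),
    )
    confidence = None
    if confidence_col and confidence_col in frame.columns:
        confidence = pd.to_numeric(frame[confidence_col], errors="coerce")
        confidence.index = frame[feature_col]
    return TaxonomyMap(lineages, confidence)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    strings = tax.lineages.apply(lambda row: ";".join(row), axis=1)
    frame = pd.DataFrame({"Feature ID": strings.index, "Taxon": strings.values})
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        frame.to_csv(fh, sep="\t", index=False, lineterminator="\n")


def read_metadata(path) -> SampleMetadata:
    frame = pd.read_csv(path, sep="\t", dtype=str)
    id_col = frame.columns[0]
    frame = frame.set_index(id_col)
    return SampleMetadata(frame)


def write_metadata(meta: SampleMetadata, path) -> None:
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        meta.frame.drop(columns=["category"]).to_csv(
            fh, sep="\t", index_label="sample_id", lineterminator="\n"
        )


def read_tree(path, fill_missing_lengths: bool = False) -> TreeNode:
    """Read a rooted Newick tree and validate branch lengths and tip names."""
    tree = TreeNode.read(str(path), format="newick")
    return validate_tree(tree, fill_missing_lengths=fill_missing_lengths)


def validate_tree(tree: TreeNode, fill_missing_lengths: bool = False) -> TreeNode:
    names = [t.name for t in tree.tips()]
    if len(names) != len(set(names)):
        seen, dups = set(), set()
        for n in names:
            (dups if n in seen else seen).add(n)
        raise ValueError(f"tree tip names not unique: {sorted(dups)}")
    if tree.length is None:
        tree.length = 0.0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            if fill_missing_lengths:
                node.length = 0.0
            else:
                raise ValueError(f"node {node.name!r} lacks a branch length")
        if node.length < 0:
            raise ValueError(f"negative branch length at node {node.name!r}")
    return tree


def write_tree(tree: TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def check_tree_coverage(tree: TreeNode, table: FeatureTable) -> list[str]:
    """Warn about tree tips absent from the table (orphans) and return them."""
    tips = {t.name for t in tree.tips()}
    orphans = sorted(tips - set(table.feature_ids))
    if orphans:
        warnings.warn(f"tree tips absent from table: {orphans}", stacklevel=2)
    missing = sorted(set(table.feature_ids) - tips)
    if missing:
        raise ValueError(f"table features missing from tree: {missing[:5]}")
    return orphans


def dataset_summary(table: FeatureTable) -> DatasetSummary:
    """Sequencing-depth bookkeeping of a count table (unrounded means)."""
    if table.shape[0] == 0 or table.shape[1] == 0:
        raise ValueError("cannot summarize an empty table")
    totals = table.sample_totals()
    grand = table.total()
    return DatasetSummary(
        n_samples=table.shape[0],
        n_features=table.shape[1],
        total_sequences=grand,
        mean_per_sample=grand / table.shape[0],
        min_per_sample=int(totals.min()),
        max_per_sample=int(totals.max()),
        mean_per_feature=grand / table.shape[1],
    )


def read_distance_matrix(path):
    from skbio import DistanceMatrix

    frame = pd.read_csv(path, sep="\t", index_col=0)
    return DistanceMatrix(frame.to_numpy(), ids=list(frame.index))


def write_distance_matrix(dm, path) -> None:
    frame = pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        frame.to_csv(fh, sep="\t", lineterminator="\n")
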