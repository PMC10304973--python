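"""End-to-end orchestration with provenance capture.

Stage order is fixed: organelle filter -> low-count filter -> shallow-sample
exclusion at the rarefaction depth -> (rarefied table for diversity) ->
genus-level collapse -> relative abundance -> alpha/beta diversity ->
abundance filter -> CLR -> core criteria -> summaries -> group analyses.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from ._utils import content_hash, write_provenance
from .core_microbiota import (
    CoreCriteria,
    CoreResult,
    core_summary,
    evaluate_criteria,
    venn_partition,
)
from .preprocess import (
    abundance_filter,
    clr_transform,
    collapse_taxonomy,
    exclude_shallow,
    filter_low_count,
    filter_organelles,
    rarefy,
    to_relative,
)
from .tables_io import (
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    dataset_summary,
    read_feature_table,
    read_metadata,
    read_taxonomy,
    read_tree,
)


@dataclass
class PipelineConfig:
    """All tunable parameters; defaults are the published workflow settings."""

    rarefaction_depth: int = 10_000
    rarefaction_iterations: int = 10
    min_feature_total: int = 10  # drop sOTUs with grand total below this
    min_feature_samples: int = 2  # drop sOTUs present in fewer samples
    collapse_level: int = 6  # L6 = genus
    abundance_mean_thresh: float = 0.01  # mean relative abundance > 1%
    abundance_max_thresh: float = 0.05  # or > 5% in at least one sample
    clr_pseudocount: float | None = None  # None = half min nonzero
    alpha_metrics: tuple[str, ...] = ("observed_features", "shannon", "faith_pd")
    beta_metrics: tuple[str, ...] = (
        "jaccard",
        "bray_curtis",
        "unweighted_unifrac",
        "weighted_unifrac",
    )
    criteria: CoreCriteria = field(default_factory=CoreCriteria)
    permanova_permutations: int = 999
    screening_min_cell_n: int = 5
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["criteria"] = dataclasses.asdict(self.criteria)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "criteria" in d and isinstance(d["criteria"], dict):
            d["criteria"] = CoreCriteria(**d["criteria"])
        for key in ("alpha_metrics", "beta_metrics"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class PipelineReport:
    stages: list = field(default_factory=list)
    results: dict = field(default_factory=dict)

    def record(self, stage: str, table) -> None:
        shape = table.shape if hasattr(table, "shape") else (None, None)
        self.stages.append(
            {"stage": stage, "n_samples": shape[0], "n_features": shape[1]}
        )

    def to_json(self) -> str:
        serializable = {
            "stages": self.stages,
            "results": {
                k: v for k, v in self.results.items() if isinstance(v, (int, float, str, list, dict))
            },
        }
        return json.dumps(serializable, indent=2, default=str)


def run_core_analysis(
    table: FeatureTable,
    taxonomy: TaxonomyMap,
    metadata: SampleMetadata,
    config: PipelineConfig = PipelineConfig(),
) -> tuple[CoreResult, PipelineReport]:
    """The preprocessing + core-criteria path (no diversity metrics).

    This is the fast path used for planted-core recovery: organelle filter ->
    low-count filter -> shallow-sample exclusion -> L6 collapse -> relative
    abundance -> F1/F2/F3 evaluation on the full (unfiltered) relative table.
    """
    report = PipelineReport()
    report.record("input", table)

    filtered, organelle_report = filter_organelles(table, taxonomy)
    report.record("organelle_filter", filtered)
    report.results["organelle_removed_max_fraction"] = float(
        organelle_report.removed_fraction.max()
    )

    filtered = filter_low_count(
        filtered, config.min_feature_total, config.min_feature_samples
    )
    report.record("low_count_filter", filtered)

    retained, excluded = exclude_shallow(filtered, config.rarefaction_depth)
    report.record("shallow_sample_exclusion", retained)
    report.results["excluded_samples"] = excluded

    collapsed = collapse_taxonomy(retained, taxonomy, config.collapse_level)
    report.record("taxonomic_collapse", collapsed)

    relab = to_relative(collapsed)
    core = evaluate_criteria(relab, metadata, config.criteria)
    report.results["venn"] = venn_partition(core)
    report.results["core_taxa"] = core.core_taxa
    report.record("core_criteria", relab.data)

    _check_monotone(report)
    return core, report


def run_pipeline(
    table: FeatureTable,
    taxonomy: TaxonomyMap,
    metadata: SampleMetadata,
    tree=None,
    config: PipelineConfig = PipelineConfig(),
    outdir: str | Path | None = None,
) -> PipelineReport:
    """Full analysis: preprocessing, diversity, core criteria, group analyses.

    Every stage's output (and a provenance JSON naming the operation,
    parameters, seed and input hash) is written under ``outdir`` when given.
    """
    from . import diversity as div
    from . import group_analysis as ga

    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    report = PipelineReport()
    report.record("input", table)
    report.results["input_summary"] = dataset_summary(table).rounded()

    filtered, organelle_report = filter_organelles(table, taxonomy)
    report.record("organelle_filter", filtered)

    filtered = filter_low_count(
        filtered, config.min_feature_total, config.min_feature_samples
    )
    report.record("low_count_filter", filtered)

    retained, excluded = exclude_shallow(filtered, config.rarefaction_depth)
    report.record("shallow_sample_exclusion", retained)
    report.results["excluded_samples"] = excluded
    report.results["final_summary"] = dataset_summary(retained).rounded()

    # diversity on the sOTU-level table
    rarefied, _ = rarefy(retained, config.rarefaction_depth, config.seed)
    report.record("rarefaction", rarefied)

    alpha = {}
    for metric in config.alpha_metrics:
        res = div.alpha_rarefaction(
            retained,
            metric,
            depth=config.rarefaction_depth,
            iterations=config.rarefaction_iterations,
            seed=config.seed,
            tree=tree,
        )
        alpha[metric] = res
        report.results[f"alpha_{metric}_mean"] = float(res.values.mean())
    report.results["_alpha"] = alpha

    beta = {}
    ordinations = {}
    for metric in config.beta_metrics:
        dm = div.beta_diversity(rarefied, metric, tree=tree)
        beta[metric] = dm
        ordinations[metric] = div.pcoa(dm)
    report.results["_beta"] = beta
    report.results["_pcoa"] = ordinations

    if beta:
        first = next(iter(beta))
        frame = metadata.require_samples(list(beta[first].ids))
        perm = ga.permanova(
            beta[first],
            frame["country"],
            n_permutations=config.permanova_permutations,
            seed=config.seed,
        )
        report.results["permanova_country"] = {
            "metric": first,
            "F": perm.f_statistic,
            "p": perm.p_value,
            "R2": perm.r_squared,
        }

    # compositional path at L6
    collapsed = collapse_taxonomy(retained, taxonomy, config.collapse_level)
    report.record("taxonomic_collapse", collapsed)
    relab = to_relative(collapsed)
    filtered_relab = abundance_filter(
        relab, config.abundance_mean_thresh, config.abundance_max_thresh
    )
    report.record("abundance_filter", filtered_relab.data)
    clr = clr_transform(filtered_relab, config.clr_pseudocount)
    report.record("clr_transform", clr.data)

    core = evaluate_criteria(relab, metadata, config.criteria)
    report.results["venn"] = venn_partition(core)
    report.results["core_taxa"] = core.core_taxa
    report.results["_core"] = core
    report.results["core_summary"] = core_summary(core).to_dict()

    means = ga.group_means(clr, metadata)
    report.results["_group_means"] = means
    if means.values.shape[0] >= 2 and means.values.shape[1] >= 2:
        try:
            report.results["_clustering"] = ga.hierarchical_cluster(means)
        except ValueError:
            pass
    report.results["_pca"] = ga.pca(clr)
    screening = ga.screen_country_effects(
        clr,
        metadata,
        min_cell_n=config.screening_min_cell_n,
        n_permutations=config.permanova_permutations,
        seed=config.seed,
    )
    report.results["_screening"] = screening
    if len(screening.table):
        sig = screening.table["significant_q0.01"].groupby(level="taxon").any()
        report.results["n_country_significant_taxa"] = int(sig.sum())

    _check_monotone(report)

    if out is not None:
        _write_outputs(report, config, relab, clr, core, out)
    return report


def _check_monotone(report: PipelineReport) -> None:
    """Sample/feature counts must be non-increasing through the filter stages."""
    filters = [
        s
        for s in report.stages
        if s["stage"]
        in {"input", "organelle_filter", "low_count_filter", "shallow_sample_exclusion"}
    ]
    for before, after in zip(filters, filters[1:]):
        if (
            after["n_samples"] > before["n_samples"]
            or after["n_features"] > before["n_features"]
        ):
            raise AssertionError(
                f"stage {after['stage']} increased table size over {before['stage']}"
            )


def _write_outputs(report, config, relab, clr, core, out: Path) -> None:
    from .tables_io import write_distance_matrix

    with open(out / "run_report.json", "w") as fh:
        fh.write(report.to_json())
    write_provenance(
        out / "provenance.json",
        "run_pipeline",
        config.to_dict(),
        input_hash=content_hash(relab.data),
    )
    relab.data.to_csv(out / "relative_abundance_L6.tsv", sep="\t")
    clr.data.to_csv(out / "clr_L6_filtered.tsv", sep="\t")
    core.table.to_csv(out / "core_criteria.tsv", sep="\t")
    with open(out / "venn.json", "w") as fh:
        json.dump(report.results["venn"], fh, indent=2)
    for metric, dm in report.results.get("_beta", {}).items():
        write_distance_matrix(dm, out / f"distance_{metric}.tsv")
    for metric, res in report.results.get("_alpha", {}).items():
        res.values.to_csv(out / f"alpha_{metric}.tsv", sep="\t")
    screening = report.results.get("_screening")
    if screening is not None and len(screening.table):
        screening.table.to_csv(out / "country_screening.tsv", sep="\t")


def load_inputs(table_path, taxonomy_path, metadata_path, tree_path=None, orientation="features"):
    table = read_feature_table(table_path, orientation=orientation)
    taxonomy = read_taxonomy(taxonomy_path)
    metadata = read_metadata(metadata_path)
    tree = read_tree(tree_path) if tree_path else None
    return table, taxonomy, metadata, tree
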