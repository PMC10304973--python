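"""Synthetic multi-country household study generator with planted ground truth.

Emulates the structure of a five-country kitchen survey: 14-15 households per
country, up to 7 sample types per household with type-specific inclusion
probabilities (two cleaning-utensil types absent from one country, mirroring
the real design's missing cells), log-normally distributed sequencing depths,
and a Dirichlet-multinomial count model over a community with:

* planted *core* taxa — ubiquitous, high mean abundance, present in every
  household;
* planted *bloom* taxa — essentially absent except for a single sample where
  they spike above 5%;
* planted *rare* "pathogen-like" taxa — present in a few percent of samples
  at trace abundance, one designated sample dominated (the 43%-in-one-sponge
  motif);
* background taxa with patchy household occupancy, so that near-universal
  occurrence is a real signal and not a side effect of sequencing depth.

Everything is deterministic given (design, model, seed); the ground truth is
regenerable and serializable alongside the dataset.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from skbio import TreeNode

from .tables_io import (
    FeatureTable,
    SampleMetadata,
    TaxonomyMap,
    write_feature_table,
    write_metadata,
    write_taxonomy,
    write_tree,
)

COUNTRIES = ("France", "Hungary", "Norway", "Portugal", "Romania")

# per-type inclusion probabilities approximating the observed per-type sample
# counts (40, 32, 51, 35, 53, 53, 38 of 74 households)
TYPE_INCLUSION = {
    "sponge": 0.54,
    "cloth": 0.43,
    "sink": 0.69,
    "cutting_board": 0.47,
    "tap_handle": 0.72,
    "countertop": 0.72,
    "handles": 0.51,
}

# one country contributes no cleaning utensils (missing-cell motif)
EXCLUDED_CELLS = (("Hungary", "sponge"), ("Hungary", "cloth"))


@dataclass(frozen=True)
class StudyDesign:
    countries: tuple[str, ...] = COUNTRIES
    households_per_country: int = 15
    sample_types: tuple[str, ...] = tuple(TYPE_INCLUSION)
    type_inclusion: dict = field(default_factory=lambda: dict(TYPE_INCLUSION))
    excluded_cells: tuple = EXCLUDED_CELLS
    mean_depth: float = 50_000.0
    depth_sigma: float = 0.7  # log-scale sd; ~1% of samples fall below 10,000
    n_taxa: int = 60


@dataclass(frozen=True)
class CommunityModel:
    n_core: int = 8
    n_bloom: int = 5
    n_rare: int = 4
    core_log_mean: float = 3.0
    core_log_sd: float = 0.4
    other_log_mean: float = 0.0
    other_log_sd: float = 1.2
    country_effect_scale: float = 0.7
    sample_type_effect_scale: float = 0.7
    household_effect_scale: float = 0.5
    noise_scale: float = 0.6  # per-sample log-abundance noise
    occupancy: float = 0.8  # P(background taxon colonizes a household)
    # DM concentration: low enough for visible overdispersion, high enough that
    # a resident taxon at >= 1% abundance has negligible per-sample dropout at
    # depth 10,000 (alpha = 500 * 0.01 = 5); sample-to-sample spikes come from
    # the log-scale noise and the explicitly planted bloom/rare motifs
    dirichlet_concentration: float = 500.0
    bloom_spike_range: tuple[float, float] = (0.06, 0.20)
    bloom_background_fraction: float = 0.03  # sporadic trace presence elsewhere
    rare_sample_fraction: float = 0.03
    rare_abundance_range: tuple[float, float] = (0.0005, 0.003)
    rare_dominated_fraction: float = 0.43
    organelle_fraction: dict = field(
        default_factory=lambda: {"cutting_board": 0.10, "default": 0.02}
    )

    def validate(self, n_taxa: int) -> None:
        planted = self.n_core + self.n_bloom + self.n_rare
        if planted > n_taxa:
            raise ValueError(
                f"planted sets ({planted} taxa) exceed n_taxa ({n_taxa})"
            )
        if any(s < 0 for s in (
            self.country_effect_scale,
            self.sample_type_effect_scale,
            self.household_effect_scale,
            self.noise_scale,
        )):
            raise ValueError("effect scales must be non-negative")


ORGANELLE_FEATURES = {
    "org_chloroplast": "Bacteria;Cyanobacteria;Cyanobacteriia;Chloroplast;unassigned;unassigned;unassigned",
    "org_mitochondria": "Bacteria;Proteobacteria;Alphaproteobacteria;Rickettsiales;Mitochondria;unassigned;unassigned",
}


@dataclass(frozen=True)
class GroundTruth:
    core_taxa: tuple[str, ...]
    bloom_taxa: tuple[str, ...]
    rare_taxa: tuple[str, ...]
    l6_labels: dict  # feature id -> L6 collapse label
    variance_components: dict
    expected_composition: pd.DataFrame = field(repr=False)
    seed: int = 0

    @property
    def core_labels(self) -> set[str]:
        return {self.l6_labels[t] for t in self.core_taxa}

    @property
    def bloom_labels(self) -> set[str]:
        return {self.l6_labels[t] for t in self.bloom_taxa}

    def to_json(self) -> str:
        payload = {
            "core_taxa": list(self.core_taxa),
            "bloom_taxa": list(self.bloom_taxa),
            "rare_taxa": list(self.rare_taxa),
            "l6_labels": self.l6_labels,
            "variance_components": self.variance_components,
            "seed": self.seed,
            "expected_composition": {
                "index": list(self.expected_composition.index),
                "columns": list(self.expected_composition.columns),
                "values": self.expected_composition.to_numpy().round(8).tolist(),
            },
        }
        return json.dumps(payload, indent=2)


@dataclass(frozen=True)
class SyntheticStudy:
    table: FeatureTable
    taxonomy: TaxonomyMap
    metadata: SampleMetadata
    tree: TreeNode
    truth: GroundTruth


def random_coalescent_tree(tip_names, rng: np.random.Generator) -> TreeNode:
    """Random sequential coalescence over the tips with Exp(1) branch lengths."""
    nodes = [TreeNode(name=str(n)) for n in tip_names]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        a.length = float(rng.exponential(1.0))
        b.length = float(rng.exponential(1.0))
        parent = TreeNode(children=[a, b])
        nodes.append(parent)
    root = nodes[0]
    root.length = 0.0
    return root


def _taxon_lineage(idx: int) -> str:
    return (
        f"Bacteria;Phylum_{idx % 7};Class_{idx % 11};Order_{idx % 13};"
        f"Family_{idx % 17};Genus_{idx:03d};unassigned"
    )


def _sample_layout(design: StudyDesign, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the household x sample-type layout; every household keeps >= 1 sample."""
    rows = []
    excluded = set(design.excluded_cells)
    for country in design.countries:
        for h in range(design.households_per_country):
            household = f"{country[:2].upper()}-H{h + 1:02d}"
            allowed = [
                t for t in design.sample_types if (country, t) not in excluded
            ]
            included = [
                t
                for t in allowed
                if rng.random() < design.type_inclusion.get(t, 0.5)
            ]
            if not included:
                included = [allowed[rng.integers(len(allowed))]]
            for t in included:
                rows.append(
                    {
                        "sample_id": f"{household}_{t}",
                        "country": country,
                        "household": household,
                        "sample_type": t,
                    }
                )
    return pd.DataFrame(rows).set_index("sample_id")


def generate_study(
    design: StudyDesign = StudyDesign(),
    model: CommunityModel = CommunityModel(),
    seed: int = 0,
) -> SyntheticStudy:
    """Generate a complete synthetic study with known planted structure."""
    model.validate(design.n_taxa)
    rng = np.random.default_rng(seed)

    layout = _sample_layout(design, rng)
    n_samples = len(layout)
    sample_ids = list(layout.index)
    households = sorted(layout["household"].unique())

    taxa = [f"sOTU_{i:03d}" for i in range(design.n_taxa)]
    core = tuple(taxa[: model.n_core])
    bloom = tuple(taxa[model.n_core : model.n_core + model.n_bloom])
    rare = tuple(
        taxa[model.n_core + model.n_bloom : model.n_core + model.n_bloom + model.n_rare]
    )
    background = taxa[model.n_core + model.n_bloom + model.n_rare :]

    n_taxa = design.n_taxa
    baseline = np.empty(n_taxa)
    baseline[: model.n_core] = rng.normal(model.core_log_mean, model.core_log_sd, model.n_core)
    baseline[model.n_core :] = rng.normal(
        model.other_log_mean, model.other_log_sd, n_taxa - model.n_core
    )

    country_eff = {
        c: rng.normal(0.0, model.country_effect_scale, n_taxa) for c in design.countries
    }
    type_eff = {
        t: rng.normal(0.0, model.sample_type_effect_scale, n_taxa)
        for t in design.sample_types
    }
    household_eff = {
        h: rng.normal(0.0, model.household_effect_scale, n_taxa) for h in households
    }
    # patchy occupancy for background taxa only; core colonizes every household
    occupancy = {
        h: np.concatenate(
            [
                np.ones(model.n_core),
                (rng.random(n_taxa - model.n_core) < model.occupancy).astype(float),
            ]
        )
        for h in households
    }

    regular = np.ones(n_taxa, dtype=bool)
    special_idx = {t: i for i, t in enumerate(taxa)}
    for t in bloom + rare:
        regular[special_idx[t]] = False

    # special-taxon placements: each bloom taxon spikes in one sample and is
    # sporadically present at trace level in a few others (so the low-count /
    # single-sample filter does not remove it before the criteria see it)
    bloom_frac: dict[str, dict[str, float]] = {}
    for t in bloom:
        spike_sample = sample_ids[rng.integers(n_samples)]
        n_trace = max(2, int(round(model.bloom_background_fraction * n_samples)))
        trace = rng.choice(sample_ids, size=n_trace, replace=False)
        placements = {
            s: float(rng.uniform(*model.rare_abundance_range)) for s in trace
        }
        placements[spike_sample] = float(rng.uniform(*model.bloom_spike_range))
        bloom_frac[t] = placements
    rare_presence = {}
    rare_frac = {}
    for k, t in enumerate(rare):
        n_present = max(2, int(round(model.rare_sample_fraction * n_samples)))
        chosen = list(rng.choice(sample_ids, size=n_present, replace=False))
        rare_presence[t] = chosen
        rare_frac[t] = {
            s: float(rng.uniform(*model.rare_abundance_range)) for s in chosen
        }
        if k == 0:  # the dominated-sample motif
            rare_frac[t][chosen[0]] = model.rare_dominated_fraction

    feature_ids = taxa + list(ORGANELLE_FEATURES)
    compositions = np.zeros((n_samples, len(feature_ids)))
    org_cols = [len(taxa), len(taxa) + 1]

    for i, sid in enumerate(sample_ids):
        row = layout.loc[sid]
        logits = (
            baseline
            + country_eff[row["country"]]
            + type_eff[row["sample_type"]]
            + household_eff[row["household"]]
            + rng.normal(0.0, model.noise_scale, n_taxa)
        )
        weights = np.exp(logits) * occupancy[row["household"]]
        weights[~regular] = 0.0
        base = weights / weights.sum()

        special = np.zeros(len(feature_ids))
        for t in bloom:
            if sid in bloom_frac[t]:
                special[special_idx[t]] = bloom_frac[t][sid]
        for t in rare:
            if sid in rare_frac[t]:
                special[special_idx[t]] = rare_frac[t][sid]
        f_org = model.organelle_fraction.get(
            row["sample_type"], model.organelle_fraction.get("default", 0.0)
        )
        special[org_cols[0]] = 0.7 * f_org
        special[org_cols[1]] = 0.3 * f_org
        q = special.sum()
        if q >= 1:
            raise ValueError("special fractions exceed the whole composition")
        compositions[i, : n_taxa] = base * (1 - q)
        compositions[i] += special

    depths = np.round(
        rng.lognormal(np.log(design.mean_depth), design.depth_sigma, n_samples)
    ).astype(np.int64)
    depths = np.maximum(depths, 1)

    counts = np.zeros((n_samples, len(feature_ids)), dtype=np.int64)
    conc = model.dirichlet_concentration
    for i in range(n_samples):
        p = compositions[i]
        support = p > 0
        alpha = conc * p[support]
        drawn = rng.dirichlet(alpha)
        counts[i, support] = rng.multinomial(depths[i], drawn / drawn.sum())

    table = FeatureTable(
        pd.DataFrame(counts, index=sample_ids, columns=feature_ids)
    )
    lineages = {t: _taxon_lineage(i) for i, t in enumerate(taxa)}
    lineages.update(ORGANELLE_FEATURES)
    taxonomy = TaxonomyMap.from_strings(lineages)
    metadata = SampleMetadata(layout)
    tree = random_coalescent_tree(feature_ids, rng)

    from .preprocess import collapse_label
    from .tables_io import parse_lineage

    l6_labels = {
        t: collapse_label(parse_lineage(lineages[t]), 6) for t in taxa
    }
    truth = GroundTruth(
        core_taxa=core,
        bloom_taxa=bloom,
        rare_taxa=rare,
        l6_labels=l6_labels,
        variance_components={
            "household": model.household_effect_scale**2,
            "country": model.country_effect_scale**2,
            "sample_type": model.sample_type_effect_scale**2,
            "noise": model.noise_scale**2,
        },
        expected_composition=pd.DataFrame(
            compositions, index=sample_ids, columns=feature_ids
        ),
        seed=seed,
    )
    return SyntheticStudy(table, taxonomy, metadata, tree, truth)


def evaluate_core_recovery(truth: GroundTruth, result) -> tuple[float, float, bool]:
    """Compare a CoreResult (on L6 labels) against the planted truth.

    Returns (sensitivity over planted core, specificity over non-core taxa,
    exact-match flag). Taxa dropped by upstream filters count as not recovered.
    """
    universe = set(truth.l6_labels.values())
    recovered = set(result.core_taxa)
    found_universe = set(result.table.index)
    alien = found_universe - universe
    if alien:
        raise ValueError(f"result taxa outside the planted universe: {sorted(alien)[:5]}")
    core = truth.core_labels
    non_core = universe - core
    tp = len(recovered & core)
    fp = len(recovered - core)
    sensitivity = tp / len(core) if core else 1.0
    specificity = (len(non_core) - fp) / len(non_core) if non_core else 1.0
    return sensitivity, specificity, recovered == core


def write_study(study: SyntheticStudy, outdir) -> dict[str, str]:
    """Write the study in the exact formats the readers consume, plus truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "table": outdir / "feature_table.tsv",
        "taxonomy": outdir / "taxonomy.tsv",
        "metadata": outdir / "metadata.tsv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "ground_truth.json",
    }
    write_feature_table(study.table, paths["table"])
    write_taxonomy(study.taxonomy, paths["taxonomy"])
    write_metadata(study.metadata, paths["metadata"])
    write_tree(study.tree, paths["tree"])
    paths["truth"].write_text(study.truth.to_json())
    return {k: str(v) for k, v in paths.items()}
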