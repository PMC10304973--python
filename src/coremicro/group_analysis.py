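"""Country / sample-type comparisons.

Averaged heatmap matrices with Euclidean complete-linkage clustering, PCA on
CLR-transformed data, distance-based PERMANOVA, per-taxon country screening
with permutation F-tests and Benjamini-Hochberg FDR, and a linear mixed model
(country and sample type fixed, household random) for alpha diversity and
core-taxon abundances.

The per-taxon screening is a deliberate substitute for 50-50 MANOVA with
rotation tests; results carry ``method='permutation_F'`` so downstream
reports can label them as such.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import cophenet, leaves_list, linkage
from scipy.spatial.distance import pdist
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from .preprocess import CLRTable, RelativeAbundanceTable
from .diversity import OrdinationResult, _fix_signs
from .tables_io import SampleMetadata


# ---------------------------------------------------------------------------
# group means and clustering
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GroupMeanMatrix:
    values: pd.DataFrame = field(repr=False)  # taxa x (country, sample_type) cells
    cell_n: pd.Series = field(repr=False)
    missing_cells: list[tuple[str, str]] = field(default_factory=list)


def group_means(
    values: CLRTable | RelativeAbundanceTable | pd.DataFrame, meta: SampleMetadata
) -> GroupMeanMatrix:
    """Arithmetic mean per (country, sample_type) cell; absent cells are omitted
    (never zero-filled) and listed."""
    data = values.data if hasattr(values, "data") else values
    frame = meta.require_samples(list(data.index))
    keys = [frame["country"], frame["sample_type"]]
    grouped = data.groupby(keys, observed=True).mean().T  # taxa x cells
    n = data.groupby(keys, observed=True).size()
    all_cells = [
        (c, t)
        for c in sorted(frame["country"].unique())
        for t in sorted(frame["sample_type"].unique())
    ]
    missing = [cell for cell in all_cells if cell not in set(grouped.columns)]
    return GroupMeanMatrix(grouped, n, missing)


@dataclass(frozen=True)
class ClusteringResult:
    row_linkage: np.ndarray = field(repr=False)
    col_linkage: np.ndarray = field(repr=False)
    row_order: list = field(default_factory=list)
    col_order: list = field(default_factory=list)

    @property
    def row_heights(self) -> np.ndarray:
        return self.row_linkage[:, 2]

    @property
    def col_heights(self) -> np.ndarray:
        return self.col_linkage[:, 2]


def hierarchical_cluster(
    matrix: GroupMeanMatrix | pd.DataFrame, scale_columns: bool = True
) -> ClusteringResult:
    """Euclidean complete-linkage clustering of rows and columns.

    With ``scale_columns`` the columns are standardized to zero mean and unit
    variance before distances are computed (scale -> distance -> cluster).
    Ties are broken deterministically by sorting labels lexicographically
    before linkage.
    """
    data = matrix.values if isinstance(matrix, GroupMeanMatrix) else matrix
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("clustering needs at least 2 rows and 2 columns")
    data = data.sort_index(axis=0).sort_index(axis=1)
    if scale_columns:
        std = data.std(axis=0, ddof=1)
        constant = std.index[std == 0].tolist()
        if constant:
            raise ValueError(f"constant column(s) cannot be scaled: {constant}")
        data = (data - data.mean(axis=0)) / std
    row_z = linkage(pdist(data.to_numpy()), method="complete")
    col_z = linkage(pdist(data.to_numpy().T), method="complete")
    return ClusteringResult(
        row_z,
        col_z,
        [data.index[i] for i in leaves_list(row_z)],
        [data.columns[i] for i in leaves_list(col_z)],
    )


def cophenetic_distances(linkage_matrix: np.ndarray) -> np.ndarray:
    return cophenet(linkage_matrix)


def linkage_to_newick(linkage_matrix: np.ndarray, labels: list[str]) -> str:
    """Serialize a linkage matrix as a Newick string (dendrogram export)."""
    n = len(labels)
    nodes = {i: (str(labels[i]), 0.0) for i in range(n)}
    for k, (a, b, height, _) in enumerate(linkage_matrix):
        na, ha = nodes.pop(int(a))
        nb, hb = nodes.pop(int(b))
        nodes[n + k] = (f"({na}:{height - ha:g},{nb}:{height - hb:g})", height)
    (newick, _), = nodes.values()
    return newick + ";"


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


def pca(values: CLRTable | pd.DataFrame) -> OrdinationResult:
    """Principal-component analysis via SVD of the column-centered matrix."""
    data = values.data if hasattr(values, "data") else values
    if data.shape[0] < 2 or data.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 taxa")
    x = data.to_numpy(dtype=float)
    centered = x - x.mean(axis=0)
    u, s, vt = np.linalg.svd(centered, full_matrices=False)
    # sign convention keyed to the loadings
    for j in range(vt.shape[0]):
        load = vt[j]
        if load[np.argmax(np.abs(load))] < 0:
            vt[j] = -load
            u[:, j] = -u[:, j]
    scores = u * s
    eigvals = s**2 / (x.shape[0] - 1)
    positive = eigvals > 1e-12 * max(eigvals[0], 1.0)
    frame = pd.DataFrame(
        scores[:, positive],
        index=data.index,
        columns=[f"PC{i + 1}" for i in range(int(positive.sum()))],
    )
    proportions = eigvals[positive] / eigvals[positive].sum()
    return OrdinationResult(frame, eigvals, proportions)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PermanovaResult:
    f_statistic: float
    p_value: float
    r_squared: float
    n_permutations: int
    n_samples: int
    n_groups: int


def _permanova_f(sq: np.ndarray, labels: np.ndarray, n_groups: int) -> tuple[float, float]:
    """Pseudo-F and R^2 from a squared-distance matrix and integer labels."""
    n = sq.shape[0]
    ss_total = sq[np.triu_indices(n, 1)].sum() / n
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(labels == g)
        if len(idx) > 1:
            block = sq[np.ix_(idx, idx)]
            ss_within += block[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ss_among = ss_total - ss_within
    f = (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))
    return f, ss_among / ss_total


def permanova(
    dm: DistanceMatrix,
    grouping,
    n_permutations: int = 999,
    seed: int = 0,
    allow_singletons: bool = False,
) -> PermanovaResult:
    """One-way PERMANOVA: pseudo-F from the among/within partition of squared
    distances, with a label-permutation p-value (add-one estimator)."""
    grouping = pd.Series(np.asarray(grouping), index=list(dm.ids))
    levels, labels = np.unique(grouping.to_numpy(), return_inverse=True)
    if len(levels) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    sizes = np.bincount(labels)
    if (sizes < 2).any() and not allow_singletons:
        bad = [str(levels[i]) for i in np.flatnonzero(sizes < 2)]
        raise ValueError(f"group(s) with a single sample: {bad}")
    sq = np.asarray(dm.data, dtype=float) ** 2
    observed_f, r2 = _permanova_f(sq, labels, len(levels))
    rng = np.random.default_rng(seed)
    exceed = 0
    perm = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(perm)
        f, _ = _permanova_f(sq, perm, len(levels))
        if f >= observed_f:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(observed_f, p, r2, n_permutations, sq.shape[0], len(levels))


# ---------------------------------------------------------------------------
# per-taxon country screening (declared substitute for 50-50 MANOVA)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScreeningResult:
    table: pd.DataFrame = field(repr=False)  # (sample_type, taxon) rows
    variance_explained: pd.Series = field(repr=False)  # % per sample type
    method: str = "permutation_F"


def _anova_f_matrix(values: np.ndarray, labels: np.ndarray, n_groups: int) -> np.ndarray:
    """One-way ANOVA F per column, vectorized over taxa."""
    n = values.shape[0]
    grand = values.mean(axis=0)
    ss_total = ((values - grand) ** 2).sum(axis=0)
    ss_within = np.zeros_like(grand)
    for g in range(n_groups):
        sub = values[labels == g]
        ss_within += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
    ss_among = ss_total - ss_within
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ss_among / (n_groups - 1)) / (ss_within / (n - n_groups))
    return np.where(np.isfinite(f), f, np.inf)


def screen_country_effects(
    values: CLRTable,
    meta: SampleMetadata,
    min_cell_n: int = 5,
    n_permutations: int = 999,
    seed: int = 0,
    alpha_levels: tuple[float, float] = (0.05, 0.01),
) -> ScreeningResult:
    """Per sample type, test each taxon for a country effect with a one-way
    permutation F-test on CLR values; BH-FDR within sample type.

    Only (country, sample type) cells with at least ``min_cell_n`` samples are
    included; sample types retaining fewer than two countries are skipped.
    The per-sample-type '% variance explained by country' is the multivariate
    among-group share of the total sum of squares over all taxa.
    """
    frame = meta.require_samples(values.sample_ids)
    data = values.data
    rng = np.random.default_rng(seed)
    records = []
    var_explained = {}
    for stype in sorted(frame["sample_type"].unique()):
        in_type = frame["sample_type"] == stype
        cells = frame.loc[in_type, "country"].value_counts()
        countries = sorted(cells.index[cells >= min_cell_n])
        if len(countries) < 2:
            warnings.warn(
                f"sample type {stype!r}: fewer than 2 countries with "
                f">= {min_cell_n} samples; skipped",
                stacklevel=2,
            )
            continue
        mask = in_type & frame["country"].isin(countries)
        sub = data.loc[mask.index[mask]].to_numpy()
        labels = pd.Categorical(frame.loc[mask.index[mask], "country"]).codes
        n_groups = len(countries)
        observed = _anova_f_matrix(sub, labels, n_groups)
        exceed = np.zeros_like(observed)
        perm = labels.copy()
        for _ in range(n_permutations):
            rng.shuffle(perm)
            exceed += _anova_f_matrix(sub, perm, n_groups) >= observed
        pvals = (1 + exceed) / (1 + n_permutations)
        qvals = multipletests(pvals, method="fdr_bh")[1]
        # multivariate among/within share across all taxa
        grand = sub.mean(axis=0)
        ss_total = ((sub - grand) ** 2).sum()
        ss_within = sum(
            ((sub[labels == g] - sub[labels == g].mean(axis=0)) ** 2).sum()
            for g in range(n_groups)
        )
        var_explained[stype] = 100.0 * (ss_total - ss_within) / ss_total
        for j, taxon in enumerate(data.columns):
            records.append(
                {
                    "sample_type": stype,
                    "taxon": taxon,
                    "f_statistic": observed[j],
                    "p_value": pvals[j],
                    "q_value": qvals[j],
                    f"significant_q{alpha_levels[0]}": qvals[j] < alpha_levels[0],
                    f"significant_q{alpha_levels[1]}": qvals[j] < alpha_levels[1],
                }
            )
    table = pd.DataFrame.from_records(records)
    if len(table):
        table = table.set_index(["sample_type", "taxon"])
    return ScreeningResult(table, pd.Series(var_explained, name="pct_variance_country"))


# ---------------------------------------------------------------------------
# linear mixed model: country + sample type fixed, household random
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MixedModelResult:
    fixed_effects: pd.DataFrame = field(repr=False)
    household_variance: float = 0.0
    residual_variance: float = 0.0
    marginal_means: pd.DataFrame = field(repr=False, default=None)

    @property
    def household_variance_share(self) -> float:
        """Household variance component as a percentage of total variance."""
        total = self.household_variance + self.residual_variance
        return 100.0 * self.household_variance / total if total > 0 else 0.0


def fit_mixed_model(response: pd.Series, meta: SampleMetadata) -> MixedModelResult:
    """REML fit of ``response ~ country + sample_type + (1 | household)``.

    Estimated marginal means per factor level average predictions over the
    levels of the other factor with equal weights; 95% CIs use the
    fixed-effect covariance.
    """
    import statsmodels.formula.api as smf

    frame = meta.require_samples(list(response.index)).copy()
    frame["y"] = response.astype(float).to_numpy()
    if frame["country"].nunique() < 2 or frame["sample_type"].nunique() < 2:
        raise ValueError("need >= 2 countries and >= 2 sample types")
    model = smf.mixedlm("y ~ C(country) + C(sample_type)", frame, groups=frame["household"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    household_var = float(fit.cov_re.iloc[0, 0])
    residual_var = float(fit.scale)

    params = fit.fe_params
    cov = fit.cov_params().loc[params.index, params.index]
    design_info = fit.model.data.design_info
    from patsy import dmatrix

    def emm(factor: str) -> pd.DataFrame:
        other = "sample_type" if factor == "country" else "country"
        levels = sorted(frame[factor].unique())
        other_levels = sorted(frame[other].unique())
        rows = []
        for level in levels:
            grid = pd.DataFrame({factor: level, other: other_levels})
            x = np.asarray(dmatrix(design_info, grid))
            contrast = x.mean(axis=0)
            estimate = float(contrast @ params.to_numpy())
            se = float(np.sqrt(contrast @ cov.to_numpy() @ contrast))
            rows.append(
                {
                    "factor": factor,
                    "level": level,
                    "estimate": estimate,
                    "se": se,
                    "ci_low": estimate - 1.96 * se,
                    "ci_high": estimate + 1.96 * se,
                }
            )
        return pd.DataFrame(rows)

    marginal = pd.concat([emm("country"), emm("sample_type")], ignore_index=True)
    fixed = pd.DataFrame(
        {"estimate": params, "se": fit.bse_fe.loc[params.index], "p_value": fit.pvalues.loc[params.index]}
    )
    return MixedModelResult(fixed, household_var, residual_var, marginal)
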