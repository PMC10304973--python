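"""Alpha and beta diversity.

Alpha metrics (observed features, Shannon entropy, Faith's phylogenetic
diversity) are averaged over repeated rarefactions to a fixed depth, matching
the common even-sampling workflow. Beta diversity covers Jaccard (on
presence/absence), Bray-Curtis, and unweighted/weighted UniFrac, with
classical PCoA for ordination. Phylogenetic metrics delegate to scikit-bio;
PCoA is computed here so that negative eigenvalues are reported but excluded
from the proportion-explained denominator and axis signs are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix, TreeNode
from skbio.diversity import alpha_diversity, beta_diversity as _skbio_beta

from .preprocess import rarefy
from .tables_io import FeatureTable

ALPHA_METRICS = ("observed_features", "shannon", "faith_pd")
BETA_METRICS = ("jaccard", "bray_curtis", "unweighted_unifrac", "weighted_unifrac")


def observed_features(counts) -> int:
    """Number of features with a nonzero count."""
    return int(np.count_nonzero(np.asarray(counts)))


def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy of the count composition; base 2 by convention."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    if total <= 0:
        raise ValueError("Shannon entropy undefined for a zero-total sample")
    p = counts[counts > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def faith_pd(counts, feature_ids, tree: TreeNode, include_root: bool = True) -> float:
    """Faith's phylogenetic diversity: branch length of the minimal subtree
    spanning the observed tips (and, by default, the root)."""
    counts = np.asarray(counts)
    observed = [f for f, c in zip(feature_ids, counts) if c > 0]
    tips = {t.name for t in tree.tips()}
    missing = [f for f in observed if f not in tips]
    if missing:
        raise ValueError(f"observed feature(s) missing from tree: {missing}")
    if not observed:
        return 0.0
    if include_root:
        value = alpha_diversity(
            "faith_pd", counts.reshape(1, -1), ids=["s"], taxa=list(feature_ids), tree=tree
        ).iloc[0]
        return float(value)
    # root-excluded variant: subtract the unshared root path
    sub = tree.shear(observed) if len(observed) < len(tips) else tree
    return float(sum(n.length or 0.0 for n in sub.traverse(include_self=False)))


def _alpha_metric(metric: str, counts, feature_ids, tree):
    if metric == "observed_features":
        return float(observed_features(counts))
    if metric == "shannon":
        return shannon(counts)
    if metric == "faith_pd":
        if tree is None:
            raise ValueError("faith_pd requires a tree")
        return faith_pd(counts, feature_ids, tree)
    raise ValueError(f"unknown alpha metric {metric!r}; choose from {ALPHA_METRICS}")


@dataclass(frozen=True)
class AlphaDiversityResult:
    metric: str
    depth: int
    iterations: int
    values: pd.Series  # per retained sample
    excluded: list[str]


def alpha_rarefaction(
    table: FeatureTable,
    metric: str,
    depth: int = 10_000,
    iterations: int = 10,
    seed: int = 0,
    tree: TreeNode | None = None,
) -> AlphaDiversityResult:
    """Mean of an alpha metric over `iterations` independent rarefactions."""
    if iterations < 1:
        raise ValueError("iterations must be >= 1")
    rng = np.random.default_rng(seed)
    feature_ids = table.feature_ids
    sums = np.zeros(table.shape[0])
    retained: list[str] = []
    excluded: list[str] = []
    for _ in range(iterations):
        rarefied, excluded = rarefy(table, depth, rng)
        retained = rarefied.sample_ids
        vals = np.array(
            [
                _alpha_metric(metric, rarefied.data.loc[s].to_numpy(), feature_ids, tree)
                for s in retained
            ]
        )
        sums[: len(retained)] += vals
    values = pd.Series(sums[: len(retained)] / iterations, index=retained, name=metric)
    return AlphaDiversityResult(metric, depth, iterations, values, excluded)


def expected_observed_features(counts, depth: int) -> float:
    """Closed-form expectation of observed features after rarefaction to `depth`:
    sum_i 1 - C(N - n_i, d) / C(N, d)."""
    from scipy.special import gammaln

    counts = np.asarray(counts, dtype=np.int64)
    n = int(counts.sum())
    if depth > n:
        raise ValueError("depth exceeds sample total")

    def log_comb(a, b):
        return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)

    expectation = 0.0
    for c in counts[counts > 0]:
        if n - c < depth:
            expectation += 1.0
        else:
            expectation += 1.0 - np.exp(log_comb(n - c, depth) - log_comb(n, depth))
    return float(expectation)


def beta_diversity(
    table: FeatureTable, metric: str, tree: TreeNode | None = None
) -> DistanceMatrix:
    """Pairwise distances between samples under one of the four supported metrics.

    Jaccard is computed on presence/absence; weighted UniFrac is the
    non-normalized variant unless `metric='weighted_unifrac_normalized'`.
    """
    counts = table.data.to_numpy()
    ids = table.sample_ids
    if metric == "jaccard":
        return _skbio_beta("jaccard", counts > 0, ids=ids)
    if metric in {"bray_curtis", "braycurtis"}:
        return _skbio_beta("braycurtis", counts, ids=ids)
    if metric in {"unweighted_unifrac", "weighted_unifrac", "weighted_unifrac_normalized"}:
        if tree is None:
            raise ValueError(f"{metric} requires a phylogenetic tree")
        kwargs = {}
        name = metric
        if metric == "weighted_unifrac_normalized":
            name, kwargs = "weighted_unifrac", {"normalized": True}
        return _skbio_beta(
            name, counts, ids=ids, taxa=table.feature_ids, tree=tree, **kwargs
        )
    raise ValueError(f"unknown beta metric {metric!r}; choose from {BETA_METRICS}")


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: pd.DataFrame  # samples x axes
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives retained)
    proportion_explained: np.ndarray  # over positive eigenvalues only

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make the largest-magnitude loading of each axis positive (deterministic)."""
    for j in range(vectors.shape[1]):
        col = vectors[:, j]
        if col[np.argmax(np.abs(col))] < 0:
            vectors[:, j] = -col
    return vectors


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical (metric) multidimensional scaling of a distance matrix.

    Eigendecomposition of the Gower-centered -D^2/2 matrix. Negative
    eigenvalues are retained in the report but contribute neither axes nor
    proportion-explained denominator.
    """
    d = np.asarray(dm.data, dtype=float)
    if not np.allclose(d, d.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    n = d.shape[0]
    centering = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centering @ (d**2) @ centering
    eigvals, eigvecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-12, 1e-10 * max(abs(eigvals[0]), 1.0))
    positive = eigvals > tol
    coords = eigvecs[:, positive] * np.sqrt(eigvals[positive])
    coords = _fix_signs(coords)
    proportions = eigvals[positive] / eigvals[positive].sum()
    frame = pd.DataFrame(
        coords,
        index=list(dm.ids),
        columns=[f"PC{i + 1}" for i in range(coords.shape[1])],
    )
    return OrdinationResult(frame, eigvals, proportions)


def write_ordination(result: OrdinationResult, coords_path, report_path) -> None:
    import json

    with open(coords_path, "w", encoding="utf-8", newline="\n") as fh:
        result.coordinates.to_csv(fh, sep="\t", index_label="sample_id", lineterminator="\n")
    report = {
        "eigenvalues": result.eigenvalues.tolist(),
        "proportion_explained": result.proportion_explained.tolist(),
    }
    with open(report_path, "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2)
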