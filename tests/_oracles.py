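"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations: distances by direct set/branch
enumeration, clustering by literal agglomeration, PERMANOVA by definition and
full enumeration. They share no code with the package paths they check.
"""

from __future__ import annotations

import itertools

import numpy as np


def jaccard_bf(x, y) -> float:
    a = {i for i, v in enumerate(x) if v > 0}
    b = {i for i, v in enumerate(y) if v > 0}
    if not a and not b:
        return 0.0
    return 1.0 - len(a & b) / len(a | b)


def bray_curtis_bf(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    denom = (x + y).sum()
    return float(np.abs(x - y).sum() / denom) if denom else 0.0


def _branches(tree):
    """(branch length, set of tip names below) for every non-root node."""
    out = []
    for node in tree.traverse(include_self=False):
        tips = {t.name for t in node.tips()} if not node.is_tip() else {node.name}
        out.append((node.length or 0.0, tips))
    return out


def unweighted_unifrac_bf(x, y, feature_ids, tree) -> float:
    a = {f for f, v in zip(feature_ids, x) if v > 0}
    b = {f for f, v in zip(feature_ids, y) if v > 0}
    unique = shared_total = 0.0
    for length, tips in _branches(tree):
        in_a, in_b = bool(tips & a), bool(tips & b)
        if in_a or in_b:
            shared_total += length
            if in_a != in_b:
                unique += length
    return unique / shared_total if shared_total else 0.0


def weighted_unifrac_bf(x, y, feature_ids, tree) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    px = dict(zip(feature_ids, x / x.sum()))
    py = dict(zip(feature_ids, y / y.sum()))
    total = 0.0
    for length, tips in _branches(tree):
        pa = sum(px.get(t, 0.0) for t in tips)
        pb = sum(py.get(t, 0.0) for t in tips)
        total += length * abs(pa - pb)
    return total


def faith_pd_bf(x, feature_ids, tree) -> float:
    """Union of root-to-tip paths over observed tips, summed branch lengths."""
    observed = {f for f, v in zip(feature_ids, x) if v > 0}
    if not observed:
        return 0.0
    used = set()
    for tip in tree.tips():
        if tip.name in observed:
            node = tip
            while node.parent is not None:
                used.add(id(node))
                node = node.parent
    return sum(
        (n.length or 0.0)
        for n in tree.traverse(include_self=False)
        if id(n) in used
    )


def complete_linkage_bf(points: np.ndarray):
    """Naive complete-linkage agglomeration; returns merge heights sorted."""
    clusters = [[i] for i in range(len(points))]
    heights = []
    while len(clusters) > 1:
        best = None
        for i, j in itertools.combinations(range(len(clusters)), 2):
            h = max(
                np.linalg.norm(points[a] - points[b])
                for a in clusters[i]
                for b in clusters[j]
            )
            if best is None or h < best[0]:
                best = (h, i, j)
        h, i, j = best
        heights.append(h)
        merged = clusters[i] + clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return sorted(heights)


def permanova_f_bf(dm: np.ndarray, labels) -> float:
    """Pseudo-F straight from the definitional sum-of-squares partition."""
    labels = np.asarray(labels)
    n = len(labels)
    groups = sorted(set(labels.tolist()))
    ss_total = sum(dm[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ss_within = 0.0
    for g in groups:
        idx = [i for i in range(n) if labels[i] == g]
        ss_within += sum(
            dm[i, j] ** 2 for i, j in itertools.combinations(idx, 2)
        ) / len(idx)
    ss_among = ss_total - ss_within
    a = len(groups)
    return (ss_among / (a - 1)) / (ss_within / (n - a))


def permanova_exact_p(dm: np.ndarray, labels) -> float:
    """Full-enumeration permutation p-value (small n only)."""
    observed = permanova_f_bf(dm, labels)
    perms = list(itertools.permutations(labels))
    exceed = sum(permanova_f_bf(dm, p) >= observed - 1e-12 for p in perms)
    return exceed / len(perms)
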