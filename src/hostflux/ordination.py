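"""Gene-content clustering diagnostics: NMDS, ANOSIM, and tree comparison."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata
from sklearn.isotonic import IsotonicRegression

from hostflux.errors import InputError
from hostflux.rng import substream
from hostflux.tree import Tree

__all__ = [
    "OrdinationResult",
    "AnosimResult",
    "nmds_embed",
    "anosim",
    "compare_trees",
    "cut_tree_groups",
]


@dataclass
class OrdinationResult:
    labels: list[str]
    coordinates: np.ndarray  # (n, k)
    stress: float            # Kruskal stress-1
    n_restarts: int
    converged: bool
    stress_sequence: list[float]  # per-iteration stress of the winning restart


@dataclass
class AnosimResult:
    statistic: float
    p_value: float
    n_permutations: int
    group_sizes: dict[str, int]


# ---------------------------------------------------------------------- #
# NMDS
# ---------------------------------------------------------------------- #

def _kruskal_stress(embedded: np.ndarray, disparities: np.ndarray) -> float:
    denom = float(np.sum(embedded ** 2))
    if denom <= 0:
        return 1.0
    return float(np.sqrt(np.sum((embedded - disparities) ** 2) / denom))


def _classical_mds(matrix: np.ndarray, k: int) -> np.ndarray:
    n = matrix.shape[0]
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centerer @ (matrix ** 2) @ centerer
    vals, vecs = np.linalg.eigh(b)
    order = np.argsort(vals)[::-1][:k]
    components = vecs[:, order] * np.sqrt(np.maximum(vals[order], 0.0))
    return components


def nmds_embed(labels: list[str], matrix: np.ndarray, k: int = 2,
               n_restarts: int = 20, max_iter: int = 300, seed: int = 0,
               tol: float = 1e-7) -> OrdinationResult:
    """Non-metric multidimensional scaling minimizing Kruskal stress-1.

    Alternates isotonic regression of disparities against the input
    distance ranks with Guttman-transform configuration updates.  The first
    restart starts from classical metric scaling, the rest from random
    configurations; the best (lowest-stress) restart is returned.  The
    per-iteration stress sequence is enforced non-increasing: an iteration
    that would raise stress terminates the restart.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape[0] < 4:
        raise InputError("nmds_embed requires at least 4 points")
    if not np.isfinite(matrix).all():
        raise InputError("non-finite distances in NMDS input")
    dvec = squareform(matrix, checks=False)
    order = np.argsort(dvec, kind="stable")
    iso = IsotonicRegression(increasing=True)
    rng = substream(seed, "nmds")
    n = matrix.shape[0]

    best: tuple[float, np.ndarray, list[float], bool] | None = None
    for restart in range(n_restarts):
        if restart == 0:
            coords = _classical_mds(matrix, k)
        else:
            coords = rng.standard_normal((n, k))
        stresses: list[float] = []
        converged = False
        prev = np.inf
        for _ in range(max_iter):
            evec = pdist(coords)
            if evec.max() <= 1e-9:  # total collapse: degenerate restart
                stresses.append(1.0)
                break
            evec = np.maximum(evec, 1e-12)
            disparities = np.empty_like(evec)
            disparities[order] = iso.fit_transform(np.arange(len(dvec)), evec[order])
            ss = float(np.sum(disparities ** 2))
            if ss <= 0:
                stresses.append(1.0)
                break
            # normalize disparities to the embedding scale (prevents the
            # shrink-to-zero degeneracy of unnormalized nonmetric SMACOF)
            disparities *= np.sqrt(np.sum(evec ** 2) / ss)
            stress = _kruskal_stress(evec, disparities)
            if stresses and stress > stresses[-1] + 1e-12:
                converged = True
                break
            stresses.append(stress)
            if prev - stress < tol:
                converged = True
                break
            prev = stress
            # Guttman transform
            ratio = squareform(disparities / evec, checks=False)
            b = -ratio
            np.fill_diagonal(b, ratio.sum(axis=1))
            coords = b @ coords / n
        final = stresses[-1] if stresses else 1.0
        if best is None or final < best[0]:
            best = (final, coords.copy(), stresses, converged)
    stress, coords, seq, converged = best
    return OrdinationResult(labels=list(labels), coordinates=coords, stress=stress,
                            n_restarts=n_restarts, converged=converged,
                            stress_sequence=seq)


# ---------------------------------------------------------------------- #
# ANOSIM
# ---------------------------------------------------------------------- #

def anosim(labels: list[str], matrix: np.ndarray, groups: dict[str, str],
           n_permutations: int = 999, seed: int = 0) -> AnosimResult:
    """Analysis of similarities on a distance matrix.

    R = (mean between-group rank − mean within-group rank) / (M/2) with
    M = n(n−1)/2 and midpoint-tied ranks; the p-value permutes group labels
    and counts permuted R ≥ observed.
    """
    matrix = np.asarray(matrix, dtype=float)
    group_vec = np.array([groups[label] for label in labels])
    names, counts = np.unique(group_vec, return_counts=True)
    if len(names) < 2:
        raise InputError("anosim requires at least 2 groups")
    if (counts < 2).any():
        small = [str(g) for g, c in zip(names, counts) if c < 2]
        raise InputError(f"anosim groups of size 1: {small}")
    dvec = squareform(matrix, checks=False)
    ranks = rankdata(dvec)
    n = len(labels)
    iu = np.triu_indices(n, k=1)
    same = group_vec[iu[0]] == group_vec[iu[1]]
    m = n * (n - 1) / 2

    def r_stat(same_mask: np.ndarray) -> float:
        return float((ranks[~same_mask].mean() - ranks[same_mask].mean()) / (m / 2.0))

    observed = r_stat(same)
    rng = substream(seed, "anosim")
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        permuted = group_vec[perm]
        same_p = permuted[iu[0]] == permuted[iu[1]]
        if r_stat(same_p) >= observed - 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return AnosimResult(statistic=observed, p_value=p,
                        n_permutations=n_permutations,
                        group_sizes={str(g): int(c) for g, c in zip(names, counts)})


# ---------------------------------------------------------------------- #
# tree comparison
# ---------------------------------------------------------------------- #

def compare_trees(tree_a: Tree, tree_b: Tree) -> dict:
    """Robinson–Foulds distance, normalized RF, cophenetic correlation,
    and the bipartitions unique to each tree."""
    tips_a, tips_b = set(tree_a.tip_names()), set(tree_b.tip_names())
    if tips_a != tips_b:
        raise InputError(
            f"tip sets differ: only in A {sorted(tips_a - tips_b)}, "
            f"only in B {sorted(tips_b - tips_a)}")
    splits_a = tree_a.bipartitions()
    splits_b = tree_b.bipartitions()
    rf = len(splits_a ^ splits_b)
    n = len(tips_a)
    max_rf = 2 * (n - 3) if n > 3 else 1
    names_a, coph_a = tree_a.cophenetic()
    _, coph_b_raw = tree_b.cophenetic()
    names_b = tree_b.tip_names()
    reorder = [names_b.index(name) for name in names_a]
    coph_b = coph_b_raw[np.ix_(reorder, reorder)]
    va = squareform(coph_a, checks=False)
    vb = squareform(coph_b, checks=False)
    if va.std() == 0 or vb.std() == 0:
        corr = float("nan")
    else:
        corr = float(np.corrcoef(va, vb)[0, 1])
    return {
        "rf": rf,
        "normalized_rf": rf / max_rf,
        "cophenetic_correlation": corr,
        "unique_to_a": sorted(sorted(s) for s in splits_a - splits_b),
        "unique_to_b": sorted(sorted(s) for s in splits_b - splits_a),
    }


def cut_tree_groups(tree: Tree, n_groups: int) -> dict[str, str]:
    """Cut an ultrametric tree into ``n_groups`` clades at the shallowest
    depth producing that many subtrees; returns tip → group label."""
    if n_groups < 1 or n_groups > len(tree.tips()):
        raise InputError("n_groups out of range")
    if n_groups == 1:
        return {t: "G1" for t in tree.tip_names()}
    work = tree.copy()
    work.set_ages_from_depths()
    ages = sorted((node.age for node in work.internal_nodes()), reverse=True)
    cut_age = ages[n_groups - 2] - 1e-12  # just below the (n_groups-1)-th split
    groups: dict[str, str] = {}
    counter = 0

    def walk(node, assigned: str | None) -> None:
        nonlocal counter
        if assigned is None and (node.is_leaf or node.age <= cut_age):
            counter += 1
            assigned = f"G{counter}"
        if node.is_leaf:
            groups[node.name] = assigned
            return
        for child in node.children:
            walk(child, assigned)

    walk(work.root, None)
    return groups
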