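"""Trait association of gene families (pan-GWAS).

For each binary genome trait (lineage or gene-content-group membership) each
family's presence pattern is scored by a 2×2 table: sensitivity, specificity,
a two-sided Fisher exact p, multiplicity-adjusted p-values (BH and
Bonferroni across the tested families of that trait), and a
label-permutation empirical p.  A family is called trait-specific only if
sensitivity and specificity both exceed 70% and the naive, adjusted, and
empirical p-values are all below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import false_discovery_control, fisher_exact, hypergeom

from hostflux.errors import InputError
from hostflux.pangenome import PresenceAbsenceMatrix
from hostflux.rng import substream

__all__ = [
    "AssociationResult",
    "score_family",
    "empirical_p",
    "select_specific_genes",
]


@dataclass
class AssociationResult:
    family: str
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float  # percent
    specificity: float  # percent
    p_naive: float
    p_bh: float = 1.0
    p_bonferroni: float = 1.0
    p_empirical: float = 1.0
    specific: bool = False
    flagged: bool = False  # constant presence column


def _validate_trait(trait: np.ndarray) -> np.ndarray:
    trait = np.asarray(trait, dtype=bool)
    if not trait.any() or trait.all():
        raise InputError("trait vector must contain at least one 0 and one 1")
    return trait


def _fisher_p_for_tp(n: int, n_present: int, n_trait: int) -> np.ndarray:
    """Two-sided Fisher exact p as a function of the TP count.

    With fixed margins the whole 2×2 table is determined by TP, so the p
    for every feasible TP can be tabulated once (sum of hypergeometric
    outcome probabilities ≤ the observed one).
    """
    lo = max(0, n_present + n_trait - n)
    hi = min(n_present, n_trait)
    support = np.arange(lo, hi + 1)
    pmf = hypergeom.pmf(support, n, n_present, n_trait)
    ps = np.array([pmf[pmf <= pmf[i] * (1 + 1e-9)].sum() for i in range(len(support))])
    out = np.full(min(n_present, n_trait) + 1, 1.0)
    out[support] = np.minimum(ps, 1.0)
    return out


def score_family(presence: np.ndarray, trait: np.ndarray,
                 family: str = "") -> AssociationResult:
    """2×2 table, sensitivity/specificity (percent), and two-sided Fisher p.

    A constant presence column carries no association signal: it is flagged
    and given p = 1.
    """
    trait = _validate_trait(trait)
    presence = np.asarray(presence, dtype=bool)
    if presence.shape != trait.shape:
        raise InputError("presence column and trait vector differ in length")
    tp = int(np.count_nonzero(presence & trait))
    fp = int(np.count_nonzero(presence & ~trait))
    fn = int(np.count_nonzero(~presence & trait))
    tn = int(np.count_nonzero(~presence & ~trait))
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    constant = presence.all() or not presence.any()
    if constant:
        p = 1.0
    else:
        _, p = fisher_exact([[tp, fp], [fn, tn]], alternative="two-sided")
    return AssociationResult(family=family, tp=tp, fp=fp, tn=tn, fn=fn,
                             sensitivity=sens, specificity=spec,
                             p_naive=float(p), flagged=constant)


def empirical_p(presence: np.ndarray, trait: np.ndarray,
                n_permutations: int = 1000, seed: int = 0,
                randomized: bool = False) -> float:
    """Label-permutation p-value for the Fisher statistic.

    Permuting trait labels preserves both margins, so each permuted table
    is determined by its TP count, which is hypergeometric; the permuted
    Fisher p values are therefore drawn by sampling TP directly (an exact
    equivalent of explicit label shuffles).

    The default (tie-inclusive) p is valid but super-uniform: the Fisher
    statistic is discrete, so ties put atoms on a few p values.
    ``randomized=True`` breaks ties uniformly, which is exactly
    Uniform(0, 1) under the null — use it for calibration checks, not for
    decisions.
    """
    trait = _validate_trait(trait)
    presence = np.asarray(presence, dtype=bool)
    n = len(trait)
    n_present = int(presence.sum())
    n_trait = int(trait.sum())
    if n_present in (0, n):
        return 1.0
    table = _fisher_p_for_tp(n, n_present, n_trait)
    observed = table[int(np.count_nonzero(presence & trait))]
    rng = substream(seed, "gwas_empirical")
    draws = rng.hypergeometric(n_present, n - n_present, n_trait, size=n_permutations)
    perm_ps = table[draws]
    if randomized:
        n_less = int(np.count_nonzero(perm_ps < observed - 1e-12))
        n_tied = int(np.count_nonzero(np.abs(perm_ps - observed) <= 1e-12))
        u = rng.uniform()
        return (n_less + u * (1 + n_tied)) / (n_permutations + 1)
    count = int(np.count_nonzero(perm_ps <= observed + 1e-12))
    return (1 + count) / (n_permutations + 1)


def select_specific_genes(matrix: PresenceAbsenceMatrix, trait: dict[str, int] | np.ndarray,
                          sens_min: float = 70.0, spec_min: float = 70.0,
                          alpha: float = 0.05, adjust: str = "bh",
                          n_permutations: int = 1000, seed: int = 0
                          ) -> list[AssociationResult]:
    """Score every family against one trait and call trait-specific genes.

    Constant families are excluded before multiplicity correction; the
    adjusted p used in the decision is BH (default) or Bonferroni, both are
    reported.  Decision: sens > sens_min, spec > spec_min, and naive,
    adjusted, and empirical p all < alpha (strict inequalities).
    """
    if adjust not in ("bh", "bonferroni"):
        raise InputError(f"unknown adjustment {adjust!r}")
    if isinstance(trait, dict):
        missing = [g for g in matrix.genomes if g not in trait]
        if missing:
            raise InputError(f"genomes without trait value: {missing}")
        trait_vec = np.array([bool(trait[g]) for g in matrix.genomes])
    else:
        trait_vec = np.asarray(trait, dtype=bool)
    trait_vec = _validate_trait(trait_vec)

    results = [score_family(matrix.values[:, j], trait_vec, family=fam)
               for j, fam in enumerate(matrix.families)]
    tested = [r for r in results if not r.flagged]
    if tested:
        naive = np.array([r.p_naive for r in tested])
        bh = false_discovery_control(naive, method="bh")
        bonf = np.minimum(1.0, len(tested) * naive)
        for r, p_bh, p_bonf in zip(tested, bh, bonf):
            r.p_bh = float(p_bh)
            r.p_bonferroni = float(p_bonf)
    for j, r in enumerate(results):
        if r.flagged:
            continue
        r.p_empirical = empirical_p(matrix.values[:, matrix.families.index(r.family)],
                                    trait_vec, n_permutations=n_permutations,
                                    seed=seed + j)
        p_adj = r.p_bh if adjust == "bh" else r.p_bonferroni
        r.specific = (r.sensitivity > sens_min and r.specificity > spec_min
                      and r.p_naive < alpha and p_adj < alpha
                      and r.p_empirical < alpha)
    return results
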