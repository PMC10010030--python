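"""Pan-genome construction, core/accessory partitioning, accumulation
curves, and gene-content (Jaccard) distances."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from hostflux.errors import InputError
from hostflux.rng import substream

__all__ = [
    "PresenceAbsenceMatrix",
    "PanPartition",
    "build_presence_matrix",
    "partition_core_accessory",
    "pan_accumulation",
    "jaccard_distances",
]


@dataclass
class PresenceAbsenceMatrix:
    """Boolean genomes × gene-families table.

    Invariants: unique genome and family ids; every family present in at
    least one genome.
    """

    genomes: list[str]
    families: list[str]
    values: np.ndarray  # bool, shape (n_genomes, n_families)
    provenance: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if len(set(self.genomes)) != len(self.genomes):
            raise InputError("duplicate genome id in presence/absence matrix")
        if len(set(self.families)) != len(self.families):
            raise InputError("duplicate family id in presence/absence matrix")
        if self.values.shape != (len(self.genomes), len(self.families)):
            raise InputError("presence/absence matrix shape mismatch")
        if self.values.size and not self.values.any(axis=0).all():
            raise InputError("every family must be present in at least one genome")

    def prevalence(self) -> np.ndarray:
        """Per-family fraction of genomes carrying the family."""
        return self.values.mean(axis=0)

    def family_sets(self) -> dict[str, set[str]]:
        fams = np.array(self.families)
        return {g: set(fams[row]) for g, row in zip(self.genomes, self.values)}

    def subset_families(self, keep: list[str]) -> "PresenceAbsenceMatrix":
        index = {f: i for i, f in enumerate(self.families)}
        cols = [index[f] for f in keep]
        return PresenceAbsenceMatrix(self.genomes, list(keep), self.values[:, cols],
                                     provenance=self.provenance)


@dataclass
class PanPartition:
    """Core / accessory / singleton split of the family universe."""

    core: list[str]
    accessory: list[str]
    singleton: list[str]
    core_threshold: float

    def __post_init__(self) -> None:
        groups = [set(self.core), set(self.accessory), set(self.singleton)]
        total = sum(len(g) for g in groups)
        if len(set().union(*groups)) != total:
            raise InputError("pan partition groups overlap")

    @property
    def all_families(self) -> set[str]:
        return set(self.core) | set(self.accessory) | set(self.singleton)


def build_presence_matrix(per_genome_families: dict[str, list[str]],
                          provenance: str = "") -> PresenceAbsenceMatrix:
    """Assemble a matrix from per-genome family lists.

    Families are the sorted union across genomes; genome order follows the
    input mapping.
    """
    if not per_genome_families:
        raise InputError("no genomes given")
    genomes = list(per_genome_families)
    if len(set(genomes)) != len(genomes):
        raise InputError("duplicate genome id")
    families = sorted(set().union(*map(set, per_genome_families.values())))
    index = {f: i for i, f in enumerate(families)}
    values = np.zeros((len(genomes), len(families)), dtype=bool)
    for i, genome in enumerate(genomes):
        for fam in per_genome_families[genome]:
            values[i, index[fam]] = True
    return PresenceAbsenceMatrix(genomes, families, values, provenance=provenance)


def partition_core_accessory(matrix: PresenceAbsenceMatrix,
                             core_threshold: float = 0.95) -> PanPartition:
    """Partition families by prevalence.

    Core: prevalence strictly above ``core_threshold``.  Singleton: present
    in exactly one genome.  Accessory: everything else (present in more than
    one genome but not above the core threshold).
    """
    if not 0.0 < core_threshold < 1.0:
        raise InputError("core_threshold must be in (0, 1)")
    counts = matrix.values.sum(axis=0)
    n = len(matrix.genomes)
    core, accessory, singleton = [], [], []
    for fam, count in zip(matrix.families, counts):
        if count / n > core_threshold:
            core.append(fam)
        elif count == 1:
            singleton.append(fam)
        else:
            accessory.append(fam)
    return PanPartition(core, accessory, singleton, core_threshold)


def pan_accumulation(matrix: PresenceAbsenceMatrix, n_permutations: int = 100,
                     seed: int = 0) -> dict:
    """Mean pan-genome accumulation curve with a Heaps-law fit.

    Genomes are added in ``n_permutations`` random orders; the mean
    cumulative number of distinct families n(N) is fit as κ·N^γ by least
    squares on log–log scale.  The pan-genome is called open iff γ > 0.
    """
    n = len(matrix.genomes)
    if n < 3:
        raise InputError("pan_accumulation requires at least 3 genomes")
    rng = substream(seed, "pan_accumulation")
    curves = np.zeros((n_permutations, n))
    for p in range(n_permutations):
        order = rng.permutation(n)
        seen = np.zeros(len(matrix.families), dtype=bool)
        for step, g in enumerate(order):
            seen |= matrix.values[g]
            curves[p, step] = seen.sum()
    mean_curve = curves.mean(axis=0)
    ns = np.arange(1, n + 1)
    slope, intercept = np.polyfit(np.log(ns), np.log(np.maximum(mean_curve, 1e-300)), 1)
    return {
        "curve": mean_curve,
        "kappa": float(np.exp(intercept)),
        "gamma": float(slope),
        "open": bool(slope > 0),
    }


def jaccard_distances(matrix: PresenceAbsenceMatrix, basis: list[str] | None = None,
                      mode: str = "standard") -> tuple[list[str], np.ndarray]:
    """Pairwise gene-content distances over a family basis.

    ``standard``: JD = 1 − |A∩B| / |A∪B| (0 for two empty sets).
    ``paper_literal``: JD = 1 − |A∩B| / |A Δ B|, the formula as printed in
    the source study; it is not a metric, can be negative, and is defined
    as 0 when the symmetric difference is empty.  ``standard`` is the
    default used downstream.
    """
    if mode not in ("standard", "paper_literal"):
        raise InputError(f"unknown Jaccard mode {mode!r}")
    sub = matrix if basis is None else matrix.subset_families(basis)
    if not sub.families:
        raise InputError("empty family basis for Jaccard distances")
    values = sub.values.astype(np.int64)
    inter = values @ values.T
    sizes = values.sum(axis=1)
    union = sizes[:, None] + sizes[None, :] - inter
    n = len(sub.genomes)
    out = np.zeros((n, n))
    if mode == "standard":
        with np.errstate(invalid="ignore", divide="ignore"):
            out = 1.0 - np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    else:
        sym_diff = union - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(sym_diff > 0, 1.0 - inter / np.maximum(sym_diff, 1), 0.0)
    np.fill_diagonal(out, 0.0)
    return list(sub.genomes), out
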