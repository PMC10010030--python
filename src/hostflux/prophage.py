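"""Directional prophage sharing between lineages.

Prophage sequences are filtered (≥ 5 kb and carrying viral genes, or no
bacterial genes at all), then shared fractions are counted per directed
lineage pair: a query prophage counts if it shares a maximal exact common
substring longer than the fragment floor with any subject sequence.  Exact
substring detection uses seed windows plus extension, which is equivalent
to (and tested against) a quadratic dynamic-programming longest-common-
substring oracle.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from hostflux.errors import InputError
from hostflux.simulate import Prophage

__all__ = [
    "ExchangeMatrix",
    "filter_prophages",
    "shares_fragment",
    "directed_shared_fraction",
    "exchange_summary",
]

MIN_LENGTH = 5000


@dataclass
class ExchangeMatrix:
    lineages: list[str]
    percentages: np.ndarray          # directed lineage × lineage; NaN diagonal
    retained_counts: dict[str, int]  # lineage → retained prophage count
    intra_percent: dict[str, float]  # lineage → mean within-lineage sharing
    intra_inter_ratio: float         # may be inf when no inter-lineage sharing

    def edge_list(self) -> list[tuple[str, str, float]]:
        rows = []
        for i, a in enumerate(self.lineages):
            for j, b in enumerate(self.lineages):
                if i != j and np.isfinite(self.percentages[i, j]):
                    rows.append((a, b, float(self.percentages[i, j])))
        return rows


def filter_prophages(prophages: list[Prophage], min_length: int = MIN_LENGTH
                     ) -> tuple[list[Prophage], list[dict]]:
    """Retention filter: keep sequences of at least ``min_length`` bp that
    carry ≥ 1 viral gene or no bacterial genes at all.  Returns the
    retained list and a discard log with reasons."""
    retained, discarded = [], []
    for p in prophages:
        if p.length < min_length:
            discarded.append({"id": p.id, "reason": "short"})
            continue
        has_viral = "viral" in p.gene_labels
        has_bacterial = "bacterial" in p.gene_labels
        if has_bacterial and not has_viral:
            discarded.append({"id": p.id, "reason": "bacterial-only"})
            continue
        retained.append(p)
    return retained, discarded


def shares_fragment(query: str, subject: str, min_fragment: int = MIN_LENGTH) -> bool:
    """True iff ``query`` and ``subject`` share an exact common substring
    strictly longer than ``min_fragment``.

    Seed windows of width w at stride s with w + s ≤ min_fragment + 1
    guarantee every qualifying common substring contains a full window;
    each window hit is extended to its maximal exact match.
    """
    target = min_fragment + 1
    if len(query) < target or len(subject) < target:
        return False
    w = target // 2
    s = target - w
    for qpos in range(0, len(query) - w + 1, s):
        window = query[qpos:qpos + w]
        spos = subject.find(window)
        while spos != -1:
            left = 0
            while qpos - left - 1 >= 0 and spos - left - 1 >= 0 and \
                    query[qpos - left - 1] == subject[spos - left - 1]:
                left += 1
            right = w
            while qpos + right < len(query) and spos + right < len(subject) and \
                    query[qpos + right] == subject[spos + right]:
                right += 1
            if left + right >= target:
                return True
            spos = subject.find(window, spos + 1)
    return False


def directed_shared_fraction(queries: list[Prophage], subjects: list[Prophage],
                             min_fragment: int = MIN_LENGTH) -> float:
    """Percentage of query prophages with a > ``min_fragment`` exact match
    in the subject set."""
    if not queries:
        raise InputError("empty query set for directed sharing")
    if not subjects:
        return 0.0
    counted = 0
    for q in queries:
        if any(shares_fragment(q.sequence, s.sequence, min_fragment) for s in subjects):
            counted += 1
    return 100.0 * counted / len(queries)


def exchange_summary(prophage_sets: dict[str, list[Prophage]],
                     lineages: dict[str, str],
                     min_fragment: int = MIN_LENGTH) -> ExchangeMatrix:
    """Directed lineage × lineage sharing matrix and intra/inter ratio.

    Inter-lineage entries pool each lineage's retained prophages as queries
    against another lineage's pool.  Intra-lineage sharing is computed per
    genome against all other genomes of its lineage, then averaged.  The
    summary ratio is mean intra over mean inter (infinite when no
    inter-lineage sharing is observed).
    """
    missing = [g for g in prophage_sets if g not in lineages]
    if missing:
        raise InputError(f"genomes without lineage: {missing}")
    retained: dict[str, list[Prophage]] = {}
    for genome, plist in prophage_sets.items():
        retained[genome], _ = filter_prophages(plist, min_fragment)
    by_lineage: dict[str, list[str]] = {}
    for genome in sorted(prophage_sets):
        by_lineage.setdefault(lineages[genome], []).append(genome)
    lineage_names = sorted(by_lineage)
    if len(lineage_names) < 2:
        raise InputError("exchange_summary requires at least 2 lineages")

    pools = {lin: [p for g in by_lineage[lin] for p in retained[g]]
             for lin in lineage_names}
    n = len(lineage_names)
    matrix = np.full((n, n), np.nan)
    for i, a in enumerate(lineage_names):
        for j, b in enumerate(lineage_names):
            if i == j:
                continue
            if not pools[a]:
                continue  # undefined, stays NaN
            matrix[i, j] = directed_shared_fraction(pools[a], pools[b], min_fragment)

    intra: dict[str, float] = {}
    for lin in lineage_names:
        per_genome = []
        for genome in by_lineage[lin]:
            own = retained[genome]
            others = [p for g in by_lineage[lin] if g != genome for p in retained[g]]
            if not own or not others:
                continue  # within-lineage sharing undefined without a partner
            per_genome.append(directed_shared_fraction(own, others, min_fragment))
        if per_genome:
            intra[lin] = float(np.mean(per_genome))

    inter_values = matrix[~np.isnan(matrix) & ~np.eye(n, dtype=bool)]
    mean_intra = float(np.mean(list(intra.values()))) if intra else 0.0
    mean_inter = float(inter_values.mean()) if inter_values.size else 0.0
    if mean_inter == 0.0:
        ratio = math.inf if mean_intra > 0 else float("nan")
    else:
        ratio = mean_intra / mean_inter
    return ExchangeMatrix(
        lineages=lineage_names,
        percentages=matrix,
        retained_counts={lin: len(pools[lin]) for lin in lineage_names},
        intra_percent=intra,
        intra_inter_ratio=ratio,
    )
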