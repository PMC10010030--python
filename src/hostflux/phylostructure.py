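"""Sequence-level distances, recombination screening, distance-based trees
with bootstrap, and lineage delineation.

The recombination screen is a pairwise homoplasy index (PHI) with a
site-permutation p-value; lineage delineation operationalizes the bimodal
intra- vs inter-lineage distance split via a kernel-density valley and
single-linkage clustering.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import dendropy
import numpy as np
from scipy.cluster.hierarchy import linkage
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import squareform
from scipy.stats import gaussian_kde
from skbio import DistanceMatrix as SkbioDistanceMatrix
from skbio.tree import nj as skbio_nj

from hostflux.errors import InputError
from hostflux.rng import substream
from hostflux.tree import Tree

__all__ = [
    "Alignment",
    "PhiResult",
    "snp_distances",
    "core_identity",
    "phi_recombination_test",
    "concatenate_recombination_free",
    "distance_tree",
    "delineate_lineages",
]

_VALID = frozenset(b"ACGT")


@dataclass
class Alignment:
    """Equal-length nucleotide rows with per-column partition labels."""

    ids: list[str]
    rows: list[str]
    partitions: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise InputError("alignment ids and rows differ in count")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise InputError("ragged alignment: rows differ in length")
        self.rows = [r.upper() for r in self.rows]
        if not self.partitions:
            self.partitions = [""] * self.length
        if len(self.partitions) != self.length:
            raise InputError("partition labels must cover every column")

    @classmethod
    def from_dict(cls, seqs: dict[str, str], partition: str = "") -> "Alignment":
        ids = list(seqs)
        rows = [seqs[i] for i in ids]
        length = len(rows[0]) if rows else 0
        return cls(ids, rows, [partition] * length)

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def matrix(self) -> np.ndarray:
        """Byte matrix (n_sequences × n_columns)."""
        return np.frombuffer("".join(self.rows).encode("ascii"),
                             dtype=np.uint8).reshape(len(self.rows), -1)


@dataclass
class PhiResult:
    statistic: float
    p_value: float
    n_informative: int
    testable: bool


def _valid_mask(matrix: np.ndarray) -> np.ndarray:
    mask = np.zeros(matrix.shape, dtype=bool)
    for base in _VALID:
        mask |= matrix == base
    return mask


def snp_distances(alignment: Alignment) -> tuple[list[str], np.ndarray]:
    """Pairwise count of columns where both rows carry unambiguous,
    differing bases; gaps, N and other ambiguity codes are ignored."""
    if len(alignment.ids) < 2:
        raise InputError("snp_distances requires at least 2 sequences")
    matrix = alignment.matrix()
    valid = _valid_mask(matrix)
    n = len(alignment.ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            out[i, j] = out[j, i] = int(np.count_nonzero((matrix[i] != matrix[j]) & both))
    return list(alignment.ids), out


def core_identity(alignment: Alignment) -> tuple[list[str], np.ndarray, list[tuple[str, str]]]:
    """Percent identity over comparable (both-unambiguous) columns.

    Diagonal is 100.  Pairs with zero comparable columns get NaN and are
    returned in the flagged list.
    """
    if len(alignment.ids) < 2:
        raise InputError("core_identity requires at least 2 sequences")
    matrix = alignment.matrix()
    valid = _valid_mask(matrix)
    n = len(alignment.ids)
    out = np.full((n, n), 100.0)
    flagged: list[tuple[str, str]] = []
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            comparable = int(np.count_nonzero(both))
            if comparable == 0:
                out[i, j] = out[j, i] = np.nan
                flagged.append((alignment.ids[i], alignment.ids[j]))
                continue
            matches = int(np.count_nonzero((matrix[i] == matrix[j]) & both))
            out[i, j] = out[j, i] = 100.0 * matches / comparable
    return list(alignment.ids), out, flagged


# ---------------------------------------------------------------------- #
# PHI recombination screen
# ---------------------------------------------------------------------- #

def _informative_sites(matrix: np.ndarray, valid: np.ndarray) -> tuple[np.ndarray, list[np.ndarray]]:
    """Columns with ≥ 2 alleles each carried by ≥ 2 sequences.

    Returns (positions, per-site integer codes with −1 for missing).
    """
    positions = []
    codes = []
    for col in range(matrix.shape[1]):
        column = matrix[:, col]
        ok = valid[:, col]
        alleles, counts = np.unique(column[ok], return_counts=True)
        if np.count_nonzero(counts >= 2) >= 2:
            code = np.full(len(column), -1, dtype=np.int64)
            for k, allele in enumerate(alleles):
                code[(column == allele) & ok] = k
            positions.append(col)
            codes.append(code)
    return np.asarray(positions, dtype=np.int64), codes


def _incompatibility(code_a: np.ndarray, code_b: np.ndarray) -> int:
    """Extra homoplasy count for a site pair: distinct joint haplotypes in
    excess of (alleles_a + alleles_b − 1); 0 means compatible."""
    both = (code_a >= 0) & (code_b >= 0)
    if not both.any():
        return 0
    a = code_a[both]
    b = code_b[both]
    n_a = len(np.unique(a))
    n_b = len(np.unique(b))
    joint = len(np.unique(a * (b.max() + 1) + b))
    return max(0, joint - (n_a + n_b - 1))


def phi_recombination_test(alignment: Alignment, window: int = 100,
                           n_permutations: int = 100, seed: int = 0) -> PhiResult:
    """Pairwise homoplasy index with a site-permutation p-value.

    The statistic is the mean incompatibility score over pairs of
    parsimony-informative sites whose alignment positions are within
    ``window`` bp.  The null distribution permutes which informative-site
    pattern sits at which position; p = (1 + #{perm ≤ observed}) /
    (n_permutations + 1).  Genes with fewer than 2 informative sites are
    non-testable and return p = 1.
    """
    if len(alignment.ids) < 4:
        raise InputError("phi_recombination_test requires at least 4 sequences")
    matrix = alignment.matrix()
    valid = _valid_mask(matrix)
    positions, codes = _informative_sites(matrix, valid)
    m = len(positions)
    if m < 2:
        return PhiResult(statistic=0.0, p_value=1.0, n_informative=m, testable=False)

    # score matrix over informative sites
    scores = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            scores[i, j] = scores[j, i] = _incompatibility(codes[i], codes[j])

    pairs_a, pairs_b = np.nonzero(
        (np.abs(positions[:, None] - positions[None, :]) <= window) & ~np.eye(m, dtype=bool))
    keep = pairs_a < pairs_b
    pairs_a, pairs_b = pairs_a[keep], pairs_b[keep]
    if len(pairs_a) == 0:
        return PhiResult(statistic=0.0, p_value=1.0, n_informative=m, testable=False)
    observed = float(scores[pairs_a, pairs_b].mean())

    rng = substream(seed, "phi_permutation")
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(m)
        stat = float(scores[perm[pairs_a], perm[pairs_b]].mean())
        if stat <= observed + 1e-12:
            count += 1
    p = (1 + count) / (n_permutations + 1)
    return PhiResult(statistic=observed, p_value=p, n_informative=m, testable=True)


def concatenate_recombination_free(genes: dict[str, Alignment],
                                   phi: dict[str, PhiResult],
                                   alpha: float = 0.05,
                                   trim_fraction: float = 0.5) -> Alignment:
    """Concatenate genes whose PHI p ≥ alpha, trimming columns that are
    gap or N in ≥ ``trim_fraction`` of rows."""
    if not genes:
        raise InputError("no gene alignments given")
    passed = [g for g in genes if phi[g].p_value >= alpha]
    if not passed:
        raise InputError("all genes rejected by the recombination screen")
    ids = list(genes[passed[0]].ids)
    pieces: list[np.ndarray] = []
    partitions: list[str] = []
    for gene in passed:
        aln = genes[gene]
        if list(aln.ids) != ids:
            order = {name: k for k, name in enumerate(aln.ids)}
            try:
                rows = [aln.rows[order[name]] for name in ids]
            except KeyError as exc:
                raise InputError(f"gene {gene} is missing sequence {exc}") from exc
            aln = Alignment(ids, rows, list(aln.partitions))
        matrix = aln.matrix()
        bad = ~_valid_mask(matrix)
        keep = bad.mean(axis=0) < trim_fraction
        pieces.append(matrix[:, keep])
        partitions.extend([gene] * int(keep.sum()))
    combined = np.concatenate(pieces, axis=1)
    rows = ["".join(map(chr, row)) for row in combined]
    return Alignment(ids, rows, partitions)


# ---------------------------------------------------------------------- #
# distance trees
# ---------------------------------------------------------------------- #

def _check_square(labels: Sequence[str], matrix: np.ndarray) -> None:
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (len(labels), len(labels)):
        raise InputError("distance matrix shape does not match labels")
    if not np.allclose(matrix, matrix.T, atol=1e-12):
        raise InputError("distance matrix is not symmetric")


def distance_tree(labels: list[str], matrix: np.ndarray, method: str = "upgma",
                  outgroup: Optional[str] = None,
                  bootstrap_alignment: Optional[Alignment] = None,
                  n_bootstrap: int = 0, seed: int = 0) -> Tree:
    """UPGMA (rooted, ultrametric) or NJ (outgroup-rooted) tree from a
    distance matrix, with optional column-resampling bootstrap support.

    Bootstrap replicates resample alignment columns, recompute SNP
    distances, rebuild with the same method, and score each internal
    bipartition as the percentage of replicates containing it.
    """
    if len(labels) < 3:
        raise InputError("distance_tree requires at least 3 labels")
    _check_square(labels, matrix)
    tree = _build_tree(labels, np.asarray(matrix, dtype=float), method, outgroup)
    tree.relabel_internal()
    if bootstrap_alignment is not None and n_bootstrap > 0:
        _add_bootstrap_support(tree, bootstrap_alignment, method, outgroup,
                               n_bootstrap, seed)
    return tree


def _build_tree(labels: list[str], matrix: np.ndarray, method: str,
                outgroup: Optional[str]) -> Tree:
    if method == "upgma":
        link = linkage(squareform(matrix, checks=False), method="average")
        return Tree.from_scipy_linkage(link, labels)
    if method == "nj":
        dm = SkbioDistanceMatrix(matrix, ids=labels)
        newick = str(skbio_nj(dm).root_at_midpoint()) if outgroup is None else None
        if outgroup is not None:
            if outgroup not in labels:
                raise InputError(f"outgroup {outgroup!r} not among labels")
            raw = str(skbio_nj(dm))
            dtree = dendropy.Tree.get(data=raw, schema="newick",
                                      preserve_underscores=True)
            node = dtree.find_node_with_taxon_label(outgroup)
            edge_len = node.edge.length or 0.0
            dtree.reroot_at_edge(node.edge, length1=edge_len / 2.0,
                                 length2=edge_len / 2.0,
                                 update_bipartitions=False)
            newick = dtree.as_string(schema="newick", suppress_rooting=True)
        return Tree.from_newick(newick)
    raise InputError(f"unknown tree method {method!r}")


def _add_bootstrap_support(tree: Tree, alignment: Alignment, method: str,
                           outgroup: Optional[str], n_bootstrap: int, seed: int) -> None:
    rng = substream(seed, "tree_bootstrap")
    matrix = alignment.matrix()
    valid = _valid_mask(matrix)
    counts: dict[frozenset[str], int] = {}
    n_cols = matrix.shape[1]
    for _ in range(n_bootstrap):
        cols = rng.integers(0, n_cols, size=n_cols)
        sub = matrix[:, cols]
        sub_valid = valid[:, cols]
        dist = _pairwise_snp(sub, sub_valid)
        rep = _build_tree(list(alignment.ids), dist, method, outgroup)
        for split in rep.bipartitions():
            counts[split] = counts.get(split, 0) + 1
    below: dict = {}
    all_tips = set(tree.tip_names())
    anchor = min(all_tips)
    for node in tree.postorder():
        if node.is_leaf:
            below[node] = {node.name}
            continue
        clade = set().union(*(below[c] for c in node.children))
        below[node] = clade
        if node is tree.root:
            continue
        side = clade if anchor not in clade else all_tips - clade
        if len(side) >= 2 and len(all_tips) - len(side) >= 2:
            node.support = 100.0 * counts.get(frozenset(side), 0) / n_bootstrap


def _pairwise_snp(matrix: np.ndarray, valid: np.ndarray) -> np.ndarray:
    n = matrix.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            both = valid[i] & valid[j]
            out[i, j] = out[j, i] = np.count_nonzero((matrix[i] != matrix[j]) & both)
    return out


# ---------------------------------------------------------------------- #
# lineage delineation
# ---------------------------------------------------------------------- #

def delineate_lineages(labels: list[str], matrix: np.ndarray,
                       threshold: Optional[float] = None,
                       min_cluster: int = 4) -> tuple[dict[str, str], float]:
    """Split genomes into lineages from a bimodal pairwise-distance matrix.

    The threshold is the kernel-density minimum between the two largest
    modes of the pairwise distances (or an explicit override); lineages are
    single-linkage connected components of pairs below the threshold.
    Components smaller than ``min_cluster`` are labelled ``unassigned``.
    """
    _check_square(labels, matrix)
    values = squareform(np.asarray(matrix, dtype=float), checks=False)
    if len(values) == 0:
        raise InputError("need at least 2 genomes")
    if threshold is None:
        if np.ptp(values) <= 0:
            raise InputError("degenerate distances (all equal); "
                             "provide an explicit threshold")
        kde = gaussian_kde(values)
        grid = np.linspace(values.min(), values.max(), 512)
        density = kde(grid)
        interior = (density[1:-1] > density[:-2]) & (density[1:-1] >= density[2:])
        peaks = np.nonzero(interior)[0] + 1
        if density[0] > density[1]:
            peaks = np.concatenate([[0], peaks])
        if density[-1] > density[-2]:
            peaks = np.concatenate([peaks, [len(grid) - 1]])
        if len(peaks) < 2:
            raise InputError("pairwise distance distribution is unimodal; "
                             "provide an explicit threshold")
        top2 = peaks[np.argsort(density[peaks])[-2:]]
        lo, hi = sorted(top2)
        valley = lo + int(np.argmin(density[lo:hi + 1]))
        threshold = float(grid[valley])
    adjacency = np.asarray(matrix) < threshold
    np.fill_diagonal(adjacency, True)
    n_comp, assignment = connected_components(adjacency, directed=False)
    out: dict[str, str] = {}
    sizes = np.bincount(assignment, minlength=n_comp)
    label_counter = 0
    comp_label: dict[int, str] = {}
    for idx, genome in enumerate(labels):
        comp = assignment[idx]
        if sizes[comp] < min_cluster:
            out[genome] = "unassigned"
            continue
        if comp not in comp_label:
            label_counter += 1
            comp_label[comp] = f"L{label_counter}"
        out[genome] = comp_label[comp]
    return out, float(threshold)
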