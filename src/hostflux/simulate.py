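"""Synthetic data generation for the whole pipeline.

Generates every input the analysis consumes — an ultrametric host phylogeny
with a Markov host-switch process, gene-family content evolved by
gain/loss/innovation, clock-like core-gene alignments with optional
recombination mosaics, prophage repertoires exchanged preferentially within
lineages, and a bimodal adhesion assay — together with a ground-truth event
log (:class:`TruthLog`) that replays exactly to the simulated tip states.

All draws derive from ``SimulationConfig.seed`` through per-operation
substreams, so a fixed config is byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from hostflux.errors import ConfigurationError, InputError
from hostflux.rng import substream
from hostflux.tree import Node, Tree

__all__ = [
    "SimulationConfig",
    "TruthLog",
    "Prophage",
    "simulate_host_phylogeny",
    "simulate_gene_content",
    "simulate_two_state_content",
    "replay_gene_content",
    "simulate_core_alignment",
    "simulate_prophage_repertoires",
    "simulate_adhesion_assay",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class SimulationConfig:
    """Parameters of the synthetic world.

    Rates are per unit tree time; the simulated tree is scaled to unit
    height, so e.g. ``clock_rate`` is substitutions per site over the whole
    root-to-tip span when set to 1.0.
    """

    n_genomes: int = 40
    n_lineages: int = 4
    host_labels: tuple[str, ...] = ("rodent", "bird", "human", "pig", "primate", "herbivore")
    root_host: str = "rodent"
    host_switch_rate: float = 0.5
    root_family_count: int = 800
    gain_rate: float = 0.1
    loss_rate: float = 0.3
    innovation_rate: float = 30.0
    clock_rate: float = 0.05
    n_core_genes: int = 20
    gene_length: int = 400
    recombination_fraction: float = 0.0
    prophage_within_rate: float = 20.0
    prophage_between_rate: float = 1.0
    adhesion_high_mean: float = 7.6
    adhesion_low_mean: float = 6.0
    adhesion_sd: float = 0.3
    lineage_separation: float = 0.7
    seed: int = 0

    def validate(self) -> None:
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError("seed must be an integer")
        if self.n_genomes < 3:
            raise ConfigurationError("n_genomes must be >= 3")
        if self.n_lineages < 1 or self.n_lineages > self.n_genomes:
            raise ConfigurationError("n_lineages must be in [1, n_genomes]")
        if self.root_host not in self.host_labels:
            raise ConfigurationError("root_host must be one of host_labels")
        if len(set(self.host_labels)) != len(self.host_labels) or not self.host_labels:
            raise ConfigurationError("host_labels must be non-empty and unique")
        for name in ("host_switch_rate", "gain_rate", "loss_rate", "innovation_rate",
                     "clock_rate", "prophage_within_rate", "prophage_between_rate",
                     "adhesion_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if not 0.0 <= self.recombination_fraction <= 1.0:
            raise ConfigurationError("recombination_fraction must be in [0, 1]")
        if not 0.5 <= self.lineage_separation < 1.0:
            raise ConfigurationError("lineage_separation must be in [0.5, 1)")
        if self.root_family_count < 1:
            raise ConfigurationError("root_family_count must be >= 1")
        if self.gene_length < 50:
            raise ConfigurationError("gene_length must be >= 50")
        if self.n_core_genes < 1:
            raise ConfigurationError("n_core_genes must be >= 1")

    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass
class TruthLog:
    """Ground-truth event log; replaying it from the root reproduces tips."""

    lineages: dict[str, str] = field(default_factory=dict)
    host_switches: list[dict] = field(default_factory=list)
    gene_events: list[dict] = field(default_factory=list)
    root_families: list[str] = field(default_factory=list)
    recombination: list[dict] = field(default_factory=list)
    prophage_transfers: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class Prophage:
    """One prophage sequence of a genome, with per-gene viral/bacterial calls."""

    id: str
    sequence: str
    gene_labels: list[str]

    @property
    def length(self) -> int:
        return len(self.sequence)


# ---------------------------------------------------------------------- #
# host phylogeny
# ---------------------------------------------------------------------- #

def simulate_host_phylogeny(config: SimulationConfig) -> tuple[Tree, TruthLog]:
    """Pure-birth ultrametric tree with a CTMC host-switch process.

    The tree is scaled to unit height.  Node split times are warped so the
    oldest ``n_lineages - 1`` splits fall near the root and the remainder
    near the tips (controlled by ``lineage_separation``), which induces the
    deep clade structure the lineage-delineation stage assumes.  Lineages
    are the ``n_lineages`` oldest clades.
    """
    config.validate()
    rng = substream(config.seed, "host_phylogeny")
    n = config.n_genomes

    # Yule process: split times and topology.
    root = Node()
    left, right = Node(), Node()
    root.add_child(left)
    root.add_child(right)
    active: list[tuple[Node, float]] = [(left, 0.0), (right, 0.0)]
    t = 0.0
    while len(active) < n:
        k = len(active)
        t += rng.exponential(1.0 / k)
        idx = rng.integers(k)
        parent, _ = active.pop(idx)
        a, b = Node(), Node()
        parent.add_child(a)
        parent.add_child(b)
        parent._split_time = t  # type: ignore[attr-defined]
        active.append((a, t))
        active.append((b, t))
    root._split_time = 0.0  # type: ignore[attr-defined]
    height = t + rng.exponential(1.0 / n)

    # Normalize split times to [0, 1); tips at 1.
    def norm(x: float) -> float:
        return x / height

    # Warp: the oldest n_lineages-1 splits into [0, 1-sep]; the rest into [sep, 1).
    sep = config.lineage_separation
    ordered = sorted(norm(getattr(node, "_split_time")) for node in _internal(root))
    k_deep = config.n_lineages - 1
    cut = ordered[k_deep - 1] if k_deep >= 1 else 0.0
    deep_max = max(cut, 1e-12)

    def warp(x: float) -> float:
        if config.n_lineages <= 1:
            return x
        if x <= cut + 1e-15:
            return (1.0 - sep) * (x / deep_max) if k_deep > 1 else 0.0
        span = max(1.0 - cut, 1e-12)
        return sep + (1.0 - sep) * (x - cut) / span * (1.0 - 1e-6)

    for node in _internal(root):
        node.age = 1.0 - warp(norm(getattr(node, "_split_time")))
    for node, _ in active:
        node.age = 0.0

    tree = Tree(root)
    # Deterministic naming: tips g001.. in preorder, internal n1.. in preorder.
    counter = 1
    for node in tree.preorder():
        if node.is_leaf:
            node.name = f"g{counter:03d}"
            counter += 1
    tree.relabel_internal()
    for node in tree.preorder():
        if node is not root:
            node.length = node.parent.age - node.age
            if node.length < 0:
                raise AssertionError("negative branch length in simulated tree")

    truth = TruthLog()

    # Lineages: the n_lineages clades rooted by the children of deep splits.
    lineage_roots: list[Node] = []

    def collect(node: Node) -> None:
        if node.is_leaf or node.age < sep - 1e-9:
            lineage_roots.append(node)
            return
        for child in node.children:
            collect(child)

    if config.n_lineages == 1:
        lineage_roots = [root]
    else:
        collect(root)
    for i, lin_root in enumerate(sorted(lineage_roots, key=lambda nd: nd.name or ""), start=1):
        label = f"L{i}"
        stack = [lin_root]
        while stack:
            node = stack.pop()
            node.lineage = label
            stack.extend(node.children)
            if node.is_leaf:
                truth.lineages[node.name] = label

    # Host-switch CTMC along branches (preorder).
    labels = list(config.host_labels)
    root.host = config.root_host
    for node in tree.preorder():
        if node is root:
            continue
        state = node.parent.host
        elapsed = 0.0
        length = node.length or 0.0
        while True:
            if config.host_switch_rate <= 0:
                break
            elapsed += rng.exponential(1.0 / config.host_switch_rate)
            if elapsed >= length:
                break
            others = [h for h in labels if h != state]
            new = others[rng.integers(len(others))] if others else state
            truth.host_switches.append({
                "branch": node.name, "from": state, "to": new,
                "age": node.parent.age - elapsed,
            })
            state = new
        node.host = state

    return tree, truth


def _internal(root: Node):
    stack = [root]
    while stack:
        node = stack.pop()
        if node.children:
            yield node
            stack.extend(node.children)


# ---------------------------------------------------------------------- #
# gene content
# ---------------------------------------------------------------------- #

def _evolve_families(present: np.ndarray, length: float, gain: float, loss: float,
                     rng: np.random.Generator,
                     start: Optional[np.ndarray] = None) -> tuple[np.ndarray, list[tuple[int, float, str]]]:
    """Two-state Gillespie for many families on one branch.

    ``start`` gives a per-family entry time on the branch (used for
    innovations created mid-branch).  Returns end states and
    ``(family index, event time, 'gain'|'loss')`` events sorted by time.
    """
    state = present.copy()
    clock = np.zeros(len(state)) if start is None else start.astype(float).copy()
    events: list[tuple[int, float, str]] = []
    while True:
        rate = np.where(state, loss, gain)
        alive = (rate > 0) & (clock < length)
        if not alive.any():
            break
        waits = np.full(len(state), np.inf)
        waits[alive] = rng.exponential(1.0 / rate[alive])
        clock = clock + np.where(np.isfinite(waits), waits, 0.0)
        clock[~alive] = np.maximum(clock[~alive], length)
        flip = alive & (clock < length)
        for idx in np.nonzero(flip)[0]:
            events.append((int(idx), float(clock[idx]), "loss" if state[idx] else "gain"))
        state[flip] = ~state[flip]
        clock[alive & ~flip] = length
    events.sort(key=lambda e: e[1])
    return state, events


def simulate_gene_content(tree: Tree, config: SimulationConfig
                          ) -> tuple[list[str], list[str], np.ndarray, TruthLog]:
    """Evolve gene-family presence/absence along ``tree``.

    Root families may be lost (``loss_rate``) and regained (``gain_rate``);
    new families arise by innovation (``innovation_rate`` per unit time) and
    are Dollo-like: confined to the subtree below their origin.  Returns
    ``(genome ids, family ids, genomes × families boolean matrix, truth)``
    restricted to families present in at least one tip.
    """
    config.validate()
    rng = substream(config.seed, "gene_content")
    truth = TruthLog()
    n_root = config.root_family_count
    families = [f"fam{i + 1:05d}" for i in range(n_root)]
    truth.root_families = list(families)
    counter = n_root

    # per-node presence over the running family universe
    root_state = np.ones(n_root, dtype=bool)
    states: dict[Node, np.ndarray] = {tree.root: root_state}

    for node in tree.preorder():
        if node is tree.root:
            continue
        parent_state = states[node.parent]
        length = node.length or 0.0
        # pad to current universe size
        state = np.zeros(len(families), dtype=bool)
        state[: len(parent_state)] = parent_state
        tracked = np.ones(len(state), dtype=bool)
        # innovations from sibling subtrees are not regainable here: a family
        # is available only if it is a root family or present at the parent
        tracked[: n_root] = True
        tracked[n_root:] = state[n_root:]
        idx_tracked = np.nonzero(tracked)[0]
        sub_state, sub_events = _evolve_families(
            state[idx_tracked], length, config.gain_rate, config.loss_rate, rng)
        new_events = [(int(idx_tracked[i]), t, kind) for i, t, kind in sub_events]

        # innovation of brand-new families along this branch
        n_new = rng.poisson(config.innovation_rate * length) if length > 0 else 0
        innov_times = np.sort(rng.uniform(0.0, length, size=n_new))
        innov_ids: list[int] = []
        for t0 in innov_times:
            counter += 1
            families.append(f"fam{counter:05d}")
            innov_ids.append(len(families) - 1)
            new_events.append((len(families) - 1, float(t0), "innovation"))
        if innov_ids:
            inn_state, inn_events = _evolve_families(
                np.ones(len(innov_ids), dtype=bool), length,
                0.0, config.loss_rate, rng, start=innov_times.copy())
            # innovations can be lost (and, once lost, regained only below
            # via gain_rate on later branches)
            for i, t, kind in inn_events:
                new_events.append((innov_ids[i], t, kind))
        new_events.sort(key=lambda e: e[1])

        final = np.zeros(len(families), dtype=bool)
        final[idx_tracked] = sub_state
        if innov_ids:
            final[np.array(innov_ids)] = inn_state
        states[node] = final
        for fam_idx, t, kind in new_events:
            truth.gene_events.append({
                "branch": node.name, "family": families[fam_idx],
                "kind": kind, "time": t,
            })
        # grow recorded states lazily: other subtrees keep shorter vectors

    tips = tree.tips()
    genomes = [t.name for t in tips]
    matrix = np.zeros((len(genomes), len(families)), dtype=bool)
    for i, tip in enumerate(tips):
        vec = states[tip]
        matrix[i, : len(vec)] = vec
    keep = matrix.any(axis=0)
    kept_families = [f for f, k in zip(families, keep) if k]
    return genomes, kept_families, matrix[:, keep], truth


def replay_gene_content(tree: Tree, truth: TruthLog, tip: str) -> set[str]:
    """Independent replay of the gene-event log along the root-to-tip path."""
    target = tree.find(tip)
    path = []
    node = target
    while node is not None:
        path.append(node)
        node = node.parent
    path.reverse()
    events_by_branch: dict[str, list[dict]] = {}
    for ev in truth.gene_events:
        events_by_branch.setdefault(ev["branch"], []).append(ev)
    present = set(truth.root_families)
    for node in path[1:]:
        for ev in sorted(events_by_branch.get(node.name, []), key=lambda e: e["time"]):
            if ev["kind"] in ("gain", "innovation"):
                present.add(ev["family"])
            else:
                present.discard(ev["family"])
    return present


# ---------------------------------------------------------------------- #
# core alignments
# ---------------------------------------------------------------------- #

def simulate_core_alignment(tree: Tree, config: SimulationConfig
                            ) -> tuple[dict[str, dict[str, str]], TruthLog]:
    """Clock-like core-gene alignments under a Jukes–Cantor-style process.

    Each of ``n_core_genes`` genes evolves site-independently at
    ``clock_rate`` substitutions/site/unit-time.  A ``recombination_fraction``
    Bernoulli draw per gene transplants a contiguous half-gene segment from a
    donor tip of one lineage into an acceptor tip of another, producing a
    mosaic; donors and acceptors are logged.
    """
    config.validate()
    if config.clock_rate < 0:
        raise ConfigurationError("clock_rate must be >= 0")
    rng = substream(config.seed, "core_alignment")
    length = config.gene_length
    truth = TruthLog()
    genes: dict[str, dict[str, str]] = {}
    lineage_of = {t.name: t.lineage for t in tree.tips()}
    lineages = sorted({v for v in lineage_of.values() if v is not None})

    for g in range(config.n_core_genes):
        gene_id = f"gene{g + 1:04d}"
        root_seq = rng.integers(0, 4, size=length, dtype=np.int8)
        seqs: dict[Node, np.ndarray] = {tree.root: root_seq}
        for node in tree.preorder():
            if node is tree.root:
                continue
            t = node.length or 0.0
            p_change = 0.75 * (1.0 - np.exp(-4.0 / 3.0 * config.clock_rate * t))
            parent_seq = seqs[node.parent]
            hit = rng.random(length) < p_change
            child_seq = parent_seq.copy()
            if hit.any():
                shift = rng.integers(1, 4, size=int(hit.sum()), dtype=np.int8)
                child_seq[hit] = (child_seq[hit] + shift) % 4
            seqs[node] = child_seq

        tip_seqs = {t.name: seqs[t] for t in tree.tips()}
        if len(lineages) >= 2 and rng.random() < config.recombination_fraction:
            donor_lin, acceptor_lin = rng.choice(len(lineages), size=2, replace=False)
            donor_lin, acceptor_lin = lineages[donor_lin], lineages[acceptor_lin]
            donors = sorted(n for n, l in lineage_of.items() if l == donor_lin)
            acceptors = sorted(n for n, l in lineage_of.items() if l == acceptor_lin)
            donor = donors[rng.integers(len(donors))]
            acceptor = acceptors[rng.integers(len(acceptors))]
            seg_len = length // 2
            start = int(rng.integers(0, length - seg_len + 1))
            tip_seqs[acceptor] = tip_seqs[acceptor].copy()
            tip_seqs[acceptor][start:start + seg_len] = tip_seqs[donor][start:start + seg_len]
            truth.recombination.append({
                "gene": gene_id, "donor": donor, "acceptor": acceptor,
                "start": start, "end": start + seg_len,
            })
        genes[gene_id] = {name: _decode(seq) for name, seq in sorted(tip_seqs.items())}
    return genes, truth


def _decode(codes: np.ndarray) -> str:
    return _BASES[codes].tobytes().decode("ascii")


def expected_p_distance(rate: float, time_distance: float) -> float:
    """Closed-form expected proportion of differing sites under the
    simulation's substitution process for two tips separated by
    ``time_distance``."""
    return 0.75 * (1.0 - np.exp(-4.0 / 3.0 * rate * time_distance))


def simulate_two_state_content(tree: Tree, gain: float, loss: float,
                               n_families: int, seed: int
                               ) -> tuple[list[str], np.ndarray]:
    """Presence/absence evolved as a plain two-state CTMC from a stationary
    root, conditioned on presence in at least one tip.

    This is the exact generative counterpart of the gain/loss likelihood
    model and is used for parameter-recovery checks.  Returns
    ``(genome ids, genomes × families boolean matrix)``.
    """
    if gain <= 0 or loss < 0:
        raise ConfigurationError("gain must be > 0 and loss >= 0")
    rng = substream(seed, "two_state_content")
    nodes = list(tree.preorder())
    tips = tree.tips()
    pi1 = gain / (gain + loss) if gain + loss > 0 else 1.0
    out = np.zeros((len(tips), 0), dtype=bool)
    blocks = []
    need = n_families
    while need > 0:
        batch = max(need * 2, 64)
        states: dict[Node, np.ndarray] = {tree.root: rng.random(batch) < pi1}
        for node in nodes:
            if node is tree.root:
                continue
            t = node.length or 0.0
            s = gain + loss
            e = np.exp(-s * t)
            p11 = (gain + loss * e) / s
            p01 = gain * (1 - e) / s
            parent = states[node.parent]
            prob = np.where(parent, p11, p01)
            states[node] = rng.random(batch) < prob
        tip_matrix = np.stack([states[t] for t in tips], axis=0)
        observed = tip_matrix[:, tip_matrix.any(axis=0)]
        blocks.append(observed)
        need -= observed.shape[1]
    matrix = np.concatenate(blocks, axis=1)[:, :n_families]
    return [t.name for t in tips], matrix


# ---------------------------------------------------------------------- #
# prophages
# ---------------------------------------------------------------------- #

def _random_prophage(rng: np.random.Generator, pid: str, min_len: int = 6000,
                     max_len: int = 15000, viral: bool = True) -> Prophage:
    length = int(rng.integers(min_len, max_len + 1))
    seq = _decode(rng.integers(0, 4, size=length, dtype=np.int8))
    n_genes = max(1, length // 1000)
    if viral:
        labels = ["viral" if rng.random() < 0.6 else "bacterial" for _ in range(n_genes)]
        if "viral" not in labels:
            labels[0] = "viral"
    else:
        labels = ["bacterial"] * n_genes
    return Prophage(id=pid, sequence=seq, gene_labels=labels)


def simulate_prophage_repertoires(tree: Tree, lineages: dict[str, str],
                                  config: SimulationConfig
                                  ) -> tuple[dict[str, list[Prophage]], TruthLog]:
    """Per-genome prophage sets with within- vs between-lineage transfer.

    Each genome starts with 1–2 private prophages (6–15 kb, ≥1 viral gene).
    Poisson numbers of transfer events copy a whole prophage from a donor to
    a recipient — within one lineage at ``prophage_within_rate`` and across
    lineages at ``prophage_between_rate`` — so every transferred pair shares
    an exact fragment above the 5-kb detection floor.  Decoy sequences
    (short, or bacterial-gene-only) are added to exercise the retention
    filter.
    """
    config.validate()
    genomes = sorted(lineages)
    if set(lineages) != set(tree.tip_names()):
        raise InputError("lineage labels must cover exactly the tree tips")
    rng = substream(config.seed, "prophages")
    truth = TruthLog(lineages=dict(lineages))
    sets: dict[str, list[Prophage]] = {}
    counter = 0
    for genome in genomes:
        own = []
        for _ in range(int(rng.integers(1, 3))):
            counter += 1
            own.append(_random_prophage(rng, f"ph{counter:04d}"))
        if rng.random() < 0.4:  # short decoy
            counter += 1
            own.append(Prophage(
                id=f"ph{counter:04d}",
                sequence=_decode(rng.integers(0, 4, size=int(rng.integers(1000, 4999)),
                                              dtype=np.int8)),
                gene_labels=["viral"],
            ))
        if rng.random() < 0.3:  # bacterial-only decoy
            counter += 1
            own.append(_random_prophage(rng, f"ph{counter:04d}", 6000, 9000, viral=False))
        sets[genome] = own

    by_lineage: dict[str, list[str]] = {}
    for genome, lin in lineages.items():
        by_lineage.setdefault(lin, []).append(genome)
    for lin in by_lineage:
        by_lineage[lin].sort()
    lineage_names = sorted(by_lineage)

    def do_transfer(donor: str, recipient: str, within: bool) -> None:
        nonlocal counter
        candidates = [p for p in sets[donor] if p.length >= 6000 and "viral" in p.gene_labels]
        if not candidates:
            return
        src = candidates[rng.integers(len(candidates))]
        counter += 1
        copy = Prophage(id=f"ph{counter:04d}", sequence=src.sequence,
                        gene_labels=list(src.gene_labels))
        sets[recipient].append(copy)
        truth.prophage_transfers.append({
            "donor": donor, "recipient": recipient,
            "donor_prophage": src.id, "new_prophage": copy.id,
            "within_lineage": within,
            "shared_length": src.length,
        })

    n_within = rng.poisson(config.prophage_within_rate)
    for _ in range(n_within):
        eligible = [l for l in lineage_names if len(by_lineage[l]) >= 2]
        if not eligible:
            break
        lin = eligible[rng.integers(len(eligible))]
        donor, recipient = rng.choice(len(by_lineage[lin]), size=2, replace=False)
        do_transfer(by_lineage[lin][donor], by_lineage[lin][recipient], within=True)

    n_between = rng.poisson(config.prophage_between_rate)
    for _ in range(n_between):
        if len(lineage_names) < 2:
            break
        i, j = rng.choice(len(lineage_names), size=2, replace=False)
        lin_a, lin_b = lineage_names[i], lineage_names[j]
        donor = by_lineage[lin_a][rng.integers(len(by_lineage[lin_a]))]
        recipient = by_lineage[lin_b][rng.integers(len(by_lineage[lin_b]))]
        do_transfer(donor, recipient, within=False)

    return sets, truth


# ---------------------------------------------------------------------- #
# adhesion assay
# ---------------------------------------------------------------------- #

REFERENCE_STRAIN = "reference-100-23"


def simulate_adhesion_assay(strains: list[str], groups: dict[str, str],
                            rodent_group: str, config: SimulationConfig) -> pd.DataFrame:
    """Log10 CFU/g adhesion table, bimodal by gene-content group.

    Strains of ``rodent_group`` draw from Normal(high mean, sd); all others
    from Normal(low mean, sd).  A fixed reference strain is appended at the
    high mean (the positive-control convention).
    """
    config.validate()
    missing = [s for s in strains if s not in groups]
    if missing:
        raise InputError(f"strains without group assignment: {missing}")
    rng = substream(config.seed, "adhesion")
    rows = []
    for strain in strains:
        mean = (config.adhesion_high_mean if groups[strain] == rodent_group
                else config.adhesion_low_mean)
        value = mean + config.adhesion_sd * rng.standard_normal()
        rows.append({"strain": strain, "group": groups[strain],
                     "log10_cfu_per_g": float(value)})
    rows.append({"strain": REFERENCE_STRAIN, "group": rodent_group,
                 "log10_cfu_per_g": float(config.adhesion_high_mean)})
    return pd.DataFrame(rows)
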