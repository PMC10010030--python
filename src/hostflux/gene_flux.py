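"""Ancestral gene-content reconstruction on a fixed tree.

Two routes: Fitch/Dollo parsimony per family, and a maximum-likelihood
two-state (absent/present) continuous-time Markov chain with per-branch-class
gain and loss rates, fitted by the pruning recursion with an ascertainment
correction for families unobservable when absent from every tip.  Marginal
ancestral presence probabilities, expected per-branch gain/loss events, and
per-node expected gene counts are derived from the fit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from hostflux.errors import InputError
from hostflux.rng import substream
from hostflux.tree import Node, Tree

__all__ = [
    "FluxReport",
    "OriginClassification",
    "parsimony_reconstruct",
    "ml_gain_loss_fit",
    "ancestral_content",
    "classify_specific_origins",
    "transition_matrix",
]


def transition_matrix(gain: float, loss: float, t: float) -> np.ndarray:
    """2×2 transition probabilities of the gain/loss chain over time ``t``
    (state 0 = absent, 1 = present)."""
    s = gain + loss
    if s <= 0 or t <= 0:
        return np.eye(2)
    e = np.exp(-s * t)
    return np.array([
        [(loss + gain * e) / s, (gain - gain * e) / s],
        [(loss - loss * e) / s, (gain + loss * e) / s],
    ])


# ---------------------------------------------------------------------- #
# parsimony
# ---------------------------------------------------------------------- #

def parsimony_reconstruct(tree: Tree, presence: dict[str, bool], mode: str = "fitch",
                          tie: str = "absent") -> dict:
    """Ancestral presence states and per-branch events for one family.

    Fitch: minimum-change state sets bottom-up, resolved top-down with ties
    broken toward ``tie`` (default absent, conservative against inflating
    the root genome).  Dollo: a single gain at the MRCA of the present tips
    and losses wherever a subtree under it carries no present tip.
    Returns ``{"states": name → 0/1, "events": [...], "length": changes}``.
    """
    tips = set(tree.tip_names())
    if set(presence) != tips:
        raise InputError("presence column tips do not match tree tips")
    if mode not in ("fitch", "dollo"):
        raise InputError(f"unknown parsimony mode {mode!r}")
    if tie not in ("absent", "present"):
        raise InputError("tie must be 'absent' or 'present'")

    states: dict[str, int] = {}
    events: list[dict] = []

    if mode == "fitch":
        sets: dict[Node, frozenset[int]] = {}
        length = 0
        for node in tree.postorder():
            if node.is_leaf:
                sets[node] = frozenset([int(presence[node.name])])
                continue
            inter = frozenset.intersection(*(sets[c] for c in node.children))
            if inter:
                sets[node] = inter
            else:
                sets[node] = frozenset.union(*(sets[c] for c in node.children))
                length += 1
        tie_state = 0 if tie == "absent" else 1
        for node in tree.preorder():
            options = sets[node]
            if node is tree.root:
                state = tie_state if len(options) > 1 else next(iter(options))
            else:
                parent_state = states[node.parent.name]
                if parent_state in options:
                    state = parent_state
                else:
                    state = tie_state if len(options) > 1 else next(iter(options))
            states[node.name] = state
        for node in tree.preorder():
            if node is tree.root:
                continue
            a, b = states[node.parent.name], states[node.name]
            if a != b:
                events.append({"branch": node.name,
                               "kind": "gain" if b > a else "loss"})
    else:  # dollo
        carriers = [name for name, v in presence.items() if v]
        if not carriers:
            raise InputError("Dollo reconstruction of an all-absent family")
        origin = tree.mrca(carriers) if len(carriers) > 1 else tree.find(carriers[0])
        has_carrier: dict[Node, bool] = {}
        for node in tree.postorder():
            if node.is_leaf:
                has_carrier[node] = bool(presence[node.name])
            else:
                has_carrier[node] = any(has_carrier[c] for c in node.children)
        in_subtree: dict[Node, bool] = {}
        for node in tree.preorder():
            if node is origin:
                in_subtree[node] = True
            elif node is tree.root:
                in_subtree[node] = False
            else:
                in_subtree[node] = in_subtree.get(node.parent, False)
        for node in tree.preorder():
            states[node.name] = int(in_subtree[node] and has_carrier[node])
        if origin is not tree.root:
            events.append({"branch": origin.name, "kind": "gain"})
        for node in tree.preorder():
            if node is tree.root or node is origin:
                continue
            if states[node.parent.name] == 1 and states[node.name] == 0:
                events.append({"branch": node.name, "kind": "loss"})
        length = len(events)

    return {"states": states, "events": events, "length": length}


# ---------------------------------------------------------------------- #
# maximum likelihood
# ---------------------------------------------------------------------- #

@dataclass
class FluxReport:
    families: list[str]
    rates: dict[str, tuple[float, float]]        # class → (gain, loss)
    log_likelihood: float
    branch_classes: dict[str, str]               # branch (child name) → class
    node_marginals: dict[str, np.ndarray]        # node name → (F,) P(present)
    expected_gains: dict[str, float]             # branch → expected gain events
    expected_losses: dict[str, float]
    node_expected_counts: dict[str, float]
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "rates": {c: list(map(float, r)) for c, r in self.rates.items()},
            "log_likelihood": float(self.log_likelihood),
            "expected_gains": {k: float(v) for k, v in self.expected_gains.items()},
            "expected_losses": {k: float(v) for k, v in self.expected_losses.items()},
            "node_expected_counts": {k: float(v) for k, v in self.node_expected_counts.items()},
            "converged": self.converged,
        }


def _branch_matrices(tree: Tree, rates: dict[str, tuple[float, float]],
                     classes: dict[str, str]) -> dict[str, np.ndarray]:
    out = {}
    for node in tree.postorder():
        if node is tree.root:
            continue
        gain, loss = rates[classes[node.name]]
        out[node.name] = transition_matrix(gain, loss, node.length or 0.0)
    return out

def _root_prior(rates: dict[str, tuple[float, float]], root_class: str) -> np.ndarray:
    gain, loss = rates[root_class]
    s = gain + loss
    if s <= 0:
        return np.array([0.5, 0.5])
    return np.array([loss / s, gain / s])


def _pruning(tree: Tree, data: np.ndarray, tips: list[str],
             matrices: dict[str, np.ndarray], pi: np.ndarray
             ) -> tuple[np.ndarray, dict[Node, np.ndarray]]:
    """Vectorized pruning: ``data`` is (F, n_tips) boolean in ``tips`` order.
    Returns per-family likelihoods and the per-node partial arrays."""
    tip_index = {name: i for i, name in enumerate(tips)}
    partials: dict[Node, np.ndarray] = {}
    for node in tree.postorder():
        if node.is_leaf:
            col = data[:, tip_index[node.name]]
            part = np.zeros((data.shape[0], 2))
            part[np.arange(len(col)), col.astype(int)] = 1.0
            partials[node] = part
            continue
        prod = np.ones((data.shape[0], 2))
        for child in node.children:
            prod *= partials[child] @ matrices[child.name].T
        partials[node] = prod
    lik = partials[tree.root] @ pi
    return lik, partials


def ml_gain_loss_fit(tree: Tree, genomes: list[str], families: list[str],
                     values: np.ndarray,
                     branch_classes: Optional[dict[str, str]] = None,
                     n_starts: int = 3, seed: int = 0,
                     compute_events: bool = True) -> FluxReport:
    """Fit per-branch-class gain/loss rates by maximum likelihood.

    The likelihood is conditioned on each family being present in at least
    one tip (pan-genome ascertainment).  The root prior is the stationary
    distribution of the root's branch class (``background`` if present,
    else the first class).  Raises on non-convergence of every restart,
    carrying the best incumbent in the exception.
    """
    if set(genomes) != set(tree.tip_names()):
        raise InputError("matrix genomes do not match tree tips")
    if not (np.asarray(values, dtype=bool).any(axis=0)).all():
        raise InputError("families absent from all tips cannot be fitted "
                         "(ascertainment)")
    tips = tree.tip_names()
    order = [genomes.index(name) for name in tips]
    # (F, n_tips) in tree tip order
    data = np.ascontiguousarray(np.asarray(values, dtype=bool)[order].T)

    if branch_classes is None:
        branch_classes = {n.name: "background" for n in tree.postorder()
                          if n is not tree.root}
    class_names = sorted(set(branch_classes.values()))
    root_class = "background" if "background" in class_names else class_names[0]
    missing = [n.name for n in tree.postorder()
               if n is not tree.root and n.name not in branch_classes]
    if missing:
        raise InputError(f"branches without class: {missing}")

    n_families = data.shape[0]
    rng = substream(seed, "ml_gain_loss")

    def unpack(params: np.ndarray) -> dict[str, tuple[float, float]]:
        rates = {}
        for i, cls in enumerate(class_names):
            rates[cls] = (float(np.exp(params[2 * i])), float(np.exp(params[2 * i + 1])))
        return rates

    absent_pattern = np.zeros((1, len(tips)), dtype=bool)

    def negloglik(params: np.ndarray) -> float:
        rates = unpack(params)
        matrices = _branch_matrices(tree, rates, branch_classes)
        pi = _root_prior(rates, root_class)
        lik, _ = _pruning(tree, data, tips, matrices, pi)
        p0, _ = _pruning(tree, absent_pattern, tips, matrices, pi)
        p0 = float(p0[0])
        if (lik <= 0).any() or p0 >= 1.0:
            return 1e12
        return -(np.log(lik).sum() - n_families * np.log1p(-p0))

    best = None
    converged = False
    for start in range(n_starts):
        if start == 0:
            x0 = np.log([0.5, 0.5] * len(class_names))
        else:
            x0 = rng.uniform(-3, 1, size=2 * len(class_names))
        res = minimize(negloglik, x0, method="L-BFGS-B",
                       bounds=[(-12.0, 6.0)] * (2 * len(class_names)))
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)
    rates = unpack(best.x)
    loglik = -float(best.fun)

    matrices = _branch_matrices(tree, rates, branch_classes)
    pi = _root_prior(rates, root_class)
    lik, partials = _pruning(tree, data, tips, matrices, pi)

    # outside (down) pass for marginals and branch joints
    down: dict[Node, np.ndarray] = {tree.root: np.broadcast_to(pi, (n_families, 2)).copy()}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        child_msgs = {c: partials[c] @ matrices[c.name].T for c in node.children}
        for child in node.children:
            msg = down[node].copy()
            for sib in node.children:
                if sib is not child:
                    msg *= child_msgs[sib]
            down[child] = msg @ matrices[child.name]

    node_marginals: dict[str, np.ndarray] = {}
    for node in tree.postorder():
        post = partials[node] * down[node]
        norm = post.sum(axis=1, keepdims=True)
        node_marginals[node.name] = (post[:, 1] / norm[:, 0]).astype(float)

    expected_gains: dict[str, float] = {}
    expected_losses: dict[str, float] = {}
    if compute_events:
        for node in tree.postorder():
            if node is tree.root:
                continue
            gain, loss = rates[branch_classes[node.name]]
            t = node.length or 0.0
            P = matrices[node.name]
            msg = down[node.parent].copy()
            for sib in node.parent.children:
                if sib is not node:
                    msg *= partials[sib] @ matrices[sib.name].T
            up_child = partials[node]
            # joint endpoint posterior per family: (F, 2 parent, 2 child)
            joint = msg[:, :, None] * P[None, :, :] * up_child[:, None, :]
            joint /= np.maximum(joint.sum(axis=(1, 2), keepdims=True), 1e-300)
            en_gain, en_loss = _expected_event_table(gain, loss, t)
            expected_gains[node.name] = float((joint * en_gain[None]).sum())
            expected_losses[node.name] = float((joint * en_loss[None]).sum())

    node_counts = {name: float(marg.sum()) for name, marg in node_marginals.items()}
    return FluxReport(families=list(families), rates=rates, log_likelihood=loglik,
                      branch_classes=dict(branch_classes),
                      node_marginals=node_marginals,
                      expected_gains=expected_gains,
                      expected_losses=expected_losses,
                      node_expected_counts=node_counts,
                      converged=converged)


def _expected_event_table(gain: float, loss: float, t: float,
                          n_grid: int = 33) -> tuple[np.ndarray, np.ndarray]:
    """E[#gains], E[#losses] on a branch of length ``t`` conditioned on the
    endpoint states, by numeric integration of the standard Markov-jump
    expectation: E[N_ab | x0=a', xt=b'] = rate · ∫ P(a'→a, s) P(b→b', t−s) ds
    / P(a'→b', t)."""
    en_gain = np.zeros((2, 2))
    en_loss = np.zeros((2, 2))
    if t <= 0 or gain + loss <= 0:
        return en_gain, en_loss
    grid = np.linspace(0.0, t, n_grid)
    Ps = np.stack([transition_matrix(gain, loss, s) for s in grid])          # P(0→s)
    Pr = np.stack([transition_matrix(gain, loss, t - s) for s in grid])      # P(s→t)
    Pt = transition_matrix(gain, loss, t)
    for a in (0, 1):
        for b in (0, 1):
            if Pt[a, b] <= 0:
                continue
            integrand_gain = Ps[:, a, 0] * Pr[:, 1, b]
            integrand_loss = Ps[:, a, 1] * Pr[:, 0, b]
            en_gain[a, b] = gain * np.trapezoid(integrand_gain, grid) / Pt[a, b]
            en_loss[a, b] = loss * np.trapezoid(integrand_loss, grid) / Pt[a, b]
    return en_gain, en_loss


def ancestral_content(report: FluxReport, tree: Tree, threshold: float = 0.5) -> dict:
    """Threshold marginal presence probabilities into per-node gene sets.

    Returns the root (LCA) family set, per-node gene counts, and whether
    the root count is below the mean tip count (genome expansion).
    """
    if not 0.0 <= threshold <= 1.0:
        raise InputError("threshold must be in [0, 1]")
    families = np.array(report.families)
    root_name = tree.root.name
    counts: dict[str, int] = {}
    for name, marg in report.node_marginals.items():
        counts[name] = int(np.count_nonzero(marg > threshold))
    root_set = sorted(families[report.node_marginals[root_name] > threshold])
    tip_counts = [counts[t] for t in tree.tip_names()]
    return {
        "root_families": root_set,
        "node_counts": counts,
        "root_count": counts[root_name],
        "mean_tip_count": float(np.mean(tip_counts)),
        "expansion": counts[root_name] < float(np.mean(tip_counts)),
    }


@dataclass
class OriginClassification:
    origins: dict[str, str]            # family → origin label
    tallies: dict[str, dict[str, int]] # lineage → origin label → count

    GAINED = "gained-on-lineage"
    RETAINED = "LCA-inherited-retained"
    PARTIAL = "LCA-inherited-partially-retained"


def classify_specific_origins(specific: dict[str, list[str]], report: FluxReport,
                              tree: Tree, tip_lineages: dict[str, str],
                              target_lineages: Optional[dict[str, set[str]]] = None,
                              threshold: float = 0.5) -> OriginClassification:
    """Classify each lineage-specific family by its evolutionary origin.

    ``gained-on-lineage``: absent at the root (marginal ≤ threshold), i.e.
    acquired during lineage evolution.  Families present at the root are
    LCA-inherited, subdivided by whether every target-clade lineage retains
    the family in at least one tip (``target_lineages`` maps each tested
    lineage to its clade; default is the lineage alone).
    """
    fam_index = {f: i for i, f in enumerate(report.families)}
    root_name = tree.root.name
    root_marg = report.node_marginals[root_name]
    tips_by_lineage: dict[str, list[str]] = {}
    for tip, lin in tip_lineages.items():
        tips_by_lineage.setdefault(lin, []).append(tip)
    origins: dict[str, str] = {}
    tallies: dict[str, dict[str, int]] = {}
    for lineage, fams in specific.items():
        tallies[lineage] = {OriginClassification.GAINED: 0,
                            OriginClassification.RETAINED: 0,
                            OriginClassification.PARTIAL: 0}
        targets = (target_lineages or {}).get(lineage, {lineage})
        for fam in fams:
            if fam not in fam_index:
                raise InputError(f"family {fam!r} absent from flux report")
            idx = fam_index[fam]
            if root_marg[idx] <= threshold:
                label = OriginClassification.GAINED
            else:
                retained = []
                for target in sorted(targets):
                    carried = any(report.node_marginals[t][idx] > threshold
                                  for t in tips_by_lineage.get(target, []))
                    retained.append(carried)
                label = (OriginClassification.RETAINED if all(retained)
                         else OriginClassification.PARTIAL)
            origins[fam] = label
            tallies[lineage][label] += 1
    return OriginClassification(origins=origins, tallies=tallies)
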