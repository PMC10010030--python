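"""Strict-clock dating and ancestral host-state reconstruction.

Dating is least-squares: node times minimize the squared deviation between
observed branch lengths (substitutions/site) and rate × elapsed time, with
contemporaneous tips at time 0 and either the root age or the rate supplied
as calibration.  Host states are reconstructed either by Fitch parsimony
(ambiguity retained) or by a maximum-likelihood asymmetric k-state CTMC
fitted with the pruning algorithm; host switches are the branches whose
endpoint modal states differ.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product
from typing import Optional

import numpy as np
from scipy.linalg import expm
from scipy.optimize import minimize

from hostflux.errors import InputError
from hostflux.rng import substream
from hostflux.tree import Node, Tree

__all__ = [
    "DatedTree",
    "HostHistory",
    "strict_clock_date",
    "ancestral_hosts",
    "enumerate_host_switches",
]


@dataclass
class DatedTree:
    tree: Tree                  # node.age in years before present; lengths in years
    rate: float                 # substitutions per site per year
    calibration: dict           # {"root_age": ...} or {"rate": ...}
    residual: float             # sum of squared branch-length deviations
    refit_constrained: bool     # True if the unconstrained solution was clipped


@dataclass
class HostHistory:
    states: list[str]
    node_probs: dict[str, np.ndarray]   # node name → probability vector
    modal: dict[str, str]
    ambiguous: list[str]                # nodes whose modal state was a tie
    rate_matrix: Optional[np.ndarray]   # fitted Q (CTMC model) or None
    log_likelihood: Optional[float]
    model: str


# ---------------------------------------------------------------------- #
# strict clock dating
# ---------------------------------------------------------------------- #

def strict_clock_date(tree: Tree, root_age: Optional[float] = None,
                      rate: Optional[float] = None) -> DatedTree:
    """Least-squares dating of a rooted tree with contemporaneous tips.

    Exactly one of ``root_age`` (fixes the root time; the rate is estimated
    jointly) or ``rate`` (converts branch lengths directly) must be given.
    Node times are constrained parent ≥ child ≥ 0; if the unconstrained
    optimum violates a constraint the constrained refit is flagged.
    """
    if (root_age is None) == (rate is None):
        raise InputError("give exactly one of root_age or rate")
    if len(tree.root.children) == 0:
        raise InputError("tree has no branches to date")
    work = tree.copy()
    names = [n.name for n in work.postorder()]
    if None in names or len(set(names)) != len(names):
        work.relabel_internal()
    internals = [n for n in work.postorder() if not n.is_leaf]
    index = {node: i for i, node in enumerate(internals)}
    depths = work.depths()
    height = max(depths[t] for t in work.tips())
    if height <= 0:
        raise InputError("tree has zero height; cannot date")

    edges: list[tuple[Node, Node, float]] = []
    for node in work.postorder():
        if node is not work.root:
            edges.append((node.parent, node, node.length or 0.0))

    def ages_of(x: np.ndarray) -> dict[Node, float]:
        ages = {node: 0.0 for node in work.tips()}
        for node, i in index.items():
            ages[node] = x[i]
        return ages

    fixed_rate = rate

    def objective(params: np.ndarray) -> float:
        if fixed_rate is not None:
            r = fixed_rate
            x = params
        else:
            r = params[-1]
            x = params[:-1]
        ages = ages_of(x)
        return sum((b - r * (ages[p] - ages[c])) ** 2 for p, c, b in edges)

    # init from the (scaled) depth solution — exact for clock-like input
    r0 = fixed_rate if fixed_rate is not None else height / root_age
    x0 = np.array([max((height - depths[n]) / r0, 0.0) for n in internals])

    constraints = []
    for parent, child, _ in edges:
        if child.is_leaf and parent in index:
            i = index[parent]
            constraints.append({"type": "ineq",
                                "fun": (lambda x, i=i: _age(x, i, fixed_rate))})
        elif parent in index and child in index:
            ip, ic = index[parent], index[child]
            constraints.append({"type": "ineq",
                                "fun": (lambda x, ip=ip, ic=ic:
                                        _age(x, ip, fixed_rate) - _age(x, ic, fixed_rate))})
    if root_age is not None:
        ir = index[work.root]
        constraints.append({"type": "eq",
                            "fun": (lambda x, ir=ir: _age(x, ir, fixed_rate) - root_age)})
        params0 = np.concatenate([x0, [r0]])
    else:
        params0 = x0

    res = minimize(objective, params0, method="SLSQP", constraints=constraints,
                   options={"maxiter": 500, "ftol": 1e-14})
    params = res.x
    if fixed_rate is not None:
        r_hat = fixed_rate
        x = params
    else:
        r_hat = float(params[-1])
        x = params[:-1]
    refit = False
    x = np.asarray(x, dtype=float)
    if (x < -1e-9).any():
        x = np.clip(x, 0.0, None)
        refit = True
    ages = ages_of(x)
    for node in work.postorder():
        node.age = float(ages[node]) if not node.is_leaf else 0.0
    for node in work.postorder():
        if node is work.root:
            continue
        span = node.parent.age - node.age
        if span < -1e-9:
            refit = True
            span = 0.0
        node.length = max(span, 0.0)
    residual = float(objective(params))
    calibration = ({"root_age": root_age} if root_age is not None else {"rate": rate})
    return DatedTree(tree=work, rate=r_hat, calibration=calibration,
                     residual=residual, refit_constrained=refit)


def _age(x: np.ndarray, i: int, fixed_rate: Optional[float]) -> float:
    # with joint rate estimation the rate is the trailing parameter
    return x[i]


# ---------------------------------------------------------------------- #
# ancestral host states
# ---------------------------------------------------------------------- #

def _fitch_sets(tree: Tree, labels: dict[str, str], states: list[str]) -> dict[str, set[str]]:
    sets: dict[Node, set[str]] = {}
    for node in tree.postorder():
        if node.is_leaf:
            sets[node] = {labels[node.name]}
            continue
        inter = set.intersection(*(sets[c] for c in node.children))
        sets[node] = inter if inter else set.union(*(sets[c] for c in node.children))
    return {node.name: sets[node] for node in tree.postorder()}


def ancestral_hosts(tree: Tree, labels: dict[str, str],
                    model: str = "ctmc_asymmetric", seed: int = 0,
                    n_starts: int = 2, state_order: Optional[list[str]] = None
                    ) -> HostHistory:
    """Reconstruct per-node host states.

    ``parsimony``: Fitch state sets with ambiguity retained (probability
    spread uniformly over the set).  ``ctmc_asymmetric``: k-state CTMC with
    independent off-diagonal rates fitted by maximum likelihood (pruning;
    root prior = stationary distribution of the fitted matrix, keeping the
    root state identifiable), marginals by the up–down algorithm.
    Modal-state ties are broken by the fixed host-state order and flagged.
    """
    tips = set(tree.tip_names())
    unlabelled = tips - set(labels)
    if unlabelled:
        raise InputError(f"unlabelled tips: {sorted(unlabelled)}")
    names = [n.name for n in tree.postorder()]
    if None in names or len(set(names)) != len(names):
        tree = tree.copy()
        tree.relabel_internal()
    states = state_order or sorted(set(labels[t] for t in tips))
    if len(states) < 1:
        raise InputError("no host states")
    k = len(states)
    state_index = {s: i for i, s in enumerate(states)}

    if model == "parsimony":
        sets = _fitch_sets(tree, labels, states)
        node_probs, modal, ambiguous = {}, {}, []
        for name, options in sets.items():
            vec = np.zeros(k)
            for s in options:
                vec[state_index[s]] = 1.0 / len(options)
            node_probs[name] = vec
            if len(options) > 1:
                ambiguous.append(name)
        # top-down refinement: keep the parent's state where allowed;
        # remaining ties break by the fixed state order
        for node in tree.preorder():
            options = sets[node.name]
            if node is tree.root or modal.get(node.parent.name) not in options:
                modal[node.name] = min(options, key=lambda s: state_index[s])
            else:
                modal[node.name] = modal[node.parent.name]
        return HostHistory(states=states, node_probs=node_probs, modal=modal,
                           ambiguous=sorted(ambiguous), rate_matrix=None,
                           log_likelihood=None, model="parsimony")
    if model != "ctmc_asymmetric":
        raise InputError(f"unknown model {model!r}")
    if k == 1:
        only = states[0]
        probs = {n.name: np.ones(1) for n in tree.postorder()}
        return HostHistory(states=states, node_probs=probs,
                           modal={n.name: only for n in tree.postorder()},
                           ambiguous=[], rate_matrix=np.zeros((1, 1)),
                           log_likelihood=0.0, model="ctmc_asymmetric")

    tip_data = {t: state_index[labels[t]] for t in tips}
    total_len = max(tree.total_branch_length(), 1e-9)
    off_diag = [(i, j) for i, j in product(range(k), repeat=2) if i != j]

    def stationary(q: np.ndarray) -> np.ndarray:
        # left null vector of Q with components summing to 1
        a = np.vstack([q.T, np.ones(k)])
        b = np.concatenate([np.zeros(k), [1.0]])
        pi, *_ = np.linalg.lstsq(a, b, rcond=None)
        pi = np.clip(pi, 1e-12, None)
        return pi / pi.sum()

    def build_q(params: np.ndarray) -> np.ndarray:
        q = np.zeros((k, k))
        for (i, j), p in zip(off_diag, params):
            q[i, j] = np.exp(p)
        np.fill_diagonal(q, -q.sum(axis=1))
        return q

    def matrices(q: np.ndarray) -> dict[str, np.ndarray]:
        cache: dict[float, np.ndarray] = {}
        out = {}
        for node in tree.postorder():
            if node is tree.root:
                continue
            t = float(node.length or 0.0)
            if t not in cache:
                cache[t] = expm(q * t)
            out[node.name] = cache[t]
        return out

    def pruning(mats: dict[str, np.ndarray], pi: np.ndarray
                ) -> tuple[float, dict[Node, np.ndarray]]:
        partials: dict[Node, np.ndarray] = {}
        for node in tree.postorder():
            if node.is_leaf:
                vec = np.zeros(k)
                vec[tip_data[node.name]] = 1.0
                partials[node] = vec
                continue
            prod = np.ones(k)
            for child in node.children:
                prod *= mats[child.name] @ partials[child]
            partials[node] = prod
        lik = float(pi @ partials[tree.root])
        return lik, partials

    def negloglik(params: np.ndarray) -> float:
        q = build_q(params)
        lik, _ = pruning(matrices(q), stationary(q))
        if lik <= 0 or not np.isfinite(lik):
            return 1e12
        return -np.log(lik)

    rng = substream(seed, "ancestral_hosts")
    base_rate = np.log(max(1.0 / total_len, 1e-6))
    best = None
    for start in range(n_starts):
        if start == 0:
            x0 = np.full(len(off_diag), base_rate)
        else:
            x0 = base_rate + rng.uniform(-1.5, 1.5, size=len(off_diag))
        res = minimize(negloglik, x0, method="L-BFGS-B",
                       bounds=[(-15.0, 8.0)] * len(off_diag))
        if best is None or res.fun < best.fun:
            best = res
    q = build_q(best.x)
    mats = matrices(q)
    pi = stationary(q)
    lik, partials = pruning(mats, pi)

    down: dict[Node, np.ndarray] = {tree.root: pi.copy()}
    for node in tree.preorder():
        if node.is_leaf:
            continue
        child_msgs = {c: mats[c.name] @ partials[c] for c in node.children}
        for child in node.children:
            msg = down[node].copy()
            for sib in node.children:
                if sib is not child:
                    msg *= child_msgs[sib]
            down[child] = msg @ mats[child.name]

    node_probs, modal, ambiguous = {}, {}, []
    for node in tree.postorder():
        post = partials[node] * down[node]
        total = post.sum()
        vec = post / total if total > 0 else np.full(k, 1.0 / k)
        node_probs[node.name] = vec
        top = np.nonzero(np.isclose(vec, vec.max(), rtol=0, atol=1e-12))[0]
        modal[node.name] = states[int(top[0])]
        if len(top) > 1:
            ambiguous.append(node.name)
    return HostHistory(states=states, node_probs=node_probs, modal=modal,
                       ambiguous=sorted(ambiguous), rate_matrix=q,
                       log_likelihood=float(np.log(lik)), model="ctmc_asymmetric")


def enumerate_host_switches(history: HostHistory, tree: Tree) -> list[dict]:
    """Branches whose endpoint modal states differ, oldest first.

    Each row: from/to states and the [parent age, child age] interval in
    which the switch occurred (ages taken from the tree's annotations when
    present).
    """
    rows = []
    for node in tree.preorder():
        if node is tree.root:
            continue
        a = history.modal[node.parent.name]
        b = history.modal[node.name]
        if a != b:
            rows.append({
                "branch": node.name,
                "from": a,
                "to": b,
                "age_interval": [node.parent.age, node.age],
            })
    rows.sort(key=lambda r: (-(r["age_interval"][0] if r["age_interval"][0] is not None else 0.0),
                             r["branch"]))
    return rows
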