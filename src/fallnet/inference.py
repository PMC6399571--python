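"""Exact inference: variable elimination, a joint-enumeration oracle, and
the per-window daily fall-risk query.

Variable elimination uses a min-degree elimination order on the moralized
evidence-reduced graph, ties broken by node declaration order. Missing
window evidence is simply marginalized — never imputed: absence of an
observation is treated as "unobserved", which is exactly what conditioning
on the available evidence alone gives.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .bayesnet import BayesNet, DataError

__all__ = [
    "InconsistentEvidenceError",
    "RiskPrediction",
    "posterior",
    "joint_enumerate",
    "joint_distribution",
    "daily_risk",
]


class InconsistentEvidenceError(ValueError):
    """Evidence configuration has zero probability under the network."""


@dataclass(frozen=True)
class RiskPrediction:
    """Posterior probability of the fall state for one daily window."""

    admission_id: str
    window_index: int
    risk: float
    evidence_coverage: int


# ---------------------------------------------------------------------------
# factors: (names tuple, ndarray with one axis per name)


def _cpt_factor(net: BayesNet, node: str) -> tuple[tuple[str, ...], np.ndarray]:
    spec = net.nodes[node]
    names = spec.parents + (node,)
    cards = tuple(net.nodes[n].n_states for n in names)
    arr = net.cpts[node].table.reshape(cards)
    return names, arr


def _reduce(names, arr, evidence: Mapping[str, int]):
    idx = tuple(
        evidence[n] if n in evidence else slice(None) for n in names
    )
    kept = tuple(n for n in names if n not in evidence)
    return kept, arr[idx]


def _multiply(f1, f2):
    n1, a1 = f1
    n2, a2 = f2
    names = n1 + tuple(n for n in n2 if n not in n1)
    # broadcast both to the union axis set
    a1b = a1.reshape(a1.shape + (1,) * (len(names) - len(n1)))
    shape2 = [a2.shape[n2.index(n)] if n in n2 else 1 for n in names]
    src = [n for n in names if n in n2]
    a2t = np.transpose(a2, [n2.index(n) for n in src]).reshape(shape2)
    return names, a1b * a2t


def _sum_out(f, name):
    names, arr = f
    ax = names.index(name)
    return tuple(n for n in names if n != name), arr.sum(axis=ax)


def _elimination_order(net: BayesNet, factors, keep: set[str]) -> list[str]:
    # min-degree on the factor interaction graph; ties by declaration order
    decl = {n: i for i, n in enumerate(net.nodes)}
    neighbors: dict[str, set[str]] = {}
    for names, _ in factors:
        for a in names:
            neighbors.setdefault(a, set()).update(n for n in names if n != a)
    todo = {n for n in neighbors if n not in keep}
    order = []
    while todo:
        pick = min(todo, key=lambda n: (len(neighbors[n] & todo), decl[n]))
        order.append(pick)
        todo.remove(pick)
        nbrs = neighbors[pick] - {pick}
        for a in nbrs:
            neighbors[a] |= nbrs - {a}
            neighbors[a].discard(pick)
    return order


def posterior(
    net: BayesNet,
    evidence: Mapping[str, str],
    query: str,
) -> np.ndarray:
    """Exact posterior ``Pr(query | evidence)`` by variable elimination.

    ``evidence`` maps node names to observed states; unmentioned nodes are
    unobserved. If the query node itself is observed the result is a point
    mass on its observed state.
    """
    net.require_fitted()
    if query not in net.nodes:
        raise DataError(f"unknown query node {query!r}")
    ev = net.encode(evidence)
    nq = net.nodes[query].n_states
    if query in ev:
        out = np.zeros(nq)
        out[ev[query]] = 1.0
        return out

    factors = []
    for node in net.nodes:
        names, arr = _cpt_factor(net, node)
        names, arr = _reduce(names, arr, ev)
        if names:
            factors.append((names, arr))
        else:  # fully observed factor: a scalar likelihood weight
            factors.append(((), arr))

    for victim in _elimination_order(net, [f for f in factors if f[0]], {query}):
        bucket = [f for f in factors if victim in f[0]]
        rest = [f for f in factors if victim not in f[0]]
        prod = bucket[0]
        for f in bucket[1:]:
            prod = _multiply(prod, f)
        rest.append(_sum_out(prod, victim))
        factors = rest

    result = ((), np.array(1.0))
    for f in factors:
        result = _multiply(result, f) if f[0] else (result[0], result[1] * f[1])
    names, arr = result
    if names != (query,):
        ax = names.index(query)
        arr = np.moveaxis(arr, ax, 0).reshape(nq, -1).sum(axis=1)
    total = arr.sum()
    if total <= 0:
        raise InconsistentEvidenceError(
            f"evidence {dict(evidence)!r} has zero probability"
        )
    return arr / total


def joint_distribution(
    net: BayesNet, nodes: Sequence[str], max_size: int = 2**20
) -> np.ndarray:
    """Exact joint marginal over ``nodes`` by full enumeration.

    Shape: one axis per requested node, in the given order. Intended as a
    test oracle and for small planted networks; refuses joint state spaces
    beyond ``max_size`` configurations.
    """
    net.require_fitted()
    all_nodes = net.node_names()
    size = 1
    for n in all_nodes:
        size *= net.nodes[n].n_states
        if size > max_size:
            raise DataError(
                f"joint state space exceeds {max_size} configurations"
            )
    joint = ((), np.array(1.0))
    for node in all_nodes:
        joint = _multiply(joint, _cpt_factor(net, node))
    names, arr = joint
    for n in names:
        if n not in nodes:
            names, arr = _sum_out((names, arr), n)
    perm = [names.index(n) for n in nodes]
    return np.transpose(arr, perm)


def joint_enumerate(
    net: BayesNet,
    evidence: Mapping[str, str],
    query: str,
    max_size: int = 2**20,
) -> np.ndarray:
    """Posterior of ``query`` by summing the fully expanded joint (oracle)."""
    ev = net.encode(evidence)
    if query in ev:
        out = np.zeros(net.nodes[query].n_states)
        out[ev[query]] = 1.0
        return out
    keep = [n for n in ev] + [query]
    marg = joint_distribution(net, keep, max_size=max_size)
    idx = tuple(ev[n] for n in ev) + (slice(None),)
    vec = marg[idx]
    total = vec.sum()
    if total <= 0:
        raise InconsistentEvidenceError(
            f"evidence {dict(evidence)!r} has zero probability"
        )
    return vec / total


def daily_risk(
    net: BayesNet,
    window,
    fall_node: str = "fall",
    positive_state: str = "yes",
    _cache: dict | None = None,
) -> RiskPrediction:
    """Posterior probability of a fall in one 24-hour window.

    All non-missing window evidence is conditioned on; missing variables
    are marginalized. The fall node is never accepted as evidence. A
    ``_cache`` dict keyed by the evidence items may be supplied to reuse
    posteriors across windows with identical evidence.
    """
    ev = {
        k: v
        for k, v in window.evidence.items()
        if k != fall_node and k in net.nodes and v is not None
    }
    key = tuple(sorted(ev.items()))
    if _cache is not None and key in _cache:
        p = _cache[key]
    else:
        vec = posterior(net, ev, fall_node)
        p = float(vec[net.nodes[fall_node].state_index(positive_state)])
        if _cache is not None:
            _cache[key] = p
    return RiskPrediction(
        admission_id=window.admission_id,
        window_index=window.window_index,
        risk=p,
        evidence_coverage=len(ev),
    )
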