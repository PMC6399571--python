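"""CPT learning: Dirichlet-weighted estimation from complete data, and
expectation-maximization when window evidence is missing.

Each CPT row is the weighted average of the empirical distribution in the
training data and a Dirichlet prior:

    p_hat = (n * P_D + n0 * theta) / (n + n0)

where ``P_D`` is the empirical frequency among the ``n`` training cases
matching the row's parent configuration, ``theta`` the prior distribution
over the node's states, and ``n0`` the equivalent sample size — the number
of past cases the prior is worth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import product
from typing import Sequence

import numpy as np
import pandas as pd

from .bayesnet import BayesNet, CPT, DataError

__all__ = [
    "DirichletPrior",
    "FitResult",
    "dirichlet_estimate",
    "fit_cpts",
    "fit_em",
    "encode_windows",
]


@dataclass(frozen=True)
class DirichletPrior:
    """Dirichlet prior: per-row distribution ``theta`` and weight ``n0``.

    ``theta=None`` means uniform over each node's states. ``n0`` may be 0
    (pure maximum likelihood; rows with no data then raise).
    """

    n0: float = 1.0
    theta: dict[str, np.ndarray] | None = None  # node -> (n_states,) vector

    def __post_init__(self) -> None:
        if self.n0 < 0:
            raise ValueError("n0 must be >= 0")

    def row(self, net: BayesNet, node: str) -> np.ndarray:
        k = net.nodes[node].n_states
        if self.theta is None or node not in self.theta:
            return np.full(k, 1.0 / k)
        vec = np.asarray(self.theta[node], dtype=float)
        if vec.shape != (k,) or not np.isclose(vec.sum(), 1.0, atol=1e-9):
            raise ValueError(f"prior theta for {node!r} is not a distribution")
        return vec


@dataclass
class FitResult:
    """A fitted network plus convergence diagnostics (EM only)."""

    net: BayesNet
    log_likelihoods: list[float] = field(default_factory=list)
    converged: bool = True
    n_iter: int = 0


def dirichlet_estimate(
    counts: Sequence[float], prior_row: Sequence[float], n0: float
) -> np.ndarray:
    """One CPT row: ``(counts + n0*theta) / (n + n0)`` with ``n = sum(counts)``.

    Equivalent to the convex combination ``(n*P_D + n0*theta)/(n+n0)`` of
    the empirical frequencies and the prior.
    """
    c = np.asarray(counts, dtype=float)
    t = np.asarray(prior_row, dtype=float)
    if c.shape != t.shape:
        raise ValueError("counts and prior_row must have the same length")
    if np.any(c < 0):
        raise ValueError("counts must be nonnegative")
    n = c.sum()
    if n + n0 <= 0:
        raise ValueError("undefined row: n = n0 = 0")
    return (c + n0 * t) / (n + n0)


def encode_windows(
    net: BayesNet,
    windows,
    fall_node: str = "fall",
    positive_state: str = "yes",
) -> np.ndarray:
    """Encode windows as an ``(n_windows, n_nodes)`` integer code matrix.

    Column order follows ``net.node_names()``; missing evidence is -1. The
    binary window label feeds the outcome node's column. Accepts a list of
    :class:`~fallnet.windowing.DailyWindow` or a DataFrame of state strings
    (one column per node, NaN/empty = missing).
    """
    names = net.node_names()
    if isinstance(windows, pd.DataFrame):
        n = len(windows)
        codes = np.full((n, len(names)), -1, dtype=np.int64)
        for j, name in enumerate(names):
            if name not in windows.columns:
                continue
            col = windows[name]
            lut = {s: i for i, s in enumerate(net.nodes[name].states)}
            mapped = col.map(lut)
            bad = col.notna() & (col != "") & mapped.isna()
            if bad.any():
                val = col[bad].iloc[0]
                raise DataError(
                    f"value {val!r} is not a state of node {name!r}"
                )
            codes[:, j] = mapped.fillna(-1).to_numpy(dtype=np.int64)
        return codes

    windows = list(windows)
    codes = np.full((len(windows), len(names)), -1, dtype=np.int64)
    col = {name: j for j, name in enumerate(names)}
    spec_index = {
        name: {s: i for i, s in enumerate(net.nodes[name].states)}
        for name in names
    }
    fall_states = net.nodes[fall_node].states if fall_node in net.nodes else None
    for i, w in enumerate(windows):
        for name, state in w.evidence.items():
            if name not in col or state is None:
                continue
            try:
                codes[i, col[name]] = spec_index[name][state]
            except KeyError:
                raise DataError(
                    f"value {state!r} is not a state of node {name!r}"
                ) from None
        if fall_states is not None:
            pos = net.nodes[fall_node].state_index(positive_state)
            codes[i, col[fall_node]] = pos if w.label else 1 - pos
    return codes


def _count_tables(net: BayesNet, codes: np.ndarray) -> dict[str, np.ndarray]:
    """Complete-data sufficient statistics: per-node (row, state) counts."""
    names = net.node_names()
    col = {name: j for j, name in enumerate(names)}
    out = {}
    for name in names:
        spec = net.nodes[name]
        k = spec.n_states
        rows = np.zeros(len(codes), dtype=np.intp)
        if spec.parents:
            cards = net.parent_cards(name)
            rows = np.ravel_multi_index(
                tuple(codes[:, col[p]] for p in spec.parents), cards
            )
        table = np.zeros((net.n_parent_configs(name), k))
        np.add.at(table, (rows, codes[:, col[name]]), 1.0)
        out[name] = table
    return out


def _estimate_from_counts(
    net: BayesNet, counts: dict[str, np.ndarray], prior: DirichletPrior
) -> dict[str, CPT]:
    cpts = {}
    for name, table in counts.items():
        theta = prior.row(net, name)
        fitted = np.empty_like(table)
        for r in range(table.shape[0]):
            fitted[r] = dirichlet_estimate(table[r], theta, prior.n0)
        cpts[name] = CPT(name, fitted)
    return cpts


def fit_cpts(
    skeleton: BayesNet,
    windows,
    prior: DirichletPrior | None = None,
    fall_node: str = "fall",
) -> BayesNet:
    """Fit every CPT from complete labeled windows.

    Raises :class:`DataError` if any window has a missing value for a
    schema variable — use :func:`fit_em` for incomplete data.
    """
    prior = prior or DirichletPrior()
    codes = encode_windows(skeleton, windows, fall_node=fall_node)
    if codes.size and (codes < 0).any():
        j = int(np.flatnonzero((codes < 0).any(axis=0))[0])
        raise DataError(
            f"missing values for node {skeleton.node_names()[j]!r}; "
            "use fit_em for incomplete data"
        )
    if prior.n0 == 0 and codes.size == 0:
        raise ValueError("undefined CPTs: no data and n0 = 0")
    counts = _count_tables(skeleton, codes)
    cpts = _estimate_from_counts(skeleton, counts, prior)
    return BayesNet(list(skeleton.nodes.values()), cpts, name=skeleton.name)


def fit_em(
    skeleton: BayesNet,
    windows,
    prior: DirichletPrior | None = None,
    tol: float = 1e-4,
    max_iter: int = 100,
    fall_node: str = "fall",
    init: BayesNet | None = None,
    max_completions: int = 4096,
) -> FitResult:
    """Fit CPTs by expectation-maximization over missing evidence.

    E-step: each incomplete window is distributed over its completions with
    weights proportional to the joint probability of the completed
    assignment under the current parameters (exact — the completion of a
    window is a full joint configuration). M-step: Dirichlet-weighted
    re-estimation from the expected counts. Iterates until the observed-data
    log-likelihood gain falls below ``tol`` or ``max_iter`` is reached; the
    log-likelihood sequence is non-decreasing.

    Non-convergence is reported via ``FitResult.converged``, not raised.
    """
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    prior = prior or DirichletPrior()
    codes = encode_windows(skeleton, windows, fall_node=fall_node)
    names = skeleton.node_names()
    cards = np.array([skeleton.nodes[n].n_states for n in names])

    # collapse identical observation patterns: EM cost depends on unique
    # patterns, not on the number of windows
    patterns, counts = np.unique(codes, axis=0, return_counts=True)

    complete = not codes.size or (patterns >= 0).all()
    if complete:
        net = fit_cpts(skeleton, windows, prior, fall_node=fall_node)
        ll = _complete_loglik(net, patterns, counts) if codes.size else 0.0
        return FitResult(net=net, log_likelihoods=[ll], converged=True, n_iter=1)

    # initial parameters: prior-only network (or a supplied warm start)
    if init is not None:
        net = init
        net.require_fitted()
    else:
        zero = {
            n: np.zeros((skeleton.n_parent_configs(n), skeleton.nodes[n].n_states))
            for n in names
        }
        n0 = prior.n0 if prior.n0 > 0 else 1.0
        start = DirichletPrior(n0=n0, theta=prior.theta)
        net = BayesNet(
            list(skeleton.nodes.values()),
            _estimate_from_counts(skeleton, zero, start),
            name=skeleton.name,
        )

    # expand every pattern's completions into one stacked matrix, with a
    # segment id per completion row pointing back to its source pattern;
    # family row indices are structural and precomputed once
    blocks, seg_ids = [], []
    for s, pat in enumerate(patterns):
        missing = np.flatnonzero(pat < 0)
        if missing.size == 0:
            blocks.append(pat[None, :])
            seg_ids.append(np.array([s]))
            continue
        n_comp = int(np.prod(cards[missing]))
        if n_comp > max_completions:
            raise DataError(
                f"a window pattern has {n_comp} completions "
                f"(> {max_completions}); too much joint missingness for exact EM"
            )
        grid = np.array(
            list(product(*[range(cards[m]) for m in missing])), dtype=np.int64
        )
        full = np.tile(pat, (n_comp, 1))
        full[:, missing] = grid
        blocks.append(full)
        seg_ids.append(np.full(n_comp, s))
    big = np.vstack(blocks)
    seg = np.concatenate(seg_ids)
    n_seg = len(patterns)
    col = {name: j for j, name in enumerate(names)}
    family_rows = {}
    for name in names:
        spec = skeleton.nodes[name]
        if spec.parents:
            family_rows[name] = np.ravel_multi_index(
                tuple(big[:, col[p]] for p in spec.parents),
                skeleton.parent_cards(name),
            )
        else:
            family_rows[name] = np.zeros(len(big), dtype=np.intp)

    lls: list[float] = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        logp = _joint_logprob(net, big, col)
        seg_max = np.full(n_seg, -np.inf)
        np.maximum.at(seg_max, seg, logp)
        p = np.exp(logp - seg_max[seg])
        z = np.zeros(n_seg)
        np.add.at(z, seg, p)
        lls.append(float(counts @ (seg_max + np.log(z))))
        w = counts[seg] * p / z[seg]
        counts_acc = {}
        for name in names:
            table = np.zeros(
                (skeleton.n_parent_configs(name), skeleton.nodes[name].n_states)
            )
            np.add.at(table, (family_rows[name], big[:, col[name]]), w)
            counts_acc[name] = table
        net = BayesNet(
            list(skeleton.nodes.values()),
            _estimate_from_counts(skeleton, counts_acc, prior),
            name=skeleton.name,
        )
        if len(lls) >= 2 and lls[-1] - lls[-2] < tol:
            converged = True
            break
    return FitResult(net=net, log_likelihoods=lls, converged=converged, n_iter=it)


def _joint_logprob(net: BayesNet, full: np.ndarray, col: dict) -> np.ndarray:
    """Log joint probability of fully assigned configuration rows."""
    logp = np.zeros(len(full))
    for name in net.node_names():
        spec = net.nodes[name]
        table = net.cpts[name].table
        if spec.parents:
            rows = np.ravel_multi_index(
                tuple(full[:, col[p]] for p in spec.parents),
                net.parent_cards(name),
            )
        else:
            rows = np.zeros(len(full), dtype=np.intp)
        with np.errstate(divide="ignore"):
            logp += np.log(table[rows, full[:, col[name]]])
    return logp


def _complete_loglik(net: BayesNet, patterns: np.ndarray, counts) -> float:
    col = {name: j for j, name in enumerate(net.node_names())}
    return float(np.dot(_joint_logprob(net, patterns, col), counts))
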