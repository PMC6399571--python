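"""Sensitivity analysis: how much observing each variable explains the
fall node.

For a categorical target the measure is entropy reduction — the mutual
information ``I(target; X) = H(target) - sum_x P(x) H(target | x)`` in bits
— and for targets with declared numeric state values, variance reduction
``V(target) - sum_x P(x) V(target | x)``, both computed from exact
posteriors. Per-subgroup values are the sums over member nodes
(one-variable-at-a-time findings, no joint observations).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bayesnet import BayesNet, DataError
from .inference import posterior

__all__ = [
    "SensitivityReport",
    "entropy_reduction",
    "variance_reduction",
    "subgroup_summation",
    "analyze",
]


def _entropy_bits(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log2(p)).sum())


def _findings_distribution(net: BayesNet, target: str, findings: str):
    """Marginal of the findings node and the per-finding target posteriors."""
    if target not in net.nodes or findings not in net.nodes:
        missing = findings if findings not in net.nodes else target
        raise DataError(f"unknown node {missing!r}")
    if target == findings:
        raise DataError("target and findings node must differ")
    pf = posterior(net, {}, findings)
    conds = []
    for i, state in enumerate(net.nodes[findings].states):
        if pf[i] <= 0:
            conds.append(None)
            continue
        conds.append(posterior(net, {findings: state}, target))
    return pf, conds


def entropy_reduction(net: BayesNet, target: str, findings: str) -> float:
    """Mutual information between target and findings node, in bits."""
    pf, conds = _findings_distribution(net, target, findings)
    h0 = _entropy_bits(posterior(net, {}, target))
    h_cond = sum(
        float(pf[i]) * _entropy_bits(c)
        for i, c in enumerate(conds) if c is not None
    )
    return h0 - h_cond


def variance_reduction(net: BayesNet, target: str, findings: str) -> float:
    """Expected reduction in the target's variance over its numeric state
    values from observing the findings node."""
    spec = net.nodes.get(target)
    if spec is None:
        raise DataError(f"unknown node {target!r}")
    if spec.numeric_values is None:
        raise DataError(
            f"target {target!r} has no declared numeric state values"
        )
    x = np.asarray(spec.numeric_values, dtype=float)

    def var(p: np.ndarray) -> float:
        mu = float(p @ x)
        return float(p @ (x - mu) ** 2)

    pf, conds = _findings_distribution(net, target, findings)
    v0 = var(posterior(net, {}, target))
    v_cond = sum(
        float(pf[i]) * var(c) for i, c in enumerate(conds) if c is not None
    )
    return v0 - v_cond


@dataclass
class SensitivityReport:
    """Per-node and per-subgroup explanation of the target node."""

    target: str
    measure: str  # "entropy_reduction" | "variance_reduction"
    per_node: dict = field(default_factory=dict)
    per_subgroup: dict = field(default_factory=dict)

    def ranked_subgroups(self) -> list[tuple[str, float]]:
        return sorted(self.per_subgroup.items(), key=lambda kv: -kv[1])

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "measure": self.measure,
            "per_node": self.per_node,
            "per_subgroup": self.per_subgroup,
        }


def subgroup_summation(report: SensitivityReport, net: BayesNet) -> dict:
    """Sum per-node values by each node's subgroup tag."""
    totals: dict[str, float] = {}
    for name, value in report.per_node.items():
        totals.setdefault(net.nodes[name].subgroup, 0.0)
        totals[net.nodes[name].subgroup] += value
    report.per_subgroup = totals
    return totals


def analyze(
    net: BayesNet,
    target: str = "fall",
    measure: str = "entropy_reduction",
    numeric_target_values: tuple[float, float] | None = None,
) -> SensitivityReport:
    """One-variable-at-a-time sensitivity of the target to every other node.

    ``measure="variance_reduction"`` requires the target to declare numeric
    state values (``numeric_target_values`` may supply them for a binary
    outcome, e.g. ``(0, 1)``).
    """
    if measure not in ("entropy_reduction", "variance_reduction"):
        raise ValueError(f"unknown measure {measure!r}")
    work = net
    if measure == "variance_reduction" and net.nodes[target].numeric_values is None:
        vals = numeric_target_values or tuple(
            float(i) for i in range(net.nodes[target].n_states)
        )
        from dataclasses import replace

        nodes = [
            replace(s, numeric_values=tuple(vals)) if s.name == target else s
            for s in net.nodes.values()
        ]
        work = BayesNet(nodes, net.cpts, name=net.name)
    fn = entropy_reduction if measure == "entropy_reduction" else variance_reduction
    report = SensitivityReport(target=target, measure=measure)
    for name, spec in net.nodes.items():
        if name == target or spec.subgroup == "outcome":
            continue
        report.per_node[name] = fn(work, target, name)
    subgroup_summation(report, net)
    return report


def plot_subgroups(reports: dict[str, SensitivityReport], path) -> None:
    """Grouped bar chart of subgroup totals, one bar group per model."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted({g for r in reports.values() for g in r.per_subgroup})
    x = np.arange(len(groups))
    width = 0.8 / max(len(reports), 1)
    fig, ax = plt.subplots(figsize=(6, 3.5))
    for i, (label, r) in enumerate(reports.items()):
        vals = [r.per_subgroup.get(g, 0.0) for g in groups]
        ax.bar(x + i * width, vals, width, label=label)
    ax.set_xticks(x + width * (len(reports) - 1) / 2)
    ax.set_xticklabels(groups, rotation=30, ha="right")
    ax.set_ylabel(next(iter(reports.values())).measure.replace("_", " "))
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
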