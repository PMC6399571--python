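"""Discrete Bayesian network: node specs, CPTs, schema loading, serialization.

A network ``B = (Pr, G)`` is a directed acyclic graph ``G`` over named
discrete variables together with one conditional probability table (CPT)
per node, factorizing the joint distribution as
``Pr(V_1..V_n) = prod_i Pr(V_i | parents(V_i))``.

CPT row convention (fixed for bit-reproducibility): the rows of a node's
table enumerate parent-state configurations in the lexicographic order of
the Cartesian product of the parents' state lists, parents in declared
order — i.e. the flat index produced by ``numpy.ravel_multi_index`` with
the parents' cardinalities as dims and C order.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import yaml

__all__ = [
    "NodeSpec",
    "CPT",
    "BayesNet",
    "SchemaError",
    "DataError",
    "load_schema",
    "bundled_schema_path",
    "forward_sample",
]

_SCHEMA_DIR = Path(__file__).parent / "schemas"

#: Subgroup tags used for sensitivity-analysis summation, mirroring the
#: standard grouping of fall-risk model variables.
SUBGROUPS = (
    "demographics",
    "administrative",
    "assessment_diagnosis",
    "intervention",
    "kpcs",
    "medication",
    "risk_tool",
    "outcome",
)


class SchemaError(ValueError):
    """Invalid network structure (cycle, unknown parent, bad states)."""


class DataError(ValueError):
    """Observed data inconsistent with the network's state spaces."""


@dataclass(frozen=True)
class NodeSpec:
    """A discrete random variable: finite ordered states and parent list.

    ``numeric_values`` optionally assigns a real value to each state (bin
    midpoints by default for binned continuous quantities); required only
    for variance-reduction sensitivity analysis.
    """

    name: str
    states: tuple[str, ...]
    parents: tuple[str, ...] = ()
    subgroup: str = "assessment_diagnosis"
    numeric_values: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.states) < 2:
            raise SchemaError(f"node {self.name!r} needs >=2 states")
        if len(set(self.states)) != len(self.states):
            raise SchemaError(f"node {self.name!r} has duplicate states")
        if len(set(self.parents)) != len(self.parents):
            raise SchemaError(f"node {self.name!r} has duplicate parents")
        if self.name in self.parents:
            raise SchemaError(f"node {self.name!r} lists itself as a parent")
        if self.subgroup not in SUBGROUPS:
            raise SchemaError(
                f"node {self.name!r}: unknown subgroup {self.subgroup!r}"
            )
        if self.numeric_values is not None and len(self.numeric_values) != len(
            self.states
        ):
            raise SchemaError(
                f"node {self.name!r}: numeric_values length != number of states"
            )

    @property
    def n_states(self) -> int:
        return len(self.states)

    def state_index(self, state: str) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise DataError(
                f"value {state!r} is not a state of node {self.name!r} "
                f"(states: {list(self.states)})"
            ) from None


@dataclass
class CPT:
    """Conditional probability table ``Pr(node | parents)``.

    ``table`` has shape ``(n_parent_configs, n_states)``; each row is the
    distribution over the node's states for one parent configuration, rows
    ordered per the module-level convention.
    """

    node: str
    table: np.ndarray

    def validate(self, atol: float = 1e-9) -> None:
        t = np.asarray(self.table, dtype=float)
        if t.ndim != 2:
            raise SchemaError(f"CPT for {self.node!r} must be 2-D")
        if np.any(t < -atol) or np.any(t > 1 + atol):
            raise SchemaError(f"CPT for {self.node!r} has entries outside [0,1]")
        if not np.allclose(t.sum(axis=1), 1.0, atol=atol):
            raise SchemaError(f"CPT rows for {self.node!r} do not sum to 1")


class BayesNet:
    """Directed acyclic graph over :class:`NodeSpec` with one CPT per node.

    CPTs may be unset (``None``) on a freshly loaded schema skeleton.
    """

    def __init__(
        self,
        nodes: Sequence[NodeSpec],
        cpts: Mapping[str, CPT] | None = None,
        name: str = "bayesnet",
    ) -> None:
        self.name = name
        self.nodes: dict[str, NodeSpec] = {}
        for spec in nodes:
            if spec.name in self.nodes:
                raise SchemaError(f"duplicate node {spec.name!r}")
            self.nodes[spec.name] = spec
        for spec in nodes:
            for p in spec.parents:
                if p not in self.nodes:
                    raise SchemaError(
                        f"node {spec.name!r} declares unknown parent {p!r}"
                    )
        self._graph = nx.DiGraph()
        self._graph.add_nodes_from(self.nodes)
        self._graph.add_edges_from(self.arcs())
        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            path = " -> ".join(str(u) for u, _ in cycle) + f" -> {cycle[0][0]}"
            raise SchemaError(f"network contains a cycle: {path}")
        self.cpts: dict[str, CPT] = dict(cpts) if cpts else {}
        for cpt in self.cpts.values():
            self._check_cpt_shape(cpt)

    # -- structure -----------------------------------------------------

    def arcs(self) -> list[tuple[str, str]]:
        return [(p, s.name) for s in self.nodes.values() for p in s.parents]

    def node_names(self) -> list[str]:
        return list(self.nodes)

    def topological_order(self) -> list[str]:
        # deterministic: stable among ties by declaration order
        order_index = {n: i for i, n in enumerate(self.nodes)}
        return list(
            nx.lexicographical_topological_sort(
                self._graph, key=lambda n: order_index[n]
            )
        )

    def children(self, name: str) -> list[str]:
        return sorted(self._graph.successors(name), key=self.node_names().index)

    def n_parent_configs(self, name: str) -> int:
        spec = self.nodes[name]
        out = 1
        for p in spec.parents:
            out *= self.nodes[p].n_states
        return out

    def parent_cards(self, name: str) -> tuple[int, ...]:
        return tuple(self.nodes[p].n_states for p in self.nodes[name].parents)

    def _check_cpt_shape(self, cpt: CPT) -> None:
        if cpt.node not in self.nodes:
            raise SchemaError(f"CPT for unknown node {cpt.node!r}")
        expected = (self.n_parent_configs(cpt.node), self.nodes[cpt.node].n_states)
        if tuple(np.asarray(cpt.table).shape) != expected:
            raise SchemaError(
                f"CPT for {cpt.node!r} has shape {np.asarray(cpt.table).shape}, "
                f"expected {expected}"
            )
        cpt.validate()

    def set_cpt(self, node: str, table: np.ndarray) -> None:
        cpt = CPT(node, np.asarray(table, dtype=float))
        self._check_cpt_shape(cpt)
        self.cpts[node] = cpt

    @property
    def fitted(self) -> bool:
        return set(self.cpts) == set(self.nodes)

    def require_fitted(self) -> None:
        missing = set(self.nodes) - set(self.cpts)
        if missing:
            raise SchemaError(f"network has unset CPTs: {sorted(missing)}")

    def summary(self) -> dict:
        """Skeleton summary: node/arc counts and per-subgroup membership."""
        groups: dict[str, list[str]] = {}
        for s in self.nodes.values():
            groups.setdefault(s.subgroup, []).append(s.name)
        return {
            "name": self.name,
            "n_nodes": len(self.nodes),
            "n_arcs": len(self.arcs()),
            "subgroups": groups,
        }

    # -- codes ---------------------------------------------------------

    def encode(self, evidence: Mapping[str, str]) -> dict[str, int]:
        """Map a name->state dict to name->state-index, validating both."""
        out = {}
        for name, state in evidence.items():
            if name not in self.nodes:
                raise DataError(f"unknown node {name!r}")
            out[name] = self.nodes[name].state_index(state)
        return out

    def row_index(self, node: str, parent_states: Sequence[int]) -> int:
        cards = self.parent_cards(node)
        if not cards:
            return 0
        return int(np.ravel_multi_index(tuple(parent_states), cards))

    # -- serialization -------------------------------------------------

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "name": self.name,
            "nodes": [
                {
                    "name": s.name,
                    "states": list(s.states),
                    "parents": list(s.parents),
                    "subgroup": s.subgroup,
                    **(
                        {"numeric_values": list(s.numeric_values)}
                        if s.numeric_values is not None
                        else {}
                    ),
                }
                for s in self.nodes.values()
            ],
            "cpts": {
                n: c.table.tolist() for n, c in self.cpts.items()
            },
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "BayesNet":
        if isinstance(source, Path):
            text = source.read_text()
        elif isinstance(source, str) and source.lstrip().startswith("{"):
            text = source
        else:
            text = Path(source).read_text()
        payload = json.loads(text)
        nodes = [
            NodeSpec(
                name=d["name"],
                states=tuple(d["states"]),
                parents=tuple(d.get("parents", ())),
                subgroup=d.get("subgroup", "assessment_diagnosis"),
                numeric_values=(
                    tuple(d["numeric_values"]) if "numeric_values" in d else None
                ),
            )
            for d in payload["nodes"]
        ]
        cpts = {
            n: CPT(n, np.asarray(t, dtype=float))
            for n, t in payload.get("cpts", {}).items()
        }
        return cls(nodes, cpts, name=payload.get("name", "bayesnet"))


def _nodes_from_mapping(raw_nodes: Iterable[Mapping], extra_arcs) -> list[NodeSpec]:
    parents: dict[str, list[str]] = {}
    for d in raw_nodes:
        parents[d["name"]] = list(d.get("parents", []))
    for arc in extra_arcs or []:
        src, dst = arc
        if dst not in parents:
            raise SchemaError(f"arc {arc!r} targets unknown node {dst!r}")
        if src not in parents[dst]:
            parents[dst].append(src)
    return [
        NodeSpec(
            name=d["name"],
            states=tuple(str(s) for s in d["states"]),
            parents=tuple(parents[d["name"]]),
            subgroup=d.get("subgroup", "assessment_diagnosis"),
            numeric_values=(
                tuple(float(v) for v in d["numeric_values"])
                if "numeric_values" in d
                else None
            ),
        )
        for d in raw_nodes
    ]


def load_schema(source: str | Path | Mapping) -> BayesNet:
    """Load a network skeleton (no CPTs) from a YAML file or parsed mapping.

    The schema lists nodes (name, states, subgroup, optional parents and
    numeric_values) and, optionally, a top-level ``arcs`` list of
    ``[from, to]`` pairs merged into the per-node parent lists.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            raw = yaml.safe_load(fh)
    else:
        raw = dict(source)
    if not isinstance(raw, dict) or "nodes" not in raw:
        raise SchemaError("schema must be a mapping with a 'nodes' list")
    nodes = _nodes_from_mapping(raw["nodes"], raw.get("arcs"))
    return BayesNet(nodes, name=raw.get("name", "schema"))


def bundled_schema_path(style: str) -> Path:
    """Path to a bundled default schema: ``development`` (Hendrich II risk
    tool with subscore parents) or ``validation`` (STRATIFY)."""
    path = _SCHEMA_DIR / f"{style}.yaml"
    if not path.exists():
        raise SchemaError(
            f"no bundled schema {style!r}; available: "
            f"{sorted(p.stem for p in _SCHEMA_DIR.glob('*.yaml'))}"
        )
    return path


def forward_sample(
    net: BayesNet, n: int, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Draw ``n`` joint samples by ancestral sampling, vectorized.

    Returns a dict of integer state-code arrays, one per node.
    """
    net.require_fitted()
    out: dict[str, np.ndarray] = {}
    for name in net.topological_order():
        spec = net.nodes[name]
        table = net.cpts[name].table
        if spec.parents:
            cards = net.parent_cards(name)
            rows = np.ravel_multi_index(
                tuple(out[p] for p in spec.parents), cards
            )
        else:
            rows = np.zeros(n, dtype=np.intp)
        cum = np.cumsum(table, axis=1)
        cum[:, -1] = 1.0  # guard float drift
        u = rng.random(n)
        # per-sample inverse-CDF lookup on that sample's CPT row
        out[name] = (u[:, None] > cum[rows]).sum(axis=1).astype(np.int64)
    return out
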