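"""Discrete Bayesian-network representation, I/O, sampling and evaluation.

A network is a DAG over discrete variables.  Node ``i`` with ``r_i`` states
and parents in joint configuration ``j`` (of ``q_i`` possible) carries the
conditional probability ``theta_ijk = P(X_i = k | pa_i = j)``.  Parent
configurations are encoded in mixed radix over the declared parent order,
first parent most significant, 0-based.
"""

from __future__ import annotations

import json
import math
import re
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "Network",
    "ParameterSet",
    "Dataset",
    "CountTable",
    "read_network",
    "write_network",
    "forward_sample",
    "count_sufficient_stats",
    "joint_kl",
    "dasgupta_sample_bound",
]

_ROW_SUM_TOL = 1e-9

# Exact joint enumeration is only attempted below this many outcomes.
_MAX_JOINT_OUTCOMES = 2_000_000


class NetworkError(ValueError):
    """Structural or validation problem in a network definition."""


@dataclass
class ParameterSet:
    """Full CPT collection: per node an array of shape ``(q_i, r_i)``.

    Every row must lie on the probability simplex.
    """

    tables: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for name, tab in self.tables.items():
            tab = np.asarray(tab, dtype=float)
            if tab.ndim != 2:
                raise NetworkError(f"CPT for {name!r} must be 2-D (q_i, r_i)")
            if np.any(tab < -_ROW_SUM_TOL) or np.any(tab > 1 + _ROW_SUM_TOL):
                raise NetworkError(f"CPT entries for {name!r} outside [0, 1]")
            rows = tab.sum(axis=1)
            if np.any(np.abs(rows - 1.0) > 1e-6):
                raise NetworkError(
                    f"CPT rows for {name!r} do not sum to 1 (sums {rows})"
                )
            self.tables[name] = tab

    def __getitem__(self, node: str) -> np.ndarray:
        return self.tables[node]

    def value(self, node: str, j: int, k: int) -> float:
        return float(self.tables[node][j, k])

    def copy(self) -> "ParameterSet":
        return ParameterSet({n: t.copy() for n, t in self.tables.items()})

    def allclose(self, other: "ParameterSet", tol: float = 1e-9) -> bool:
        return set(self.tables) == set(other.tables) and all(
            np.allclose(self.tables[n], other.tables[n], atol=tol)
            for n in self.tables
        )


@dataclass
class Network:
    """DAG over discrete variables with per-node cardinalities.

    ``parents[v]`` is an ordered list; its order fixes the mixed-radix
    parent-configuration encoding.  ``state_names`` maps each node to its
    state labels (defaults to "0", "1", ...).
    """

    nodes: list[str]
    parents: dict[str, list[str]]
    cardinalities: dict[str, int]
    state_names: dict[str, list[str]] = field(default_factory=dict)
    true_params: ParameterSet | None = None

    def __post_init__(self) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for child, pas in self.parents.items():
            if child not in self.cardinalities:
                raise NetworkError(f"unknown node {child!r} in parent map")
            for p in pas:
                if p not in self.cardinalities:
                    raise NetworkError(f"unknown parent {p!r} of {child!r}")
                g.add_edge(p, child)
        try:
            cycle = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            cycle = None
        if cycle:
            raise NetworkError(f"graph contains a cycle: {cycle}")
        for v, r in self.cardinalities.items():
            if r < 2:
                raise NetworkError(f"node {v!r} has cardinality {r} < 2")
        for v in self.nodes:
            self.state_names.setdefault(
                v, [str(k) for k in range(self.cardinalities[v])]
            )
            if len(self.state_names[v]) != self.cardinalities[v]:
                raise NetworkError(f"state names of {v!r} mismatch cardinality")
        self._graph = g
        if self.true_params is not None:
            self.validate_params(self.true_params)

    # -- structure helpers -------------------------------------------------
    def cardinality(self, node: str) -> int:
        return self.cardinalities[node]

    def parent_config_count(self, node: str) -> int:
        q = 1
        for p in self.parents[node]:
            q *= self.cardinalities[p]
        return q

    def topological_order(self) -> list[str]:
        # lexicographic tie-break on declared order keeps sampling reproducible
        pos = {v: i for i, v in enumerate(self.nodes)}
        return list(nx.lexicographical_topological_sort(self._graph, key=pos.get))

    def parent_config_index(self, node: str, parent_states: dict[str, int]) -> int:
        """Mixed-radix index of a parent configuration (first parent most
        significant)."""
        j = 0
        for p in self.parents[node]:
            j = j * self.cardinalities[p] + int(parent_states[p])
        return j

    def parent_config_states(self, node: str, j: int) -> dict[str, int]:
        """Inverse of :meth:`parent_config_index`."""
        pas = self.parents[node]
        out: dict[str, int] = {}
        for p in reversed(pas):
            out[p] = j % self.cardinalities[p]
            j //= self.cardinalities[p]
        return {p: out[p] for p in pas}

    def validate_params(self, params: ParameterSet) -> None:
        for v in self.nodes:
            if v not in params.tables:
                raise NetworkError(f"missing CPT for node {v!r}")
            q, r = params.tables[v].shape
            if (q, r) != (self.parent_config_count(v), self.cardinalities[v]):
                raise NetworkError(
                    f"CPT shape {(q, r)} for {v!r} does not match "
                    f"({self.parent_config_count(v)}, {self.cardinalities[v]})"
                )

    def n_joint_outcomes(self) -> int:
        return int(np.prod([self.cardinalities[v] for v in self.nodes]))


@dataclass
class Dataset:
    """Complete discrete observations; one integer state index per node."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        self.records = self.records.astype(int)

    @property
    def size(self) -> int:
        return len(self.records)

    def validate(self, net: Network) -> None:
        for v in net.nodes:
            if v not in self.records.columns:
                raise NetworkError(f"dataset missing column {v!r}")
            col = self.records[v].to_numpy()
            bad = np.nonzero((col < 0) | (col >= net.cardinalities[v]))[0]
            if bad.size:
                raise NetworkError(
                    f"record {int(bad[0])}: state {int(col[bad[0]])} out of "
                    f"range for node {v!r}"
                )

    def to_csv(self, path, net: Network) -> None:
        labelled = pd.DataFrame(
            {v: [net.state_names[v][s] for s in self.records[v]] for v in net.nodes}
        )
        labelled.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, net: Network) -> "Dataset":
        raw = pd.read_csv(path, dtype=str)
        cols = {}
        for v in net.nodes:
            lut = {s: k for k, s in enumerate(net.state_names[v])}
            cols[v] = raw[v].map(lut)
            if cols[v].isna().any():
                row = int(cols[v].isna().idxmax())
                raise NetworkError(f"record {row}: unknown state for node {v!r}")
        return cls(pd.DataFrame(cols).astype(int))


@dataclass
class CountTable:
    """Sufficient statistics: per node an integer array ``n_ijk`` of shape
    ``(q_i, r_i)`` with row sums ``n_ij``."""

    counts: dict[str, np.ndarray]

    def n_ijk(self, node: str, j: int, k: int) -> int:
        return int(self.counts[node][j, k])

    def n_ij(self, node: str, j: int) -> int:
        return int(self.counts[node][j].sum())

    def row_sums(self, node: str) -> np.ndarray:
        return self.counts[node].sum(axis=1)


# ---------------------------------------------------------------------------
# I/O


def _network_to_dict(net: Network) -> dict:
    out = {"nodes": []}
    for v in net.nodes:
        entry = {
            "name": v,
            "states": net.state_names[v],
            "parents": net.parents[v],
        }
        if net.true_params is not None:
            entry["cpt"] = net.true_params[v].tolist()
        out["nodes"].append(entry)
    return out


def _network_from_dict(spec: dict) -> Network:
    nodes, parents, cards, states = [], {}, {}, {}
    tables: dict[str, np.ndarray] = {}
    has_cpt = False
    for entry in spec["nodes"]:
        v = entry["name"]
        nodes.append(v)
        states[v] = [str(s) for s in entry["states"]]
        cards[v] = len(states[v])
        parents[v] = list(entry.get("parents", []))
        if "cpt" in entry:
            has_cpt = True
            tables[v] = np.asarray(entry["cpt"], dtype=float)
    params = ParameterSet(tables) if has_cpt else None
    return Network(nodes, parents, cards, states, params)


_BIF_NAME = r"[A-Za-z0-9_\-\.]+"


def _parse_bif(text: str) -> Network:
    # strip comments
    text = re.sub(r"//[^\n]*", "", text)
    nodes, parents, cards, states = [], {}, {}, {}
    tables: dict[str, dict[tuple, list[float]]] = {}
    for m in re.finditer(
        rf"variable\s+({_BIF_NAME})\s*\{{\s*type\s+discrete\s*\[\s*(\d+)\s*\]"
        rf"\s*\{{([^}}]*)\}}\s*;\s*\}}",
        text,
    ):
        v, r, statelist = m.group(1), int(m.group(2)), m.group(3)
        nodes.append(v)
        cards[v] = r
        states[v] = [s.strip() for s in statelist.split(",")]
        if len(states[v]) != r:
            raise NetworkError(f"BIF: state count mismatch for {v!r}")
        parents[v] = []
    for m in re.finditer(
        rf"probability\s*\(\s*({_BIF_NAME})\s*(?:\|([^)]*))?\)\s*\{{(.*?)\}}",
        text,
        re.DOTALL,
    ):
        v = m.group(1)
        if v not in cards:
            raise NetworkError(f"BIF: probability block for unknown node {v!r}")
        pas = [p.strip() for p in m.group(2).split(",")] if m.group(2) else []
        parents[v] = pas
        body = m.group(3)
        rows: dict[tuple, list[float]] = {}
        table_m = re.search(r"table\s+([^;]+);", body)
        if table_m:
            vals = [float(x) for x in table_m.group(1).split(",")]
            rows[()] = vals
        for rm in re.finditer(r"\(([^)]*)\)\s*([^;]+);", body):
            key = tuple(s.strip() for s in rm.group(1).split(","))
            rows[key] = [float(x) for x in rm.group(2).split(",")]
        tables[v] = rows
    net = Network(nodes, parents, cards, states)
    if any(tables.values()):
        full: dict[str, np.ndarray] = {}
        for v in nodes:
            q, r = net.parent_config_count(v), cards[v]
            tab = np.zeros((q, r))
            rows = tables.get(v, {})
            if not rows:
                raise NetworkError(f"BIF: no probabilities for {v!r}")
            if () in rows:
                tab[0] = rows[()]
            else:
                for key, vals in rows.items():
                    ps = {
                        p: states[p].index(s)
                        for p, s in zip(parents[v], key)
                    }
                    tab[net.parent_config_index(v, ps)] = vals
            full[v] = tab
        net.true_params = ParameterSet(full)
        net.validate_params(net.true_params)
    return net


def _write_bif(net: Network) -> str:
    lines = ["network unknown {", "}"]
    for v in net.nodes:
        sts = ", ".join(net.state_names[v])
        lines += [
            f"variable {v} {{",
            f"  type discrete [ {net.cardinalities[v]} ] {{ {sts} }};",
            "}",
        ]
    if net.true_params is not None:
        for v in net.nodes:
            pas = net.parents[v]
            head = v if not pas else f"{v} | " + ", ".join(pas)
            lines.append(f"probability ( {head} ) {{")
            tab = net.true_params[v]
            if not pas:
                lines.append(
                    "  table " + ", ".join(f"{x:.12g}" for x in tab[0]) + ";"
                )
            else:
                for j in range(tab.shape[0]):
                    cfg = net.parent_config_states(v, j)
                    key = ", ".join(net.state_names[p][cfg[p]] for p in pas)
                    row = ", ".join(f"{x:.12g}" for x in tab[j])
                    lines.append(f"  ({key}) {row};")
            lines.append("}")
    return "\n".join(lines) + "\n"


def read_network(path, format: str | None = None) -> Network:
    """Read a network from JSON (this package's canonical schema) or BIF."""
    path = str(path)
    if format is None:
        format = "bif" if path.endswith(".bif") else "json"
    with open(path) as fh:
        text = fh.read()
    if format == "json":
        return _network_from_dict(json.loads(text))
    if format == "bif":
        return _parse_bif(text)
    raise ValueError(f"unknown network format {format!r}")


def write_network(net: Network, path, format: str | None = None) -> None:
    path = str(path)
    if format is None:
        format = "bif" if path.endswith(".bif") else "json"
    with open(path, "w") as fh:
        if format == "json":
            json.dump(_network_to_dict(net), fh, indent=1)
        elif format == "bif":
            fh.write(_write_bif(net))
        else:
            raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------------------
# Sampling and sufficient statistics


def forward_sample(net: Network, n: int, seed: int | np.random.Generator) -> Dataset:
    """Draw ``n`` complete records by ancestral sampling from the true CPTs."""
    if net.true_params is None:
        raise NetworkError("forward_sample requires true_params on the network")
    if n < 0:
        raise ValueError("n must be >= 0")
    rng = np.random.default_rng(seed)
    order = net.topological_order()
    data: dict[str, np.ndarray] = {}
    for v in order:
        tab = net.true_params[v]
        pas = net.parents[v]
        if not pas:
            j = np.zeros(n, dtype=int)
        else:
            j = np.zeros(n, dtype=int)
            for p in pas:
                j = j * net.cardinalities[p] + data[p]
        u = rng.random(n)
        cdf = np.cumsum(tab, axis=1)
        data[v] = (u[:, None] > cdf[j]).sum(axis=1)
    frame = pd.DataFrame({v: data.get(v, np.zeros(n, dtype=int)) for v in net.nodes})
    return Dataset(frame)


def count_sufficient_stats(data: Dataset, net: Network) -> CountTable:
    """Tally ``N_ijk`` from a complete dataset."""
    data.validate(net)
    counts: dict[str, np.ndarray] = {}
    for v in net.nodes:
        q, r = net.parent_config_count(v), net.cardinalities[v]
        j = np.zeros(data.size, dtype=int)
        for p in net.parents[v]:
            j = j * net.cardinalities[p] + data.records[p].to_numpy()
        k = data.records[v].to_numpy()
        tab = np.zeros((q, r), dtype=int)
        np.add.at(tab, (j, k), 1)
        counts[v] = tab
    return CountTable(counts)


# ---------------------------------------------------------------------------
# Joint distribution and KL divergence


def joint_outcomes(net: Network) -> tuple[np.ndarray, np.ndarray]:
    """All joint outcomes (rows) and their probabilities under the true CPTs."""
    if net.true_params is None:
        raise NetworkError("network has no true parameters")
    return _enumerate_joint(net, net.true_params)


def _enumerate_joint(net: Network, params: ParameterSet) -> tuple[np.ndarray, np.ndarray]:
    total = net.n_joint_outcomes()
    if total > _MAX_JOINT_OUTCOMES:
        raise NetworkError(
            f"joint enumeration over {total} outcomes refused; network too large"
        )
    shape = [net.cardinalities[v] for v in net.nodes]
    grid = np.indices(shape).reshape(len(shape), -1).T  # (total, n)
    col = {v: grid[:, i] for i, v in enumerate(net.nodes)}
    prob = np.ones(total)
    for v in net.nodes:
        j = np.zeros(total, dtype=int)
        for p in net.parents[v]:
            j = j * net.cardinalities[p] + col[p]
        prob *= params[v][j, col[v]]
    return grid, prob


def parent_config_marginals(net: Network, node: str) -> np.ndarray:
    """``P*(pa_i = j)`` for every parent configuration of ``node``, by exact
    marginalization of the true joint."""
    grid, prob = joint_outcomes(net)
    col = {v: grid[:, i] for i, v in enumerate(net.nodes)}
    q = net.parent_config_count(node)
    j = np.zeros(len(prob), dtype=int)
    for p in net.parents[node]:
        j = j * net.cardinalities[p] + col[p]
    out = np.zeros(q)
    np.add.at(out, j, prob)
    return out


def joint_kl(true_net: Network, est: ParameterSet, per_row_average: bool = False) -> float:
    """KL(P* || P-hat) of the joint distributions.

    Computed by factorization: sum over nodes and parent configurations of
    the configuration probability under the truth times the row-wise KL of
    the conditional.  Rows where the estimate has a zero against positive
    truth yield ``inf``.  With ``per_row_average`` the unweighted mean of
    per-row KLs is returned instead (an alternative summary; the joint KL is
    the default).
    """
    if true_net.true_params is None:
        raise NetworkError("true_net has no true parameters")
    true_net.validate_params(est)
    total = 0.0
    rows = []
    for v in true_net.nodes:
        w = parent_config_marginals(true_net, v)
        t = true_net.true_params[v]
        e = est[v]
        for j in range(t.shape[0]):
            mask = t[j] > 0
            if np.any(e[j][mask] <= 0):
                row_kl = math.inf
            else:
                row_kl = float(
                    np.sum(t[j][mask] * np.log(t[j][mask] / e[j][mask]))
                )
            rows.append(row_kl)
            if w[j] > 0:
                total += w[j] * row_kl
    if per_row_average:
        return float(np.mean(rows))
    return total


# ---------------------------------------------------------------------------


def dasgupta_sample_bound(n: int, k: int, eps: float, delta: float) -> float:
    """Lower bound on the sample size needed to learn the parameters of a
    binary network with ``n`` nodes and at most ``k`` parents per node, to
    error rate ``eps`` with confidence ``1 - delta``:

        288 n^2 2^k / eps^2 * ln^2(1 + 3n/eps) * ln((1 + 3n/eps) / (eps delta))
    """
    if n < 1 or k < 0:
        raise ValueError("need n >= 1 and k >= 0")
    if eps <= 0 or not (0 < delta < 1):
        raise ValueError("need eps > 0 and 0 < delta < 1")
    a = 1 + 3 * n / eps
    return (
        288 * n**2 * 2**k / eps**2 * math.log(a) ** 2 * math.log(a / (eps * delta))
    )
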