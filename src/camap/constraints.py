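"""Expert parameter constraints on CPT entries.

Three constraint kinds, all linear in the CPT entries of one node:

* range — lower/upper bounds on a single entry;
* intra-distribution — an ordering between two states of the same row;
* cross-distribution (a.k.a. monotonic influence) — an ordering of the same
  child state across two parent configurations.

Together with the implicit simplex conditions they carve a convex polytope
out of each node's CPT space.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import yaml
from scipy.optimize import linprog

from .network import Network, ParameterSet

__all__ = [
    "RangeConstraint",
    "IntraConstraint",
    "CrossConstraint",
    "ConstraintSet",
    "Violation",
    "parse_constraints",
    "serialize_constraints",
    "check_satisfaction",
    "feasibility",
]


class ConstraintError(ValueError):
    pass


@dataclass(frozen=True)
class RangeConstraint:
    """``lower <= theta_ijk <= upper``."""

    node: str
    j: int
    k: int
    lower: float
    upper: float

    def __post_init__(self) -> None:
        if not (0 <= self.lower <= self.upper <= 1):
            raise ConstraintError(
                f"range bounds [{self.lower}, {self.upper}] invalid"
            )


@dataclass(frozen=True)
class IntraConstraint:
    """``theta_ij[lesser] <= theta_ij[greater]`` within one row."""

    node: str
    j: int
    lesser: int
    greater: int

    def __post_init__(self) -> None:
        if self.lesser == self.greater:
            raise ConstraintError("intra constraint needs two distinct states")


@dataclass(frozen=True)
class CrossConstraint:
    """``theta_i[lesser_j][k] <= theta_i[greater_j][k]`` across two rows."""

    node: str
    lesser_j: int
    greater_j: int
    k: int

    def __post_init__(self) -> None:
        if self.lesser_j == self.greater_j:
            raise ConstraintError(
                "cross constraint needs two distinct parent configurations"
            )


Constraint = RangeConstraint | IntraConstraint | CrossConstraint


@dataclass
class ConstraintSet:
    """All constraints, grouped per node."""

    by_node: dict[str, list[Constraint]] = field(default_factory=dict)

    @classmethod
    def from_list(cls, constraints: list[Constraint]) -> "ConstraintSet":
        out: dict[str, list[Constraint]] = {}
        for c in constraints:
            out.setdefault(c.node, []).append(c)
        return cls(out)

    def all(self) -> list[Constraint]:
        return [c for cs in self.by_node.values() for c in cs]

    def for_node(self, node: str) -> list[Constraint]:
        return list(self.by_node.get(node, []))

    def __len__(self) -> int:
        return sum(len(v) for v in self.by_node.values())

    def validate(self, net: Network) -> None:
        for node, cs in self.by_node.items():
            if node not in net.cardinalities:
                raise ConstraintError(f"constraint on unknown node {node!r}")
            q, r = net.parent_config_count(node), net.cardinalities[node]
            for c in cs:
                js = (
                    [c.j]
                    if isinstance(c, (RangeConstraint, IntraConstraint))
                    else [c.lesser_j, c.greater_j]
                )
                ks = (
                    [c.k]
                    if isinstance(c, (RangeConstraint, CrossConstraint))
                    else [c.lesser, c.greater]
                )
                if any(j < 0 or j >= q for j in js):
                    raise ConstraintError(f"{c}: parent configuration out of range")
                if any(k < 0 or k >= r for k in ks):
                    raise ConstraintError(f"{c}: state out of range")


# ---------------------------------------------------------------------------
# parsing


def _state_index(net: Network, node: str, s, where: str) -> int:
    names = net.state_names[node]
    if isinstance(s, int) and 0 <= s < len(names):
        return s
    s = str(s)
    if s in names:
        return names.index(s)
    raise ConstraintError(f"{where}: unknown state {s!r} for node {node!r}")


def _config_index(net: Network, node: str, cfg: dict, where: str) -> int:
    pas = net.parents[node]
    if set(cfg) != set(pas):
        raise ConstraintError(
            f"{where}: parent configuration must name exactly {pas}"
        )
    states = {p: _state_index(net, p, cfg[p], where) for p in pas}
    return net.parent_config_index(node, states)


def _entry_to_constraint(entry: dict, net: Network, where: str) -> Constraint:
    kind = entry.get("type")
    node = entry.get("node")
    if node not in net.cardinalities:
        raise ConstraintError(f"{where}: unknown node {node!r}")
    if kind == "range":
        return RangeConstraint(
            node=node,
            j=_config_index(net, node, entry.get("parents", {}), where),
            k=_state_index(net, node, entry["state"], where),
            lower=float(entry.get("lower", 0.0)),
            upper=float(entry.get("upper", 1.0)),
        )
    if kind == "intra":
        return IntraConstraint(
            node=node,
            j=_config_index(net, node, entry.get("parents", {}), where),
            lesser=_state_index(net, node, entry["lesser_state"], where),
            greater=_state_index(net, node, entry["greater_state"], where),
        )
    if kind == "cross":
        return CrossConstraint(
            node=node,
            lesser_j=_config_index(net, node, entry["lesser"], where),
            greater_j=_config_index(net, node, entry["greater"], where),
            k=_state_index(net, node, entry["state"], where),
        )
    raise ConstraintError(f"{where}: unknown constraint type {kind!r}")


def parse_constraints(path, net: Network) -> ConstraintSet:
    """Parse a YAML/JSON constraint file against a network.

    Duplicates are dropped with a warning.  The file holds a top-level
    ``constraints`` list; each item names its ``type`` (range/intra/cross)
    and its CPT coordinates by node, state label and parent configuration.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return constraints_from_doc(doc, net)


def constraints_from_doc(doc, net: Network) -> ConstraintSet:
    entries = (doc or {}).get("constraints", []) or []
    seen: set[Constraint] = set()
    out: list[Constraint] = []
    for idx, entry in enumerate(entries):
        c = _entry_to_constraint(entry, net, f"constraint #{idx + 1}")
        if c in seen:
            warnings.warn(f"duplicate constraint dropped: {c}")
            continue
        seen.add(c)
        out.append(c)
    cs = ConstraintSet.from_list(out)
    cs.validate(net)
    return cs


def serialize_constraints(cs: ConstraintSet, net: Network) -> dict:
    """Inverse of :func:`constraints_from_doc` on the canonical DSL."""

    def cfg(node: str, j: int) -> dict:
        states = net.parent_config_states(node, j)
        return {p: net.state_names[p][s] for p, s in states.items()}

    entries = []
    for c in cs.all():
        if isinstance(c, RangeConstraint):
            entries.append(
                {
                    "type": "range",
                    "node": c.node,
                    "parents": cfg(c.node, c.j),
                    "state": net.state_names[c.node][c.k],
                    "lower": c.lower,
                    "upper": c.upper,
                }
            )
        elif isinstance(c, IntraConstraint):
            entries.append(
                {
                    "type": "intra",
                    "node": c.node,
                    "parents": cfg(c.node, c.j),
                    "lesser_state": net.state_names[c.node][c.lesser],
                    "greater_state": net.state_names[c.node][c.greater],
                }
            )
        else:
            entries.append(
                {
                    "type": "cross",
                    "node": c.node,
                    "state": net.state_names[c.node][c.k],
                    "lesser": cfg(c.node, c.lesser_j),
                    "greater": cfg(c.node, c.greater_j),
                }
            )
    return {"constraints": entries}


def write_constraints(cs: ConstraintSet, net: Network, path) -> None:
    doc = serialize_constraints(cs, net)
    path = str(path)
    with open(path, "w") as fh:
        if path.endswith(".json"):
            json.dump(doc, fh, indent=1)
        else:
            yaml.safe_dump(doc, fh, sort_keys=False)


# ---------------------------------------------------------------------------
# satisfaction and feasibility


@dataclass(frozen=True)
class Violation:
    constraint: Constraint
    margin: float  # positive amount by which the constraint is missed


def check_satisfaction(
    params: ParameterSet, cs: ConstraintSet, tol: float = 1e-9
) -> list[Violation]:
    """Return the constraints violated by ``params`` (empty = all satisfied).

    The margin is how far the offending quantity lies outside the allowed
    region; inequalities are non-strict with tolerance ``tol``.
    """
    out: list[Violation] = []
    for c in cs.all():
        tab = params[c.node]
        if isinstance(c, RangeConstraint):
            v = tab[c.j, c.k]
            if v < c.lower - tol:
                out.append(Violation(c, float(c.lower - v)))
            elif v > c.upper + tol:
                out.append(Violation(c, float(v - c.upper)))
        elif isinstance(c, IntraConstraint):
            gap = tab[c.j, c.lesser] - tab[c.j, c.greater]
            if gap > tol:
                out.append(Violation(c, float(gap)))
        else:
            gap = tab[c.lesser_j, c.k] - tab[c.greater_j, c.k]
            if gap > tol:
                out.append(Violation(c, float(gap)))
    return out


def node_polytope(
    cs: ConstraintSet, net: Network, node: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Linear description of the feasible set of one node's full CPT.

    Variables are the flattened ``(q, r)`` CPT of ``node``.  Returns
    ``(A_ub, b_ub, A_eq, b_eq)`` for ``A_ub x <= b_ub``, ``A_eq x = b_eq``;
    the simplex conditions (row sums, 0/1 box as inequalities) are included.
    """
    q, r = net.parent_config_count(node), net.cardinalities[node]
    dim = q * r

    def var(j: int, k: int) -> int:
        return j * r + k

    a_ub: list[np.ndarray] = []
    b_ub: list[float] = []
    # box: 0 <= x <= 1
    eye = np.eye(dim)
    a_ub.extend(-eye)
    b_ub.extend([0.0] * dim)
    a_ub.extend(eye)
    b_ub.extend([1.0] * dim)
    for c in cs.for_node(node):
        if isinstance(c, RangeConstraint):
            row = np.zeros(dim)
            row[var(c.j, c.k)] = -1.0
            a_ub.append(row)
            b_ub.append(-c.lower)
            row = np.zeros(dim)
            row[var(c.j, c.k)] = 1.0
            a_ub.append(row)
            b_ub.append(c.upper)
        elif isinstance(c, IntraConstraint):
            row = np.zeros(dim)
            row[var(c.j, c.lesser)] = 1.0
            row[var(c.j, c.greater)] = -1.0
            a_ub.append(row)
            b_ub.append(0.0)
        else:
            row = np.zeros(dim)
            row[var(c.lesser_j, c.k)] = 1.0
            row[var(c.greater_j, c.k)] = -1.0
            a_ub.append(row)
            b_ub.append(0.0)
    a_eq = np.zeros((q, dim))
    for j in range(q):
        a_eq[j, j * r : (j + 1) * r] = 1.0
    b_eq = np.ones(q)
    return np.array(a_ub), np.array(b_ub), a_eq, b_eq


def feasibility(
    cs: ConstraintSet, net: Network
) -> tuple[bool, ParameterSet | None]:
    """Is the constraint polytope (constraints plus simplex conditions)
    nonempty?  On success returns a feasible witness ParameterSet built from
    per-node Chebyshev-center LPs (interior whenever the polytope has
    interior)."""
    cs.validate(net)
    tables: dict[str, np.ndarray] = {}
    for node in net.nodes:
        q, r = net.parent_config_count(node), net.cardinalities[node]
        a_ub, b_ub, a_eq, b_eq = node_polytope(cs, net, node)
        # Chebyshev center restricted to the affine row-sum subspace:
        # maximize s with A(x0 + N z) + ||A N row|| s <= b.
        x0, basis = _affine_parametrization(a_eq, b_eq)
        an = a_ub @ basis
        bn = b_ub - a_ub @ x0
        norms = np.linalg.norm(an, axis=1)
        a_lp = np.hstack([an, norms[:, None]])
        c_lp = np.zeros(a_lp.shape[1])
        c_lp[-1] = -1.0  # maximize s
        res = linprog(
            c_lp,
            A_ub=a_lp,
            b_ub=bn,
            bounds=[(None, None)] * basis.shape[1] + [(None, None)],
            method="highs",
        )
        if not res.success or res.x[-1] < -1e-9:
            return False, None
        x = x0 + basis @ res.x[:-1]
        tab = np.clip(x.reshape(q, r), 0.0, None)
        tab /= tab.sum(axis=1, keepdims=True)
        tables[node] = tab
    return True, ParameterSet(tables)


def _affine_parametrization(a_eq: np.ndarray, b_eq: np.ndarray):
    """Particular solution and orthonormal null-space basis of A x = b."""
    from scipy.linalg import lstsq, null_space

    x0 = lstsq(a_eq, b_eq)[0]
    basis = null_space(a_eq)
    return x0, basis
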