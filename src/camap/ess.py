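"""Equivalent-sample-size (ESS) bounds and cross-validated selection.

The posterior-mode estimate of a CPT entry is the count/prior blend

    theta_hat_ijk = (N_ijk + a_ij * p_ijk) / (N_ij + a_ij)

with prior shape ``p`` and local ESS ``a_ij``.  Whether the blend satisfies
an expert constraint depends on ``a_ij``; substituting the blend into each
constraint kind yields a condition on ``a_ij`` that is linear (range,
intra) or quadratic (cross, after tying the two configurations' ESS
together).  This module solves those conditions in closed form, aggregates
them into per-configuration lower bounds, and selects global and local ESS
values by cross-validated held-out log-likelihood.

Bound semantics: each bound op reports the full solution set of the
condition on ``a >= 0`` as an interval (the component relevant for a lower
bound), with:

* ``bound`` — the threshold above which the constraint holds for every
  larger ESS, when such a threshold exists (the usual case; this is the
  quantity the closed-form expressions produce);
* otherwise, for a bounded solution interval, its left end, with
  ``persistent=False`` — the post-hoc satisfaction pass is then the guard;
* ``satisfiable=False`` when no ESS can enforce the constraint (the prior
  shape itself contradicts it).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .constraints import (
    ConstraintSet,
    CrossConstraint,
    IntraConstraint,
    RangeConstraint,
)
from .network import CountTable, Dataset, Network
from .prior import PriorSpec

__all__ = [
    "ESSBound",
    "ESSAssignment",
    "ess_bound_range",
    "ess_bound_intra",
    "ess_bound_cross",
    "derive_local_bounds",
    "effective_bounds",
    "cross_validate_global_ess",
    "assign_local_ess",
]

_TOL = 1e-12
_INF = math.inf


@dataclass(frozen=True)
class ESSBound:
    """Solution of one ESS condition, optionally tagged with the CPT
    coordinates and the constraint it came from."""

    bound: float | None  # smallest usable ESS; None when unsatisfiable
    upper: float  # right end of the solution component (inf = unbounded)
    satisfiable: bool
    persistent: bool  # True when every a >= bound satisfies the constraint
    node: str | None = None
    j: int | None = None
    source: object = None

    def at(self, node: str, j: int, source) -> "ESSBound":
        return replace(self, node=node, j=j, source=source)


def _unsat() -> ESSBound:
    return ESSBound(None, -_INF, False, False)


def _from_interval(lo: float, hi: float) -> ESSBound:
    if hi < max(lo, 0.0) - _TOL:
        return _unsat()
    lo = max(lo, 0.0)
    return ESSBound(lo, hi, True, math.isinf(hi))


def _solve_linear(coef: float, rhs: float) -> tuple[float, float] | None:
    """Solution interval of ``coef * a <= rhs`` intersected with a >= 0."""
    if abs(coef) <= _TOL:
        return (0.0, _INF) if rhs >= -_TOL else None
    if coef > 0:
        hi = rhs / coef
        return (0.0, hi) if hi >= -_TOL else None
    return (max(0.0, rhs / coef), _INF)


def ess_bound_range(
    n_ijk: float, n_ij: float, prior: float, lower: float, upper: float
) -> ESSBound:
    """Smallest ESS for which the blend lands in ``[lower, upper]``.

    Substituting the blend into the bounds gives two linear conditions:
    ``a (lower - p) <= N_ijk - N_ij lower`` and
    ``a (p - upper) <= N_ij upper - N_ijk``; their intersection is the
    solution set.
    """
    s1 = _solve_linear(lower - prior, n_ijk - n_ij * lower)
    s2 = _solve_linear(prior - upper, n_ij * upper - n_ijk)
    if s1 is None or s2 is None:
        return _unsat()
    return _from_interval(max(s1[0], s2[0]), min(s1[1], s2[1]))


def ess_bound_intra(
    n_lesser: float, n_greater: float, prior_lesser: float, prior_greater: float
) -> ESSBound:
    """Smallest ESS enforcing ``theta_hat[lesser] <= theta_hat[greater]``
    within one row: ``a (p_les - p_gr) <= N_gr - N_les``."""
    s = _solve_linear(prior_lesser - prior_greater, n_greater - n_lesser)
    if s is None:
        return _unsat()
    return _from_interval(*s)


def ess_bound_cross(
    n_j1k: float,
    n_j1: float,
    n_j2k: float,
    n_j2: float,
    prior_j1k: float,
    prior_j2k: float,
) -> ESSBound:
    """Smallest common ESS ``a = a_ij1 = a_ij2`` enforcing the ordering
    ``theta_hat[j1, k] <= theta_hat[j2, k]`` across two configurations.

    Clearing denominators yields the quadratic condition
    ``a^2 (p1 - p2) + a (N_j1k - N_j2k + N_j2 p1 - N_j1 p2)
    + (N_j2 N_j1k - N_j1 N_j2k) <= 0``.
    """
    a = prior_j1k - prior_j2k
    b = n_j1k - n_j2k + n_j2 * prior_j1k - n_j1 * prior_j2k
    c = n_j2 * n_j1k - n_j1 * n_j2k
    if abs(a) <= _TOL:
        s = _solve_linear(b, -c)
        if s is None:
            return _unsat()
        return _from_interval(*s)
    disc = b * b - 4 * a * c
    if a < 0:
        if disc <= 0:  # parabola opens down, never positive
            return _from_interval(0.0, _INF)
        r1 = (-b + math.sqrt(disc)) / (2 * a)  # smaller root (a < 0)
        r2 = (-b - math.sqrt(disc)) / (2 * a)  # larger root
        # q <= 0 outside (r1, r2); the unbounded component [r2, inf) is the
        # persistent lower bound
        return _from_interval(r2, _INF)
    # a > 0: q <= 0 only between the roots -- a bounded window, no
    # persistent bound exists
    if disc < 0:
        return _unsat()
    r1 = (-b - math.sqrt(disc)) / (2 * a)
    r2 = (-b + math.sqrt(disc)) / (2 * a)
    return _from_interval(r1, r2)


# ---------------------------------------------------------------------------
# aggregation over a constraint set


def derive_local_bounds(
    counts: CountTable, prior: PriorSpec, cs: ConstraintSet
) -> list[ESSBound]:
    """One :class:`ESSBound` per (constraint, configuration it touches).

    A cross constraint ties two configurations' ESS together, so it emits a
    bound for both.
    """
    out: list[ESSBound] = []
    for c in cs.all():
        n = counts.counts[c.node]
        p = prior[c.node]
        rows = n.sum(axis=1)
        if isinstance(c, RangeConstraint):
            b = ess_bound_range(
                n[c.j, c.k], rows[c.j], p[c.j, c.k], c.lower, c.upper
            )
            out.append(b.at(c.node, c.j, c))
        elif isinstance(c, IntraConstraint):
            b = ess_bound_intra(
                n[c.j, c.lesser], n[c.j, c.greater], p[c.j, c.lesser], p[c.j, c.greater]
            )
            out.append(b.at(c.node, c.j, c))
        else:
            b = ess_bound_cross(
                n[c.lesser_j, c.k],
                rows[c.lesser_j],
                n[c.greater_j, c.k],
                rows[c.greater_j],
                p[c.lesser_j, c.k],
                p[c.greater_j, c.k],
            )
            out.append(b.at(c.node, c.lesser_j, c))
            out.append(b.at(c.node, c.greater_j, c))
    return out


def effective_bounds(bounds: list[ESSBound]) -> dict[tuple[str, int], float]:
    """Per-configuration effective lower bound: the max over all finite
    bounds naming that configuration.  Unsatisfiable bounds map to ``inf``
    (callers fall back to the maximum candidate with a warning)."""
    out: dict[tuple[str, int], float] = {}
    for b in bounds:
        key = (b.node, b.j)
        val = _INF if not b.satisfiable else float(b.bound)
        out[key] = max(out.get(key, 0.0), val)
    return out


# ---------------------------------------------------------------------------
# cross-validation


@dataclass
class ESSAssignment:
    """Selected global ESS per node and local ESS per parent configuration."""

    global_ess: dict[str, float]
    local_ess: dict[str, np.ndarray]  # per node, shape (q_i,)
    bounds: list[ESSBound] = field(default_factory=list)
    cv_traces: dict = field(default_factory=dict)

    def alpha(self, node: str) -> np.ndarray:
        return self.local_ess[node]

    @classmethod
    def constant(cls, net: Network, value: float) -> "ESSAssignment":
        return cls(
            global_ess={v: value for v in net.nodes},
            local_ess={
                v: np.full(net.parent_config_count(v), float(value))
                for v in net.nodes
            },
        )


def _folds(n: int, folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    if n < 10 and folds > 1 and folds != n:
        warnings.warn(f"only {n} records; falling back to leave-one-out")
        folds = n
    folds = min(folds, n)
    perm = rng.permutation(n)
    return [np.asarray(f) for f in np.array_split(perm, folds)]


def _node_count_arrays(data: Dataset, net: Network, node: str):
    """Per-record (parent-config, state) index pair for one node."""
    j = np.zeros(data.size, dtype=int)
    for p in net.parents[node]:
        j = j * net.cardinalities[p] + data.records[p].to_numpy()
    return j, data.records[node].to_numpy()


def _counts_from_idx(j, k, q, r, keep) -> np.ndarray:
    tab = np.zeros((q, r))
    np.add.at(tab, (j[keep], k[keep]), 1)
    return tab


def _heldout_ll(train_counts, test_j, test_k, prior_tab, alphas) -> np.ndarray:
    """Held-out log-likelihood for each candidate ESS (vectorized).

    ``alphas`` has shape (ncand, q) -- a per-configuration ESS for each
    candidate.  Returns shape (ncand,).
    """
    rows = train_counts.sum(axis=1)  # (q,)
    est = (train_counts[None] + alphas[:, :, None] * prior_tab[None]) / (
        rows[None, :, None] + alphas[:, :, None]
    )
    vals = est[:, test_j, test_k]  # (ncand, ntest)
    return np.log(np.clip(vals, 1e-300, None)).sum(axis=1)


def cross_validate_global_ess(
    data: Dataset,
    net: Network,
    prior: PriorSpec,
    candidates: list[int] | None = None,
    folds: int = 5,
    seed: int | np.random.Generator = 0,
) -> tuple[dict[str, int], dict]:
    """Select one global ESS per node by K-fold cross-validation.

    Each candidate ESS is scored by the summed held-out log-likelihood of
    the blend estimates fit on the training folds; ties go to the smallest
    candidate.  Returns the selection and the per-node score traces.
    """
    if candidates is None:
        candidates = list(range(1, 51))
    if not candidates:
        raise ValueError("candidate list must be nonempty")
    if data.size == 0:
        raise ValueError("cannot cross-validate on an empty dataset")
    rng = np.random.default_rng(seed)
    fold_idx = _folds(data.size, folds, rng)
    cand = np.asarray(sorted(candidates), dtype=float)
    selected: dict[str, int] = {}
    traces: dict[str, np.ndarray] = {}
    for v in net.nodes:
        q, r = net.parent_config_count(v), net.cardinalities[v]
        j, k = _node_count_arrays(data, net, v)
        alphas = np.repeat(cand[:, None], q, axis=1)  # global: same per config
        scores = np.zeros(len(cand))
        for test in fold_idx:
            keep = np.ones(data.size, dtype=bool)
            keep[test] = False
            tr = _counts_from_idx(j, k, q, r, keep)
            scores += _heldout_ll(tr, j[test], k[test], prior[v], alphas)
        best = int(np.argmax(np.round(scores, 10)))  # argmax takes first = smallest
        selected[v] = int(cand[best])
        traces[v] = scores
    return selected, traces


def assign_local_ess(
    global_ess: dict[str, int],
    bounds: list[ESSBound],
    data: Dataset,
    net: Network,
    prior: PriorSpec,
    max_candidate: int = 50,
    folds: int = 5,
    seed: int | np.random.Generator = 0,
    counts: CountTable | None = None,
    cs: ConstraintSet | None = None,
) -> ESSAssignment:
    """Turn the global selection into per-configuration local ESS values.

    Unconstrained configurations inherit the global ESS.  A constrained
    configuration keeps the global ESS when it already clears the bound;
    otherwise its ESS is cross-validated over the integer grid from
    ``ceil(bound)`` to ``max_candidate`` (just ``ceil(bound)``, with a
    warning, when that exceeds the grid).  When ``cs`` is supplied, a final
    satisfaction pass escalates the two ESS values of any still-violated
    cross constraint jointly along the grid.
    """
    rng = np.random.default_rng(seed)
    fold_idx = _folds(data.size, folds, rng)
    eff = effective_bounds(bounds)
    assignment = ESSAssignment(
        global_ess=dict(global_ess),
        local_ess={
            v: np.full(net.parent_config_count(v), float(global_ess[v]))
            for v in net.nodes
        },
        bounds=bounds,
    )
    for (node, j), bound in eff.items():
        g = global_ess[node]
        if math.isinf(bound):
            warnings.warn(
                f"node {node!r} config {j}: unsatisfiable ESS bound; "
                f"falling back to max candidate {max_candidate}"
            )
            assignment.local_ess[node][j] = max_candidate
            continue
        if g >= bound:
            continue  # global ESS already clears the bound
        lo = max(1, math.ceil(bound - 1e-9))
        if lo > max_candidate:
            warnings.warn(
                f"node {node!r} config {j}: bound {bound:.3g} exceeds the "
                f"candidate grid; using {lo}"
            )
            assignment.local_ess[node][j] = lo
            continue
        cand = np.arange(lo, max_candidate + 1, dtype=float)
        q, r = net.parent_config_count(node), net.cardinalities[node]
        jj, kk = _node_count_arrays(data, net, node)
        scores = np.zeros(len(cand))
        base = assignment.local_ess[node]
        for test in fold_idx:
            keep = np.ones(data.size, dtype=bool)
            keep[test] = False
            tr = _counts_from_idx(jj, kk, q, r, keep)
            alphas = np.repeat(base[None, :], len(cand), axis=0)
            alphas[:, j] = cand
            scores += _heldout_ll(tr, jj[test], kk[test], prior[node], alphas)
        best = int(np.argmax(np.round(scores, 10)))
        assignment.local_ess[node][j] = cand[best]
        assignment.cv_traces[(node, j)] = scores
    if cs is not None and counts is not None:
        _posthoc_cross_pass(assignment, counts, prior, cs, max_candidate)
    return assignment


def _posthoc_cross_pass(
    assignment: ESSAssignment,
    counts: CountTable,
    prior: PriorSpec,
    cs: ConstraintSet,
    max_candidate: int,
) -> None:
    """The cross bounds are derived under a shared ESS for the two
    configurations, but selection may assign them different values; re-check
    the final blends and jointly escalate both ESS values until the
    ordering holds or the grid is exhausted."""
    from .estimators import map_estimate

    for c in cs.all():
        if not isinstance(c, CrossConstraint):
            continue
        for _ in range(2 * max_candidate):
            est = map_estimate(counts, prior, assignment)
            tab = est[c.node]
            if tab[c.lesser_j, c.k] <= tab[c.greater_j, c.k] + 1e-9:
                break
            a = assignment.local_ess[c.node]
            if a[c.lesser_j] >= max_candidate and a[c.greater_j] >= max_candidate:
                warnings.warn(f"cross constraint {c} unresolved at max ESS")
                break
            a[c.lesser_j] = min(max_candidate, a[c.lesser_j] + 1)
            a[c.greater_j] = min(max_candidate, a[c.greater_j] + 1)
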