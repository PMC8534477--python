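"""Parameter estimators: ML, MAP, max-entropy baselines and the full
constraint-adjusted MAP pipeline.

All estimators return a :class:`~camap.network.ParameterSet` with
normalized rows and are deterministic given their inputs and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .constraints import (
    ConstraintSet,
    check_satisfaction,
    feasibility,
    node_polytope,
)
from .ess import (
    ESSAssignment,
    assign_local_ess,
    cross_validate_global_ess,
    derive_local_bounds,
)
from .network import CountTable, Dataset, Network, ParameterSet, count_sufficient_stats
from .prior import PriorSpec, elicit_prior

__all__ = [
    "EstimatorConfig",
    "FitResult",
    "ml_estimate",
    "map_estimate",
    "map_uniform",
    "cml_estimate",
    "cme_estimate",
    "me_estimate",
    "camap_fit",
]


@dataclass
class EstimatorConfig:
    """Tunables of the full pipeline.

    ``max_ess`` bounds the candidate ESS grid (integers 1..max_ess);
    ``me_epsilon`` is the likelihood slack, in nats per record, of the
    entropy baselines; ``smoothing_floor`` is only applied where a caller
    explicitly asks for floored ML output.
    """

    smoothing_floor: float = 1e-12
    max_ess: int = 50
    cv_folds: int = 5
    tau: float = 0.1
    n_prior_samples: int = 100
    burn_in: int = 100
    thin: int = 10
    seed: int = 0
    me_epsilon: float = 0.05

    def __post_init__(self) -> None:
        if self.max_ess < 1:
            raise ValueError("max_ess must be >= 1")
        for name in ("smoothing_floor", "cv_folds", "tau", "n_prior_samples",
                     "me_epsilon"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FitResult:
    params: ParameterSet
    prior: PriorSpec | None = None
    ess: ESSAssignment | None = None
    violations: list | None = None
    cv_traces: dict = field(default_factory=dict)
    notes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------


def ml_estimate(counts: CountTable, floor: float | None = None) -> ParameterSet:
    """Maximum-likelihood estimate ``N_ijk / N_ij``.

    Empty rows (no observations for a parent configuration) fall back to
    uniform.  An optional probability floor clips zero estimates, for
    consumers that need finite KL against a positive truth; floored rows
    are renormalized.
    """
    tables: dict[str, np.ndarray] = {}
    for v, tab in counts.counts.items():
        tab = np.asarray(tab, dtype=float)
        rows = tab.sum(axis=1, keepdims=True)
        out = np.where(rows > 0, tab / np.where(rows > 0, rows, 1), 1.0 / tab.shape[1])
        if floor is not None:
            out = np.clip(out, floor, None)
            out /= out.sum(axis=1, keepdims=True)
        tables[v] = out
    return ParameterSet(tables)


def _alpha_array(ess, node: str, q: int) -> np.ndarray:
    if isinstance(ess, ESSAssignment):
        return np.asarray(ess.alpha(node), dtype=float)
    if isinstance(ess, dict):
        val = ess[node]
        return np.asarray(val, dtype=float) * np.ones(q) if np.isscalar(val) \
            else np.asarray(val, dtype=float)
    return float(ess) * np.ones(q)


def map_estimate(counts: CountTable, prior: PriorSpec, ess) -> ParameterSet:
    """Posterior-mode blend ``(N_ijk + a_ij p_ijk) / (N_ij + a_ij)``.

    ``ess`` may be an :class:`ESSAssignment`, a per-node dict (scalar or
    per-configuration array), or a single scalar applied everywhere.
    """
    tables: dict[str, np.ndarray] = {}
    for v, tab in counts.counts.items():
        tab = np.asarray(tab, dtype=float)
        q, r = tab.shape
        alpha = _alpha_array(ess, v, q)[:, None]
        rows = tab.sum(axis=1, keepdims=True)
        denom = rows + alpha
        p = np.asarray(prior[v], dtype=float)
        out = np.where(denom > 0, (tab + alpha * p) / np.where(denom > 0, denom, 1),
                       1.0 / r)
        tables[v] = out
    return ParameterSet(tables)


def map_uniform(counts: CountTable, ess: float = 1.0) -> ParameterSet:
    """MAP with a flat prior shape ``1/r_i`` and a fixed (default 1) ESS."""
    tables: dict[str, np.ndarray] = {}
    for v, tab in counts.counts.items():
        tab = np.asarray(tab, dtype=float)
        q, r = tab.shape
        rows = tab.sum(axis=1, keepdims=True)
        tables[v] = (tab + ess / r) / (rows + ess)
    return ParameterSet(tables)


# ---------------------------------------------------------------------------
# constrained optimization baselines


def _node_loglik(theta: np.ndarray, counts: np.ndarray) -> float:
    mask = counts > 0
    return float(np.sum(counts[mask] * np.log(np.clip(theta[mask], 1e-300, None))))


def _optimize_node(
    net: Network,
    node: str,
    cs: ConstraintSet,
    objective,
    jac,
    extra_constraints=(),
    start: np.ndarray | None = None,
) -> np.ndarray:
    """Maximize a smooth concave objective over one node's constraint
    polytope with SLSQP."""
    q, r = net.parent_config_count(node), net.cardinalities[node]
    a_ub, b_ub, a_eq, b_eq = node_polytope(cs, net, node)
    cons = [
        {"type": "ineq", "fun": lambda x, A=a_ub, b=b_ub: b - A @ x,
         "jac": lambda x, A=a_ub: -A},
        {"type": "eq", "fun": lambda x, A=a_eq, b=b_eq: A @ x - b,
         "jac": lambda x, A=a_eq: A},
        *extra_constraints,
    ]
    if start is None:
        ok, witness = feasibility(ConstraintSet({node: cs.for_node(node)}), net)
        if not ok:
            raise ValueError(f"infeasible constraints for node {node!r}")
        start = witness[node].reshape(-1)
    res = minimize(
        lambda x: -objective(x),
        start,
        jac=(lambda x: -jac(x)) if jac else None,
        constraints=cons,
        bounds=[(1e-9, 1.0)] * (q * r),
        method="SLSQP",
        options={"maxiter": 500, "ftol": 1e-12},
    )
    x = np.clip(res.x.reshape(q, r), 1e-12, None)
    return x / x.sum(axis=1, keepdims=True)


def cml_estimate(counts: CountTable, cs: ConstraintSet, net: Network) -> ParameterSet:
    """Constrained maximum likelihood: per node, maximize the multinomial
    log-likelihood subject to the expert constraints and simplex
    conditions (a concave program; cross constraints couple rows, so the
    node's full CPT is optimized jointly)."""
    tables: dict[str, np.ndarray] = {}
    for v in net.nodes:
        n = np.asarray(counts.counts[v], dtype=float)
        flat = n.reshape(-1)
        if not cs.for_node(v):
            tables[v] = ml_estimate(CountTable({v: n}))[v]
            continue
        tables[v] = _optimize_node(
            net,
            v,
            cs,
            objective=lambda x, c=flat: _node_loglik(x, c),
            jac=lambda x, c=flat: np.where(c > 0, c / np.clip(x, 1e-12, None), 0.0),
        )
    return ParameterSet(tables)


def cme_estimate(
    counts: CountTable,
    cs: ConstraintSet,
    net: Network,
    me_epsilon: float = 0.05,
) -> ParameterSet:
    """Constrained maximum entropy: per node, maximize the summed row
    entropies subject to the constraints and to staying within
    ``me_epsilon`` nats per record of the constrained maximum
    log-likelihood.  Large slack recovers the most uniform feasible CPT;
    vanishing slack recovers constrained ML.
    """
    ref = cml_estimate(counts, cs, net)
    n_total = int(sum(np.asarray(t).sum() for t in counts.counts.values())) \
        // max(len(counts.counts), 1)
    tables: dict[str, np.ndarray] = {}
    for v in net.nodes:
        n = np.asarray(counts.counts[v], dtype=float)
        flat = n.reshape(-1)
        ll_max = _node_loglik(ref[v].reshape(-1), flat)
        slack = me_epsilon * max(n_total, 1)

        def entropy(x):
            xc = np.clip(x, 1e-300, None)
            return float(-np.sum(xc * np.log(xc)))

        def entropy_jac(x):
            return -(np.log(np.clip(x, 1e-300, None)) + 1.0)

        ll_con = {
            "type": "ineq",
            "fun": lambda x, c=flat, m=ll_max - slack: _node_loglik(x, c) - m,
            "jac": lambda x, c=flat: np.where(c > 0, c / np.clip(x, 1e-12, None), 0.0),
        }
        tables[v] = _optimize_node(
            net, v, cs, objective=entropy, jac=entropy_jac,
            extra_constraints=(ll_con,),
            start=ref[v].reshape(-1),
        )
    return ParameterSet(tables)


def me_estimate(
    counts: CountTable, net: Network, me_epsilon: float = 0.05
) -> ParameterSet:
    """Unconstrained maximum-entropy baseline (empty constraint set)."""
    return cme_estimate(counts, ConstraintSet(), net, me_epsilon)


# ---------------------------------------------------------------------------
# full pipeline


def camap_fit(
    net: Network,
    data: Dataset,
    cs: ConstraintSet,
    config: EstimatorConfig | None = None,
) -> FitResult:
    """Constraint-adjusted MAP estimation, end to end.

    Pipeline: feasibility check -> prior elicitation by polytope sampling
    -> per-configuration ESS bounds -> cross-validated global ESS ->
    local ESS assignment (with post-hoc cross-constraint pass) -> blend
    estimate.  The result carries the prior, the ESS assignment, the CV
    traces and a constraint-violation report.
    """
    config = config or EstimatorConfig()
    ok, _ = feasibility(cs, net)
    if not ok:
        raise ValueError("expert constraints are infeasible; aborting")
    counts = count_sufficient_stats(data, net)
    rng = np.random.default_rng(config.seed)
    prior = elicit_prior(
        cs,
        net,
        n_samples=config.n_prior_samples,
        tau=config.tau,
        seed=rng,
        burn_in=config.burn_in,
        thin=config.thin,
    )
    bounds = derive_local_bounds(counts, prior, cs)
    candidates = list(range(1, config.max_ess + 1))
    global_ess, traces = cross_validate_global_ess(
        data, net, prior, candidates, folds=config.cv_folds,
        seed=int(rng.integers(2**31)),
    )
    assignment = assign_local_ess(
        global_ess,
        bounds,
        data,
        net,
        prior,
        max_candidate=config.max_ess,
        folds=config.cv_folds,
        seed=int(rng.integers(2**31)),
        counts=counts,
        cs=cs,
    )
    params = map_estimate(counts, prior, assignment)
    violations = check_satisfaction(params, cs, tol=1e-6)
    notes = []
    if violations:
        notes.append(f"{len(violations)} constraint(s) remain violated")
    return FitResult(
        params=params,
        prior=prior,
        ess=assignment,
        violations=violations,
        cv_traces=traces,
        notes=notes,
    )
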