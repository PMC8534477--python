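"""Informative Dirichlet-mean elicitation from the constraint polytope.

The prior shape for each node is the coordinate-wise mean of points sampled
(approximately) uniformly from the convex polytope cut out of the node's
CPT space by the expert constraints plus the simplex conditions.  Sampling
uses hit-and-run: from the current point, pick a random direction inside
the affine row-sum subspace, intersect the line with the polytope, and draw
the next point uniformly on the resulting chord.  A diversity rule keeps
consecutive *retained* samples at least ``tau`` apart in Euclidean norm,
spreading the retained set over the feasible region.

Because the polytope is convex, the mean of feasible points is itself
feasible, so the elicited prior always satisfies the constraints it came
from.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .constraints import ConstraintSet, check_satisfaction, feasibility, node_polytope
from .network import Network, ParameterSet

__all__ = ["PriorSpec", "SamplerState", "HitAndRunSampler", "elicit_prior"]


class ElicitationError(RuntimeError):
    pass


@dataclass
class PriorSpec:
    """Elicited prior shape: one probability table per node, plus the
    sampling settings that produced it."""

    values: ParameterSet
    sample_count: int
    diversity_tau: float
    seed: int | None = None

    def __getitem__(self, node: str) -> np.ndarray:
        return self.values[node]

    @classmethod
    def uniform(cls, net: Network) -> "PriorSpec":
        tables = {
            v: np.full(
                (net.parent_config_count(v), net.cardinalities[v]),
                1.0 / net.cardinalities[v],
            )
            for v in net.nodes
        }
        return cls(ParameterSet(tables), sample_count=0, diversity_tau=0.0)


@dataclass
class SamplerState:
    """Walk bookkeeping: the current chain point and the last retained
    point (the diversity rule compares candidates against the latter)."""

    current: np.ndarray
    last_retained: np.ndarray | None = None
    iteration: int = 0
    tau: float = 0.1
    n_tau_shrinks: int = 0
    retained: list[np.ndarray] = field(default_factory=list)


class HitAndRunSampler:
    """Uniform sampler over one node's constraint polytope.

    Parameters
    ----------
    tau:
        Minimum Euclidean separation between consecutive retained samples.
        Halved (up to ``max_tau_shrinks`` times, then dropped) when the
        polytope is too small to honour it.
    burn_in:
        Hit-and-run steps discarded before the first retained sample.
    thin:
        Steps between retained samples.
    """

    def __init__(
        self,
        cs: ConstraintSet,
        net: Network,
        node: str,
        tau: float = 0.1,
        burn_in: int = 100,
        thin: int = 10,
        max_retries: int = 50,
        max_tau_shrinks: int = 10,
    ) -> None:
        self.net = net
        self.node = node
        self.tau = tau
        self.burn_in = burn_in
        self.thin = thin
        self.max_retries = max_retries
        self.max_tau_shrinks = max_tau_shrinks

        a_ub, b_ub, a_eq, b_eq = node_polytope(cs, net, node)
        ok, witness = feasibility(
            ConstraintSet({node: cs.for_node(node)}), net
        )
        if not ok:
            raise ElicitationError(
                f"constraint polytope for node {node!r} is empty"
            )
        from scipy.linalg import null_space

        self._basis = null_space(a_eq)  # (dim, q(r-1))
        self._x0 = witness[node].reshape(-1)  # interior start (Chebyshev center)
        self._an = a_ub @ self._basis
        self._bn = b_ub - a_ub @ self._x0
        self._z = np.zeros(self._basis.shape[1])

    # -- internals ---------------------------------------------------------
    def _step(self, rng: np.random.Generator) -> None:
        d = rng.standard_normal(self._z.shape[0])
        d /= np.linalg.norm(d)
        # chord: bn - an z >= an d * t
        num = self._bn - self._an @ self._z
        den = self._an @ d
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = num / den
        t_hi = np.min(ratios[den > 1e-12], initial=np.inf)
        t_lo = np.max(ratios[den < -1e-12], initial=-np.inf)
        if not np.isfinite(t_hi) or not np.isfinite(t_lo) or t_hi < t_lo:
            return  # degenerate chord; keep current point
        self._z = self._z + d * (t_lo + (t_hi - t_lo) * rng.random())

    def _point(self) -> np.ndarray:
        x = self._x0 + self._basis @ self._z
        q, r = (
            self.net.parent_config_count(self.node),
            self.net.cardinalities[self.node],
        )
        tab = np.clip(x.reshape(q, r), 0.0, None)
        return tab / tab.sum(axis=1, keepdims=True)

    # -- public ------------------------------------------------------------
    def start_state(self, rng: np.random.Generator) -> SamplerState:
        for _ in range(self.burn_in):
            self._step(rng)
        return SamplerState(current=self._point().reshape(-1), tau=self.tau)

    def sample(self, state: SamplerState, rng: np.random.Generator) -> np.ndarray:
        """Next retained CPT block for the node, honouring the diversity rule."""
        while True:
            for _ in range(self.max_retries):
                for _ in range(self.thin):
                    self._step(rng)
                cand = self._point()
                flat = cand.reshape(-1)
                state.iteration += 1
                if (
                    state.last_retained is None
                    or state.tau <= 0
                    or np.linalg.norm(flat - state.last_retained) >= state.tau
                ):
                    state.last_retained = flat
                    state.current = flat
                    state.retained.append(flat)
                    return cand
            if state.n_tau_shrinks < self.max_tau_shrinks:
                state.n_tau_shrinks += 1
                state.tau /= 2.0
                warnings.warn(
                    f"node {self.node!r}: diversity tau halved to {state.tau:g}"
                )
            else:
                warnings.warn(
                    f"node {self.node!r}: diversity constraint dropped"
                )
                state.tau = 0.0


def sample_feasible_point(
    cs: ConstraintSet,
    net: Network,
    node: str,
    state: SamplerState,
    sampler: HitAndRunSampler,
    rng: np.random.Generator,
) -> np.ndarray:
    """One retained feasible CPT block for ``node`` (thin wrapper over
    :meth:`HitAndRunSampler.sample`)."""
    return sampler.sample(state, rng)


def elicit_prior(
    cs: ConstraintSet,
    net: Network,
    n_samples: int = 100,
    tau: float = 0.1,
    seed: int | np.random.Generator = 0,
    burn_in: int = 100,
    thin: int = 10,
) -> PriorSpec:
    """Elicit the prior shape as the mean of ``n_samples`` retained polytope
    samples per node.

    Nodes (and rows) without constraints are sampled over the bare simplex
    through the same code path, which yields an approximately uniform prior
    for them.  The returned prior satisfies every constraint in ``cs``.
    """
    rng = np.random.default_rng(seed)
    cs.validate(net)
    tables: dict[str, np.ndarray] = {}
    for node in net.nodes:
        sampler = HitAndRunSampler(
            cs, net, node, tau=tau, burn_in=burn_in, thin=thin
        )
        state = sampler.start_state(rng)
        q, r = net.parent_config_count(node), net.cardinalities[node]
        acc = np.zeros((q, r))
        for _ in range(n_samples):
            acc += sampler.sample(state, rng)
        tables[node] = acc / n_samples
    prior = PriorSpec(
        ParameterSet(tables),
        sample_count=n_samples,
        diversity_tau=tau,
        seed=seed if isinstance(seed, int) else None,
    )
    violations = check_satisfaction(prior.values, cs, tol=1e-7)
    if violations:  # pragma: no cover - convexity should prevent this
        raise ElicitationError(f"elicited prior violates constraints: {violations}")
    return prior
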