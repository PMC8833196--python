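"""Exact maximum-entropy (Gibbs) computations on finite state spaces.

The central object is a finite table of loss values H over discrete states
(environment states or genotypes).  At inverse evolutionary temperature
``beta`` the maximum-entropy distribution subject to a fixed average loss is
the Gibbs distribution

    p(state) = exp(-beta * H(state)) / Z(beta),

with partition function Z, average loss U = <H>, Shannon entropy S (nats)
and free energy F = -log(Z)/beta = U - S/beta.  In the evolutionary reading
H is (minus log) additive fitness, 1/beta is the evolutionary temperature
(overall stochasticity of evolution: drift, mutation rate, environmental
noise), Z is macroscopic fitness and F the adaptive potential.

All logarithms are natural; entropies are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import brentq, minimize
from scipy.special import logsumexp, xlogy

__all__ = [
    "LossTable",
    "GibbsEnsemble",
    "MaxEntReport",
    "partition_function",
    "gibbs_ensemble",
    "solve_beta_for_loss",
    "fitness_of",
    "maxent_verify",
]


@dataclass(frozen=True)
class LossTable:
    """Finite loss landscape: an ordered list of states with loss values.

    Parameters
    ----------
    states : sequence of str
        Unique state identifiers (environment states x or genotypes q).
    loss : mapping state -> float
        Dimensionless loss H for each state; must be finite.
    label : str, optional
        Free-text description.
    """

    states: tuple[str, ...]
    loss: Mapping[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.states) == 0:
            raise ValueError("no states")
        if len(set(self.states)) != len(self.states):
            raise ValueError("state identifiers must be unique")
        missing = [s for s in self.states if s not in self.loss]
        if missing:
            raise ValueError(f"loss missing for states: {missing[:5]}")
        H = np.asarray([self.loss[s] for s in self.states], dtype=float)
        if not np.all(np.isfinite(H)):
            raise ValueError("loss values must be finite")
        object.__setattr__(self, "states", tuple(self.states))

    @classmethod
    def from_values(cls, H: Sequence[float], label: str = "") -> "LossTable":
        """Build a table with auto-generated state names s0, s1, ..."""
        states = tuple(f"s{i}" for i in range(len(H)))
        return cls(states, dict(zip(states, map(float, H))), label)

    @property
    def values(self) -> np.ndarray:
        """Loss values in state order."""
        return np.asarray([self.loss[s] for s in self.states], dtype=float)

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class GibbsEnsemble:
    """Equilibrium ensemble at inverse temperature beta.

    Attributes
    ----------
    beta : float
        Inverse evolutionary temperature (>= 0).
    probs : dict state -> float
        Gibbs probabilities, proportional to exp(-beta*H).
    logZ : float
        Log partition function.
    U : float
        Average loss <H>.
    S : float
        Shannon entropy in nats, in [0, log(#states)].
    F : float
        Free energy -logZ/beta (U - S/beta); ``-inf`` convention is never
        needed since beta=0 yields F = nan by definition (no constraint).
    """

    beta: float
    probs: dict[str, float]
    logZ: float
    U: float
    S: float
    F: float

    @property
    def T(self) -> float:
        """Evolutionary temperature 1/beta."""
        return np.inf if self.beta == 0 else 1.0 / self.beta

    def prob_vector(self, states: Sequence[str]) -> np.ndarray:
        return np.asarray([self.probs[s] for s in states], dtype=float)


def _check_beta(beta: float) -> float:
    beta = float(beta)
    if not np.isfinite(beta):
        raise ValueError("beta must be finite")
    if beta < 0:
        raise ValueError("beta must be >= 0 (negative temperatures out of scope)")
    return beta


def partition_function(table: LossTable, beta: float) -> float:
    """Log partition function log Z = log sum_states exp(-beta * H).

    Uses a max-shifted log-sum-exp so large beta (up to ~1e3) cannot
    overflow.
    """
    beta = _check_beta(beta)
    return float(logsumexp(-beta * table.values))


def gibbs_ensemble(table: LossTable, beta: float) -> GibbsEnsemble:
    """Exact Gibbs ensemble on a finite loss table.

    Returns probabilities p ∝ exp(-beta*H), the average loss U, entropy S
    and free energy F = -logZ/beta (nan at beta = 0, where the loss
    constraint is absent and the distribution is uniform).
    """
    beta = _check_beta(beta)
    H = table.values
    logw = -beta * H
    logZ = float(logsumexp(logw))
    logp = logw - logZ
    p = np.exp(logp)
    U = float(p @ H)
    # S = -sum p log p, safe at p == 0 (ground-state limit)
    S = float(-np.sum(xlogy(p, p)))
    S = max(S, 0.0)
    F = -logZ / beta if beta > 0 else float("nan")
    return GibbsEnsemble(
        beta=beta,
        probs=dict(zip(table.states, p.tolist())),
        logZ=logZ,
        U=U,
        S=S,
        F=F,
    )


def solve_beta_for_loss(
    table: LossTable, target_U: float, tol: float = 1e-10, beta_max: float = 1e6
) -> float:
    """Inverse temperature beta at which the Gibbs average loss equals target_U.

    U(beta) decreases strictly from mean(H) at beta = 0 toward min(H) as
    beta → ∞ (on a non-degenerate table), so the root is unique on the
    beta >= 0 branch and is found by bracketed root-finding.

    Raises
    ------
    ValueError
        If target_U <= min(H) ("unreachable loss") or target_U > mean(H)
        ("requires negative beta").
    """
    H = table.values
    Hmin, Hmean = float(H.min()), float(H.mean())
    target_U = float(target_U)
    if np.ptp(H) == 0.0:
        # degenerate table: any beta satisfies U = const; convention beta = 0
        if not np.isclose(target_U, Hmin, rtol=1e-12, atol=1e-12):
            raise ValueError("unreachable loss: all states share a single loss value")
        return 0.0
    if target_U <= Hmin:
        raise ValueError(f"unreachable loss: target_U={target_U} <= min(H)={Hmin}")
    if target_U > Hmean:
        raise ValueError(
            f"requires negative beta: target_U={target_U} > mean(H)={Hmean}"
        )
    if target_U == Hmean:
        return 0.0

    def gap(beta: float) -> float:
        return gibbs_ensemble(table, beta).U - target_U

    lo, hi = 0.0, 1.0
    while gap(hi) > 0:
        hi *= 2.0
        if hi > beta_max:
            raise ValueError("beta exceeds search limit; target_U too close to min(H)")
    beta = brentq(gap, lo, hi, xtol=tol, rtol=8.9e-16, maxiter=500)
    return float(beta)


def fitness_of(table: LossTable, beta: float) -> dict[str, float]:
    """Per-state Malthusian fitness φ(state) = exp(-beta * H(state)).

    The sum of φ over states equals the partition function Z.
    """
    beta = _check_beta(beta)
    phi = np.exp(-beta * table.values)
    return dict(zip(table.states, phi.tolist()))


@dataclass(frozen=True)
class MaxEntReport:
    """Outcome of the independent constrained-entropy-maximization check."""

    converged: bool
    max_norm_distance: float
    optimizer_message: str
    maxent_probs: dict[str, float] = field(repr=False, default_factory=dict)


def maxent_verify(table: LossTable, beta: float, n_restarts: int = 3) -> MaxEntReport:
    """Numerically maximize entropy subject to the Gibbs average loss.

    Solves max_p { -Σ p log p } over the probability simplex with the
    constraint Σ p H = U(beta), by SLSQP on softmax-parametrized logits
    penalised only through the equality constraints (direct primal solve,
    independent of the exponential-family closed form).  Reports the
    max-norm distance to the analytic Gibbs probabilities; the two agree
    to < 1e-6 when the optimizer converges.
    """
    beta = _check_beta(beta)
    ens = gibbs_ensemble(table, beta)
    H = table.values
    n = len(H)
    target_U = ens.U
    gibbs_p = ens.prob_vector(table.states)

    def neg_entropy(p: np.ndarray) -> float:
        return float(np.sum(xlogy(p, p)))

    def neg_entropy_grad(p: np.ndarray) -> np.ndarray:
        with np.errstate(divide="ignore"):
            g = np.log(np.maximum(p, 1e-300)) + 1.0
        return g

    constraints = [
        {"type": "eq", "fun": lambda p: np.sum(p) - 1.0, "jac": lambda p: np.ones(n)},
        {"type": "eq", "fun": lambda p: p @ H - target_U, "jac": lambda p: H},
    ]
    bounds = [(0.0, 1.0)] * n

    best = None
    rng = np.random.default_rng(0)
    starts = [np.full(n, 1.0 / n)]
    for _ in range(max(0, n_restarts - 1)):
        x = rng.dirichlet(np.ones(n))
        starts.append(x)
    message = ""
    for x0 in starts:
        res = minimize(
            neg_entropy,
            x0,
            jac=neg_entropy_grad,
            method="SLSQP",
            bounds=bounds,
            constraints=constraints,
            options={"maxiter": 1000, "ftol": 1e-16},
        )
        p = np.clip(res.x, 0.0, None)
        tot = p.sum()
        if tot > 0:
            p = p / tot
        dist = float(np.max(np.abs(p - gibbs_p)))
        feas = abs(p @ H - target_U)
        if res.success and feas < 1e-8:
            cand = (dist, True, res.message, p)
        else:
            cand = (dist, False, res.message, p)
        if best is None or cand[0] < best[0]:
            best = cand
        message = res.message
        if best[0] < 1e-8 and best[1]:
            break
    dist, ok, message, p = best
    return MaxEntReport(
        converged=bool(ok),
        max_norm_distance=dist,
        optimizer_message=str(message),
        maxent_probs=dict(zip(table.states, p.tolist())),
    )
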