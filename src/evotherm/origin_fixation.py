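"""Weak-mutation origin-fixation dynamics on a finite landscape.

In the weak-mutation (ideal mutation) regime mutations arise rarely and
are fixed or lost before the next one appears, so the population is
monomorphic between events and evolution is a Markov chain on genotype
space: propose a uniformly random Hamming-1 neighbor, accept it with the
probability that a single mutant lineage fixes in a population of size Ne.

Per-genotype Malthusian fitness derives from the landscape free energy via
Z(q) = exp(-beta * F(q)); the fitness ratio of a proposed mutant is
w = exp(-beta * dF).  Both implemented kernels satisfy detailed balance
with respect to the Sella–Hirsh equilibrium

    pi(q) ∝ Z(q)**nu = exp(-beta * nu * F(q)),

with stationary exponent nu = Ne - 1 for the haploid Moran kernel and a
configurable nu for the Metropolis kernel.  The chain is therefore an
exact sampler of the evolutionary equilibrium distribution, and its
long-run genotype frequencies recover the Gibbs law of the landscape.

The temperature-ratio statistic compares two equilibria: since
log Z(q) = -beta * F(q), the per-genotype ratios log Z1(q) / log Z2(q)
collapse to the single number beta1/beta2 = T2/T1 whenever the landscape
is shared and epistasis is absent — giving an operational evolutionary
temperature scale.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .landscape import Landscape

__all__ = [
    "SimulationConfig",
    "Trajectory",
    "StationaryComparison",
    "fixation_probability",
    "simulate",
    "exact_stationary",
    "empirical_distribution",
    "total_variation",
    "compare_stationary",
    "logz_from_frequencies",
    "temperature_ratio",
]

_KERNELS = ("moran", "metropolis")


@dataclass(frozen=True)
class SimulationConfig:
    """Run parameters for the origin-fixation chain.

    Attributes
    ----------
    Ne : int
        Effective population size (>= 2).
    beta : float
        Inverse evolutionary temperature (> 0).
    kernel : {'moran', 'metropolis'}
        Fixation-probability kernel.
    steps : int
        Number of proposed-mutation events.
    burn_in : int
        Events discarded before computing empirical frequencies
        (default steps // 10 when negative).
    seed : int
        RNG seed.
    tau : float
        Nominal mutation interval (bookkeeping only; one event per tau).
    nu : float or None
        Stationary exponent override for the metropolis kernel
        (acceptance min(1, w**nu)); defaults to Ne - 1.
    """

    Ne: int
    beta: float
    kernel: str = "moran"
    steps: int = 100_000
    burn_in: int = -1
    seed: int = 0
    tau: float = 1.0
    nu: float | None = None

    def __post_init__(self) -> None:
        if self.Ne < 2:
            raise ValueError("Ne must be >= 2")
        if not self.beta > 0:
            raise ValueError("beta must be > 0")
        if self.kernel not in _KERNELS:
            raise ValueError(f"unknown kernel {self.kernel!r}; expected {_KERNELS}")
        if self.burn_in < 0:
            object.__setattr__(self, "burn_in", self.steps // 10)
        if not self.burn_in < self.steps:
            raise ValueError("burn_in must be < steps")

    @property
    def stationary_nu(self) -> float:
        """Exponent nu of the stationary law pi ∝ exp(-beta*nu*F)."""
        if self.kernel == "metropolis" and self.nu is not None:
            return float(self.nu)
        return float(self.Ne - 1)


@dataclass(frozen=True)
class Trajectory:
    """Resident genotype after each proposed-mutation event."""

    config: SimulationConfig
    visits: tuple[str, ...]

    def post_burn_in(self) -> tuple[str, ...]:
        return self.visits[self.config.burn_in :]


@dataclass(frozen=True)
class StationaryComparison:
    """Empirical vs exact stationary distribution of one simulation."""

    empirical: dict[str, float]
    exact: dict[str, float]
    tv_distance: float


def fixation_probability(
    w: float, Ne: int, kernel: str = "moran", nu: float | None = None
) -> float:
    """Probability that a single mutant of relative fitness w fixes.

    moran
        Haploid Moran result (1 - 1/w) / (1 - w**-Ne), with the neutral
        limit 1/Ne at w = 1.  Detailed balance holds with stationary
        weight phi(q)**(Ne-1).
    metropolis
        min(1, w**nu) / Ne with nu = Ne - 1 by default; same stationary
        law as moran (the 1/Ne factor is symmetric and preserves the
        neutral fixation rate).
    """
    w = float(w)
    if w <= 0:
        raise ValueError("fitness ratio w must be > 0")
    if Ne < 2:
        raise ValueError("Ne must be >= 2")
    if kernel == "moran":
        logw = np.log(w)
        if abs(logw) < 1e-12:
            return 1.0 / Ne
        # (1 - 1/w) / (1 - w^-Ne), stable for very small/large w via expm1
        num = -np.expm1(-logw)
        den = -np.expm1(-Ne * logw)
        if den == 0.0:
            return 1.0 / Ne
        if np.isinf(den):  # deleterious limit: w**-Ne overflow
            return float(num * np.exp(Ne * logw)) if logw < 0 else 1.0
        return float(num / den)
    if kernel == "metropolis":
        exponent = float(Ne - 1) if nu is None else float(nu)
        return float(min(1.0, w**exponent) / Ne)
    raise ValueError(f"unknown kernel {kernel!r}; expected {_KERNELS}")


def simulate(
    landscape: Landscape, config: SimulationConfig, start: str | None = None
) -> Trajectory:
    """Run the origin-fixation chain; visits record the resident genotype
    after each proposed-mutation event (rejected proposals repeat the
    resident)."""
    rng = np.random.default_rng(config.seed)
    genotypes = landscape.genotypes
    index = {g: i for i, g in enumerate(genotypes)}
    space = landscape.space
    F = landscape.values()
    beta = config.beta

    # Precompute neighbor indices (regular graph) and acceptance probs.
    nbr = np.empty((len(genotypes), space.degree), dtype=np.int64)
    for g, i in index.items():
        nbr[i, :] = [index[h] for h in space.neighbors(g)]
    accept = np.empty_like(nbr, dtype=float)
    for i in range(len(genotypes)):
        for j in range(space.degree):
            w = float(np.exp(-beta * (F[nbr[i, j]] - F[i])))
            accept[i, j] = fixation_probability(w, config.Ne, config.kernel, config.nu)

    cur = index[start] if start is not None else int(rng.integers(len(genotypes)))
    props = rng.integers(0, space.degree, size=config.steps)
    unif = rng.random(config.steps)
    visits = np.empty(config.steps, dtype=np.int64)
    for t in range(config.steps):
        j = props[t]
        if unif[t] < accept[cur, j]:
            cur = nbr[cur, j]
        visits[t] = cur
    names = np.asarray(genotypes, dtype=object)
    return Trajectory(config=config, visits=tuple(names[visits].tolist()))


def exact_stationary(
    landscape: Landscape,
    Ne: int,
    beta: float,
    kernel: str = "moran",
    nu: float | None = None,
) -> dict[str, float]:
    """Closed-form stationary law pi(q) ∝ exp(-beta*nu*F(q)), normalized
    in log space; nu is the kernel's stationary exponent (Ne - 1 unless
    overridden for the metropolis kernel)."""
    if kernel not in _KERNELS:
        raise ValueError(f"unknown kernel {kernel!r}; expected {_KERNELS}")
    exponent = float(Ne - 1) if (kernel == "moran" or nu is None) else float(nu)
    F = landscape.values()
    logw = -beta * exponent * F
    logw -= logw.max()
    w = np.exp(logw)
    w /= w.sum()
    return dict(zip(landscape.genotypes, w.tolist()))


def empirical_distribution(
    trajectory: Trajectory, support: Sequence[str]
) -> dict[str, float]:
    """Visit frequencies over a fixed support, after burn-in."""
    counts = Counter(trajectory.post_burn_in())
    n = sum(counts.values())
    return {g: counts.get(g, 0) / n for g in support}


def total_variation(p: Mapping[str, float], q: Mapping[str, float]) -> float:
    """Total variation distance: half the L1 distance over the union support."""
    keys = set(p) | set(q)
    return 0.5 * sum(abs(p.get(k, 0.0) - q.get(k, 0.0)) for k in keys)


def compare_stationary(
    landscape: Landscape, trajectory: Trajectory
) -> StationaryComparison:
    """Empirical vs exact stationary law of the trajectory's own config."""
    cfg = trajectory.config
    exact = exact_stationary(landscape, cfg.Ne, cfg.beta, cfg.kernel, cfg.nu)
    emp = empirical_distribution(trajectory, landscape.genotypes)
    return StationaryComparison(
        empirical=emp, exact=exact, tv_distance=total_variation(emp, exact)
    )


def logz_from_frequencies(
    freqs: Mapping[str, float], nu: float, reference: str | None = None
) -> dict[str, float]:
    """Per-genotype log macroscopic fitness from equilibrium frequencies.

    Since pi(q) ∝ Z(q)**nu, log Z(q) = (log pi(q) - log pi(q_ref)) / nu up
    to the additive gauge fixed by the reference genotype (default: the
    most frequent one, i.e. log Z is measured relative to the fittest
    genotype).  Genotypes never visited are dropped.
    """
    obs = {g: f for g, f in freqs.items() if f > 0}
    if not obs:
        raise ValueError("no observed genotypes")
    if reference is None:
        reference = max(obs, key=obs.get)
    if reference not in obs:
        raise ValueError(f"reference genotype {reference!r} not observed")
    ref_logp = np.log(obs[reference])
    return {g: (float(np.log(f)) - float(ref_logp)) / nu for g, f in obs.items()}


def temperature_ratio(
    logZ1: Mapping[str, float],
    logZ2: Mapping[str, float],
    eps: float = 1e-6,
    method: str = "median",
) -> tuple[float, float, int]:
    """Evolutionary temperature ratio T2/T1 = beta1/beta2 from two equilibria.

    Without epistasis log Z(q) = -beta * F(q), so the per-genotype ratios
    r(q) = logZ1(q) / logZ2(q) are independent of q and equal beta1/beta2.
    Genotypes with |logZ2| <= eps are excluded (near-zero denominators).

    Parameters
    ----------
    method : {'median', 'wls'}
        Central estimate: the median of r(q) (robust default), or weighted
        least squares of logZ1 on logZ2 through the origin with weights
        logZ2**2 (equivalently, sum(z1*z2)/sum(z2*z2)).

    Returns
    -------
    (ratio, dispersion, n_excluded)
        dispersion = max_q |r(q) - median(r)| over retained genotypes, the
        q-independence diagnostic (≈ 0 for exact inputs on a shared
        landscape).
    """
    common = sorted(set(logZ1) & set(logZ2))
    if not common:
        raise ValueError("no shared genotypes")
    z1 = np.asarray([logZ1[g] for g in common], dtype=float)
    z2 = np.asarray([logZ2[g] for g in common], dtype=float)
    keep = np.abs(z2) > eps
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("logZ too close to zero for every shared genotype")
    r = z1[keep] / z2[keep]
    med = float(np.median(r))
    if method == "median":
        ratio = med
    elif method == "wls":
        ratio = float(np.dot(z1[keep], z2[keep]) / np.dot(z2[keep], z2[keep]))
    else:
        raise ValueError(f"unknown method {method!r}")
    dispersion = float(np.max(np.abs(r - med)))
    return ratio, dispersion, n_excluded
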