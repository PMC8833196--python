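"""The "ideal gas of organisms": a closed-form phenomenological loss.

The average population loss is modeled as

    U(S, K) = a * S**n * exp(b*K/S),

where S is the entropy of the environment (nats), K the number of
adaptable variables (genes/sites available to selection), a > 0 a loss
scale, b > 0 the population-size-independent stochasticity coefficient of
the relation Ne ∝ exp(bK/S), and n > 1 the environment-entropy exponent
(richer environments mean larger per-organism loss).  The conjugate
intensive variables are the evolutionary temperature T = ∂U/∂S and the
evolutionary potential mu = ∂U/∂K (loss change per adaptable variable
added), and the grand potential is the double Legendre transform

    Omega(T, mu) = U - T*S - mu*K = (1 - n) * S * mu / b = (1 - n) * U.

Because U is homogeneous of degree n in (S, K), the degree-1 Euler
identity T*S + mu*K = U generalizes to T*S + mu*K = n*U; the package
reports the Euler ratio rather than asserting the degree-1 form.

The grand potential can also be reconstructed phenomenologically from
time-series observations: if the distribution of K at temperature T has
cumulants kappa_j, then

    Omega(T, mu) = -T * sum_j kappa_j * (mu/T)**j / j!,

the cumulant-generating-function expansion of the grand-canonical log
partition sum.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhenoModel",
    "IntensiveState",
    "CumulantSpec",
    "FirstLawReport",
    "U_of",
    "intensives",
    "entropy_from_intensives",
    "grand_potential",
    "euler_first_law_check",
    "K_required",
    "Ne_of",
    "cumulants_from_samples",
    "reconstruct_grand_potential",
]


@dataclass(frozen=True)
class PhenoModel:
    """Parameters (a, b, n) of U(S,K) = a * S**n * exp(b*K/S).

    a : loss scale (> 0); b : stochasticity coefficient (> 0) linking
    population size to adaptable variables, Ne = exp(b*K/S); n :
    environment-entropy exponent (> 1; the n = 1 branch degenerates the
    Legendre inversion and is rejected where it matters).
    """

    a: float = 1.0
    b: float = 1.0
    n: float = 2.0

    def __post_init__(self) -> None:
        for name in ("a", "b", "n"):
            v = getattr(self, name)
            if not (np.isfinite(v)):
                raise ValueError(f"{name} must be finite")
        if self.a <= 0 or self.b <= 0:
            raise ValueError("a and b must be > 0")
        if self.n == 1.0:
            raise ValueError("n = 1 is a degenerate Legendre branch")


@dataclass(frozen=True)
class IntensiveState:
    """Intensive description at a point (S, K): T_evo = ∂U/∂S,
    mu = ∂U/∂K, the loss U itself and the grand potential
    Omega = U - T_evo*S - mu*K."""

    T_evo: float
    mu: float
    U: float
    Omega: float


@dataclass(frozen=True)
class FirstLawReport:
    """First-law and Euler-identity diagnostics at (S, K)."""

    dU_exact: float
    dU_first_law: float
    residual: float
    euler_ratio: float


def _check_SK(S: float, K: float) -> tuple[float, float]:
    S, K = float(S), float(K)
    if S <= 0:
        raise ValueError("S must be > 0")
    if K < 0:
        raise ValueError("K must be >= 0")
    return S, K


def U_of(model: PhenoModel, S: float, K: float) -> float:
    """Average loss U(S,K) = a * S**n * exp(b*K/S)."""
    S, K = _check_SK(S, K)
    return model.a * S**model.n * math.exp(model.b * K / S)


def intensives(model: PhenoModel, S: float, K: float) -> IntensiveState:
    """Analytic intensive variables at (S, K).

    mu = (b/S) * U and T_evo = (mu/b) * (n - b*K/S); these are the exact
    partial derivatives of U and match central finite differences to
    O(h^2).  Omega = U - T*S - mu*K = (1-n)*U exactly for this model.
    """
    S, K = _check_SK(S, K)
    U = U_of(model, S, K)
    mu = model.b / S * U
    T_evo = (mu / model.b) * (model.n - model.b * K / S)
    Omega = U - T_evo * S - mu * K
    return IntensiveState(T_evo=T_evo, mu=mu, U=U, Omega=Omega)


def entropy_from_intensives(model: PhenoModel, T_evo: float, mu: float) -> float:
    """Invert T = (mu/b)(n + log(a*b/mu) + (n-1) log S) for S (n > 1 branch)."""
    if mu <= 0:
        raise ValueError("mu must be > 0 on this branch")
    logS = (model.b * T_evo / mu - model.n - math.log(model.a * model.b / mu)) / (
        model.n - 1.0
    )
    return math.exp(logS)


def grand_potential(
    model: PhenoModel,
    S: float | None = None,
    K: float | None = None,
    T_evo: float | None = None,
    mu: float | None = None,
) -> float:
    """Grand potential Omega via either route.

    Extensive route (S, K given): Omega = U - T*S - mu*K, which equals
    (1-n)*S*mu/b = (1-n)*U identically.  Intensive route (T_evo, mu
    given): invert the temperature relation for S, then apply
    Omega = (1-n)*S*mu/b.  The two routes agree to ~1e-9 relative.
    """
    if model.n <= 1:
        raise ValueError("degenerate Legendre branch: need n > 1")
    if S is not None and K is not None:
        st = intensives(model, S, K)
        return (1.0 - model.n) * float(S) * st.mu / model.b
    if T_evo is not None and mu is not None:
        if mu <= 0:
            raise ValueError("mu must be > 0 for the intensive route")
        S_inv = entropy_from_intensives(model, T_evo, mu)
        return (1.0 - model.n) * S_inv * mu / model.b
    raise ValueError("supply either (S, K) or (T_evo, mu)")


def euler_first_law_check(
    model: PhenoModel, S: float, K: float, dS: float, dK: float
) -> FirstLawReport:
    """Check dU = T*dS + mu*dK to second order, and report the Euler ratio
    (T*S + mu*K)/U (equal to n for this degree-n homogeneous model).

    The exact increment is evaluated symmetrically about (S, K), i.e.
    dU = U(S+dS/2, K+dK/2) - U(S-dS/2, K-dK/2), so the quadratic Taylor
    term cancels and the residual against T*dS + mu*dK is O(d^3)."""
    S, K = _check_SK(S, K)
    if abs(dS) > 1e-3 * S or (K > 0 and abs(dK) > 1e-3 * K):
        raise ValueError("increments must satisfy |dS|/S, |dK|/K <= 1e-3")
    st = intensives(model, S, K)
    dU_exact = U_of(model, S + dS / 2, K + dK / 2) - U_of(
        model, S - dS / 2, K - dK / 2
    )
    dU_first_law = st.T_evo * dS + st.mu * dK
    euler_ratio = (st.T_evo * S + st.mu * K) / st.U
    return FirstLawReport(
        dU_exact=dU_exact,
        dU_first_law=dU_first_law,
        residual=abs(dU_exact - dU_first_law),
        euler_ratio=euler_ratio,
    )


def K_required(model: PhenoModel, S: float, Ne: float) -> float:
    """Adaptable variables needed by a population of size Ne in an
    environment of entropy S: K = S * log(Ne) / b."""
    if Ne <= 1:
        raise ValueError("Ne must be > 1")
    S = float(S)
    if S <= 0:
        raise ValueError("S must be > 0")
    return S * math.log(Ne) / model.b


def Ne_of(model: PhenoModel, S: float, K: float) -> float:
    """Inverse of K_required: Ne = exp(b*K/S)."""
    S, K = _check_SK(S, K)
    return math.exp(model.b * K / S)


@dataclass(frozen=True)
class CumulantSpec:
    """Estimated cumulants kappa_1..kappa_m of the K-distribution at a
    given evolutionary temperature, for grand-potential reconstruction."""

    cumulants: tuple[float, ...]
    T_evo: float
    truncation: int

    def __post_init__(self) -> None:
        if self.truncation != len(self.cumulants):
            raise ValueError("truncation must equal the number of cumulants")
        if self.truncation < 1:
            raise ValueError("need at least one cumulant")
        if self.truncation > 10:
            raise ValueError("truncation m > 10 exceeds the numerical sanity cap")


def _raw_to_cumulants(raw: np.ndarray) -> np.ndarray:
    # kappa_r = m'_r - sum_{j=1}^{r-1} C(r-1, j-1) kappa_j m'_{r-j}
    m = len(raw)
    kappa = np.zeros(m)
    for r in range(1, m + 1):
        acc = raw[r - 1]
        for j in range(1, r):
            acc -= math.comb(r - 1, j - 1) * kappa[j - 1] * raw[r - j - 1]
        kappa[r - 1] = acc
    return kappa


def cumulants_from_samples(samples, m: int = 6, T_evo: float = 1.0) -> CumulantSpec:
    """Cumulant estimates from an i.i.d. sample.

    Orders 1..4 use the unbiased k-statistics; orders 5..m use plug-in
    estimates from sample raw moments (biased at O(1/n), documented).
    Deterministic for fixed input.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if m > 10:
        raise ValueError("m > 10 exceeds the numerical sanity cap")
    if m < 1:
        raise ValueError("m must be >= 1")
    nobs = x.size
    if nobs < 10 * m:
        raise ValueError(f"need at least 10*m = {10 * m} samples, got {nobs}")

    raw = np.array([np.mean(x**r) for r in range(1, m + 1)])
    kappa = _raw_to_cumulants(raw)

    # replace orders 1..4 by exact unbiased k-statistics
    n_ = float(nobs)
    xbar = x.mean()
    d = x - xbar
    m2 = np.mean(d**2)
    m3 = np.mean(d**3)
    m4 = np.mean(d**4)
    k = [float(xbar)]
    if m >= 2:
        k.append(float(n_ / (n_ - 1) * m2))
    if m >= 3:
        k.append(float(n_**2 / ((n_ - 1) * (n_ - 2)) * m3))
    if m >= 4:
        k4 = (
            n_**2
            * ((n_ + 1) * m4 - 3 * (n_ - 1) * m2**2)
            / ((n_ - 1) * (n_ - 2) * (n_ - 3))
        )
        k.append(float(k4))
    kappa[: len(k)] = k
    return CumulantSpec(cumulants=tuple(kappa.tolist()), T_evo=float(T_evo), truncation=m)


def reconstruct_grand_potential(spec: CumulantSpec, mu: float) -> float:
    """Grand potential from the truncated cumulant series:

        Omega = -T * sum_{j=1..m} kappa_j * (mu/T)**j / j!

    Warns when the last retained term exceeds 1% of the partial sum
    (heuristic convergence check; the series radius is not known a
    priori).
    """
    if spec.T_evo == 0:
        raise ValueError("T_evo = 0: the cumulant expansion is undefined")
    ratio = float(mu) / spec.T_evo
    terms = [
        kap * ratio**j / math.factorial(j)
        for j, kap in enumerate(spec.cumulants, start=1)
    ]
    total = sum(terms)
    if terms and total != 0 and abs(terms[-1]) > 0.01 * abs(total):
        warnings.warn(
            "cumulant series may not have converged: last term "
            f"{terms[-1]:.3g} exceeds 1% of the partial sum {total:.3g}",
            RuntimeWarning,
            stacklevel=2,
        )
    return -spec.T_evo * total
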