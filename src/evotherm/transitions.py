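"""The origin of life as a phase transition between dual ensembles.

Before the transition the system is an ideal gas of molecules with grand
potential Omega_p(T, M) = C_p * T**alpha * exp(gamma*M/T) (physical
temperature T, chemical potential M); after it, an ideal gas of organisms
with Omega_b(T_evo, mu) = C_b * mu**c * exp(b*T_evo/mu) (evolutionary
temperature and potential).  Phases coexist where the two grand
potentials are equal.

The dual mappings relate the two descriptions of the same system:

    T_evo0 = (alpha/b) * mu0 * log(T_phys0)      (learning loss is
                                                  logarithmically smaller
                                                  than stochastic loss)
    M0     = (c/gamma) * T_phys0 * log(mu0)

Under these mappings Omega_p = Omega_b identically when C_p = C_b, for
any T_phys0 > 1.  The marked critical point additionally requires the
two temperatures to coincide, T_evo0 = T_phys0, which reduces to the
fixed point T = k*log(T) with k = alpha*mu0/b: no real solution for
k < e, the tangent root T = e at k = e, and two roots (one in (1, e),
one in (e, inf)) for k > e.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "PhysicalPhase",
    "BiologicalPhase",
    "CriticalPoint",
    "ScanRow",
    "PhaseScanResult",
    "dual_temperature",
    "dual_chemical_potential",
    "log_omega_p",
    "log_omega_b",
    "coexistence_residual",
    "critical_points",
    "phase_scan",
]


@dataclass(frozen=True)
class PhysicalPhase:
    """Ideal gas of molecules: Omega_p = C_p * T**alpha * exp(gamma*M/T)."""

    alpha: float = 1.0
    gamma: float = 1.0
    C_p: float = 1.0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.alpha, self.gamma, self.C_p))):
            raise ValueError("phase parameters must be finite")
        if self.alpha <= 0 or self.gamma <= 0 or self.C_p <= 0:
            raise ValueError("alpha, gamma, C_p must be > 0")


@dataclass(frozen=True)
class BiologicalPhase:
    """Ideal gas of organisms: Omega_b = C_b * mu**c * exp(b*T_evo/mu)."""

    b: float = 1.0
    c: float = 1.0
    C_b: float = 1.0

    def __post_init__(self) -> None:
        if not all(map(math.isfinite, (self.b, self.c, self.C_b))):
            raise ValueError("phase parameters must be finite")
        if self.b <= 0 or self.c <= 0 or self.C_b <= 0:
            raise ValueError("b, c, C_b must be > 0")


@dataclass(frozen=True)
class CriticalPoint:
    """A coexistence point in both descriptions.

    T_phys0/M0 are the physical temperature and chemical potential,
    T_evo0/mu0 the evolutionary temperature and potential, ``branch``
    labels the fixed-point root ('low-T', 'high-T' or 'tangent'), and
    ``residual`` is |Omega_p - Omega_b| at the point.
    """

    T_phys0: float
    M0: float
    T_evo0: float
    mu0: float
    residual: float
    branch: str = ""


def dual_temperature(
    alpha: float, b: float, mu0: float, tol: float = 1e-12
) -> list[float]:
    """Roots T > 1 of the fixed point T = k*log(T), k = alpha*mu0/b.

    Returns [] for k < e (no real solution: max of k*log(T) - T is
    k*(log k - 1) < 0), [e] at k = e (tangency), and the two bracketed
    roots [low, high] for k > e, each found by bisection to ~1e-12.
    """
    if mu0 <= 0:
        raise ValueError("mu0 must be > 0")
    k = alpha * mu0 / b
    if k <= 0:
        return []
    e = math.e
    if abs(k - e) <= 1e-12 * e:
        return [e]
    if k < e:
        return []

    def f(T: float) -> float:
        return T - k * math.log(T)

    # f(1) = 1 > 0, f(e) = e - k < 0, f(T) -> +inf: one root each side of e
    low = brentq(f, 1.0 + 1e-15, e, xtol=tol, rtol=8.9e-16)
    hi = 2.0 * e
    while f(hi) < 0:
        hi *= 2.0
    high = brentq(f, e, hi, xtol=tol, rtol=8.9e-16)
    return [float(low), float(high)]


def dual_chemical_potential(
    c: float, gamma: float, T_phys0: float, mu0: float
) -> float:
    """Chemical potential dual: M0 = (c/gamma) * T_phys0 * log(mu0)
    (negative for mu0 < 1)."""
    if mu0 <= 0:
        raise ValueError("mu0 must be > 0")
    return c / gamma * T_phys0 * math.log(mu0)


def log_omega_p(phys: PhysicalPhase, T: float, M: float) -> float:
    """log Omega_p, evaluated in log space (T > 0 required)."""
    if T <= 0:
        raise ValueError("T must be > 0")
    return math.log(phys.C_p) + phys.alpha * math.log(T) + phys.gamma * M / T


def log_omega_b(bio: BiologicalPhase, T_evo: float, mu: float) -> float:
    """log Omega_b, evaluated in log space (mu > 0 required)."""
    if mu <= 0:
        raise ValueError("mu must be > 0")
    return math.log(bio.C_b) + bio.c * math.log(mu) + bio.b * T_evo / mu

def coexistence_residual(
    phys: PhysicalPhase, bio: BiologicalPhase, point: CriticalPoint
) -> float:
    """|Omega_p(T0, M0) - Omega_b(T_evo0, mu0)| at a candidate point.

    Computed via the log forms to avoid overflow; vanishes (< 1e-8)
    under the dual mappings with C_p = C_b.
    """
    lp = log_omega_p(phys, point.T_phys0, point.M0)
    lb = log_omega_b(bio, point.T_evo0, point.mu0)
    for v in (lp, lb):
        if not math.isfinite(v):
            raise ValueError("non-finite grand potential at the candidate point")
    m = max(lp, lb)
    return float(math.exp(m) * abs(math.exp(lp - m) - math.exp(lb - m)))


def critical_points(
    phys: PhysicalPhase, bio: BiologicalPhase, mu0: float
) -> list[CriticalPoint]:
    """Coexistence points with coincident temperatures.

    Solves the fixed point of the temperature dual for T_phys0, then maps
    M0 = (c/gamma)*T_phys0*log(mu0) and T_evo0 = (alpha*mu0/b)*log(T_phys0)
    (equal to T_phys0 at a root).  Both roots are returned when they
    exist, labeled 'low-T' and 'high-T'; no silent selection.
    """
    roots = dual_temperature(phys.alpha, bio.b, mu0)
    labels = ["tangent"] if len(roots) == 1 else ["low-T", "high-T"]
    out = []
    for T0, label in zip(roots, labels):
        M0 = dual_chemical_potential(bio.c, phys.gamma, T0, mu0)
        T_evo0 = phys.alpha * mu0 / bio.b * math.log(T0)
        pt = CriticalPoint(
            T_phys0=T0, M0=M0, T_evo0=T_evo0, mu0=mu0, residual=0.0, branch=label
        )
        res = coexistence_residual(phys, bio, pt)
        out.append(
            CriticalPoint(
                T_phys0=T0, M0=M0, T_evo0=T_evo0, mu0=mu0, residual=res, branch=label
            )
        )
    return out


@dataclass(frozen=True)
class ScanRow:
    T_evo: float
    omega_p: float
    omega_b: float
    favored: str


@dataclass(frozen=True)
class PhaseScanResult:
    """Grid classification plus bisected crossings (critical evolutionary
    temperatures), or 'no transition in range' when the sign of
    Omega_p - Omega_b never changes."""

    rows: tuple[ScanRow, ...]
    crossings: tuple[float, ...]

    @property
    def message(self) -> str:
        if self.crossings:
            pts = ", ".join(f"{t:.6g}" for t in self.crossings)
            return f"critical evolutionary temperature(s): {pts}"
        return "no transition in range"


def _default_mapping(mu0: float, phys: PhysicalPhase, bio: BiologicalPhase):
    """Common-temperature probe: both descriptions evaluated at the same
    temperature (T_phys = T_evo), with M from the chemical-potential dual
    and mu fixed at mu0.  Crossings then sit exactly at the fixed-point
    roots of the temperature dual."""

    def mapping(T_evo: float) -> tuple[float, float, float]:
        T_phys = T_evo
        M = dual_chemical_potential(bio.c, phys.gamma, T_phys, mu0)
        return T_phys, M, mu0

    return mapping


def phase_scan(
    phys: PhysicalPhase,
    bio: BiologicalPhase,
    T_evo_grid: Sequence[float],
    mu0: float = 1.0,
    mapping: Callable[[float], tuple[float, float, float]] | None = None,
) -> PhaseScanResult:
    """Classify the favored phase along an ascending grid of evolutionary
    temperatures ("lower grand potential wins"), bisecting each sign
    change of Omega_p - Omega_b to ~1e-10 and reporting it as a critical
    evolutionary temperature."""
    grid = np.asarray(list(T_evo_grid), dtype=float)
    if grid.size < 2:
        raise ValueError("grid needs at least 2 points")
    if not np.all(np.diff(grid) > 0):
        raise ValueError("grid must be sorted ascending")
    if mapping is None:
        mapping = _default_mapping(mu0, phys, bio)

    def diff(T_evo: float) -> float:
        T_phys, M, mu = mapping(float(T_evo))
        return log_omega_p(phys, T_phys, M) - log_omega_b(bio, T_evo, mu)

    rows = []
    diffs = []
    for T in grid:
        T_phys, M, mu = mapping(float(T))
        lp = log_omega_p(phys, T_phys, M)
        lb = log_omega_b(bio, float(T), mu)
        d = lp - lb
        diffs.append(d)
        favored = "physical" if d < 0 else ("biological" if d > 0 else "coexist")
        rows.append(
            ScanRow(
                T_evo=float(T),
                omega_p=math.exp(lp),
                omega_b=math.exp(lb),
                favored=favored,
            )
        )
    crossings = []
    for i in range(len(grid) - 1):
        if diffs[i] == 0.0:
            crossings.append(float(grid[i]))
        elif diffs[i] * diffs[i + 1] < 0:
            t = brentq(diff, grid[i], grid[i + 1], xtol=1e-10, rtol=8.9e-16)
            crossings.append(float(t))
    if diffs[-1] == 0.0:
        crossings.append(float(grid[-1]))
    return PhaseScanResult(rows=tuple(rows), crossings=tuple(crossings))
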