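"""Synthetic genotype spaces and loss/fitness landscapes.

A genotype space is the set of all length-L strings over an alphabet of
size A, with edges between Hamming-distance-1 pairs (the mutation graph).
Landscapes assign a per-genotype free energy F(q); the ``additive`` kind
has no epistasis (F is a sum of independent per-site contributions, the
regime in which the ideal-mutation equilibrium theory is exact), while
``random_field`` and ``house_of_cards`` are rugged controls.

Sites may be annotated by variable class: selected sites carry nonzero
effects (adaptable variables), neutral sites carry zero effect, and
constant (core) sites are masked from mutation entirely.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = ["GenotypeSpace", "Landscape", "make_space", "make_landscape"]

_MAX_GENOTYPES = 100_000


@dataclass(frozen=True)
class GenotypeSpace:
    """Complete genotype space: all A**L strings over digits 0..A-1.

    ``constant_sites`` are masked from mutation (core variables q(c)):
    neighbor enumeration skips them, so the mutation graph restricted to
    the remaining sites is still connected and regular with degree
    (L - #constant) * (A - 1).
    """

    L: int
    A: int
    constant_sites: frozenset[int] = frozenset()

    def __post_init__(self) -> None:
        if self.L < 1 or self.A < 2:
            raise ValueError("need L >= 1 and A >= 2")
        if self.A**self.L > _MAX_GENOTYPES:
            raise ValueError(
                f"A**L = {self.A ** self.L} exceeds the enumeration limit "
                f"{_MAX_GENOTYPES}"
            )
        bad = [s for s in self.constant_sites if not 0 <= s < self.L]
        if bad:
            raise ValueError(f"constant sites out of range: {bad}")
        object.__setattr__(self, "constant_sites", frozenset(self.constant_sites))

    @property
    def n_genotypes(self) -> int:
        return self.A**self.L

    @property
    def mutable_sites(self) -> tuple[int, ...]:
        return tuple(i for i in range(self.L) if i not in self.constant_sites)

    @property
    def degree(self) -> int:
        return len(self.mutable_sites) * (self.A - 1)

    def genotypes(self) -> list[str]:
        """All genotypes in lexicographic order."""
        alphabet = "0123456789"[: self.A] if self.A <= 10 else None
        if alphabet is None:
            raise ValueError("alphabets larger than 10 are not supported")
        return ["".join(tup) for tup in itertools.product(alphabet, repeat=self.L)]

    def neighbors(self, genotype: str) -> list[str]:
        """Hamming-1 neighbors of a genotype (mutable sites only)."""
        if len(genotype) != self.L:
            raise ValueError("genotype length mismatch")
        out = []
        for i in self.mutable_sites:
            for a in range(self.A):
                c = str(a)
                if c != genotype[i]:
                    out.append(genotype[:i] + c + genotype[i + 1 :])
        return out

    def edges(self) -> Iterator[tuple[str, str]]:
        """Each undirected Hamming-1 edge once (lexicographic orientation)."""
        for g in self.genotypes():
            for h in self.neighbors(g):
                if g < h:
                    yield (g, h)


def make_space(
    L: int, A: int, constant_sites: Sequence[int] = ()
) -> GenotypeSpace:
    """Enumerable genotype space with Hamming-1 mutation structure."""
    return GenotypeSpace(L=int(L), A=int(A), constant_sites=frozenset(constant_sites))


@dataclass(frozen=True)
class Landscape:
    """Per-genotype free energy F(q) over a complete genotype space.

    For ``kind='additive'`` the per-site contributions are stored in
    ``site_effects`` (shape L x A) so the no-epistasis property is
    directly checkable: F(q) = sum_i site_effects[i][q_i] exactly.
    """

    space: GenotypeSpace
    F: dict[str, float]
    kind: str
    seed: int
    site_effects: tuple[tuple[float, ...], ...] | None = field(default=None)

    def __post_init__(self) -> None:
        vals = np.asarray(list(self.F.values()), dtype=float)
        if not np.all(np.isfinite(vals)):
            raise ValueError("landscape F values must be finite")
        if len(self.F) != self.space.n_genotypes:
            raise ValueError("landscape must cover every genotype")

    @property
    def genotypes(self) -> list[str]:
        return self.space.genotypes()

    def values(self) -> np.ndarray:
        return np.asarray([self.F[g] for g in self.genotypes], dtype=float)


_KINDS = ("additive", "random_field", "house_of_cards")


def make_landscape(
    space: GenotypeSpace,
    kind: str = "additive",
    params: dict | None = None,
    seed: int = 0,
) -> Landscape:
    """Deterministic landscape of the requested kind.

    Parameters
    ----------
    kind : {'additive', 'random_field', 'house_of_cards'}
        additive — F(q) = Σ_sites f_i(q_i), site effects either given via
        ``params['site_effects']`` (L x A nested list) or drawn i.i.d.
        Normal(0, sigma); neutral sites (``params['neutral_sites']``)
        carry zero effect.
        random_field — site effects drawn as for additive plus i.i.d.
        Normal(0, sigma_epi) epistatic noise per genotype.
        house_of_cards — an independent Normal(0, sigma) value per
        genotype (maximal ruggedness).
    params : dict, optional
        ``sigma`` (default 1.0), ``sigma_epi`` (default 0.5),
        ``site_effects``, ``neutral_sites``.
    seed : int
        Seeds a dedicated generator; identical (kind, params, seed) give
        identical landscapes.
    """
    if kind not in _KINDS:
        raise ValueError(f"unknown landscape kind {kind!r}; expected one of {_KINDS}")
    params = dict(params or {})
    sigma = float(params.get("sigma", 1.0))
    rng = np.random.default_rng(seed)
    genotypes = space.genotypes()

    if kind == "house_of_cards":
        vals = rng.normal(0.0, sigma, size=len(genotypes))
        return Landscape(
            space=space,
            F=dict(zip(genotypes, vals.tolist())),
            kind=kind,
            seed=int(seed),
        )

    if "site_effects" in params:
        eff = np.asarray(params["site_effects"], dtype=float)
        if eff.shape != (space.L, space.A):
            raise ValueError(f"site_effects must have shape ({space.L}, {space.A})")
    else:
        eff = rng.normal(0.0, sigma, size=(space.L, space.A))
    neutral = set(params.get("neutral_sites", ()))
    for i in neutral:
        eff[i, :] = 0.0

    idx = np.array([[int(c) for c in g] for g in genotypes], dtype=int)
    F_add = eff[np.arange(space.L), idx].sum(axis=1)

    if kind == "random_field":
        sigma_epi = float(params.get("sigma_epi", 0.5))
        F_add = F_add + rng.normal(0.0, sigma_epi, size=len(genotypes))
        site_effects = None
    else:
        site_effects = tuple(tuple(row) for row in eff.tolist())

    return Landscape(
        space=space,
        F=dict(zip(genotypes, F_add.tolist())),
        kind=kind,
        seed=int(seed),
        site_effects=site_effects,
    )
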