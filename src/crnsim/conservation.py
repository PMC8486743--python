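"""Moiety conservation laws from the left null space of the stoichiometric matrix.

A conservation law is a nonnegative integer vector ``gamma`` with
``gamma^T S = 0``: the aggregate ``gamma^T x(t)`` (the moiety total, nM) is
invariant along every trajectory.  The set of states sharing the totals
``c_j = gamma_j^T x0`` of a full generating set is the stoichiometric
compatibility class SC(c); equilibria are computed within one class.

The generating set is found in two stages: an exact rational basis of the
left null space (no floating-point rank decisions), then one small linear
program per species to produce nonnegative integer generators, each
re-verified in integer arithmetic.  Generators are canonicalized (gcd 1,
sorted by support size then species order) so outputs are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction
from math import gcd
from pathlib import Path
from typing import Sequence

import numpy as np
import sympy
from scipy.optimize import linprog

from .crn_core import CRN

__all__ = [
    "ConservationLaw",
    "CompatibilityClass",
    "conservation_laws",
    "totals",
    "uncovered_species",
    "class_distance",
    "left_nullity",
    "exact_rank",
    "IncompleteBasisWarning",
    "export_laws_csv",
]


class IncompleteBasisWarning(UserWarning):
    """The nonnegative generators found do not span the full left null space."""


@dataclass(frozen=True)
class ConservationLaw:
    """One moiety conservation law gamma with gamma^T S = 0 exactly."""

    gamma: tuple[int, ...]
    species_ids: tuple[str, ...]

    @property
    def support(self) -> tuple[str, ...]:
        return tuple(s for s, g in zip(self.species_ids, self.gamma) if g > 0)

    def total(self, x0: np.ndarray) -> float:
        """Conserved aggregate concentration c = gamma^T x0 (nM)."""
        return float(np.dot(self.gamma, x0))

    def __repr__(self) -> str:
        terms = " + ".join(
            (f"{g}*{s}" if g != 1 else s)
            for s, g in zip(self.species_ids, self.gamma)
            if g > 0
        )
        return f"ConservationLaw({terms})"


@dataclass(frozen=True)
class CompatibilityClass:
    """A stoichiometric compatibility class: laws plus their totals c."""

    laws: tuple[ConservationLaw, ...]
    c: tuple[float, ...]

    @classmethod
    def from_state(
        cls, laws: Sequence[ConservationLaw], x0: np.ndarray
    ) -> "CompatibilityClass":
        return cls(tuple(laws), tuple(law.total(x0) for law in laws))


# -- exact rank ----------------------------------------------------------

_PRIMES = (2147483647, 2147483629)


def _rank_mod_p(M: np.ndarray, p: int) -> int:
    """Rank of an integer matrix over GF(p) by vectorized elimination."""
    A = np.mod(M.astype(np.int64), p)
    rows, cols = A.shape
    rank = 0
    for col in range(cols):
        if rank == rows:
            break
        pivots = np.nonzero(A[rank:, col])[0]
        if pivots.size == 0:
            continue
        pr = rank + pivots[0]
        A[[rank, pr]] = A[[pr, rank]]
        inv = pow(int(A[rank, col]), p - 2, p)
        A[rank] = (A[rank] * inv) % p
        mask = np.arange(rows) != rank
        factors = A[mask, col][:, None]
        A[mask] = (A[mask] - factors * A[rank][None, :]) % p
        rank += 1
    return rank


def exact_rank(M: np.ndarray) -> int:
    """Rank of an integer matrix in exact arithmetic.

    Small matrices go through sympy's rational elimination; large ones use
    modular elimination over two distinct 31-bit primes (ranks agree for
    every matrix whose determinantal divisors avoid both primes, which a
    disagreement would reveal).
    """
    M = np.asarray(M, dtype=np.int64)
    if M.size == 0:
        return 0
    if max(M.shape) <= 60:
        return sympy.Matrix(M).rank()
    ranks = {_rank_mod_p(M, p) for p in _PRIMES}
    if len(ranks) != 1:  # pragma: no cover - astronomically unlikely
        return sympy.Matrix(M).rank()
    return ranks.pop()


def left_nullity(crn: CRN) -> int:
    """Dimension of the left null space of S (number of independent laws)."""
    return crn.n - exact_rank(crn.S)


# -- rational left null space -------------------------------------------


def left_nullspace_rational(crn: CRN) -> list[tuple[Fraction, ...]]:
    """An exact rational basis of {gamma : gamma^T S = 0}."""
    M = sympy.Matrix(crn.S.T.tolist())
    return [
        tuple(Fraction(int(v.p), int(v.q)) for v in vec)
        for vec in M.nullspace()
    ]


def _integerize(vec: Sequence[Fraction]) -> tuple[int, ...]:
    denom_lcm = 1
    for f in vec:
        denom_lcm = denom_lcm * f.denominator // gcd(denom_lcm, f.denominator)
    ints = [int(f * denom_lcm) for f in vec]
    g = 0
    for v in ints:
        g = gcd(g, abs(v))
    if g > 1:
        ints = [v // g for v in ints]
    return tuple(ints)


def _exactify(gamma_float: np.ndarray, S: np.ndarray) -> tuple[int, ...] | None:
    """Round an LP solution to an exact integer law; None when it fails."""
    fracs = [Fraction(float(v)).limit_denominator(10**6) for v in gamma_float]
    cand = _integerize(fracs)
    arr = np.array(cand, dtype=object)
    if np.all(arr >= 0) and not np.all(arr == 0):
        residual = arr @ S.astype(object)
        if np.all(residual == 0):
            return cand
    return None


def conservation_laws(crn: CRN, *, include_pools: bool = False) -> list[ConservationLaw]:
    """Compute a nonnegative-integer generating set of moiety conservation laws.

    Returns one :class:`ConservationLaw` per dimension of the left null
    space of ``S``.  Constant-pool species have identically zero rows of
    ``S`` and would each contribute a trivial singleton law; these are
    suppressed unless ``include_pools`` is set, and the nullity is counted
    on the dynamic species only.

    If no nonnegative basis spans the computed null space (possible for
    networks with unconstrained exchange stoichiometry), the function
    returns the laws it found and raises :class:`IncompleteBasisWarning`
    with the rational basis attached, rather than failing silently.
    """
    S = crn.S
    pool = crn.constant_pool_mask
    n = crn.n
    target_dim = n - exact_rank(S)
    if not include_pools:
        target_dim -= int(pool.sum())
    if target_dim <= 0:
        return []

    r = crn.r
    ids = crn.species_ids
    found: dict[tuple[int, ...], None] = {}
    bounds = [(0.0, 0.0) if (pool[i] and not include_pools) else (0.0, None) for i in range(n)]

    basis_rows: list[tuple[int, ...]] = []
    current_rank = 0
    # one LP per species: smallest-total law through that species
    for i in range(n):
        if pool[i] and not include_pools:
            continue
        b = list(bounds)
        b[i] = (1.0, None)
        res = linprog(
            c=np.ones(n),
            A_eq=S.T.astype(float),
            b_eq=np.zeros(r),
            bounds=b,
            method="highs",
        )
        if not res.success:
            continue  # species not covered by any nonnegative law
        cand = _exactify(res.x, S)
        if cand is None or cand in found:
            continue
        found[cand] = None

    # greedy independent subset, smallest supports first
    ordered = sorted(
        found,
        key=lambda g: (sum(1 for v in g if v > 0), tuple(-v for v in g)),
    )
    laws: list[ConservationLaw] = []
    stack: list[tuple[int, ...]] = []
    for cand in ordered:
        trial = np.array(stack + [cand], dtype=np.int64)
        if exact_rank(trial) > current_rank:
            stack.append(cand)
            current_rank += 1
            laws.append(ConservationLaw(cand, tuple(ids)))
            if current_rank == target_dim:
                break

    if current_rank < target_dim:
        rational = left_nullspace_rational(crn)
        warnings.warn(
            f"only {current_rank} of {target_dim} independent nonnegative "
            f"generators found; rational left-null basis has "
            f"{len(rational)} vectors: {rational}",
            IncompleteBasisWarning,
            stacklevel=2,
        )
    laws.sort(key=lambda law: (len(law.support), law.support))
    return laws


# -- derived quantities --------------------------------------------------


def totals(laws: Sequence[ConservationLaw], x0: np.ndarray) -> np.ndarray:
    """Conserved totals c_j = gamma_j^T x0 for each law (nM)."""
    x0 = np.asarray(x0, dtype=float)
    if laws and len(x0) != len(laws[0].gamma):
        raise ValueError(
            f"state length {len(x0)} does not match law length {len(laws[0].gamma)}"
        )
    return np.array([law.total(x0) for law in laws])


def uncovered_species(crn: CRN, laws: Sequence[ConservationLaw]) -> set[str]:
    """Species with zero coefficient in every generator.

    In signaling networks these are the species that undergo explicit
    degradation or exchange mass with the environment; constant-pool
    species are excluded (they are held fixed, not unconserved).
    """
    covered: set[str] = set()
    for law in laws:
        covered.update(law.support)
    return {
        sp.id
        for sp in crn.species
        if sp.id not in covered and not sp.is_constant_pool
    }


def class_distance(
    laws: Sequence[ConservationLaw], x: np.ndarray, c: np.ndarray
) -> float:
    """Relative distance of a state from the compatibility class SC(c).

    ``max_j |gamma_j^T x - c_j| / max(1, |c_j|)``; zero (up to tolerance)
    iff x lies in SC(c).
    """
    if len(laws) == 0:
        return 0.0
    cur = totals(laws, x)
    c = np.asarray(c, dtype=float)
    if cur.shape != c.shape:
        raise ValueError("totals vector length does not match number of laws")
    return float(np.max(np.abs(cur - c) / np.maximum(1.0, np.abs(c))))


def export_laws_csv(
    laws: Sequence[ConservationLaw], x0: np.ndarray | None, path: str | Path
) -> None:
    """One row per law: law index, support species, coefficients, total."""
    import pandas as pd

    rows = []
    for idx, law in enumerate(laws):
        rows.append(
            {
                "law": idx,
                "species": ";".join(law.support),
                "coefficients": ";".join(
                    str(g) for g in law.gamma if g > 0
                ),
                "total_nM": law.total(x0) if x0 is not None else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
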