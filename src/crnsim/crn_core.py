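"""Chemical reaction network container, file formats, and mass-action kinetics.

A network is a list of species with initial concentrations (nM), and a list
of irreversible reactions with mass-action rate constants (s^-1 for
first-order, (nM s)^-1 for second-order).  Reversible reactions are always
stored as two irreversible reactions cross-linked through ``reverse_of``.
The dynamics are ``xdot = S v(x, k)`` where ``S`` is the n x r integer
stoichiometric matrix and ``v`` the mass-action flux vector.

Species flagged ``is_constant_pool`` model inexhaustible synthesis pools
(e.g. a generator species feeding protein production): their concentration
is held fixed by zeroing their row of ``S``.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from lxml import etree

__all__ = [
    "Species",
    "Reaction",
    "CRN",
    "CRNValidationError",
    "load_crn",
    "write_reaction_table",
    "stoichiometric_matrix",
    "mass_action_flux",
    "rhs",
    "flux_jacobian",
    "fold_constant_pools",
]


class CRNValidationError(ValueError):
    """Raised when a network definition violates its structural contracts."""


@dataclass(frozen=True)
class Species:
    """A well-mixed chemical species (protein, complex, or pool)."""

    id: str
    initial_concentration: float = 0.0
    is_constant_pool: bool = False

    def __post_init__(self) -> None:
        if self.initial_concentration < 0:
            raise CRNValidationError(
                f"species {self.id!r}: negative initial concentration "
                f"{self.initial_concentration}"
            )


@dataclass(frozen=True)
class Reaction:
    """One irreversible mass-action reaction.

    ``reactants`` and ``products`` map species ids to positive integer
    stoichiometries.  ``reverse_of`` names the partner reaction when this
    direction is one half of a reversible pair.
    """

    id: str
    reactants: Mapping[str, int]
    products: Mapping[str, int]
    rate_constant: float
    reverse_of: str | None = None

    def __post_init__(self) -> None:
        if self.rate_constant < 0 or math.isnan(self.rate_constant):
            raise CRNValidationError(
                f"reaction {self.id!r}: rate constant must be >= 0, "
                f"got {self.rate_constant}"
            )
        for side, stoich in (("reactant", self.reactants), ("product", self.products)):
            for sp, coeff in stoich.items():
                if not (isinstance(coeff, (int, np.integer)) and coeff > 0):
                    raise CRNValidationError(
                        f"reaction {self.id!r}: {side} {sp!r} has non-positive "
                        f"or non-integer stoichiometry {coeff!r}"
                    )
        if dict(self.reactants) == dict(self.products):
            raise CRNValidationError(
                f"reaction {self.id!r}: reactants and products are identical"
            )


class CRN:
    """A chemical reaction network under mass-action kinetics.

    Parameters
    ----------
    species
        Ordered species list; order fixes the row indexing of ``S``.
    reactions
        Ordered reaction list; order fixes the column indexing of ``S``.

    Attributes
    ----------
    S : numpy.ndarray
        n x r integer net-stoichiometry matrix with constant-pool rows
        forced to zero.
    k : numpy.ndarray
        Length-r rate-constant vector.
    """

    def __init__(self, species: Sequence[Species], reactions: Sequence[Reaction]):
        self.species: list[Species] = list(species)
        self.reactions: list[Reaction] = list(reactions)
        self._validate()
        self.species_index: dict[str, int] = {
            sp.id: i for i, sp in enumerate(self.species)
        }
        self.reaction_index: dict[str, int] = {
            rx.id: j for j, rx in enumerate(self.reactions)
        }
        self.S = self._build_S()
        self.k = np.array([rx.rate_constant for rx in self.reactions], dtype=float)
        self._build_flux_tables()

    # -- structure -------------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.species)

    @property
    def r(self) -> int:
        return len(self.reactions)

    @property
    def x0(self) -> np.ndarray:
        return np.array([sp.initial_concentration for sp in self.species])

    @property
    def species_ids(self) -> list[str]:
        return [sp.id for sp in self.species]

    @property
    def constant_pool_mask(self) -> np.ndarray:
        return np.array([sp.is_constant_pool for sp in self.species])

    def _validate(self) -> None:
        seen: set[str] = set()
        for sp in self.species:
            if sp.id in seen:
                raise CRNValidationError(f"duplicate species id {sp.id!r}")
            seen.add(sp.id)
        seen_rx: set[str] = set()
        by_id = {rx.id: rx for rx in self.reactions}
        for rx in self.reactions:
            if rx.id in seen_rx:
                raise CRNValidationError(f"duplicate reaction id {rx.id!r}")
            seen_rx.add(rx.id)
            for sp in (*rx.reactants, *rx.products):
                if sp not in seen:
                    raise CRNValidationError(
                        f"reaction {rx.id!r} references unknown species {sp!r}"
                    )
            if rx.reverse_of is not None:
                partner = by_id.get(rx.reverse_of)
                if partner is None:
                    raise CRNValidationError(
                        f"reaction {rx.id!r}: reverse_of points to missing "
                        f"reaction {rx.reverse_of!r}"
                    )
                if partner.reverse_of != rx.id:
                    raise CRNValidationError(
                        f"reverse_of link between {rx.id!r} and "
                        f"{rx.reverse_of!r} is not symmetric"
                    )

    def _build_S(self) -> np.ndarray:
        S = np.zeros((self.n, self.r), dtype=np.int64)
        for j, rx in enumerate(self.reactions):
            for sp, coeff in rx.reactants.items():
                S[self.species_index[sp], j] -= coeff
            for sp, coeff in rx.products.items():
                S[self.species_index[sp], j] += coeff
        S[self.constant_pool_mask, :] = 0
        return S

    def _build_flux_tables(self) -> None:
        # Flattened reactant index list with per-reaction segments so the
        # monomial v_j = k_j * prod x_i^s_ij is a single reduceat call.
        # Zeroth-order reactions point at a padding entry that is always 1.
        flat: list[int] = []
        offsets: list[int] = []
        for rx in self.reactions:
            offsets.append(len(flat))
            for sp, coeff in sorted(rx.reactants.items()):
                flat.extend([self.species_index[sp]] * coeff)
            if not rx.reactants:
                flat.append(self.n)  # padding slot
        self._flux_flat = np.array(flat, dtype=np.intp)
        self._flux_offsets = np.array(offsets, dtype=np.intp)
        # per-reaction (species_idx, stoich) pairs for the Jacobian
        self._reactant_pairs: list[list[tuple[int, int]]] = [
            [(self.species_index[sp], c) for sp, c in sorted(rx.reactants.items())]
            for rx in self.reactions
        ]

    # -- kinetics --------------------------------------------------------

    def flux(self, x: np.ndarray, *, clip: bool = False) -> np.ndarray:
        """Mass-action flux vector v(x, k), length r."""
        x = np.asarray(x, dtype=float)
        if x.shape != (self.n,):
            raise CRNValidationError(
                f"state has shape {x.shape}, expected ({self.n},)"
            )
        if clip:
            x = np.maximum(x, 0.0)
        elif np.any(x < 0):
            bad = self.species[int(np.argmin(x))].id
            raise CRNValidationError(f"negative concentration for species {bad!r}")
        if self.r == 0:
            return np.zeros(0)
        xa = np.append(x, 1.0)
        v = self.k * np.multiply.reduceat(xa[self._flux_flat], self._flux_offsets)
        return v

    def rhs(self, x: np.ndarray, *, clip: bool = False) -> np.ndarray:
        """ODE right-hand side S v(x, k); exactly zero for constant pools."""
        return self.S @ self.flux(x, clip=clip)

    def jacobian(self, x: np.ndarray) -> np.ndarray:
        """d(rhs)/dx, dense n x n; uses the exact monomial derivatives."""
        x = np.maximum(np.asarray(x, dtype=float), 0.0)
        Jv = np.zeros((self.r, self.n))
        for j, pairs in enumerate(self._reactant_pairs):
            kj = self.k[j]
            if kj == 0.0 or not pairs:
                continue
            for i, (idx, coeff) in enumerate(pairs):
                term = kj * coeff * x[idx] ** (coeff - 1)
                for i2, (idx2, coeff2) in enumerate(pairs):
                    if i2 != i:
                        term *= x[idx2] ** coeff2
                Jv[j, idx] += term
        return self.S @ Jv

    # -- editing ---------------------------------------------------------

    def with_rate_constants(self, new_k: Mapping[str, float]) -> "CRN":
        """Copy of the network with the listed reactions' constants replaced."""
        unknown = set(new_k) - set(self.reaction_index)
        if unknown:
            raise CRNValidationError(f"unknown reaction ids: {sorted(unknown)}")
        reactions = [
            Reaction(
                rx.id,
                rx.reactants,
                rx.products,
                new_k.get(rx.id, rx.rate_constant),
                rx.reverse_of,
            )
            for rx in self.reactions
        ]
        return CRN(self.species, reactions)

    def with_initial_concentrations(self, x0: np.ndarray) -> "CRN":
        species = [
            Species(sp.id, float(c), sp.is_constant_pool)
            for sp, c in zip(self.species, x0, strict=True)
        ]
        return CRN(species, self.reactions)

    def reactions_involving(self, species_id: str) -> list[Reaction]:
        """Reactions where the species appears as reactant or product."""
        if species_id not in self.species_index:
            raise CRNValidationError(f"unknown species {species_id!r}")
        return [
            rx
            for rx in self.reactions
            if species_id in rx.reactants or species_id in rx.products
        ]

    def __repr__(self) -> str:
        return f"CRN(n={self.n} species, r={self.r} reactions)"


# -- module-level functional API (thin wrappers over CRN methods) --------


def stoichiometric_matrix(crn: CRN) -> np.ndarray:
    """The n x r integer matrix S with constant-pool rows zeroed."""
    return crn.S.copy()


def mass_action_flux(crn: CRN, x: np.ndarray) -> np.ndarray:
    return crn.flux(x)


def rhs(crn: CRN, x: np.ndarray) -> np.ndarray:
    return crn.rhs(x)


def flux_jacobian(crn: CRN, x: np.ndarray) -> np.ndarray:
    return crn.jacobian(x)


# -- reaction-table dialect ----------------------------------------------
#
# Plain TSV with two blocks::
#
#     # species
#     A	1.0	0
#     B	1.0	0
#     C	0.0	0
#     # reactions
#     bind	A + B -> C	1.0
#     unbind	C -> A + B	1.0	bind
#
# Species columns: id, initial concentration (nM), constant-pool flag (0/1).
# Reaction columns: id, equation "A + 2 B -> C", rate constant, optional
# reverse_of id.  The arrow side with no species is written "0" (null).

_TERM_RE = re.compile(r"^\s*(?:(\d+)\s+)?(\S+)\s*$")


def _parse_side(text: str, rx_id: str) -> dict[str, int]:
    text = text.strip()
    if text in ("0", "", "null", "-"):
        return {}
    out: dict[str, int] = {}
    for term in text.split("+"):
        m = _TERM_RE.match(term)
        if not m:
            raise CRNValidationError(f"reaction {rx_id!r}: cannot parse term {term!r}")
        coeff = int(m.group(1) or 1)
        out[m.group(2)] = out.get(m.group(2), 0) + coeff
    return out


def _format_side(stoich: Mapping[str, int]) -> str:
    if not stoich:
        return "0"
    return " + ".join(
        (f"{c} {sp}" if c != 1 else sp) for sp, c in sorted(stoich.items())
    )


def read_reaction_table(path: str | Path) -> CRN:
    species: list[Species] = []
    reactions: list[Reaction] = []
    block = None
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            header = stripped.lstrip("#").strip().lower()
            if header in ("species", "reactions"):
                block = header
            continue
        cols = [c.strip() for c in line.split("\t")]
        if block == "species":
            if len(cols) < 2:
                raise CRNValidationError(
                    f"{path}:{lineno}: species row needs id and x0"
                )
            flag = cols[2] if len(cols) > 2 and cols[2] else "0"
            species.append(
                Species(cols[0], float(cols[1]), flag in ("1", "true", "True"))
            )
        elif block == "reactions":
            if len(cols) < 3:
                raise CRNValidationError(
                    f"{path}:{lineno}: reaction row needs id, equation, k"
                )
            rx_id, equation, k = cols[0], cols[1], cols[2]
            if "->" not in equation:
                raise CRNValidationError(
                    f"{path}:{lineno}: equation {equation!r} lacks '->'"
                )
            lhs, sep, rhs_ = equation.partition("->")
            reverse_of = cols[3] if len(cols) > 3 and cols[3] else None
            reactions.append(
                Reaction(
                    rx_id,
                    _parse_side(lhs, rx_id),
                    _parse_side(rhs_, rx_id),
                    float(k),
                    reverse_of,
                )
            )
        else:
            raise CRNValidationError(
                f"{path}:{lineno}: data before a '# species'/'# reactions' header"
            )
    return CRN(species, reactions)


def write_reaction_table(crn: CRN, path: str | Path) -> None:
    """Serialize a network in the reaction-table dialect (lossless)."""
    lines = ["# species"]
    for sp in crn.species:
        lines.append(
            f"{sp.id}\t{sp.initial_concentration!r}\t{int(sp.is_constant_pool)}"
        )
    lines.append("# reactions")
    for rx in crn.reactions:
        eq = f"{_format_side(rx.reactants)} -> {_format_side(rx.products)}"
        lines.append(f"{rx.id}\t{eq}\t{rx.rate_constant!r}\t{rx.reverse_of or ''}")
    Path(path).write_text("\n".join(lines) + "\n")


# -- SBML reader ---------------------------------------------------------


def _local(tag: str) -> str:
    return tag.rsplit("}", 1)[-1]


def _findall(el, name: str):
    return [c for c in el.iter() if _local(c.tag) == name]


def _children(el, name: str):
    return [c for c in el if _local(c.tag) == name]


def _math_parameter_refs(kinetic_law, param_ids: set[str]) -> list[str]:
    """Parameter ids referenced in kinetic-law MathML, in document order."""
    refs: list[str] = []
    for ci in _findall(kinetic_law, "ci"):
        name = (ci.text or "").strip()
        if name in param_ids and name not in refs:
            refs.append(name)
    return refs


_FWD_HINTS = re.compile(r"(^|_)(kf|kon|k1f|kf\d*|k\d*f)($|_)|forward", re.I)
_REV_HINTS = re.compile(r"(^|_)(kr|koff|k1r|kr\d*|k\d*r|kb)($|_)|backward|reverse", re.I)


def read_sbml(path: str | Path) -> CRN:
    """Read an SBML Level 2/3 model into a :class:`CRN`.

    Supported subset: species with initial concentration/amount and
    boundary/constant flags, reactions with integer stoichiometries and
    mass-action kinetic laws.  Reversible reactions are split into a
    forward/backward pair linked through ``reverse_of``; the two rate
    constants are taken from the kinetic law's parameters (first and second
    parameter referenced by the rate expression, with name-based
    forward/reverse hints as fallback).  Compartments, events, and
    assignment rules are out of scope and rejected when present.
    """
    try:
        tree = etree.parse(str(path))
    except (etree.XMLSyntaxError, OSError) as exc:
        raise CRNValidationError(f"cannot parse SBML file {path}: {exc}") from exc
    root = tree.getroot()
    if _local(root.tag) != "sbml":
        raise CRNValidationError(f"{path}: root element is not <sbml>")
    models = _findall(root, "model")
    if not models:
        raise CRNValidationError(f"{path}: no <model> element")
    model = models[0]
    for banned in ("listOfEvents", "listOfRules"):
        if _findall(model, banned):
            raise CRNValidationError(
                f"{path}: SBML {banned} is not supported (mass action only)"
            )

    species: list[Species] = []
    for el in _findall(model, "species"):
        sid = el.get("id")
        conc = el.get("initialConcentration", el.get("initialAmount", "0"))
        constant = el.get("boundaryCondition") == "true" or el.get("constant") == "true"
        species.append(Species(sid, float(conc), constant))

    global_params = {
        p.get("id"): float(p.get("value", "nan"))
        for lst in _children(model, "listOfParameters")
        for p in _children(lst, "parameter")
    }

    reactions: list[Reaction] = []
    for el in _findall(model, "reaction"):
        rid = el.get("id")
        reversible = el.get("reversible", "true") == "true"

        def side(tag: str) -> dict[str, int]:
            out: dict[str, int] = {}
            for lst in _children(el, tag):
                for ref in _children(lst, "speciesReference"):
                    st = float(ref.get("stoichiometry", "1"))
                    if abs(st - round(st)) > 1e-9 or round(st) < 1:
                        raise CRNValidationError(
                            f"{path}: reaction {rid!r} has non-integer "
                            f"stoichiometry {st}"
                        )
                    sp = ref.get("species")
                    out[sp] = out.get(sp, 0) + int(round(st))
            return out

        reactants = side("listOfReactants")
        products = side("listOfProducts")

        klaws = _children(el, "kineticLaw")
        if not klaws:
            raise CRNValidationError(f"{path}: reaction {rid!r} has no kinetic law")
        klaw = klaws[0]
        local_params = {
            p.get("id"): float(p.get("value", "nan"))
            for lst in klaw
            if _local(lst.tag) in ("listOfParameters", "listOfLocalParameters")
            for p in lst
            if _local(p.tag) in ("parameter", "localParameter")
        }
        params = {**global_params, **local_params}
        refs = _math_parameter_refs(klaw, set(params))
        if not refs:
            refs = list(local_params)
        if not refs:
            raise CRNValidationError(
                f"{path}: reaction {rid!r}: no rate constant found"
            )

        if reversible:
            if len(refs) < 2:
                raise CRNValidationError(
                    f"{path}: reversible reaction {rid!r} needs two rate "
                    f"constants, found {refs}"
                )
            kf_id, kr_id = refs[0], refs[1]
            # name hints override positional order when unambiguous
            if _REV_HINTS.search(kf_id) and _FWD_HINTS.search(kr_id):
                kf_id, kr_id = kr_id, kf_id
            kf, kr = params[kf_id], params[kr_id]
            if math.isnan(kf) or math.isnan(kr):
                raise CRNValidationError(
                    f"{path}: reaction {rid!r}: rate constant without a value"
                )
            reactions.append(
                Reaction(rid, reactants, products, kf, reverse_of=f"{rid}_rev")
            )
            reactions.append(
                Reaction(f"{rid}_rev", products, reactants, kr, reverse_of=rid)
            )
        else:
            k = params[refs[0]]
            if math.isnan(k):
                raise CRNValidationError(
                    f"{path}: reaction {rid!r}: rate constant without a value"
                )
            reactions.append(Reaction(rid, reactants, products, k))

    return CRN(species, reactions)


def load_crn(path: str | Path, format: str = "auto") -> CRN:
    """Load a network from SBML or from the reaction-table dialect.

    ``format`` is one of ``"sbml"``, ``"reaction-table"``, or ``"auto"``
    (sniffed from the file: XML declaration / ``<sbml`` root means SBML).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "auto":
        head = path.read_text(errors="replace")[:200].lstrip()
        format = "sbml" if head.startswith("<") else "reaction-table"
    if format == "sbml":
        return read_sbml(path)
    if format == "reaction-table":
        return read_reaction_table(path)
    raise ValueError(f"unknown format {format!r}")


def fold_constant_pools(crn: CRN) -> CRN:
    """Rewrite constant-pool species as pseudo-reactions from the null complex.

    Every reaction consuming a pool species G has G dropped from its reactant
    list and its rate constant multiplied by the pool concentration [G]0;
    a first-order consumption ``G -> X`` thus becomes the zeroth-order
    synthesis ``0 -> X`` with constant ``k [G]0``.  Dynamically equivalent to
    the default zero-row convention.
    """
    pool_ids = {sp.id: sp.initial_concentration for sp in crn.species if sp.is_constant_pool}
    species = [sp for sp in crn.species if not sp.is_constant_pool]
    reactions = []
    for rx in crn.reactions:
        reactants = dict(rx.reactants)
        k = rx.rate_constant
        for sp, coeff in list(reactants.items()):
            if sp in pool_ids:
                k *= pool_ids[sp] ** coeff
                del reactants[sp]
        products = {sp: c for sp, c in rx.products.items() if sp not in pool_ids}
        if reactants == products:
            continue  # reaction acted only on pools
        reactions.append(Reaction(rx.id, reactants, products, k, rx.reverse_of))
    return CRN(species, reactions)
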