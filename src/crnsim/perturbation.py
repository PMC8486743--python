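"""In-silico mutations and competitive-inhibitor drugs as network transformations.

Loss of function (LoF) of a protein empties (or scales down, for a partial
degree) the conserved moiety totals of every conservation law containing
it: the initial concentrations of the protein and of all its compounds are
multiplied by ``1 - degree``.  Proteins fed by a constant synthesis pool
(not covered by any law) are mutated through the pool instead: the
generator species' fixed concentration is scaled.

Gain of function (GoF) locks a protein in its active state by removing its
deactivation reactions: their rate constants are multiplied by
``1 - degree`` (zeroed at degree 1, equivalent to deleting the
corresponding columns of S).  The removal must preserve the left null
space of S exactly — i.e. the mutated network keeps every conservation law
of the original — which is enforced with an exact rank check.

A drug is modelled as a competitive inhibitor: a reversible binding
``target + Drug <-> complex`` with fast binding relative to unbinding,
dosed as a fraction ``alpha`` of the target's conserved moiety total.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .conservation import ConservationLaw, conservation_laws, exact_rank
from .crn_core import CRN, CRNValidationError, Reaction, Species

__all__ = [
    "MutationSpec",
    "DrugSpec",
    "PerturbationError",
    "apply_lof",
    "apply_gof",
    "apply_mutations",
    "add_drug",
    "washout",
    "load_perturbations",
]


class PerturbationError(ValueError):
    """Raised when a mutation or drug specification cannot be applied."""


@dataclass(frozen=True)
class MutationSpec:
    """A loss- or gain-of-function mutation of one protein.

    ``degree`` interpolates linearly between the physiological network (0)
    and the complete mutation (1): on moiety totals for LoF, on the listed
    deactivation-reaction rate constants for GoF.
    """

    kind: str  # "LoF" | "GoF"
    protein: str
    degree: float = 1.0
    removed_reactions: tuple[str, ...] = ()
    generator_species: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("LoF", "GoF"):
            raise PerturbationError(f"kind must be 'LoF' or 'GoF', got {self.kind!r}")
        if not 0.0 <= self.degree <= 1.0:
            raise PerturbationError(f"degree must be in [0, 1], got {self.degree}")
        if self.kind == "GoF" and not self.removed_reactions:
            raise PerturbationError(
                f"GoF of {self.protein!r} requires a nonempty removed_reactions list"
            )
        if self.kind == "GoF" and self.generator_species is not None:
            raise PerturbationError("generator_species applies to LoF only")


@dataclass(frozen=True)
class DrugSpec:
    """A competitive inhibitor of one target protein.

    Default rate constants follow the fast-binding regime (k1f >> k1r):
    binding at 0.5 (nM s)^-1 and unbinding at 0.005 s^-1.  ``alpha`` doses
    the drug as a fraction of the conserved total of the target's moiety;
    ``dose`` (nM), when given, overrides the alpha route.
    """

    target: str
    k1f: float = 0.5
    k1r: float = 0.005
    alpha: float = 1.0
    complex_name: str = ""
    drug_name: str = "Drug"
    dose: float | None = None
    law_index: int | None = None

    def __post_init__(self) -> None:
        if self.k1f < 0 or self.k1r < 0:
            raise PerturbationError("drug rate constants must be >= 0")
        if self.alpha < 0:
            raise PerturbationError("alpha must be >= 0")
        if not self.complex_name:
            object.__setattr__(
                self, "complex_name", f"{self.target}_{self.drug_name}"
            )


# -- LoF -----------------------------------------------------------------


def apply_lof(
    crn: CRN,
    x0: np.ndarray,
    spec: MutationSpec,
    laws: Sequence[ConservationLaw] | None = None,
) -> np.ndarray:
    """Project the initial state for a loss-of-function mutation.

    Returns a new x0; the network itself is unchanged.  For a protein
    covered by conservation laws, every species in the support of each
    containing law is scaled by ``1 - degree`` (degree 1 empties the
    compatibility-class slots, so the mutated equilibrium keeps them at
    zero).  For a generator-fed protein the constant pool is scaled
    instead.
    """
    if spec.kind != "LoF":
        raise PerturbationError(f"apply_lof got a {spec.kind} spec")
    x0 = np.asarray(x0, dtype=float).copy()
    factor = 1.0 - spec.degree

    if spec.generator_species is not None:
        idx = crn.species_index.get(spec.generator_species)
        if idx is None:
            raise PerturbationError(
                f"generator species {spec.generator_species!r} not in network"
            )
        if not crn.species[idx].is_constant_pool:
            raise PerturbationError(
                f"{spec.generator_species!r} is not a constant-pool species"
            )
        x0[idx] *= factor
        return x0

    if spec.protein not in crn.species_index:
        raise PerturbationError(f"unknown protein {spec.protein!r}")
    if laws is None:
        laws = conservation_laws(crn)
    containing = [law for law in laws if spec.protein in law.support]
    if not containing:
        raise PerturbationError(
            f"protein {spec.protein!r} is not covered by any conservation law; "
            "if its synthesis is fed by a constant pool, set generator_species"
        )
    if len(containing) > 1:
        warnings.warn(
            f"LoF of {spec.protein!r} zeroes {len(containing)} conservation "
            "laws (protein appears in more than one moiety)",
            stacklevel=2,
        )
    affected: set[str] = set()
    for law in containing:
        affected.update(law.support)
    for sp in affected:
        x0[crn.species_index[sp]] *= factor
    return x0


# -- GoF -----------------------------------------------------------------


def apply_gof(crn: CRN, spec: MutationSpec) -> CRN:
    """Return the network with the deactivation reactions removed (degree 1)
    or slowed (their rate constants scaled by ``1 - degree``).

    The left null space must be preserved: removing the listed columns of S
    may not change its rank, otherwise new conservation laws would appear
    (a symptom of wrongly including a reverse partner or a lone synthesis
    step in the removal list) and a hard error names the offending set.
    """
    if spec.kind != "GoF":
        raise PerturbationError(f"apply_gof got a {spec.kind} spec")
    missing = [r for r in spec.removed_reactions if r not in crn.reaction_index]
    if missing:
        raise PerturbationError(f"unknown reaction ids in removal list: {missing}")

    cols = [crn.reaction_index[r] for r in spec.removed_reactions]
    keep = np.ones(crn.r, dtype=bool)
    keep[cols] = False
    if exact_rank(crn.S[:, keep]) != exact_rank(crn.S):
        raise PerturbationError(
            f"GoF of {spec.protein!r}: removing reactions "
            f"{list(spec.removed_reactions)} changes the left null space of S "
            "(a conservation law would be created); check the removal list "
            "for reverse partners or lone synthesis/degradation steps"
        )
    factor = 1.0 - spec.degree
    new_k = {
        r: crn.reactions[crn.reaction_index[r]].rate_constant * factor
        for r in spec.removed_reactions
    }
    return crn.with_rate_constants(new_k)


# -- composition ---------------------------------------------------------


def apply_mutations(
    crn: CRN,
    x0: np.ndarray,
    specs: Sequence[MutationSpec],
    laws: Sequence[ConservationLaw] | None = None,
) -> tuple[CRN, np.ndarray]:
    """Apply any number of LoF and GoF mutations; order-invariant.

    GoF removals transform the network, LoF projections transform the
    initial state; because each acts multiplicatively on disjoint data the
    result is independent of the order of ``specs``.  A protein may not
    receive both a LoF and a GoF.
    """
    by_protein: dict[str, set[str]] = {}
    for spec in specs:
        by_protein.setdefault(spec.protein, set()).add(spec.kind)
    conflicts = [p for p, kinds in by_protein.items() if len(kinds) > 1]
    if conflicts:
        raise PerturbationError(
            f"conflicting LoF and GoF specs for protein(s) {conflicts}"
        )
    if laws is None and any(
        s.kind == "LoF" and s.generator_species is None for s in specs
    ):
        laws = conservation_laws(crn)

    # canonical order: GoF on the network first, then LoF projections,
    # each sub-list sorted by protein so the output is reproducible
    new_crn = crn
    for spec in sorted(
        (s for s in specs if s.kind == "GoF"), key=lambda s: s.protein
    ):
        new_crn = apply_gof(new_crn, spec)
    new_x0 = np.asarray(x0, dtype=float).copy()
    for spec in sorted(
        (s for s in specs if s.kind == "LoF"), key=lambda s: s.protein
    ):
        # laws are computed on the original network; GoF preserves them
        new_x0 = apply_lof(crn, new_x0, spec, laws=laws)
    return new_crn, new_x0


# -- drugs ---------------------------------------------------------------


def add_drug(
    crn: CRN,
    x_start: np.ndarray,
    spec: DrugSpec,
    laws: Sequence[ConservationLaw] | None = None,
) -> tuple[CRN, np.ndarray]:
    """Extend the network with a competitive inhibitor of ``spec.target``.

    Adds species ``drug_name`` and ``complex_name`` and the reversible pair
    ``target + Drug <-> complex`` with constants (k1f, k1r).  The initial
    state is ``x_start`` extended with the drug at ``alpha * c`` — ``c``
    being the conserved total of the target's conservation law evaluated at
    ``x_start`` — and the complex at zero.  The drugged network gains
    exactly one new conservation law, Drug + complex.
    """
    if spec.target not in crn.species_index:
        raise PerturbationError(f"drug target {spec.target!r} not in network")
    for name in (spec.drug_name, spec.complex_name):
        if name in crn.species_index:
            raise PerturbationError(f"species {name!r} already exists")
    x_start = np.asarray(x_start, dtype=float)

    if spec.dose is not None:
        dose = float(spec.dose)
    else:
        if laws is None:
            laws = conservation_laws(crn)
        containing = [law for law in laws if spec.target in law.support]
        if not containing:
            raise PerturbationError(
                f"target {spec.target!r} is not covered by any conservation "
                "law; dose the drug with an absolute amount instead"
            )
        if len(containing) > 1:
            if spec.law_index is None:
                raise PerturbationError(
                    f"target {spec.target!r} appears in {len(containing)} "
                    "conservation laws; select one with law_index"
                )
            containing = [containing[spec.law_index]]
        c = containing[0].total(x_start)
        dose = spec.alpha * c

    species = list(crn.species) + [
        Species(spec.drug_name, dose, False),
        Species(spec.complex_name, 0.0, False),
    ]
    bind_id = f"bind_{spec.complex_name}"
    unbind_id = f"unbind_{spec.complex_name}"
    reactions = list(crn.reactions) + [
        Reaction(
            bind_id,
            {spec.target: 1, spec.drug_name: 1},
            {spec.complex_name: 1},
            spec.k1f,
            reverse_of=unbind_id,
        ),
        Reaction(
            unbind_id,
            {spec.complex_name: 1},
            {spec.target: 1, spec.drug_name: 1},
            spec.k1r,
            reverse_of=bind_id,
        ),
    ]
    drugged = CRN(species, reactions)
    x0 = np.concatenate([x_start, [dose, 0.0]])
    return drugged, x0


def washout(crn: CRN, spec: DrugSpec, k_deg: float) -> CRN:
    """Stop the drug action: binding off, drug degraded.

    Sets the forward binding constant to zero and adds a degradation
    reaction ``Drug -> 0`` with constant ``k_deg`` (s^-1), so free drug —
    including what the dissociating complex releases — is consumed and the
    network relaxes back to the (mutated) drug-free equilibrium.  With
    ``k_deg = 0`` free drug persists; this is flagged.
    """
    bind_id = f"bind_{spec.complex_name}"
    if bind_id not in crn.reaction_index or spec.drug_name not in crn.species_index:
        raise PerturbationError(
            f"network has no drug {spec.drug_name!r} bound as {spec.complex_name!r}"
        )
    if k_deg < 0:
        raise PerturbationError("k_deg must be >= 0")
    if k_deg == 0:
        warnings.warn(
            "washout with k_deg = 0: free drug is not consumed and persists "
            "at equilibrium",
            stacklevel=2,
        )
    out = crn.with_rate_constants({bind_id: 0.0})
    reactions = list(out.reactions) + [
        Reaction(f"degrade_{spec.drug_name}", {spec.drug_name: 1}, {}, k_deg)
    ]
    return CRN(out.species, reactions)


# -- config files --------------------------------------------------------


def load_perturbations(path) -> tuple[list[MutationSpec], list[DrugSpec]]:
    """Read mutations and drugs from a YAML/JSON perturbation file.

    Layout::

        mutations:
          - {kind: LoF, protein: AKT, degree: 1.0}
          - {kind: GoF, protein: Raf, reactions: [deph_bind, deph_cat]}
          - {kind: LoF, protein: p53, generator: p53_generator}
        drugs:
          - {target: Raf, k1f: 0.5, k1r: 0.005, alpha: 0.75}
    """
    import yaml

    with open(path) as fh:
        doc = yaml.safe_load(fh) or {}
    mutations = []
    for entry in doc.get("mutations", []) or []:
        mutations.append(
            MutationSpec(
                kind=entry["kind"],
                protein=entry["protein"],
                degree=float(entry.get("degree", 1.0)),
                removed_reactions=tuple(entry.get("reactions", ())),
                generator_species=entry.get("generator"),
            )
        )
    drugs = []
    for entry in doc.get("drugs", []) or []:
        drugs.append(
            DrugSpec(
                target=entry["target"],
                k1f=float(entry.get("k1f", 0.5)),
                k1r=float(entry.get("k1r", 0.005)),
                alpha=float(entry.get("alpha", 1.0)),
                complex_name=entry.get("complex", ""),
                drug_name=entry.get("drug", "Drug"),
                dose=entry.get("dose"),
                law_index=entry.get("law_index"),
            )
        )
    return mutations, drugs
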