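"""Quantifying mutation and drug effects on the equilibrium concentration profile.

The central index is the per-species relative difference

    delta_i = (x~_i - x_i) / x_i

between a perturbed equilibrium x~ and a reference (physiological)
equilibrium x.  delta_i = -1 means the species' function is completely
shut down; |delta_i| above a significance threshold (default 0.03) marks
the species as significantly affected.  Flux traces decompose a species'
time derivative into per-reaction mass-action fluxes (reversible pairs
summed), which is how feedback routes through the network are read off.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .crn_core import CRN
from .equilibrium import (
    EquilibriumResult,
    SolverOptions,
    Trajectory,
    find_equilibrium,
)
from .perturbation import DrugSpec, add_drug

__all__ = [
    "DeltaProfile",
    "FluxTrace",
    "delta_profile",
    "affected_fraction",
    "flux_traces",
    "bisymlog",
    "titrate",
    "TitrationResult",
    "export_delta_csv",
    "export_flux_csv",
]

#: reference concentrations below this floor (nM) give an undefined delta
REFERENCE_FLOOR = 1e-12

#: default bi-symmetric log constant, per the convention C = 1/ln(10)
BISYMLOG_C = 1.0 / np.log(10.0)


@dataclass(frozen=True)
class DeltaProfile:
    """Per-species relative concentration change with significance mask.

    ``delta`` is NaN where the reference concentration is below the floor
    (``defined`` False there); such species are flagged, never silently
    reported as unchanged, and count as not significant.
    """

    delta: np.ndarray
    defined: np.ndarray
    significant: np.ndarray
    threshold: float
    species_ids: tuple[str, ...]

    def get(self, species_id: str) -> float:
        return float(self.delta[self.species_ids.index(species_id)])

    @property
    def undefined_species(self) -> tuple[str, ...]:
        return tuple(
            s for s, d in zip(self.species_ids, self.defined) if not d
        )


def delta_profile(
    x_mut: np.ndarray,
    x_ref: np.ndarray,
    threshold: float = 0.03,
    species_ids: Sequence[str] | None = None,
    floor: float = REFERENCE_FLOOR,
) -> DeltaProfile:
    """Relative difference (x_mut - x_ref) / x_ref with significance mask."""
    x_mut = np.asarray(x_mut, dtype=float)
    x_ref = np.asarray(x_ref, dtype=float)
    if x_mut.shape != x_ref.shape:
        raise ValueError("x_mut and x_ref must have equal length")
    if np.any(x_ref < 0):
        raise ValueError("reference concentrations must be >= 0")
    defined = x_ref >= floor
    delta = np.full(x_mut.shape, np.nan)
    np.divide(x_mut - x_ref, x_ref, out=delta, where=defined)
    significant = np.zeros(x_mut.shape, dtype=bool)
    significant[defined] = np.abs(delta[defined]) > threshold
    ids = tuple(species_ids) if species_ids is not None else tuple(
        f"s{i}" for i in range(x_mut.size)
    )
    return DeltaProfile(delta, defined, significant, threshold, ids)


def affected_fraction(profile: DeltaProfile) -> float:
    """Percentage of species significantly affected (|delta| > threshold);
    undefined entries count as unaffected."""
    n = profile.delta.size
    return 100.0 * int(profile.significant.sum()) / n if n else 0.0


@dataclass(frozen=True)
class FluxTrace:
    """Signed flux contribution of one reaction (or reversible pair) to a species.

    ``values`` is the net stoichiometric coefficient of the species times
    the mass-action flux, sampled on ``times``; for a reversible pair the
    forward and backward contributions are summed into one trace.
    """

    reaction_ids: tuple[str, ...]
    times: np.ndarray
    values: np.ndarray


def flux_traces(crn: CRN, traj: Trajectory, species: str) -> list[FluxTrace]:
    """Decompose a species' derivative into per-reaction flux traces.

    At every sampled time the traces sum to the species' ODE right-hand
    side.  Reactions where the species appears only catalytically (equal
    reactant and product stoichiometry) contribute identically zero.
    """
    if species not in crn.species_index:
        raise ValueError(f"unknown species {species!r}")
    i = crn.species_index[species]
    incident = [
        j
        for j, rx in enumerate(crn.reactions)
        if species in rx.reactants or species in rx.products
    ]
    if not incident:
        return []

    V = np.empty((crn.r, traj.t.size))
    for col in range(traj.t.size):
        V[:, col] = crn.flux(traj.X[:, col], clip=True)

    paired: set[int] = set()
    traces: list[FluxTrace] = []
    for j in incident:
        if j in paired:
            continue
        rx = crn.reactions[j]
        ids = [rx.id]
        values = crn.S[i, j] * V[j]
        if rx.reverse_of is not None:
            jr = crn.reaction_index[rx.reverse_of]
            paired.add(jr)
            ids.append(rx.reverse_of)
            values = values + crn.S[i, jr] * V[jr]
        traces.append(FluxTrace(tuple(ids), traj.t.copy(), values))
    return traces


def bisymlog(v, C: float = BISYMLOG_C):
    """Bi-symmetric log transform sign(v) * log10(1 + |v|/C).

    Odd, strictly increasing, zero at zero; linearizes near the origin and
    behaves logarithmically for |v| >> C.  Used to display delta profiles
    spanning [-1, 1e4] on one axis.
    """
    if C <= 0:
        raise ValueError("bisymlog constant C must be > 0")
    v = np.asarray(v, dtype=float)
    out = np.sign(v) * np.log10(1.0 + np.abs(v) / C)
    return out if out.ndim else float(out)


@dataclass(frozen=True)
class TitrationResult:
    """Dose sweep outcome: per-alpha delta profiles and restoration scores."""

    alphas: tuple[float, ...]
    profiles: tuple[DeltaProfile, ...]
    scores: tuple[int, ...]
    equilibria: tuple[EquilibriumResult, ...]

    @property
    def best_alpha(self) -> float:
        return self.alphas[int(np.argmax(self.scores))]


def titrate(
    crn_mut: CRN,
    x_mut_eq: np.ndarray,
    x_phys_eq: np.ndarray,
    drug: DrugSpec,
    alphas: Sequence[float],
    laws=None,
    threshold: float = 0.03,
    options: SolverOptions | None = None,
) -> TitrationResult:
    """Sweep the drug dose fraction alpha and score restoration.

    For each alpha the drugged network is equilibrated from the mutated
    equilibrium, and the delta profile of the original species versus the
    physiological equilibrium is computed.  The restoration score counts
    species brought within the significance threshold of their
    physiological value (drug and complex excluded).  Ranking across
    alphas, not the absolute score, is the meaningful output.
    """
    alphas = tuple(sorted(float(a) for a in alphas))
    n = crn_mut.n
    profiles = []
    scores = []
    equilibria = []
    for alpha in alphas:
        spec = replace(drug, alpha=alpha, dose=None)
        drugged, x0 = add_drug(crn_mut, x_mut_eq, spec, laws=laws)
        res = find_equilibrium(drugged, x0, options=options)
        profile = delta_profile(
            res.x_eq[:n],
            np.asarray(x_phys_eq, dtype=float),
            threshold=threshold,
            species_ids=crn_mut.species_ids,
        )
        # defined, non-significant species; drug and complex are already
        # excluded because the profile covers the original n species only
        score = int(np.sum(profile.defined & ~profile.significant))
        profiles.append(profile)
        scores.append(score)
        equilibria.append(res)
    return TitrationResult(alphas, tuple(profiles), tuple(scores), tuple(equilibria))


def export_delta_csv(
    profile: DeltaProfile,
    x_ref: np.ndarray,
    x_mut: np.ndarray,
    path: str | Path,
) -> None:
    """Delta report: species, reference and perturbed concentrations, delta,
    significance flag (undefined deltas left blank)."""
    df = pd.DataFrame(
        {
            "species": list(profile.species_ids),
            "x_ref_nM": np.asarray(x_ref, dtype=float),
            "x_mut_nM": np.asarray(x_mut, dtype=float),
            "delta": profile.delta,
            "significant": profile.significant,
        }
    )
    df.to_csv(path, index=False)


def export_flux_csv(traces: Sequence[FluxTrace], path: str | Path) -> None:
    """Long-format flux report: time, reaction id(s), signed flux (nM/s)."""
    rows = []
    for tr in traces:
        label = "+".join(tr.reaction_ids)
        for t, v in zip(tr.times, tr.values):
            rows.append({"time_s": t, "reactions": label, "signed_flux_nM_s": v})
    pd.DataFrame(rows).to_csv(path, index=False)
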