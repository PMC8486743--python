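"""Small synthetic networks with known conservation laws and checkable equilibria.

Every fixture is generated programmatically and returns a
:class:`FixtureBundle` carrying the network, its initial state, the
expected conservation-law generators (verified exactly against S), and —
where a closed form exists — the analytic equilibrium.  The fixtures
emulate the structural motifs the mutation/drug machinery relies on:
bimolecular binding/unbinding, kinase/phosphatase phosphorylation cycles,
activation toggles, constant generator pools, and degradation reactions
that break conservation coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .conservation import ConservationLaw
from .crn_core import CRN, Reaction, Species

__all__ = [
    "FixtureBundle",
    "toy_binding",
    "isomerization",
    "phospho_cycle",
    "cascade",
    "stiff_chain",
    "degradation_chain",
    "generator_pool",
    "random_crn",
]


@dataclass
class FixtureBundle:
    """A generated network plus everything needed to verify it independently."""

    crn: CRN
    x0: np.ndarray
    laws_expected: list[ConservationLaw]
    x_eq_expected: np.ndarray | None
    provenance: str
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        # laws must annihilate S exactly, by construction
        S = self.crn.S.astype(object)
        for law in self.laws_expected:
            res = np.array(law.gamma, dtype=object) @ S
            if not np.all(res == 0):
                raise AssertionError(
                    f"fixture law {law!r} does not annihilate S"
                )


def _law(crn: CRN, coeffs: dict[str, int]) -> ConservationLaw:
    ids = tuple(crn.species_ids)
    gamma = tuple(coeffs.get(s, 0) for s in ids)
    return ConservationLaw(gamma, ids)


def toy_binding(
    kf: float = 1.0, kr: float = 1.0, a0: float = 1.0, b0: float = 1.0
) -> FixtureBundle:
    """Reversible bimolecular binding A + B <-> C.

    Conserved moieties: A + C = c1 and B + C = c2.  The equilibrium
    concentration of the complex solves the quadratic
    ``kf (c1 - x)(c2 - x) = kr x`` on [0, min(c1, c2)]; for
    kf = kr = c1 = c2 = 1 the root is (3 - sqrt(5))/2.
    """
    species = [Species("A", a0), Species("B", b0), Species("C", 0.0)]
    reactions = [
        Reaction("bind", {"A": 1, "B": 1}, {"C": 1}, kf, reverse_of="unbind"),
        Reaction("unbind", {"C": 1}, {"A": 1, "B": 1}, kr, reverse_of="bind"),
    ]
    crn = CRN(species, reactions)
    c1, c2 = a0, b0
    # kf x^2 - (kf (c1 + c2) + kr) x + kf c1 c2 = 0, smaller root
    b_coef = kf * (c1 + c2) + kr
    disc = b_coef**2 - 4.0 * kf * kf * c1 * c2
    x_c = (b_coef - math.sqrt(disc)) / (2.0 * kf)
    x_eq = np.array([c1 - x_c, c2 - x_c, x_c])
    return FixtureBundle(
        crn=crn,
        x0=crn.x0,
        laws_expected=[_law(crn, {"A": 1, "C": 1}), _law(crn, {"B": 1, "C": 1})],
        x_eq_expected=x_eq,
        provenance=(
            "binding equilibrium from the quadratic "
            "kf (c1 - x)(c2 - x) = kr x, smaller root"
        ),
    )


def isomerization(
    kf: float = 1.0, kr: float = 1.0, total: float = 2.0
) -> FixtureBundle:
    """Two-state toggle A <-> B; equilibrium x_B = total kf / (kf + kr)."""
    species = [Species("A", total), Species("B", 0.0)]
    reactions = [
        Reaction("fwd", {"A": 1}, {"B": 1}, kf, reverse_of="back"),
        Reaction("back", {"B": 1}, {"A": 1}, kr, reverse_of="fwd"),
    ]
    crn = CRN(species, reactions)
    xb = total * kf / (kf + kr)
    return FixtureBundle(
        crn=crn,
        x0=crn.x0,
        laws_expected=[_law(crn, {"A": 1, "B": 1})],
        x_eq_expected=np.array([total - xb, xb]),
        provenance="first-order toggle, x_B = total kf/(kf+kr)",
    )


def _cycle_reactions(
    sub: str, psub: str, kin: str, pase: str, tag: str, p: dict[str, float]
) -> list[Reaction]:
    """Michaelis-Menten style phosphorylation/dephosphorylation of one substrate."""
    ck = f"{sub}_{kin}"
    cp = f"{psub}_{pase}"
    return [
        Reaction(
            f"kin_bind_{tag}", {sub: 1, kin: 1}, {ck: 1}, p["a_kin"],
            reverse_of=f"kin_unbind_{tag}",
        ),
        Reaction(
            f"kin_unbind_{tag}", {ck: 1}, {sub: 1, kin: 1}, p["d_kin"],
            reverse_of=f"kin_bind_{tag}",
        ),
        Reaction(f"kin_cat_{tag}", {ck: 1}, {psub: 1, kin: 1}, p["c_kin"]),
        Reaction(
            f"ph_bind_{tag}", {psub: 1, pase: 1}, {cp: 1}, p["a_ph"],
            reverse_of=f"ph_unbind_{tag}",
        ),
        Reaction(
            f"ph_unbind_{tag}", {cp: 1}, {psub: 1, pase: 1}, p["d_ph"],
            reverse_of=f"ph_bind_{tag}",
        ),
        Reaction(f"ph_cat_{tag}", {cp: 1}, {sub: 1, pase: 1}, p["c_ph"]),
    ]


_CYCLE_DEFAULTS = {
    "a_kin": 0.01,  # (nM s)^-1
    "d_kin": 0.1,  # s^-1
    "c_kin": 0.1,  # s^-1
    "a_ph": 0.01,
    "d_ph": 0.1,
    "c_ph": 0.1,
}


def phospho_cycle(
    substrate_total: float = 100.0,
    kinase_total: float = 20.0,
    phosphatase_total: float = 20.0,
    params: dict[str, float] | None = None,
) -> FixtureBundle:
    """One kinase/phosphatase cycle with explicit enzyme-substrate complexes.

    Species: substrate T, phospho-form pT, kinase K, phosphatase P, and
    the complexes T_K and pT_P.  Moieties: substrate {T, pT, T_K, pT_P},
    kinase {K, T_K}, phosphatase {P, pT_P}.  The dephosphorylation forward
    steps (``ph_bind_1`` binding and ``ph_cat_1`` catalysis) are the
    deactivation reactions a gain-of-function mutation of T removes.
    """
    p = {**_CYCLE_DEFAULTS, **(params or {})}
    species = [
        Species("T", substrate_total),
        Species("pT", 0.0),
        Species("K", kinase_total),
        Species("P", phosphatase_total),
        Species("T_K", 0.0),
        Species("pT_P", 0.0),
    ]
    reactions = _cycle_reactions("T", "pT", "K", "P", "1", p)
    crn = CRN(species, reactions)
    laws = [
        _law(crn, {"T": 1, "pT": 1, "T_K": 1, "pT_P": 1}),
        _law(crn, {"K": 1, "T_K": 1}),
        _law(crn, {"P": 1, "pT_P": 1}),
    ]
    return FixtureBundle(
        crn=crn,
        x0=crn.x0,
        laws_expected=laws,
        x_eq_expected=None,
        provenance="kinase/phosphatase cycle; equilibrium by integration only",
        meta={"gof_reactions": ("ph_bind_1", "ph_cat_1")},
    )


def cascade(
    n_tiers: int = 4,
    params: dict[str, float] | None = None,
    substrate_total: float = 100.0,
    phosphatase_total: float = 20.0,
    upstream_total: float = 5.0,
    k_act: float = 0.05,
    k_deact: float = 0.5,
) -> FixtureBundle:
    """A miniature MAPK-shaped kinase cascade (Ras -> Raf -> MEK -> ERK at 4 tiers).

    Tier 1 is an activation toggle R <-> aR (GTPase-like: slow spontaneous
    activation, fast deactivation, so the resting network keeps most of the
    tier-1 moiety inactive).  Each downstream tier t is a phospho-cycle
    whose kinase is the previous tier's active form; tier t's substrate is
    T{t} with phospho-form pT{t} and phosphatase P{t}.

    Gain of function of R removes the deactivation ``deactivate_R``
    (meta["gof_reactions"]); the natural drug target for restoring the
    cascade is the tier-2 substrate T2 (meta["drug_target"]), mirroring an
    upstream-GTPase mutation treated with a kinase inhibitor one tier down.
    """
    if n_tiers < 2:
        raise ValueError("cascade needs n_tiers >= 2")
    p = {**_CYCLE_DEFAULTS, **(params or {})}
    species = [Species("R", upstream_total), Species("aR", 0.0)]
    reactions = [
        Reaction("activate_R", {"R": 1}, {"aR": 1}, k_act),
        Reaction("deactivate_R", {"aR": 1}, {"R": 1}, k_deact),
    ]
    law_specs: list[dict[str, int]] = [{"R": 1, "aR": 1}]
    prev_active = "aR"
    for t in range(2, n_tiers + 1):
        sub, psub, pase = f"T{t}", f"pT{t}", f"P{t}"
        species += [
            Species(sub, substrate_total),
            Species(psub, 0.0),
            Species(pase, phosphatase_total),
            Species(f"{sub}_{prev_active}", 0.0),
            Species(f"{psub}_{pase}", 0.0),
        ]
        reactions += _cycle_reactions(sub, psub, prev_active, pase, str(t), p)
        # the kinase complex of this tier belongs to the upstream moiety
        law_specs[-1][f"{sub}_{prev_active}"] = 1
        law_specs.append(
            {sub: 1, psub: 1, f"{sub}_{prev_active}": 1, f"{psub}_{pase}": 1}
        )
        law_specs.append({pase: 1, f"{psub}_{pase}": 1})
        # re-order so substrate law can absorb next tier's kinase complex
        law_specs[-2], law_specs[-1] = law_specs[-1], law_specs[-2]
        prev_active = psub
    crn = CRN(species, reactions)
    laws = [_law(crn, spec) for spec in law_specs]
    return FixtureBundle(
        crn=crn,
        x0=crn.x0,
        laws_expected=laws,
        x_eq_expected=None,
        provenance=(
            "activation toggle driving chained phospho-cycles; "
            "laws hold by motif construction"
        ),
        meta={
            "gof_protein": "R",
            "gof_reactions": ("deactivate_R",),
            "drug_target": "T2",
        },
    )


def stiff_chain() -> FixtureBundle:
    """A + B <-> C <-> D with rate constants spanning six orders of magnitude.

    Tree-structured reversible chain, so the equilibrium satisfies detailed
    balance; used to exercise the stiff integrator.
    """
    species = [
        Species("A", 10.0),
        Species("B", 5.0),
        Species("C", 0.0),
        Species("D", 0.0),
    ]
    reactions = [
        Reaction("bind", {"A": 1, "B": 1}, {"C": 1}, 1e2, reverse_of="unbind"),
        Reaction("unbind", {"C": 1}, {"A": 1, "B": 1}, 1e-3, reverse_of="bind"),
        Reaction("iso_f", {"C": 1}, {"D": 1}, 1e1, reverse_of="iso_b"),
        Reaction("iso_b", {"D": 1}, {"C": 1}, 1e-4, reverse_of="iso_f"),
    ]
    crn = CRN(species, reactions)
    laws = [
        _law(crn, {"A": 1, "C": 1, "D": 1}),
        _law(crn, {"B": 1, "C": 1, "D": 1}),
    ]
    return FixtureBundle(
        crn=crn,
        x0=crn.x0,
        laws_expected=laws,
        x_eq_expected=None,
        provenance="detailed-balance chain, constants span 1e-4..1e2",
    )


def degradation_chain() -> FixtureBundle:
    """A <-> B plus C -> 0: species C escapes every conservation law."""
    species = [Species("A", 1.0), Species("B", 1.0), Species("C", 1.0)]
    reactions = [
        Reaction("fwd", {"A": 1}, {"B": 1}, 1.0, reverse_of="back"),
        Reaction("back", {"B": 1}, {"A": 1}, 1.0, reverse_of="fwd"),
        Reaction("degrade_C", {"C": 1}, {}, 0.1),
    ]
    crn = CRN(species, reactions)
    return FixtureBundle(
        crn=crn,
        x0=crn.x0,
        laws_expected=[_law(crn, {"A": 1, "B": 1})],
        x_eq_expected=np.array([1.0, 1.0, 0.0]),
        provenance="degradation empties C; A/B toggle splits evenly",
    )


def generator_pool(
    pool_conc: float = 5.0, k_syn: float = 0.01, k_deg: float = 0.05
) -> FixtureBundle:
    """Synthesis-fed protein: constant pool G feeds X, X degrades.

    G is a constant-pool species (its row of S is zeroed), so X has no
    conservation law; its equilibrium is the synthesis/degradation balance
    x_X = k_syn [G] / k_deg.  This is the motif behind generator-routed
    loss-of-function mutations.
    """
    species = [Species("G", pool_conc, is_constant_pool=True), Species("X", 0.0)]
    reactions = [
        Reaction("synthesize", {"G": 1}, {"G": 1, "X": 1}, k_syn),
        Reaction("degrade", {"X": 1}, {}, k_deg),
    ]
    crn = CRN(species, reactions)
    x_eq = np.array([pool_conc, k_syn * pool_conc / k_deg])
    return FixtureBundle(
        crn=crn,
        x0=crn.x0,
        laws_expected=[],
        x_eq_expected=x_eq,
        provenance="zeroth-order synthesis vs first-order degradation balance",
        meta={"generator": "G", "product": "X"},
    )


def random_crn(
    n_moieties: int = 4, reactions_per_moiety: int = 3, seed: int = 0
) -> FixtureBundle:
    """Reproducible random network assembled from motifs with prescribed laws.

    Each moiety m contributes a chain of interconvertible forms
    ``X{m}_0 <-> X{m}_1 <-> ...``; additional bimolecular bindings join
    forms of two distinct moieties into a complex that carries coefficient
    one in both moieties' laws.  Because every motif preserves the
    prescribed integer conservation matrix, the laws hold by construction
    and the left null space is nontrivial by design.
    """
    if n_moieties < 1 or reactions_per_moiety < 1:
        raise ValueError("sizes must be >= 1")
    rng = np.random.default_rng(seed)
    species: list[Species] = []
    reactions: list[Reaction] = []
    members: list[list[str]] = []
    base_forms: list[list[str]] = []
    for m in range(n_moieties):
        forms = [f"X{m}_{i}" for i in range(reactions_per_moiety)]
        for i, name in enumerate(forms):
            species.append(
                Species(name, float(rng.uniform(0.5, 5.0)) if i == 0 else 0.0)
            )
        for i in range(len(forms) - 1):
            kf = float(rng.uniform(0.1, 2.0))
            kr = float(rng.uniform(0.1, 2.0))
            fid, bid = f"conv{m}_{i}_f", f"conv{m}_{i}_b"
            reactions.append(
                Reaction(fid, {forms[i]: 1}, {forms[i + 1]: 1}, kf, reverse_of=bid)
            )
            reactions.append(
                Reaction(bid, {forms[i + 1]: 1}, {forms[i]: 1}, kr, reverse_of=fid)
            )
        members.append(list(forms))
        base_forms.append(forms)

    if n_moieties >= 2:
        n_bind = n_moieties  # one complex per moiety on average
        for b in range(n_bind):
            m1, m2 = rng.choice(n_moieties, size=2, replace=False)
            # bind base forms only, so each complex sits in exactly two laws
            f1 = base_forms[m1][int(rng.integers(len(base_forms[m1])))]
            f2 = base_forms[m2][int(rng.integers(len(base_forms[m2])))]
            cx = f"cx{b}_{f1}_{f2}"
            species.append(Species(cx, 0.0))
            members[m1].append(cx)
            members[m2].append(cx)
            kf = float(rng.uniform(0.1, 2.0))
            kr = float(rng.uniform(0.1, 2.0))
            reactions.append(
                Reaction(
                    f"bind{b}", {f1: 1, f2: 1}, {cx: 1}, kf, reverse_of=f"unbind{b}"
                )
            )
            reactions.append(
                Reaction(
                    f"unbind{b}", {cx: 1}, {f1: 1, f2: 1}, kr, reverse_of=f"bind{b}"
                )
            )

    crn = CRN(species, reactions)
    laws = []
    for m in range(n_moieties):
        coeffs: dict[str, int] = {}
        for name in members[m]:
            coeffs[name] = coeffs.get(name, 0) + 1
        laws.append(_law(crn, coeffs))
    return FixtureBundle(
        crn=crn,
        x0=crn.x0,
        laws_expected=laws,
        x_eq_expected=None,
        provenance=f"motif-composed random network, seed={seed}",
        meta={"seed": seed},
    )
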