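"""LoF/GoF mutations, their composition, drugs, and washout."""

import itertools

import numpy as np
import pytest

from crnsim import fixtures as fx
from crnsim.conservation import conservation_laws, totals
from crnsim.crn_core import CRN, Reaction, Species
from crnsim.equilibrium import find_equilibrium, trajectory
from crnsim.perturbation import (
    DrugSpec,
    MutationSpec,
    PerturbationError,
    add_drug,
    apply_gof,
    apply_lof,
    apply_mutations,
    washout,
)


class TestMutationSpec:
    def test_gof_requires_reactions(self):
        with pytest.raises(PerturbationError, match="removed_reactions"):
            MutationSpec("GoF", "X", 1.0)

    def test_degree_bounds(self):
        with pytest.raises(PerturbationError, match="degree"):
            MutationSpec("LoF", "X", 1.5)


class TestLoF:
    def test_full_lof_zeroes_law_support(self, toy_binding_bundle):
        crn = toy_binding_bundle.crn
        laws = conservation_laws(crn)
        x0 = apply_lof(crn, np.array([1.0, 1.0, 0.0]),
                       MutationSpec("LoF", "A", 1.0), laws=laws)
        assert x0.tolist() == [0.0, 1.0, 0.0]

    def test_partial_lof_scales_support(self, toy_binding_bundle):
        crn = toy_binding_bundle.crn
        laws = conservation_laws(crn)
        x0 = apply_lof(crn, np.array([0.8, 1.0, 0.2]),
                       MutationSpec("LoF", "A", 0.5), laws=laws)
        assert x0 == pytest.approx([0.4, 1.0, 0.1])

    def test_generator_route_scales_pool(self):
        gp = fx.generator_pool()
        spec = MutationSpec("LoF", "X", 1.0, generator_species="G")
        x0 = apply_lof(gp.crn, gp.x0, spec)
        assert x0[gp.crn.species_index["G"]] == 0.0
        res = find_equilibrium(gp.crn, x0)
        assert res.x_eq[gp.crn.species_index["X"]] == pytest.approx(0.0, abs=1e-12)

    def test_uncovered_protein_without_generator_errors(self):
        bundle = fx.degradation_chain()
        laws = conservation_laws(bundle.crn)
        with pytest.raises(PerturbationError, match="generator"):
            apply_lof(bundle.crn, bundle.x0, MutationSpec("LoF", "C", 1.0), laws=laws)

    def test_post_equilibrium_supports_stay_zero(self, cascade_bundle, cascade_laws):
        crn = cascade_bundle.crn
        spec = MutationSpec("LoF", "T3", 1.0)
        x0 = apply_lof(crn, cascade_bundle.x0, spec, laws=cascade_laws)
        res = find_equilibrium(crn, x0, laws=cascade_laws)
        assert res.converged
        support = set()
        for law in cascade_laws:
            if "T3" in law.support:
                support |= set(law.support)
        for sp in support:
            assert res.x_eq[crn.species_index[sp]] == pytest.approx(0.0, abs=1e-12)


class TestGoF:
    def test_degree_one_zeroes_rate_constants(self, phospho_bundle):
        crn = apply_gof(
            phospho_bundle.crn,
            MutationSpec("GoF", "T", 1.0, phospho_bundle.meta["gof_reactions"]),
        )
        for rid in phospho_bundle.meta["gof_reactions"]:
            assert crn.reactions[crn.reaction_index[rid]].rate_constant == 0.0

    def test_partial_degree_halves_constants(self, phospho_bundle):
        orig = phospho_bundle.crn
        mut = apply_gof(
            orig, MutationSpec("GoF", "T", 0.5, phospho_bundle.meta["gof_reactions"])
        )
        for rid in phospho_bundle.meta["gof_reactions"]:
            j = orig.reaction_index[rid]
            assert mut.k[j] == pytest.approx(orig.k[j] / 2)

    def test_left_null_space_preserved(self, phospho_bundle):
        orig_laws = conservation_laws(phospho_bundle.crn)
        mut = apply_gof(
            phospho_bundle.crn,
            MutationSpec("GoF", "T", 1.0, phospho_bundle.meta["gof_reactions"]),
        )
        S = mut.S.astype(object)
        for law in orig_laws:
            assert np.all(np.array(law.gamma, dtype=object) @ S == 0)
        assert len(conservation_laws(mut)) == len(orig_laws)

    def test_locked_active_state_at_equilibrium(self, phospho_bundle):
        mut = apply_gof(
            phospho_bundle.crn,
            MutationSpec("GoF", "T", 1.0, phospho_bundle.meta["gof_reactions"]),
        )
        res = find_equilibrium(mut)
        assert res.converged
        # free unphosphorylated substrate is exhausted
        assert res.concentration("T") == pytest.approx(0.0, abs=1e-9)
        assert res.concentration("pT") == pytest.approx(100.0, abs=1e-6)

    def test_removing_lone_synthesis_step_errors(self):
        # A -> B -> C chain: each column is essential to the rank; removing
        # one creates a spurious conservation law and must be refused
        crn = CRN(
            [Species("A", 1.0), Species("B", 0.0), Species("C", 0.0)],
            [
                Reaction("ab", {"A": 1}, {"B": 1}, 1.0),
                Reaction("bc", {"B": 1}, {"C": 1}, 1.0),
            ],
        )
        with pytest.raises(PerturbationError, match="null space"):
            apply_gof(crn, MutationSpec("GoF", "B", 1.0, ("ab",)))

    def test_removing_both_directions_of_isolated_binding_errors(
        self, toy_binding_bundle
    ):
        with pytest.raises(PerturbationError, match="null space"):
            apply_gof(
                toy_binding_bundle.crn,
                MutationSpec("GoF", "C", 1.0, ("bind", "unbind")),
            )

    def test_unknown_reaction_id(self, phospho_bundle):
        with pytest.raises(PerturbationError, match="unknown reaction"):
            apply_gof(phospho_bundle.crn, MutationSpec("GoF", "T", 1.0, ("nope",)))


class TestComposition:
    def test_empty_list_is_identity(self, cascade_bundle):
        crn, x0 = apply_mutations(cascade_bundle.crn, cascade_bundle.x0, [])
        assert crn is cascade_bundle.crn or np.array_equal(crn.k, cascade_bundle.crn.k)
        assert np.array_equal(x0, cascade_bundle.x0)

    def test_order_invariance_all_permutations(self, cascade_bundle, cascade_laws):
        specs = [
            MutationSpec("GoF", "R", 1.0, ("deactivate_R",)),
            MutationSpec("LoF", "P4", 1.0),
            MutationSpec("LoF", "T3", 0.5),
        ]
        ref_crn, ref_x0 = apply_mutations(
            cascade_bundle.crn, cascade_bundle.x0, specs, laws=cascade_laws
        )
        for perm in itertools.permutations(specs):
            crn, x0 = apply_mutations(
                cascade_bundle.crn, cascade_bundle.x0, list(perm), laws=cascade_laws
            )
            assert np.array_equal(crn.k, ref_crn.k)
            assert np.array_equal(x0, ref_x0)

    def test_conflicting_specs_rejected(self, cascade_bundle):
        specs = [
            MutationSpec("LoF", "T3", 1.0),
            MutationSpec("GoF", "T3", 1.0, ("ph_bind_3", "ph_cat_3")),
        ]
        with pytest.raises(PerturbationError, match="conflicting"):
            apply_mutations(cascade_bundle.crn, cascade_bundle.x0, specs)


class TestDrug:
    def test_dose_is_alpha_times_conserved_total(
        self, cascade_gof_crn, cascade_mut_eq, cascade_laws
    ):
        spec = DrugSpec(target="T2", alpha=0.75)
        drugged, x0 = add_drug(
            cascade_gof_crn, cascade_mut_eq.x_eq, spec, laws=cascade_laws
        )
        c = next(
            law for law in cascade_laws if "T2" in law.support
        ).total(cascade_mut_eq.x_eq)
        assert x0[drugged.species_index["Drug"]] == pytest.approx(0.75 * c)
        assert x0[drugged.species_index["T2_Drug"]] == 0.0

    def test_default_rate_constants_fast_binding(self):
        spec = DrugSpec(target="T2")
        assert spec.k1f == 0.5 and spec.k1r == 0.005

    def test_alpha_zero_preserves_equilibrium(
        self, cascade_gof_crn, cascade_mut_eq, cascade_laws
    ):
        spec = DrugSpec(target="T2", alpha=0.0)
        drugged, x0 = add_drug(
            cascade_gof_crn, cascade_mut_eq.x_eq, spec, laws=cascade_laws
        )
        res = find_equilibrium(drugged, x0)
        n = cascade_gof_crn.n
        rel = np.abs(res.x_eq[:n] - cascade_mut_eq.x_eq) / np.maximum(
            np.abs(cascade_mut_eq.x_eq), 1.0
        )
        assert np.max(rel) <= 1e-6

    def test_drug_gains_exactly_one_new_law(
        self, cascade_gof_crn, cascade_mut_eq, cascade_laws
    ):
        spec = DrugSpec(target="T2", alpha=0.5)
        drugged, x0 = add_drug(
            cascade_gof_crn, cascade_mut_eq.x_eq, spec, laws=cascade_laws
        )
        new_laws = conservation_laws(drugged)
        assert len(new_laws) == len(cascade_laws) + 1
        drug_law = [
            law for law in new_laws if "Drug" in law.support
        ]
        assert len(drug_law) == 1
        assert set(drug_law[0].support) == {"Drug", "T2_Drug"}

    def test_drug_total_conserved_along_trajectory(
        self, cascade_gof_crn, cascade_mut_eq, cascade_laws
    ):
        spec = DrugSpec(target="T2", alpha=0.5)
        drugged, x0 = add_drug(
            cascade_gof_crn, cascade_mut_eq.x_eq, spec, laws=cascade_laws
        )
        traj = trajectory(drugged, x0, np.linspace(0, 2000, 25))
        total = traj.series("Drug") + traj.series("T2_Drug")
        assert np.max(np.abs(total - total[0])) / max(1.0, total[0]) <= 1e-6

    def test_unknown_target(self, cascade_gof_crn, cascade_mut_eq):
        with pytest.raises(PerturbationError, match="target"):
            add_drug(cascade_gof_crn, cascade_mut_eq.x_eq, DrugSpec(target="ZZ"))


class TestWashout:
    def test_return_to_mutated_equilibrium(
        self, cascade_gof_crn, cascade_mut_eq, cascade_laws
    ):
        spec = DrugSpec(target="T2", alpha=0.75)
        drugged, x0 = add_drug(
            cascade_gof_crn, cascade_mut_eq.x_eq, spec, laws=cascade_laws
        )
        with_drug = find_equilibrium(drugged, x0)
        washed = washout(drugged, spec, k_deg=0.01)
        after = find_equilibrium(washed, with_drug.x_eq)
        n = cascade_gof_crn.n
        rel = np.abs(after.x_eq[:n] - cascade_mut_eq.x_eq) / np.maximum(
            np.abs(cascade_mut_eq.x_eq), 1.0
        )
        assert np.max(rel) <= 1e-4

    def test_zero_degradation_flagged(
        self, cascade_gof_crn, cascade_mut_eq, cascade_laws
    ):
        spec = DrugSpec(target="T2", alpha=0.75)
        drugged, _ = add_drug(
            cascade_gof_crn, cascade_mut_eq.x_eq, spec, laws=cascade_laws
        )
        with pytest.warns(UserWarning, match="persists"):
            washout(drugged, spec, k_deg=0.0)

    def test_washout_without_drug_errors(self, cascade_gof_crn):
        with pytest.raises(PerturbationError, match="no drug"):
            washout(cascade_gof_crn, DrugSpec(target="T2"), k_deg=0.01)
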