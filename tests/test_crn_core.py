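"""Network container, kinetics evaluation, and file formats."""

import numpy as np
import pytest

from crnsim import fixtures as fx
from crnsim.crn_core import (
    CRN,
    CRNValidationError,
    Reaction,
    Species,
    fold_constant_pools,
    load_crn,
    read_reaction_table,
    write_reaction_table,
)
from crnsim.equilibrium import trajectory


class TestStoichiometricMatrix:
    @pytest.mark.parametrize(
        "reactants, products, expected_col",
        [
            ({"A": 1, "B": 1}, {"C": 1}, [-1, -1, 1]),
            ({"A": 2}, {"B": 1}, [-2, 1, 0]),
            ({"C": 1}, {"A": 1, "B": 1}, [1, 1, -1]),
        ],
    )
    def test_net_production_columns(self, reactants, products, expected_col):
        crn = CRN(
            [Species("A", 1.0), Species("B", 1.0), Species("C", 0.0)],
            [Reaction("r", reactants, products, 1.0)],
        )
        assert crn.S[:, 0].tolist() == expected_col

    def test_reversible_split_gives_opposite_columns(self):
        b = fx.isomerization()
        assert b.crn.S[:, 0].tolist() == [-1, 1]
        assert b.crn.S[:, 1].tolist() == [1, -1]

    def test_constant_pool_row_zeroed(self):
        gp = fx.generator_pool()
        i = gp.crn.species_index["G"]
        assert np.all(gp.crn.S[i, :] == 0)


class TestMassActionFlux:
    def test_bimolecular_flux(self):
        crn = CRN(
            [Species("A", 2.0), Species("B", 3.0), Species("C", 0.0)],
            [Reaction("r", {"A": 1, "B": 1}, {"C": 1}, 1.0)],
        )
        assert crn.flux(np.array([2.0, 3.0, 0.0])) == pytest.approx([6.0])

    def test_second_order_self_reaction(self):
        crn = CRN(
            [Species("A", 4.0), Species("B", 0.0)],
            [Reaction("r", {"A": 2}, {"B": 1}, 0.5)],
        )
        assert crn.flux(np.array([4.0, 0.0])) == pytest.approx([8.0])

    def test_zero_reactant_gives_zero_flux(self):
        crn = CRN(
            [Species("A", 0.0), Species("B", 1.0), Species("C", 0.0)],
            [Reaction("r", {"A": 1, "B": 1}, {"C": 1}, 7.0)],
        )
        assert crn.flux(np.array([0.0, 1.0, 0.0])) == pytest.approx([0.0])

    def test_negative_concentration_rejected(self):
        b = fx.toy_binding()
        with pytest.raises(CRNValidationError, match="negative"):
            b.crn.flux(np.array([-0.1, 1.0, 0.0]))

    def test_flux_nonnegative_on_random_states(self, rng):
        b = fx.cascade()
        for _ in range(20):
            x = rng.uniform(0, 10, size=b.crn.n)
            assert np.all(b.crn.flux(x) >= 0)


class TestRhs:
    def test_toy_binding_initial_derivative(self):
        b = fx.toy_binding(kf=1.0, kr=1.0, a0=1.0, b0=1.0)
        assert b.crn.rhs(np.array([1.0, 1.0, 0.0])) == pytest.approx([-1.0, -1.0, 1.0])

    def test_zero_at_closed_form_equilibrium(self, toy_binding_bundle):
        xdot = toy_binding_bundle.crn.rhs(toy_binding_bundle.x_eq_expected)
        assert np.max(np.abs(xdot)) <= 1e-12

    def test_constant_pool_component_exactly_zero(self):
        gp = fx.generator_pool()
        x = np.array([5.0, 2.0])
        assert gp.crn.rhs(x)[gp.crn.species_index["G"]] == 0.0

    def test_consistent_with_trajectory_finite_differences(self, toy_binding_bundle):
        crn = toy_binding_bundle.crn
        t = np.linspace(0.0, 1.0, 201)
        traj = trajectory(crn, crn.x0, t)
        i = crn.species_index["C"]
        mid = (traj.X[:, 1:] + traj.X[:, :-1]) / 2
        fd = np.diff(traj.X[i]) / np.diff(t)
        analytic = np.array([crn.rhs(mid[:, j])[i] for j in range(mid.shape[1])])
        rel = np.abs(fd - analytic) / np.maximum(np.abs(analytic), 1e-8)
        assert np.max(rel) <= 1e-4

    def test_jacobian_matches_numerical_derivative(self, rng):
        crn = fx.phospho_cycle().crn
        x = rng.uniform(0.5, 5.0, size=crn.n)
        J = crn.jacobian(x)
        eps = 1e-6
        for i in range(crn.n):
            dx = np.zeros(crn.n)
            dx[i] = eps
            col = (crn.rhs(x + dx) - crn.rhs(x - dx)) / (2 * eps)
            assert np.allclose(J[:, i], col, rtol=1e-5, atol=1e-7)


class TestReactionTable:
    def test_one_line_network(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text(
            "# species\nA\t1.0\nB\t1.0\nC\t0.0\n"
            "# reactions\nr1\tA + B -> C\t1.0\n"
        )
        crn = load_crn(p)
        assert (crn.n, crn.r) == (3, 1)
        assert crn.reactions[0].rate_constant == 1.0

    def test_unknown_species_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("# species\nA\t1.0\n# reactions\nr1\tA -> D\t1.0\n")
        with pytest.raises(CRNValidationError, match="unknown species"):
            load_crn(p)

    @pytest.mark.parametrize(
        "maker", [fx.toy_binding, fx.phospho_cycle, fx.cascade, fx.stiff_chain]
    )
    def test_round_trip_bit_exact(self, maker, tmp_path):
        crn = maker().crn
        p = tmp_path / "net.tsv"
        write_reaction_table(crn, p)
        back = read_reaction_table(p)
        assert np.array_equal(crn.S, back.S)
        assert np.array_equal(crn.k, back.k)
        assert [r.reverse_of for r in crn.reactions] == [
            r.reverse_of for r in back.reactions
        ]
        # writing again is byte-identical
        p2 = tmp_path / "net2.tsv"
        write_reaction_table(back, p2)
        assert p.read_bytes() == p2.read_bytes()

    def test_stoichiometric_coefficients_survive(self, tmp_path):
        crn = CRN(
            [Species("A", 4.0), Species("B", 0.0)],
            [Reaction("dimerize", {"A": 2}, {"B": 1}, 0.5)],
        )
        p = tmp_path / "d.tsv"
        write_reaction_table(crn, p)
        back = read_reaction_table(p)
        assert back.reactions[0].reactants == {"A": 2}


class TestSBML:
    def test_species_and_boundary_flags(self, sbml_toy_path):
        crn = load_crn(sbml_toy_path, format="sbml")
        assert crn.species_ids == ["A", "B", "C", "G"]
        assert crn.species[3].is_constant_pool
        assert crn.species[0].initial_concentration == 1.0

    def test_reversible_reaction_split_with_constants(self, sbml_toy_path):
        crn = load_crn(sbml_toy_path)
        fwd = crn.reactions[crn.reaction_index["bindR"]]
        rev = crn.reactions[crn.reaction_index["bindR_rev"]]
        assert fwd.rate_constant == 0.7
        assert rev.rate_constant == 0.2
        assert fwd.reverse_of == "bindR_rev" and rev.reverse_of == "bindR"

    def test_constant_pool_mapped_and_row_zeroed(self, sbml_toy_path):
        crn = load_crn(sbml_toy_path)
        g = crn.species_index["G"]
        assert np.all(crn.S[g, :] == 0)

    def test_unparsable_file_raises_format_error(self, tmp_path):
        p = tmp_path / "bad.xml"
        p.write_text("<sbml><model></sbml>")
        with pytest.raises(CRNValidationError):
            load_crn(p, format="sbml")

    def test_missing_file(self):
        with pytest.raises(FileNotFoundError):
            load_crn("no/such/file.xml")


class TestValidation:
    def test_duplicate_species(self):
        with pytest.raises(CRNValidationError, match="duplicate"):
            CRN([Species("A", 1.0), Species("A", 2.0)], [])

    def test_negative_rate_constant(self):
        with pytest.raises(CRNValidationError, match="rate constant"):
            Reaction("r", {"A": 1}, {"B": 1}, -1.0)

    def test_identity_reaction_rejected(self):
        with pytest.raises(CRNValidationError, match="identical"):
            Reaction("r", {"A": 1}, {"A": 1}, 1.0)

    def test_asymmetric_reverse_link_rejected(self):
        with pytest.raises(CRNValidationError, match="symmetric"):
            CRN(
                [Species("A", 1.0), Species("B", 0.0)],
                [
                    Reaction("f", {"A": 1}, {"B": 1}, 1.0, reverse_of="b"),
                    Reaction("b", {"B": 1}, {"A": 1}, 1.0, reverse_of=None),
                ],
            )


class TestConstantPoolFolding:
    def test_pseudo_reaction_equivalent_dynamics(self):
        gp = fx.generator_pool()
        folded = fold_constant_pools(gp.crn)
        assert "G" not in folded.species_index
        # synthesis becomes zeroth order with constant k_syn * [G]0
        syn = folded.reactions[folded.reaction_index["synthesize"]]
        assert syn.reactants == {}
        assert syn.rate_constant == pytest.approx(0.01 * 5.0)
        x = np.array([2.0])
        full = gp.crn.rhs(np.array([5.0, 2.0]))
        assert folded.rhs(x)[0] == pytest.approx(full[gp.crn.species_index["X"]])
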