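"""Binding thermodynamics, field equations, packing and the SCF solver."""

from dataclasses import replace

import numpy as np
import pytest

from acnp import (
    BulkSolution,
    ConvergenceError,
    OsmoticField,
    RadialGrid,
    binding_constant_to_potential,
    captured_antigen,
    conformation_weight,
    ligation_factors,
    packing_residual,
    solution_density_profiles,
    solve_self_consistent,
    species_partition_function,
    surface_fractions_covalent,
    surface_fractions_streptavidin,
)
from acnp.conformer_lab import ShellVolumeProfile, SpeciesEnsemble
from acnp.theory_core import free_energy, water_volume_fraction


@pytest.fixture
def grid3():
    return RadialGrid(r_np=10.0, dr=1.0, n_layers=3)


def _ensemble(grid, profiles, species="A", n_antigens=0, n_att=None):
    profiles = np.asarray(profiles, dtype=float)
    return SpeciesEnsemble(
        species=species, grid=grid, v_profiles=profiles,
        com_radii=np.full(len(profiles), grid.r_np + 1.0),
        n_attempted=n_att or len(profiles), n_antigens=n_antigens,
        molecular_volume=float(profiles.sum(axis=1).mean()))


class TestBindingConstants:
    def test_standard_state_gives_zero(self):
        assert binding_constant_to_potential(1.0) == 0.0

    def test_nanomolar_affinity(self):
        assert binding_constant_to_potential(1e-9) == pytest.approx(
            -9 * np.log(10), rel=1e-12)

    def test_nonpositive_kd_rejected(self):
        with pytest.raises(ValueError):
            binding_constant_to_potential(0.0)

    @pytest.mark.parametrize("x,rho", [(0.3, 2.0), (1.7, 50.0), (10.0, 1.0)])
    def test_two_site_factors_match_state_enumeration(self, x, rho):
        """Site-enumeration oracle: microstates {00, 10, 01, 11} with
        intrinsic per-site constants Kd and Kd*rho carry weights
        1 : x : x : x*(x/rho); the macroscopic multipliers follow."""
        kd = 1e-9
        c = x * kd
        m1, m2 = ligation_factors(c, kd, rho, g_mode=2)
        assert m1 == pytest.approx(x + x, rel=1e-12)
        assert m2 == pytest.approx(x * (x / rho), rel=1e-12)
        # the g=1 convention uses sequential macroscopic constants
        m1s, m2s = ligation_factors(c, kd, rho, g_mode=1)
        assert (m1s, m2s) == (pytest.approx(x), pytest.approx(x * x / rho))


class TestConformationWeight:
    def test_field_free_weight_is_one(self, grid3):
        prof = ShellVolumeProfile(grid=grid3, v=np.array([1.0, 2.0, 0.5]))
        assert conformation_weight(prof, OsmoticField.zero(grid3)) == 1.0

    def test_single_bead_exponential(self, grid3):
        v0 = 0.7
        prof = ShellVolumeProfile(grid=grid3, v=np.array([0.0, v0, 0.0]))
        fld = OsmoticField(grid=grid3, beta_pi=np.array([0.0, 2.5 / v0, 0.0]))
        assert conformation_weight(prof, fld) == pytest.approx(np.exp(-2.5))

    def test_weight_multiplicative_over_disjoint_union(self, grid3):
        rng = np.random.default_rng(1)
        va = np.array([1.0, 0.0, 0.3])
        vb = np.array([0.0, 2.0, 0.1])
        fld = OsmoticField(grid=grid3, beta_pi=rng.uniform(0, 2, 3))
        wa = conformation_weight(ShellVolumeProfile(grid3, va), fld)
        wb = conformation_weight(ShellVolumeProfile(grid3, vb), fld)
        wab = conformation_weight(ShellVolumeProfile(grid3, va + vb), fld)
        assert wab == pytest.approx(wa * wb, rel=1e-12)


class TestPartitionFunction:
    def test_field_free_q_is_one_and_p_uniform(self, grid3):
        ens = _ensemble(grid3, [[1, 0, 0], [0, 2, 0], [0, 0, 3]])
        q, p = species_partition_function(ens, OsmoticField.zero(grid3))
        assert q == pytest.approx(1.0)
        np.testing.assert_allclose(p, 1 / 3)

    def test_single_conformation_p_is_one(self, grid3):
        ens = _ensemble(grid3, [[1.0, 1.0, 1.0]])
        fld = OsmoticField(grid=grid3, beta_pi=np.array([3.0, 1.0, 0.0]))
        q, p = species_partition_function(ens, fld)
        np.testing.assert_allclose(p, [1.0])
        assert 0 < q < 1

    def test_q_decreases_when_field_raised_where_supported(self, grid3):
        ens = _ensemble(grid3, [[1, 0.5, 0], [0.2, 1, 0.1]])
        rng = np.random.default_rng(4)
        for _ in range(10):
            base = rng.uniform(0, 1, 3)
            q0, _ = species_partition_function(
                ens, OsmoticField(grid=grid3, beta_pi=base))
            for k in range(3):
                bumped = base.copy()
                bumped[k] += 0.1
                q1, _ = species_partition_function(
                    ens, OsmoticField(grid=grid3, beta_pi=bumped))
                assert q1 < q0


class TestSurfaceFractions:
    def test_no_antigen_all_unbound(self):
        assert surface_fractions_covalent(1, 1, 1, 0.0, 1e-9, 100.0) == \
            (1.0, 0.0, 0.0)

    def test_mass_action_half_occupancy(self):
        f = surface_fractions_covalent(1, 1, 1, 1e-9, 1e-9, 1e12, g_mode=1)
        assert f[0] == pytest.approx(0.5)
        assert f[1] == pytest.approx(0.5)
        assert f[2] == pytest.approx(0.0, abs=1e-11)

    def test_equal_thirds_from_two_site_partition_function(self):
        f = surface_fractions_covalent(1, 1, 1, 1e-9, 1e-9, 1.0, g_mode=1)
        np.testing.assert_allclose(f, 1 / 3, rtol=1e-12)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            surface_fractions_covalent(-1, 1, 1, 1e-9, 1e-9, 100.0)

    def test_streptavidin_mass_action(self):
        f = surface_fractions_streptavidin(
            {"A": 1.0, "Aa": 1.0, "Aaa": 1.0},
            {"A": 1e-14, "Aa": 0.0, "Aaa": 0.0}, kd_biotin=1e-14)
        assert f[0] == pytest.approx(0.5)
        assert f[1] == pytest.approx(0.5)

    def test_streptavidin_vanishing_kd_fills_every_site(self):
        f = surface_fractions_streptavidin(
            {"A": 1.0, "Aa": 1.0, "Aaa": 1.0},
            {"A": 1e-9, "Aa": 0.0, "Aaa": 0.0}, kd_biotin=1e-22)
        assert f[0] < 1e-12

    def test_streptavidin_empty_solution_warns_not_raises(self):
        with pytest.warns(UserWarning):
            f = surface_fractions_streptavidin(
                {"A": 1.0, "Aa": 1.0, "Aaa": 1.0},
                {"A": 0.0, "Aa": 0.0, "Aaa": 0.0}, kd_biotin=1e-14)
        assert f == (1.0, 0.0, 0.0, 0.0)


class TestSolutionProfiles:
    def test_zero_field_gives_bulk_everywhere(self, grid3):
        bulk = BulkSolution(concentrations={"a": 1e-6},
                            molecular_volumes={"a": 5.0})
        rho = solution_density_profiles(bulk, OsmoticField.zero(grid3))
        np.testing.assert_allclose(rho["a"], bulk.density("a"))
        np.testing.assert_allclose(
            water_volume_fraction(bulk, OsmoticField.zero(grid3)),
            bulk.phi_w_bulk)

    def test_point_volume_species_is_field_blind(self, grid3):
        bulk = BulkSolution(concentrations={"a": 1e-6},
                            molecular_volumes={"a": 0.0})
        fld = OsmoticField(grid=grid3, beta_pi=np.array([5.0, 1.0, 0.0]))
        np.testing.assert_allclose(solution_density_profiles(bulk, fld)["a"],
                                   bulk.density("a"))

    def test_raising_field_depletes_finite_volume_species(self, grid3):
        bulk = BulkSolution(concentrations={"a": 1e-6},
                            molecular_volumes={"a": 5.0})
        lo = solution_density_profiles(bulk, OsmoticField.zero(grid3))["a"]
        fld = OsmoticField(grid=grid3, beta_pi=np.array([0.0, 0.7, 0.0]))
        hi = solution_density_profiles(bulk, fld)["a"]
        assert hi[1] < lo[1]
        assert hi[0] == lo[0] and hi[2] == lo[2]


class TestPackingResidual:
    def test_pure_water_zero_field_is_exactly_packed(self, grid3):
        bulk = BulkSolution(concentrations={}, molecular_volumes={})
        res = packing_residual(OsmoticField.zero(grid3), None, {}, bulk,
                               grid3)
        np.testing.assert_array_equal(res, 0.0)

    def test_overfilled_shell_has_positive_residual(self, crowded_state):
        res = packing_residual(crowded_state.field, crowded_state.surface,
                               crowded_state.solution_densities,
                               crowded_state.bulk, crowded_state.grid)
        assert np.abs(res).max() <= 1e-8  # converged state packs exactly
        # now zero the field: the crowded layer overfills its shells
        res0 = packing_residual(OsmoticField.zero(crowded_state.grid),
                                crowded_state.surface,
                                crowded_state.solution_densities,
                                crowded_state.bulk, crowded_state.grid)
        assert res0.max() > 0


class TestSolver:
    def test_empty_surface_pure_water_converges_immediately(self, grid3):
        ens = {"A": _ensemble(grid3, [[0.5, 0.2, 0.0]])}
        bulk = BulkSolution(concentrations={}, molecular_volumes={})
        state = solve_self_consistent(ens, bulk, "covalent", 0.0, kd=1e-9)
        assert state.diagnostics["iterations"] == 0
        np.testing.assert_array_equal(state.field.beta_pi, 0.0)
        assert state.beta_free_energy == pytest.approx(0.0, abs=1e-12)

    def test_dilute_limit_recovers_mass_action_within_one_percent(
            self, dilute_state):
        f = dilute_state.surface.fractions
        m1, m2 = ligation_factors(100e-9, 1e-9, 100.0, g_mode=2)
        ens = dilute_state.surface.ensembles
        # geometric acceptance re-weights the field-free equilibrium
        qr1 = ens["Aa"].acceptance_fraction / ens["A"].acceptance_fraction
        qr2 = ens["Aaa"].acceptance_fraction / ens["A"].acceptance_fraction
        expect = np.array([1.0, m1 * qr1, m2 * qr2])
        expect /= expect.sum()
        assert f["Aa"] / f["A"] == pytest.approx(expect[1] / expect[0],
                                                 rel=0.01)

    def test_incompressibility_and_normalization_everywhere(
            self, crowded_state, dilute_state):
        for state in (crowded_state, dilute_state):
            res = packing_residual(state.field, state.surface,
                                   state.solution_densities, state.bulk,
                                   state.grid)
            assert np.abs(res).max() <= 1e-8
            assert sum(state.surface.fractions.values()) == pytest.approx(
                1.0, abs=1e-12)
            for p in state.surface.probs.values():
                assert p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_field_decays_beyond_the_antibody_layer(self, crowded_state):
        bp = crowded_state.field.beta_pi
        tail = bp[-5:]
        assert np.abs(tail).max() < 1e-6
        outer = bp[25:]
        assert (np.diff(np.abs(outer) + 1e-30) <= 1e-9).all()

    def test_grid_extent_insensitivity(self, toy_ensembles, antigen_bulk,
                                       toy_antibody, toy_antigen,
                                       spacer_chains):
        from acnp import assemble_species_conformations

        caps = {}
        for n_layers in (45, 90):
            grid = RadialGrid(r_np=50.0, dr=1.0, n_layers=n_layers)
            ens = {sp: assemble_species_conformations(
                spacer_chains, toy_antibody, toy_antigen, n, 10, grid,
                seed=7 * (n + 1), species=sp)
                for n, sp in ((0, "A"), (1, "Aa"), (2, "Aaa"))}
            st = solve_self_consistent(ens, antigen_bulk, "covalent", 2e3,
                                       kd=1e-9, avidity_ratio=100.0,
                                       damping=0.3)
            caps[n_layers] = st.captured_antigen_count
        assert caps[90] == pytest.approx(caps[45], rel=1e-3)

    def test_infeasible_packing_raises_with_history(self, grid3):
        # a single rigid conformation that overfills its shell at any field
        huge = grid3.shell_volumes[0] * 2.0
        ens = {"A": _ensemble(grid3, [[huge, 0.0, 0.0]])}
        bulk = BulkSolution(concentrations={}, molecular_volumes={})
        with pytest.raises(ConvergenceError) as err:
            solve_self_consistent(ens, bulk, "covalent", 1.0, kd=1e-9,
                                  max_iter=50)
        assert len(err.value.residual_history) > 0

    def test_free_energy_rises_under_random_feasible_perturbations(
            self, crowded_state):
        """The converged state is a local minimum of the constant-mu free
        energy: reweighting conformer probabilities or site fractions and
        renormalizing never lowers beta*W (100 random probes)."""
        rng = np.random.default_rng(0)
        base = free_energy(crowded_state)
        assert base == pytest.approx(crowded_state.beta_free_energy)
        for t in range(100):
            sp = ("A", "Aa", "Aaa")[t % 3]
            probs = dict(crowded_state.surface.probs)
            p = probs[sp] * np.exp(0.02 * rng.standard_normal(len(probs[sp])))
            probs[sp] = p / p.sum()
            fr = dict(crowded_state.surface.fractions)
            fr["A"] = max(fr["A"] + 0.01 * rng.standard_normal(), 1e-9)
            tot = sum(fr.values())
            fr = {k: v / tot for k, v in fr.items()}
            trial = replace(crowded_state,
                            surface=replace(crowded_state.surface,
                                            probs=probs, fractions=fr))
            assert free_energy(trial) > base

    def test_captured_antigen_observables(self, crowded_state):
        count, per_area = captured_antigen(crowded_state)
        f = crowded_state.surface.fractions
        ns = crowded_state.surface.n_sites
        assert count == pytest.approx(ns * (f["Aa"] + 2 * f["Aaa"]))
        assert per_area == pytest.approx(count / (4 * np.pi * 50.0**2))
        assert count <= 2 * ns  # two Fabs bound at most
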