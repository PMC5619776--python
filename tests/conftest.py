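"""Shared fixtures: toy molecules, small ensembles, converged states, sweeps."""

import logging

import pytest

from acnp import (
    BulkSolution,
    RadialGrid,
    assemble_species_conformations,
    generate_spacer_conformations,
    make_test_configs,
    make_toy_antibody,
    make_toy_antigen,
    solve_self_consistent,
)
from acnp.sweep_pipeline import run_sweep

logging.getLogger("acnp").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def toy_antibody():
    return make_toy_antibody(5)


@pytest.fixture(scope="session")
def toy_antigen():
    return make_toy_antigen()


@pytest.fixture(scope="session")
def grid45():
    return RadialGrid(r_np=50.0, dr=1.0, n_layers=45)


@pytest.fixture(scope="session")
def spacer_chains():
    return generate_spacer_conformations(50, 60, seed=11)


@pytest.fixture(scope="session")
def toy_ensembles(spacer_chains, toy_antibody, toy_antigen, grid45):
    """A/Aa/Aaa ensembles of the 5-bead-arm antibody with a 50-bead spacer."""
    return {
        sp: assemble_species_conformations(
            spacer_chains, toy_antibody, toy_antigen, n, 10, grid45,
            seed=7 * (n + 1), species=sp)
        for n, sp in ((0, "A"), (1, "Aa"), (2, "Aaa"))
    }


@pytest.fixture(scope="session")
def antigen_bulk(toy_antigen):
    return BulkSolution(concentrations={"a": 100e-9},
                        molecular_volumes={"a": toy_antigen.total_volume})


@pytest.fixture(scope="session")
def crowded_state(toy_ensembles, antigen_bulk):
    """Converged covalent equilibrium deep in the crowded regime."""
    return solve_self_consistent(toy_ensembles, antigen_bulk, "covalent",
                                 2e4, kd=1e-9, avidity_ratio=100.0,
                                 damping=0.3)


@pytest.fixture(scope="session")
def dilute_state(toy_ensembles, antigen_bulk):
    """Converged covalent equilibrium at near-zero coverage (field ~ 0)."""
    return solve_self_consistent(toy_ensembles, antigen_bulk, "covalent",
                                 1.0, kd=1e-9, avidity_ratio=100.0,
                                 damping=0.3)


@pytest.fixture(scope="session")
def trend_curves():
    """All reduced-sampling panel sweeps, solved once per session."""
    out = {}
    for name, cfg in make_test_configs().items():
        curves, manifest = run_sweep(cfg)
        out[name] = {"curves": curves, "manifest": manifest}
    return out
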