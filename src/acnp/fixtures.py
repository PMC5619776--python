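"""Synthetic inputs and independent oracles.

Everything here exists so the full pipeline is testable without downloads:
a deterministic Y-shaped toy antibody and a compact toy antigen, a
freely-rotating-chain sampler (plus its closed form) to validate the RIS
spacer statistics, a field-free Langmuir oracle, and an exhaustive-grid
minimizer of the free energy on tiny systems.  The oracles re-derive the
free-energy formula in standalone code and share no numerical kernels with
``theory_core``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from . import conformer_lab as cl
from .theory_core import RadialGrid, WATER_VOLUME_NM3


# ---------------------------------------------------------------------------
# Toy molecules and world
# ---------------------------------------------------------------------------

def make_toy_antigen() -> cl.BeadModel:
    """Compact 7-bead close-packed cluster (octahedron + center).

    Large enough to exercise crowding against the Fab-tip neighborhood,
    small enough for fast sampling.  The anchor bead faces the binding site.
    """
    l = cl.BOND_LENGTH
    pos = np.array([
        [0.0, 0.0, 0.0],
        [l, 0.0, 0.0], [-l, 0.0, 0.0],
        [0.0, l, 0.0], [0.0, -l, 0.0],
        [0.0, 0.0, l], [0.0, 0.0, -l],
    ])
    return cl.BeadModel(positions=pos, bead_diameter=cl.BEAD_DIAMETER,
                        anchor_index=6, label="toy-antigen")


@dataclass(frozen=True)
class ToyWorld:
    """Deterministic small test universe with closed-form checkable volumes."""

    antibody: cl.BeadModel
    antigen: cl.BeadModel
    grid: RadialGrid
    kd: float = 1e-9
    c_a: float = 100e-9
    avidity_ratio: float = 100.0


def make_toy_world(arm_length: int = 5, r_np: float = 20.0, dr: float = 5.0,
                   n_layers: int = 4, **constants) -> ToyWorld:
    return ToyWorld(
        antibody=cl.make_toy_antibody(arm_length),
        antigen=make_toy_antigen(),
        grid=RadialGrid(r_np=r_np, dr=dr, n_layers=n_layers),
        **constants,
    )


# ---------------------------------------------------------------------------
# Field-free binding oracle
# ---------------------------------------------------------------------------

def langmuir_oracle(c: float, kd: float) -> float:
    """Single-site occupancy c/(c + Kd) in the dilute, field-free limit."""
    if c < 0 or kd < 0 or (c == 0 and kd == 0):
        raise ValueError("require c, kd >= 0 and not both zero")
    return c / (c + kd)


# ---------------------------------------------------------------------------
# Chain-statistics oracles
# ---------------------------------------------------------------------------

def freely_rotating_chain_r2(n: int, bond_length: float = cl.BOND_LENGTH,
                             bond_angle_deg: float = cl.BOND_ANGLE_DEG) -> float:
    """Closed-form mean squared end-to-end distance of a freely rotating chain.

    With equal trans/gauche+- weights the dihedral averages <cos phi> and
    <sin phi> vanish, so the ideal RIS chain has exactly the bond-vector
    correlations of a freely rotating chain: <b_i . b_{i+k}> = alpha^k with
    alpha = -cos(theta_bond).
    """
    a = -np.cos(np.deg2rad(bond_angle_deg))
    if n < 1:
        return 0.0
    return bond_length**2 * (n * (1 + a) / (1 - a)
                             - 2 * a * (1 - a**n) / (1 - a) ** 2)


def frc_chain_sampler(n: int, n_samples: int, seed: int,
                      bond_length: float = cl.BOND_LENGTH,
                      bond_angle_deg: float = cl.BOND_ANGLE_DEG) -> np.ndarray:
    """Monte-Carlo freely-rotating chains; returns end-to-end vectors.

    Independent of the RIS generator: each new bond is the previous bond
    tilted by the supplementary bond angle about a uniformly random azimuth
    (continuous dihedral), built by Gram-Schmidt rather than dihedral-state
    frames.
    """
    rng = np.random.default_rng(seed)
    gamma = np.pi - np.deg2rad(bond_angle_deg)
    b = np.tile(np.array([0.0, 0.0, 1.0]), (n_samples, 1))
    end = bond_length * b.copy()
    for _ in range(1, n):
        # random unit vector perpendicular to b
        v = rng.standard_normal((n_samples, 3))
        v -= (np.einsum("ij,ij->i", v, b))[:, None] * b
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        b = np.cos(gamma) * b + np.sin(gamma) * v
        b /= np.linalg.norm(b, axis=1, keepdims=True)
        end += bond_length * b
    return end


# ---------------------------------------------------------------------------
# Brute-force free-energy minimizer (tiny systems)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TinySpecies:
    """One bound species of a tiny system: conformer volume profiles and the
    effective surface self-energy (binding free energy folded with the bulk
    chemical potentials, as in the mass-action fractions)."""

    label: str
    v_profiles: np.ndarray       # (n_conf, n_shells) nm^3
    beta_mu_eff: float
    n_attempted: int | None = None

    @property
    def n_conf(self) -> int:
        return self.v_profiles.shape[0]

    @property
    def n_att(self) -> int:
        return self.n_attempted if self.n_attempted is not None else self.n_conf


@dataclass(frozen=True)
class TinySystem:
    """A <=5-shell, <=3-conformation system amenable to exhaustive search."""

    grid: RadialGrid
    species: tuple               # of TinySpecies
    n_sites: float
    v_w: float = WATER_VOLUME_NM3


def _simplex_grid(dim: int, m: int) -> np.ndarray:
    """All compositions (k_1/m, ..., k_dim/m) with sum k_i = m."""
    combos = [np.array(c, dtype=float) / m
              for c in itertools.product(range(m + 1), repeat=dim)
              if sum(c) == m]
    return np.asarray(combos)


def tiny_objective(system: TinySystem, fractions: np.ndarray,
                   probs: list) -> float:
    """beta*W of one trial composition, water eliminated through packing.

    Standalone re-derivation of the free energy: water translational entropy
    relative to the pure-solvent bulk plus the bound layer's conformational
    entropy, mixing entropy and self-energy.  Infeasible trials (a shell
    overfilled) return +inf.
    """
    shell_v = system.grid.shell_volumes
    phi_b = np.zeros(system.grid.n_layers)
    for f, p, sp in zip(fractions, probs, system.species):
        phi_b += system.n_sites * f * (np.asarray(p) @ sp.v_profiles) / shell_v
    phi_w = 1.0 - phi_b
    if (phi_w <= 0).any():
        return np.inf
    bw = float(np.sum((shell_v / system.v_w)
                      * (phi_w * (np.log(phi_w) - 1.0) + 1.0)))
    for f, p, sp in zip(fractions, probs, system.species):
        if f <= 0:
            continue
        p = np.asarray(p)
        pos = p > 0
        s_conf = float(np.sum(p[pos] * np.log(p[pos]))) + np.log(sp.n_att)
        bw += system.n_sites * f * (np.log(f) + sp.beta_mu_eff + s_conf)
    return bw


def brute_force_minimize(system: TinySystem, resolution: int = 16,
                         max_states: int = 1_000_000) -> tuple:
    """Exhaustive grid minimum of beta*W over (f_i, P_i).

    Site fractions and per-species conformer probabilities each live on a
    simplex discretized with ``resolution`` divisions; packing is enforced
    exactly by water elimination.  Returns ``(beta_w_min, argmin)`` where
    ``argmin`` maps labels to (f, P).  Refuses state spaces beyond
    ``max_states`` with a size estimate.
    """
    f_grid = _simplex_grid(len(system.species), resolution)
    p_grids = [_simplex_grid(sp.n_conf, resolution) for sp in system.species]
    n_states = len(f_grid) * int(np.prod([len(g) for g in p_grids]))
    if n_states > max_states:
        raise ValueError(
            f"state space has ~{n_states:.2e} grid points (> {max_states:.0e}); "
            "reduce resolution or system size"
        )

    shell_v = system.grid.shell_volumes
    # per species: bound volume per shell and conformational entropy per P
    w_shell = [g @ sp.v_profiles for g, sp in zip(p_grids, system.species)]
    s_conf = []
    for g, sp in zip(p_grids, system.species):
        with np.errstate(divide="ignore", invalid="ignore"):
            x = np.where(g > 0, g * np.log(np.maximum(g, 1e-300)), 0.0)
        s_conf.append(x.sum(axis=1) + np.log(sp.n_att))

    best = (np.inf, None)
    for f in f_grid:
        # accumulate over the cartesian product of conformer grids
        phi = np.zeros((1, system.grid.n_layers))
        lin = np.zeros(1)
        for fi, w, s, sp in zip(f, w_shell, s_conf, system.species):
            phi = (phi[:, None, :] + system.n_sites * fi
                   * w[None, :, :] / shell_v).reshape(-1, system.grid.n_layers)
            add = (system.n_sites * fi
                   * (np.log(fi) + sp.beta_mu_eff + s)) if fi > 0 else \
                np.zeros(len(s))
            lin = (lin[:, None] + add[None, :]).reshape(-1)
        phi_w = 1.0 - phi
        feasible = (phi_w > 0).all(axis=1)
        if not feasible.any():
            continue
        water = np.full(len(phi), np.inf)
        pw = phi_w[feasible]
        water[feasible] = ((shell_v / system.v_w)
                           * (pw * (np.log(pw) - 1.0) + 1.0)).sum(axis=1)
        total = water + lin
        k = int(np.argmin(total))
        if total[k] < best[0]:
            idx = np.unravel_index(k, [len(g) for g in p_grids])
            argmin = {sp.label: (float(fi), p_grids[i][idx[i]])
                      for i, (sp, fi) in enumerate(zip(system.species, f))}
            best = (float(total[k]), argmin)
    if best[1] is None:
        raise ValueError("no feasible composition on the grid")
    return best


def random_tiny_system(rng: np.random.Generator) -> tuple:
    """A randomized tiny two-species system plus the matched solver inputs.

    Returns ``(system, solver_kwargs)`` where ``solver_kwargs`` feeds
    ``theory_core.solve_self_consistent`` with an equivalent covalent setup
    (g_mode=1, c_a/Kd chosen to reproduce the random binding factor, the
    second ligation switched off).
    """
    from .theory_core import BulkSolution

    n_shells = int(rng.integers(2, 6))
    grid = RadialGrid(r_np=5.0, dr=1.0, n_layers=n_shells)
    n_sites = float(rng.uniform(5.0, 25.0))
    species = []
    m1 = float(np.exp(rng.uniform(-2.0, 2.5)))
    for label, mu in (("A", 0.0), ("Aa", -np.log(m1))):
        n_conf = int(rng.integers(2, 4))
        v = rng.uniform(0.0, 8.0, size=(n_conf, n_shells))
        species.append(TinySpecies(label=label, v_profiles=v, beta_mu_eff=mu))
    system = TinySystem(grid=grid, species=tuple(species), n_sites=n_sites)

    ensembles = {
        sp.label: cl.SpeciesEnsemble(
            species=sp.label, grid=grid, v_profiles=sp.v_profiles,
            com_radii=np.full(sp.n_conf, grid.r_np + 1.0),
            n_attempted=sp.n_conf, n_antigens=(0 if sp.label == "A" else 1),
            molecular_volume=float(sp.v_profiles.sum(axis=1).mean()),
        )
        for sp in species
    }
    bulk = BulkSolution(concentrations={"a": m1}, molecular_volumes={},
                        v_w=system.v_w)
    solver_kwargs = dict(ensembles=ensembles, bulk=bulk, scheme="covalent",
                         n_sites=n_sites, kd=1.0, avidity_ratio=1e12,
                         g_mode=1)
    return system, solver_kwargs


# ---------------------------------------------------------------------------
# Mini sweep configurations
# ---------------------------------------------------------------------------

#: Shared coverage axis (sites/nm^2).  The top sits at ~4x the lateral
#: footprint-jamming coverage of the small toy molecules; beyond that the
#: purely radial mean field stops being a trustworthy description.
_SIGMA_GRID = np.geomspace(0.03, 1.5, 12)


def _sigma_sites(r_np: float) -> np.ndarray:
    return _SIGMA_GRID * 4.0 * np.pi * r_np**2


def make_test_configs() -> dict:
    """Named reduced-sampling sweep configs mirroring the study's panels.

    Each runs in well under two minutes on one CPU; seeds are fixed so runs
    are reproducible.  Two toy geometries are used: the 5-bead-arm antibody
    with the 50-monomer spacer for the spacer-effect and low-concentration
    panels, and a 3-bead-arm antibody with a 10-monomer spacer — which
    reproduces the antigen:molecule volume ratio of the full-size
    antibody-antigen pair — for the panels whose point is the interior
    binding maximum and its response to affinity, radius and conjugation
    scheme.  The toy geometry rescales all absolute coverages, so these
    configs probe shapes and orderings, not the original axis values.
    """
    from .sweep_pipeline import SweepConfig

    big = dict(n_spacer_samples=300, n_orientations=20, arm_length=5,
               seed=11, dr=1.0, r_max_margin=45.0, solver_damping=0.3)
    ratio = dict(n_spacer_samples=800, n_orientations=40, arm_length=1,
                 seed=11, dr=0.5, r_max_margin=30.0, solver_damping=0.3)
    coarse = list(np.geomspace(30, 3e4, 9))
    fine = list(_sigma_sites(50.0))
    configs = {
        # low concentration, high affinity, spacer on/off
        "fig2A-mini": SweepConfig(
            scheme="covalent", r_np=[50.0], spacer_lengths=[50],
            kd=[1e-11], antigen_bulk=[20e-12], n_sites=coarse, **big),
        "fig2B-mini": SweepConfig(
            scheme="covalent", r_np=[50.0], spacer_lengths=[0],
            kd=[1e-11], antigen_bulk=[20e-12], n_sites=coarse, **big),
        # high concentration, no spacer (spacer-gain partner of fig2C-mini)
        "fig2D-mini": SweepConfig(
            scheme="covalent", r_np=[50.0], spacer_lengths=[0],
            kd=[1e-9], antigen_bulk=[100e-9], n_sites=fine, **ratio),
        # high concentration, two affinities: interior maximum and its shift
        "fig2C-mini": SweepConfig(
            scheme="covalent", r_np=[50.0], spacer_lengths=[5],
            kd=[1e-9, 1e-11], antigen_bulk=[100e-9], n_sites=fine, **ratio),
        # radius comparison on matched coverage (sites/nm^2) axes: the
        # maximum washes out on the small, highly curved particle
        "fig5B-R10-mini": SweepConfig(
            scheme="covalent", r_np=[10.0], spacer_lengths=[5],
            kd=[1e-9], antigen_bulk=[100e-9],
            n_sites=list(_sigma_sites(10.0)), **ratio),
        "fig5B-R50-mini": SweepConfig(
            scheme="covalent", r_np=[50.0], spacer_lengths=[5],
            kd=[1e-9], antigen_bulk=[100e-9],
            n_sites=list(_sigma_sites(50.0)), **ratio),
        # streptavidin at high concentration (covalent partner: fig2C-mini)
        "fig6C-mini": SweepConfig(
            scheme="streptavidin", r_np=[50.0], spacer_lengths=[5],
            kd=[1e-9], mixtures=[{"A_total": 100e-9, "a_total": 200e-9}],
            n_sites=fine, **ratio),
        # concentration-independent antibody load plateau
        "fig8A-mini": SweepConfig(
            scheme="streptavidin", r_np=[50.0], spacer_lengths=[5],
            kd=[1e-9],
            mixtures=[{"A_total": 100e-9, "a_total": 200e-9},
                      {"A_total": 400e-9, "a_total": 800e-9}],
            n_sites=fine, **ratio),
    }
    return configs
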