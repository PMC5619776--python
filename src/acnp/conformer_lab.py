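"""Coarse-grained molecular species and surface-tethered conformational ensembles.

A molecule (spacer + antibody, optionally carrying one or two antigens) is
represented as a set of equal-size beads.  Residue-level models place one
0.6 nm bead at each alpha carbon; PEG-like spacers place one 0.6 nm bead per
ethylene-glycol monomer.  Spacer conformations are drawn from a rotational
isomeric state (RIS) chain with hard-sphere self-avoidance; the antibody is a
rigid body with full rotational freedom about its tether point.  Every
accepted conformation of a grafted species is reduced to a per-shell occupied
volume on a radial grid around the spherical nanoparticle; those profiles are
the only conformational information the mean-field theory needs.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

import numpy as np

from .theory_core import RadialGrid

#: Default bead diameter (nm) for both residue beads and spacer monomer beads.
BEAD_DIAMETER = 0.6

#: Default distance (nm) between successive spacer bead centers (tangent beads).
BOND_LENGTH = 0.6

#: Tetrahedral backbone bond angle (degrees) used by the RIS chain generator.
BOND_ANGLE_DEG = 109.47

#: Dihedral angles (degrees) of the three rotational isomeric states.
RIS_DIHEDRALS_DEG = (180.0, 60.0, -60.0)


class PDBFormatError(ValueError):
    """The PDB text could not be parsed or contains no usable CA atoms."""


class SamplingError(RuntimeError):
    """Conformer sampling failed (e.g. self-avoidance rejection runaway)."""


class GridExtentError(ValueError):
    """A bead center fell beyond the outer edge of the radial grid."""


def bead_volume(diameter: float) -> float:
    """Volume (nm^3) of a single bead of the given diameter."""
    return (np.pi / 6.0) * diameter**3


# ---------------------------------------------------------------------------
# Bead models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BeadModel:
    """Rigid bead representation of one molecule.

    Parameters
    ----------
    positions : (n, 3) array
        Bead centers in nm, in the molecule's body frame.
    bead_diameter : float
        Diameter of every bead (nm).
    anchor_index : int
        Index of the bead bonded to the spacer / surface.
    label : str
        Species tag.
    binding_site_indices : tuple of int
        Bead indices acting as antigen binding sites (Fab tips).
    metadata : dict
        Free-form provenance (e.g. skipped-residue tally for PDB input).
    """

    positions: np.ndarray
    bead_diameter: float = BEAD_DIAMETER
    anchor_index: int = 0
    label: str = ""
    binding_site_indices: tuple = ()
    binding_site_directions: tuple = ()   # outward unit vectors, one per site
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        pos = np.asarray(self.positions, dtype=float)
        if pos.ndim != 2 or pos.shape[1] != 3 or pos.shape[0] == 0:
            raise ValueError("positions must be a non-empty (n, 3) array")
        object.__setattr__(self, "positions", pos)
        if self.bead_diameter <= 0:
            raise ValueError("bead_diameter must be positive")
        if not (0 <= self.anchor_index < len(pos)):
            raise ValueError("anchor_index out of range")
        for i in self.binding_site_indices:
            if not (0 <= i < len(pos)):
                raise ValueError("binding site index out of range")

    @property
    def n_beads(self) -> int:
        return self.positions.shape[0]

    @property
    def total_volume(self) -> float:
        """Total bead volume (nm^3)."""
        return self.n_beads * bead_volume(self.bead_diameter)


@dataclass(frozen=True)
class Conformation:
    """One molecular state in the nanoparticle frame (origin = NP center)."""

    positions: np.ndarray
    species: str
    spacer_beads: int
    com_radius: float
    bead_diameter: float = BEAD_DIAMETER


@dataclass(frozen=True)
class ShellVolumeProfile:
    """Per-shell occupied volume (nm^3) of one conformation."""

    grid: RadialGrid
    v: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.v, dtype=float)
        if v.shape != (self.grid.n_layers,):
            raise ValueError("profile length must equal grid.n_layers")
        object.__setattr__(self, "v", v)

    @property
    def total_volume(self) -> float:
        return float(self.v.sum())


@dataclass(frozen=True)
class SpeciesEnsemble:
    """Conformational ensemble of one grafted (or solution) species.

    ``v_profiles[k]`` holds the per-shell occupied volume of accepted
    conformation ``k``; ``n_attempted`` counts all generated spacer x
    orientation combinations, so the field-free partition function
    ``q = n_accepted / n_attempted`` carries the purely geometric
    (nanoparticle-overlap) accessibility of the species.
    """

    species: str
    grid: RadialGrid
    v_profiles: np.ndarray        # (n_accepted, n_layers)
    com_radii: np.ndarray         # (n_accepted,)
    n_attempted: int
    n_antigens: int
    molecular_volume: float       # nm^3

    def __post_init__(self):
        v = np.asarray(self.v_profiles, dtype=float)
        c = np.asarray(self.com_radii, dtype=float)
        if v.ndim != 2 or v.shape[1] != self.grid.n_layers:
            raise ValueError("v_profiles must be (n_accepted, n_layers)")
        if v.shape[0] == 0:
            raise ValueError("ensemble has no accepted conformations")
        if c.shape != (v.shape[0],):
            raise ValueError("com_radii length mismatch")
        if self.n_attempted < v.shape[0]:
            raise ValueError("n_attempted < number of accepted conformations")
        if self.n_antigens not in (0, 1, 2):
            raise ValueError("n_antigens must be 0, 1 or 2")
        object.__setattr__(self, "v_profiles", v)
        object.__setattr__(self, "com_radii", c)

    @property
    def n_conformations(self) -> int:
        return self.v_profiles.shape[0]

    @property
    def acceptance_fraction(self) -> float:
        return self.n_conformations / self.n_attempted


def point_species_ensemble(species: str, grid: RadialGrid) -> SpeciesEnsemble:
    """Ensemble of a volumeless point site (streptavidin): one empty profile."""
    return SpeciesEnsemble(
        species=species,
        grid=grid,
        v_profiles=np.zeros((1, grid.n_layers)),
        com_radii=np.array([grid.r_np]),
        n_attempted=1,
        n_antigens=0,
        molecular_volume=0.0,
    )


# ---------------------------------------------------------------------------
# PDB input
# ---------------------------------------------------------------------------

def read_alpha_carbon_beads(pdb_text: str, chain_selection) -> BeadModel:
    """One bead per residue at the alpha-carbon position.

    Coordinates are converted from Angstrom to nm; every bead gets the default
    0.6 nm diameter.  Residues without a CA atom are skipped; their count is
    recorded in ``metadata['skipped_residues']`` and reported as a warning.

    Parameters
    ----------
    pdb_text : str
        Contents of a PDB file (ATOM records).
    chain_selection : iterable of str
        Chain identifiers to keep.
    """
    from Bio.PDB import PDBParser

    chains = set(chain_selection)
    parser = PDBParser(QUIET=True)
    try:
        structure = parser.get_structure("m", io.StringIO(pdb_text))
    except Exception as exc:  # Bio.PDB raises various types on bad input
        raise PDBFormatError(f"could not parse PDB text: {exc}") from exc

    coords = []
    skipped = 0
    matched_chain = False
    for model in structure:
        for chain in model:
            if chain.id not in chains:
                continue
            matched_chain = True
            for residue in chain:
                if residue.id[0] != " ":  # skip heteroatoms / waters
                    continue
                if "CA" in residue:
                    coords.append(residue["CA"].coord / 10.0)  # A -> nm
                else:
                    skipped += 1
        break  # first model only

    if not coords:
        if not matched_chain or skipped == 0:
            raise PDBFormatError(
                f"no residues selected: chains {sorted(chains)} contain no CA atoms"
            )
        raise PDBFormatError("no CA atoms found in the selected chains")
    if skipped:
        warnings.warn(f"{skipped} residue(s) without a CA atom were skipped")
    return BeadModel(
        positions=np.asarray(coords, dtype=float),
        bead_diameter=BEAD_DIAMETER,
        anchor_index=0,
        label="+".join(sorted(chains)),
        metadata={"skipped_residues": skipped},
    )


# ---------------------------------------------------------------------------
# Toy antibody (download-free stand-in for a real IgG structure)
# ---------------------------------------------------------------------------

def make_toy_antibody(arm_length: int, seed: int = 0,
                      arm_angle_deg: float = 50.0) -> BeadModel:
    """Deterministic Y-shaped rigid bead model.

    Three straight arms of ``arm_length`` beads each at 0.6 nm spacing: one
    stem (anchored at its base, mimicking Fc-end grafting) and two upper arms
    whose terminal beads act as Fab-tip binding sites.  ``seed`` is accepted
    for API symmetry with the samplers but the construction is deterministic.
    """
    if arm_length < 1:
        raise ValueError("arm_length must be >= 1")
    del seed  # deterministic construction
    l = BOND_LENGTH
    theta = np.deg2rad(arm_angle_deg)
    stem = np.column_stack([
        np.zeros(arm_length), np.zeros(arm_length),
        l * np.arange(arm_length),
    ])
    top = stem[-1]
    beads = [stem]
    tips, tip_dirs = [], []
    for sgn in (+1, -1):
        u = np.array([sgn * np.sin(theta), 0.0, np.cos(theta)])
        arm = top + l * np.outer(np.arange(1, arm_length + 1), u)
        beads.append(arm)
        tips.append(sum(len(b) for b in beads) - 1)
        tip_dirs.append(tuple(u))
    return BeadModel(
        positions=np.vstack(beads),
        bead_diameter=BEAD_DIAMETER,
        anchor_index=0,
        label="toy-antibody",
        binding_site_indices=tuple(tips),
        binding_site_directions=tuple(tip_dirs),
    )


# ---------------------------------------------------------------------------
# RIS spacer generation
# ---------------------------------------------------------------------------

def _ris_step(b_prev, b_prev2, cos_t, sin_t, phi):
    """Next bond direction from the previous two bonds and a dihedral angle.

    Natural-extension frame: the new bond makes the backbone bond angle with
    ``b_prev`` and dihedral ``phi`` about it, measured from the plane spanned
    by ``b_prev2`` and ``b_prev``.  All inputs may be batched (m, 3).
    """
    n = np.cross(b_prev2, b_prev)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, b_prev)
    d = (-cos_t * b_prev
         + sin_t * (np.cos(phi)[..., None] * m + np.sin(phi)[..., None] * n))
    return d


def generate_spacer_conformations(
    n_monomers: int,
    n_samples: int,
    seed: int,
    *,
    bond_length: float = BOND_LENGTH,
    bead_diameter: float = BEAD_DIAMETER,
    bond_angle_deg: float = BOND_ANGLE_DEG,
    dihedral_states_deg: tuple = RIS_DIHEDRALS_DEG,
    state_weights=None,
    self_avoid: bool = True,
    max_attempt_factor: int = 2000,
) -> np.ndarray:
    """Sample grafted spacer chains with a rotational isomeric state model.

    Chains start at the grafting point (the origin), with the first bond along
    +z (the outward surface normal).  Successive bonds keep a fixed backbone
    bond angle; dihedrals are drawn from the trans/gauche+- states with the
    given statistical weights (equal by default).  Self-intersecting chains
    (any non-bonded bead pair closer than one bead diameter) are rejected and
    regenerated.  Disabling ``self_avoid`` yields the ideal RIS chain, used
    only for statistical validation.

    Returns an array of shape ``(n_samples, n_monomers, 3)`` of bead centers
    in nm.  ``n_monomers = 0`` returns the single empty chain ``(1, 0, 3)``.
    """
    if n_monomers < 0:
        raise ValueError("n_monomers must be >= 0")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_monomers == 0:
        return np.zeros((1, 0, 3))

    rng = np.random.default_rng(seed)
    if state_weights is None:
        w = np.full(len(dihedral_states_deg), 1.0 / len(dihedral_states_deg))
    else:
        w = np.asarray(state_weights, dtype=float)
        w = w / w.sum()
    phis = np.deg2rad(np.asarray(dihedral_states_deg, dtype=float))
    theta = np.deg2rad(bond_angle_deg)
    # backbone bond angle theta at each bead; successive bond vectors make
    # the supplementary angle, i.e. b_k . b_{k+1} = -cos(theta)
    cos_t, sin_t = np.cos(theta), np.sin(theta)
    cutoff2 = (bead_diameter * (1.0 - 1e-9)) ** 2

    chains = []
    attempts = 0
    max_attempts = max_attempt_factor * n_samples
    while sum(c.shape[0] for c in chains) < n_samples:
        need = n_samples - sum(c.shape[0] for c in chains)
        batch = max(2 * need, 64)
        if attempts + batch > max_attempts:
            batch = max_attempts - attempts
            if batch <= 0:
                acc = sum(c.shape[0] for c in chains) / max(attempts, 1)
                raise SamplingError(
                    f"self-avoidance rejection runaway: acceptance {acc:.2e} "
                    f"after {attempts} attempts (n_monomers={n_monomers}, "
                    f"bond_angle={bond_angle_deg})"
                )
        attempts += batch

        pos = np.zeros((batch, n_monomers, 3))
        alive = np.ones(batch, dtype=bool)
        pos[:, 0, 2] = bond_length
        if n_monomers >= 2:
            # second bead: fixed bond angle, uniform azimuth
            psi = rng.uniform(0.0, 2 * np.pi, size=batch)
            d = np.column_stack([
                sin_t * np.cos(psi), sin_t * np.sin(psi),
                np.full(batch, -cos_t),
            ])
            pos[:, 1] = pos[:, 0] + bond_length * d
            b_prev2 = np.tile(np.array([0.0, 0.0, 1.0]), (batch, 1))
            b_prev = d
            if self_avoid:  # bead 1 is bonded to bead 0: nothing to check yet
                pass
            states = rng.choice(len(phis), size=(batch, n_monomers), p=w)
            for k in range(2, n_monomers):
                d = _ris_step(b_prev, b_prev2, cos_t, sin_t, phis[states[:, k]])
                pos[:, k] = pos[:, k - 1] + bond_length * d
                if self_avoid:
                    # check new bead against all non-bonded predecessors
                    diff = pos[:, k, None, :] - pos[:, : k - 1, :]
                    d2 = np.einsum("ijk,ijk->ij", diff, diff)
                    alive &= ~(d2 < cutoff2).any(axis=1)
                b_prev2, b_prev = b_prev, d
        chains.append(pos[alive][: n_samples])

    out = np.concatenate(chains, axis=0)[:n_samples]
    return out


# ---------------------------------------------------------------------------
# Rigid-body assembly of grafted species
# ---------------------------------------------------------------------------

def _random_rotation_matrices(rng: np.random.Generator, count: int) -> np.ndarray:
    """Uniform random rotations via normalized quaternions, shape (count,3,3)."""
    q = rng.standard_normal((count, 4))
    q /= np.linalg.norm(q, axis=1, keepdims=True)
    w, x, y, z = q.T
    return np.stack([
        np.stack([1 - 2 * (y**2 + z**2), 2 * (x * y - z * w), 2 * (x * z + y * w)], -1),
        np.stack([2 * (x * y + z * w), 1 - 2 * (x**2 + z**2), 2 * (y * z - x * w)], -1),
        np.stack([2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x**2 + y**2)], -1),
    ], axis=1)


def antigen_body_coords(antibody: BeadModel, antigen: BeadModel,
                        site: int) -> np.ndarray:
    """Antigen bead coordinates in the antibody body frame for one bound pose.

    The toy pose extends the Fab arm in a straight line: the antigen's anchor
    bead is placed one bond length beyond the tip along the arm direction and
    the cluster is carried rigidly.  For crystallographic complexes the bound
    pose comes directly from the complex coordinates instead.
    """
    tip_idx = antibody.binding_site_indices[site]
    tip = antibody.positions[tip_idx]
    if antibody.binding_site_directions:
        u = np.asarray(antibody.binding_site_directions[site], dtype=float)
    else:
        # arm direction: from the bead preceding the tip (falls back to anchor)
        prev = antibody.positions[tip_idx - 1] if tip_idx > 0 else \
            antibody.positions[antibody.anchor_index]
        u = tip - prev
    norm = np.linalg.norm(u)
    u = u / norm if norm > 0 else np.array([0.0, 0.0, 1.0])
    shift = tip + BOND_LENGTH * u - antigen.positions[antigen.anchor_index]
    return antigen.positions + shift


def assemble_species_conformations(
    spacers: np.ndarray,
    antibody: BeadModel,
    antigen: BeadModel | None,
    n_antigens: int,
    n_orientations: int,
    grid: RadialGrid,
    seed: int,
    *,
    species: str | None = None,
    bond_length: float = BOND_LENGTH,
) -> SpeciesEnsemble:
    """Tether the rigid antibody (+ bound antigens) to each spacer conformation.

    The antibody anchor bead continues the spacer chain: it sits one bond
    length beyond the spacer free end along the last spacer bond (along the
    outward surface normal when there is no spacer), and the rigid body
    rotates freely about that tether point; ``n_antigens`` antigen copies
    ride rigidly in their bound poses.  Conformations with any bead center
    inside the nanoparticle (|pos| < R_NP + bead radius) are rejected.
    Accepted conformations are binned to per-shell volume profiles.
    """
    if n_antigens < 0 or n_antigens > len(antibody.binding_site_indices):
        raise ValueError(
            f"n_antigens={n_antigens} exceeds the antibody's "
            f"{len(antibody.binding_site_indices)} binding sites"
        )
    if n_antigens > 0 and antigen is None:
        raise ValueError("antigen model required when n_antigens > 0")
    if species is None:
        species = {0: "A", 1: "Aa", 2: "Aaa"}[n_antigens]

    rng = np.random.default_rng(seed)
    rots = _random_rotation_matrices(rng, n_orientations)

    # body-frame bead stack: antibody (anchor at origin) + bound antigens
    body = [antibody.positions - antibody.positions[antibody.anchor_index]]
    vol_parts = [np.full(antibody.n_beads, bead_volume(antibody.bead_diameter))]
    for s in range(n_antigens):
        g = antigen_body_coords(antibody, antigen, s)
        body.append(g - antibody.positions[antibody.anchor_index])
        vol_parts.append(np.full(antigen.n_beads, bead_volume(antigen.bead_diameter)))
    body = np.vstack(body)
    body_volumes = np.concatenate(vol_parts)

    graft = np.array([0.0, 0.0, grid.r_np])
    r_bead_body = antibody.bead_diameter / 2.0
    r_bead_spacer = BEAD_DIAMETER / 2.0
    spacer_volume = bead_volume(BEAD_DIAMETER)
    r_min_body = grid.r_np + r_bead_body
    r_min_spacer = grid.r_np + r_bead_spacer

    n_spacers = spacers.shape[0]
    n_spacer_beads = spacers.shape[1]
    profiles, com_radii = [], []
    n_attempted = n_spacers * n_orientations

    rotated_bodies = np.einsum("oij,bj->obi", rots, body)  # (O, nb, 3)
    z_hat = np.array([0.0, 0.0, 1.0])
    for s in range(n_spacers):
        chain = spacers[s] + graft  # (n_spacer_beads, 3)
        if n_spacer_beads and (np.linalg.norm(chain, axis=1) < r_min_spacer).any():
            continue  # whole spacer clashes with the NP for every orientation
        # tether point: one bond beyond the chain end along its last bond
        if n_spacer_beads == 0:
            anchor = graft + bond_length * z_hat
        elif n_spacer_beads == 1:
            u = spacers[s][0] / np.linalg.norm(spacers[s][0])
            anchor = chain[-1] + bond_length * u
        else:
            u = chain[-1] - chain[-2]
            anchor = chain[-1] + bond_length * u / np.linalg.norm(u)
        cand = rotated_bodies + anchor  # (O, nb, 3)
        radii = np.linalg.norm(cand, axis=2)  # (O, nb)
        ok = (radii >= r_min_body).all(axis=1)
        for o in np.nonzero(ok)[0]:
            pos = np.vstack([chain, cand[o]]) if n_spacer_beads else cand[o]
            r = np.concatenate([np.linalg.norm(chain, axis=1), radii[o]]) \
                if n_spacer_beads else radii[o]
            vols = np.concatenate([np.full(n_spacer_beads, spacer_volume),
                                   body_volumes]) if n_spacer_beads else body_volumes
            idx = grid.shell_index(r)
            if (idx >= grid.n_layers).any():
                raise GridExtentError(
                    f"bead center at r={r.max():.2f} nm beyond R_max="
                    f"{grid.r_max:.2f} nm; enlarge the grid"
                )
            v = np.bincount(idx, weights=vols, minlength=grid.n_layers)
            profiles.append(v)
            com_radii.append(float(np.linalg.norm(pos.mean(axis=0))))

    if not profiles:
        raise SamplingError(
            f"no accepted conformations for species {species!r}: geometry too "
            f"restrictive (R_NP={grid.r_np} nm, spacer={n_spacer_beads} beads)"
        )
    mol_volume = (n_spacer_beads * spacer_volume
                  + antibody.total_volume
                  + (n_antigens * antigen.total_volume if antigen is not None else 0.0))
    return SpeciesEnsemble(
        species=species,
        grid=grid,
        v_profiles=np.asarray(profiles),
        com_radii=np.asarray(com_radii),
        n_attempted=n_attempted,
        n_antigens=n_antigens,
        molecular_volume=mol_volume,
    )


# ---------------------------------------------------------------------------
# Shell binning and conformational observables
# ---------------------------------------------------------------------------

def _sphere_overlap_volume(d, a, r):
    """Volume of a sphere of radius ``a`` centered at distance ``d`` from the
    origin that lies inside the origin-centered sphere of radius ``r``."""
    d = np.asarray(d, dtype=float)
    full = (4.0 / 3.0) * np.pi * a**3
    out = np.zeros_like(d)
    inside = r >= d + a
    out[inside] = full
    lens = (~inside) & (d < r + a) & (d + r > a)
    dd = d[lens]
    out[lens] = (np.pi * (a + r - dd) ** 2
                 * (dd**2 + 2 * dd * r - 3 * r**2 + 2 * dd * a
                    + 6 * a * r - 3 * a**2) / (12 * dd))
    engulfed = (d + r <= a)  # grid sphere entirely inside the bead
    out[engulfed] = (4.0 / 3.0) * np.pi * r**3
    return out


def bin_volume_to_shells(conformation: Conformation, grid: RadialGrid,
                         mode: str = "center") -> ShellVolumeProfile:
    """Assign each bead's volume to radial shells.

    ``mode="center"`` (default) puts the whole bead volume in the shell that
    contains its center — exact volume conservation by construction, and an
    adequate dialect whenever dr is not small against the bead diameter.
    ``mode="exact"`` splits each bead over shells by analytic sphere-shell
    overlap, for discretization-convergence checks.
    """
    pos = np.asarray(conformation.positions, dtype=float)
    r = np.linalg.norm(pos, axis=1)
    v0 = bead_volume(conformation.bead_diameter)
    if mode == "center":
        idx = grid.shell_index(r)
        if (idx >= grid.n_layers).any() or (idx < 0).any():
            raise GridExtentError(
                f"bead center at r={r.max():.3f} nm outside the grid "
                f"[{grid.r_np}, {grid.r_max}] nm; enlarge R_max"
            )
        v = np.bincount(idx, weights=np.full(len(r), v0), minlength=grid.n_layers)
    elif mode == "exact":
        a = conformation.bead_diameter / 2.0
        if (r + a > grid.r_max).any():
            raise GridExtentError("bead extends beyond R_max; enlarge the grid")
        edges = grid.edges
        cum = np.stack([_sphere_overlap_volume(r, a, e) for e in edges])  # (n+1, nb)
        v = (cum[1:] - cum[:-1]).sum(axis=1)
    else:
        raise ValueError(f"unknown binning mode {mode!r}")
    return ShellVolumeProfile(grid=grid, v=v)


def center_of_mass_radius(conformation: Conformation) -> float:
    """Distance of the unweighted bead centroid from the NP center (nm)."""
    pos = np.asarray(conformation.positions, dtype=float)
    if pos.shape[0] == 0:
        raise ValueError("conformation has no beads")
    return float(np.linalg.norm(pos.mean(axis=0)))


# ---------------------------------------------------------------------------
# Ensemble cache I/O
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: SpeciesEnsemble, path) -> None:
    """Write an NPZ cache plus a JSON provenance sidecar (path + '.json')."""
    import json
    from pathlib import Path

    path = Path(path)
    np.savez_compressed(
        path,
        v_profiles=ensemble.v_profiles,
        com_radii=ensemble.com_radii,
        grid=np.array([ensemble.grid.r_np, ensemble.grid.dr, ensemble.grid.n_layers]),
    )
    sidecar = {
        "species": ensemble.species,
        "n_antigens": ensemble.n_antigens,
        "n_attempted": ensemble.n_attempted,
        "n_accepted": ensemble.n_conformations,
        "acceptance_fraction": ensemble.acceptance_fraction,
        "molecular_volume_nm3": ensemble.molecular_volume,
    }
    with open(str(path) + ".json", "w") as fh:
        json.dump(sidecar, fh, indent=2)


def load_ensemble(path) -> SpeciesEnsemble:
    import json

    data = np.load(str(path))
    with open(str(path) + ".json") as fh:
        meta = json.load(fh)
    r_np, dr, n_layers = data["grid"]
    grid = RadialGrid(r_np=float(r_np), dr=float(dr), n_layers=int(n_layers))
    return SpeciesEnsemble(
        species=meta["species"],
        grid=grid,
        v_profiles=data["v_profiles"],
        com_radii=data["com_radii"],
        n_attempted=meta["n_attempted"],
        n_antigens=meta["n_antigens"],
        molecular_volume=meta["molecular_volume_nm3"],
    )
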