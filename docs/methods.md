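# Methods

## Model

The system is a single spherical nanoparticle of radius `R_NP` in an
aqueous bath held at fixed composition (fixed chemical potentials), with
`N_s` tether sites on its surface.  Space around the particle is discretized
into concentric shells of thickness `dr`; all structure is resolved radially
only, which is the natural mean-field description for an isolated sphere.

Six species are tracked.  Surface-bound: unbound antibody `A`, one-antigen
complex `Aa`, two-antigen complex `Aaa`, and (in the streptavidin scheme)
empty streptavidin sites `S`, treated as point sites with zero volume.  In
solution: free antigen `a` and, for the streptavidin scheme, the
biotinylated species `A`, `Aa`, `Aaa`; plus water `w` with molecular volume
`v_w`.

Every molecule is a set of 0.6 nm beads — one per amino acid (placed at the
alpha carbon for PDB input) and one per ethylene-glycol monomer of the
spacer.  A grafted species is built by (i) sampling spacer conformations
from a three-state rotational isomeric state chain (trans/gauche±,
tetrahedral backbone angle, 0.6 nm bonds, hard-sphere self-avoidance at one
bead diameter), (ii) attaching the rigid antibody one bond beyond the chain
end, continuing the last bond direction, with a uniformly random rigid
rotation about that tether point, and (iii) attaching 0–2 rigid antigen
copies in their bound pose at the Fab tips.  Conformations with any bead
inside the particle are rejected; the rejected fraction is part of the
statistics (it enters the partition functions as zero-weight states, i.e.
the geometric accessibility of the species).  Each accepted conformation is
reduced to its per-shell occupied volume `v_i(α; r)`; by default the whole
bead volume is assigned to the shell containing the bead center (exact
volume conservation by construction; an analytic sphere–shell overlap mode
exists for discretization checks).

## Free energy and its minimization

The free energy combines the translational entropy of water, the
translational entropy and self-energy of the solution species, the
conformational entropy of the bound species, and the mixing entropy and
self-energy (binding free energy) of the bound layer.  Attractions enter
only through dissociation constants; the standard-state conversion is
`βΔμ° = ln(Kd / 1 M)`, under which the dilute mass-action ratio
`f_bound/f_free = c/Kd` is exact.  Excluded volume enters through local
incompressibility: in every shell the species volume fractions plus water
must sum to one.

Minimizing under that constraint (Lagrange multiplier field `βπ(r)`, the
local osmotic pressure) gives closed-form expressions for every unknown in
terms of the field — Boltzmann conformer weights `exp(−Σ_r βπ(r) v(α; r))`,
solution profiles `ρ_j(r) = ρ_j^bulk exp(−βπ(r) v_j)`, water
`φ_w(r) = φ_w^bulk exp(−βπ(r) v_w)`, and mass-action site fractions
reweighted by the conformational partition functions `q_i`.  The field
itself is fixed by solving the packing constraint in every shell
simultaneously.

Two ligation conventions are supported for the two equivalent Fab sites
with intrinsic constants `Kd` and `Kd × avidity_ratio`: site enumeration
(`g_mode=2`; first ligation carries the degeneracy factor 2, the second the
pairing factor 1/2) and sequential macroscopic constants (`g_mode=1`).  One
shared implementation serves both the surface equilibrium and the bulk
mixture solver, so the two ends of the streptavidin scheme are always
thermodynamically consistent.  The default `avidity_ratio = 100` encodes a
much weaker second ligation, consistent with the rarity of the two-antigen
complex; it is a config parameter and should be fit to experiment when one
is available.

The reported free energy is the constant-chemical-potential (semi-grand)
potential relative to the uniform bulk: the chemical-potential terms that
hold the bath fixed are folded into each contribution.  This is the
quantity the constrained minimization actually minimizes — it is what the
exhaustive tiny-system oracle minimizes too, and any feasible perturbation
of a converged state raises it.  Water is eliminated through the packing
constraint when evaluating trial states, so perturbed compositions remain
physically meaningful.

The bulk water packing fraction is `1 − Σ_j ρ_j^bulk v_j` rather than
exactly 1, so the packing residual vanishes identically far from the
particle even with solutes present (the correction is ~1e-5 at the
concentrations of interest).

## Solver

Unknown: the field vector `βπ(r)` (zero-initialized, or warm-started from
the previous coverage point during sweeps).  Strategy, in order:

1. Newton solve of the per-shell packing system — a dense-Jacobian Powell
   hybrid for grids up to 400 shells (the systems here are 40–120 shells,
   where a dense Jacobian is cheap and far more robust than Krylov
   iterations), Jacobian-free Newton–Krylov above that.
2. If Newton stalls, a damped fixed-point sweep (each shell's field moved
   toward the value that locally restores packing, with an adaptive step
   that halves on residual growth) re-centers the field, then Newton
   retries.
3. If the point still fails, a homotopy ladder climbs the coverage from
   10% of `N_s` in stages, warm-starting each stage.

Convergence is declared at a max-norm packing residual ≤ 1e-8; fraction and
probability normalizations hold to 1e-12 by construction (log-sum-exp
softmax).  All partition-function work is done in log space, so fields
strong enough to suppress a species by hundreds of k_BT cause no underflow.
Near the finite-ensemble jamming coverage the packing system becomes
genuinely infeasible (no field can satisfy packing with the sampled
conformations); such points raise a convergence error carrying the residual
history, and sweep drivers record them as failed points rather than
guessing.

The bulk mixture equilibrium (streptavidin scheme pre-step) reduces to one
monotone scalar equation in the free-antigen concentration, solved by
bracketed Brent iteration to machine precision; both mass balances close to
better than 1e-10 relative across pM–µM compositions.

## Grid and sampling defaults

`dr = 0.5 nm` (never below the bead diameter for the center-assignment
dialect to stay adequate), `R_max = R_NP + 100 nm` for production runs —
far enough that `βπ(R_max) = 0` to solver tolerance; doubling the margin
changes captured antigen by well under 0.1% (shipped as a test).  Test and
acceptance runs use a 30–45 nm margin matched to their shorter molecules.
Production-scale conformer sampling is configurable; the shipped study
configs use 300–800 spacer samples × 20–40 orientations per species
(6 000–32 000 attempted conformations), which keeps every reported trend
stable under reseeding.

## The toy world, and what it can and cannot show

Real antibody work requires user-supplied structures (the package
coarse-grains any PDB chain selection); tests and examples instead use a
deterministic toy world: a Y-shaped antibody of three straight bead arms
anchored at the stem base with two Fab-tip binding sites, and a 7-bead
octahedral antigen cluster.

The toy world reproduces, and the test suite asserts, the phenomenology of
crowded AcNP surfaces: the interior capture maximum at high antigen
concentration and its shift to higher coverage with stronger affinity; the
monotone-to-plateau behavior without a spacer and the capture gain with
one; the washing-out of the maximum on small, highly curved particles and
the higher per-area efficiency of those particles; the crowding-driven
disappearance of the two-antigen complex at finite coverage; the outward
stretch of antigen-laden antibodies (largest mean center-of-mass radius);
and, for the streptavidin scheme, the self-regulated antibody load that
plateaus with site count independently of bulk concentration, captures less
than the covalent scheme at matched conditions, and barely exceeds one
antigen per bound antibody.

Quantitative axis values do **not** transfer to full-size systems.  A real
antibody is ~1300 residues (~150 nm³ with its antigen); the toy molecules
are 20–100× smaller, so every absolute coverage in the toy world is shifted
by roughly that volume ratio — maxima appear near 0.7–1.0 molecules/nm²
instead of the ~0.002–0.003 antibodies/nm² expected for IgG-scale ligands.
What is matched is the dimensionless competition that produces the
maximum: the antigen:molecule volume ratio.  The interior-maximum panels
use a 1-bead-arm antibody with a 5-monomer spacer, making the 7-bead
antigen ~40–90% of the molecule — the regime of a gp120-class antigen on a
Fab arm — so that capturing an antigen substantially raises the complex's
insertion cost and crowding can overcome the mass-action gain.  With a
small antigen on a large spacered antibody the bound antigen simply pokes
out of the crowded layer and capture is monotone; that regime is real, but
it is not the one the interior maximum lives in.

Two further limits of the reduced description are worth knowing.  First,
coverage axes stop at σ = 1.5 sites/nm², about four times the lateral
footprint-jamming coverage of the toy molecules: beyond that, a purely
radial mean field (which ignores lateral packing correlations) stops being
trustworthy, and with finite conformer samples a spurious capture re-rise
can appear as the field concentrates probability on a handful of stretched
conformations.  Second, near that limit results should be checked against
the effective number of contributing conformations before being believed.

## Numerical and degenerate-input choices

- RIS statistical weights default to equal trans/gauche± (configurable);
  with equal weights the dihedral averages vanish and the ideal chain has
  exactly freely-rotating-chain statistics — the shipped oracle exploits
  this with both a closed form and an independent Monte-Carlo sampler.
- Self-avoidance is a hard-sphere check within the spacer only; the
  antibody is rigid and never self-checked, and spacer–antibody crossings
  are not excluded (a deliberate simplification; the dominant excluded
  volume is molecule–molecule, which the field handles).
- Zero concentrations contribute zero terms (no log-of-zero anywhere);
  `c = 0` mixtures and `N_s = 0` surfaces are exact no-ops.
- Maxima on binding curves are located by parabolic interpolation through
  the three points bracketing the discrete argmax, ties resolved to the
  lowest coverage; endpoint maxima are flagged as boundary rather than
  interpolated.
- Determinism: all randomness flows from user seeds through
  `numpy.random.default_rng`; identical configs and seeds give
  byte-identical sweep outputs.
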