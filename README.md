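# acnp — molecular theory of antigen capture by antibody-conjugated nanoparticles

Antibody-conjugated nanoparticles (AcNPs) capture antigen from solution for
sensing, imaging and targeted-therapy applications.  Because antibodies are
large, flexible-tethered ligands, the amount of captured antigen is **not**
monotone in the number of antibodies grafted to the particle: capture rises,
peaks at a surprisingly low surface coverage, and then stalls or falls as
excluded-volume crowding makes every additional binding event entropically
expensive.  `acnp` implements a self-consistent molecular (mean-field)
theory that predicts this behavior from molecular structure alone, for both
covalently grafted antibodies and antibodies anchored through
streptavidin–biotin bonds.

The package is for computational biophysicists and assay designers who want
to explore how surface coverage, bulk concentration, affinity, avidity,
spacer length and particle radius shape the binding capacity of an AcNP.

## The model

A spherical nanoparticle of radius `R_NP` carries `N_s` tether sites.  Each
molecular species — unbound antibody `A`, one-antigen complex `Aa`,
two-antigen complex `Aaa`, streptavidin `S`, free antigen `a`, and water
`w` — is coarse-grained to beads of diameter 0.6 nm (one bead per residue or
per ethylene-glycol monomer).  Spacer conformations come from a rotational
isomeric state (RIS) chain with hard-sphere self-avoidance; the antibody is
a rigid body with full rotational freedom about its tether point.

The Helmholtz free energy per k_BT contains four contributions:

```
βF = Σ_r (V_r) ρ_w(r) [ln ρ_w(r) v_w − 1]                      (water)
   + Σ_j Σ_r V_r ρ_j(r) [ln ρ_j(r) v_w − 1 + βμ°_j]            (solution species)
   + N_s Σ_i f_i Σ_α P_i(α) ln P_i(α)                          (bound conformations)
   + N_s Σ_i f_i [ln f_i + βμ°_i]                              (bound mixing + binding)
```

subject to **local incompressibility**: in every radial shell the volume
fractions of all species plus water sum to one.  There are no explicit
attractive interactions — all attractions are folded into dissociation
constants `Kd` (antibody–antigen, with an avidity-scaled second ligation)
and `Kd_biotin` (streptavidin–biotin); repulsion is pure excluded volume.
Minimizing under the constraint yields a single interaction field, the
local osmotic pressure `βπ(r)`, through which everything couples:

```
P_i(α) ∝ exp(−Σ_r βπ(r) v_i(α; r))      conformer probabilities
ρ_j(r) = ρ_j^bulk exp(−βπ(r) v_j)       solution densities
f_i    : mass action reweighted by q_i  site fractions
```

The solver finds `βπ(r)` by a damped fixed-point sweep plus a dense-Jacobian
Newton polish, to a packing residual below 1e-8 in every shell.

## Worked example

Capture as a function of coverage for the built-in toy antibody (1-bead-arm
Y model, 5-monomer spacer, 7-bead antigen) on a 50 nm particle at 100 nM
antigen and Kd = 1 nM:

```python
import numpy as np
from acnp import (BulkSolution, RadialGrid, assemble_species_conformations,
                  generate_spacer_conformations, make_toy_antibody,
                  make_toy_antigen, solve_self_consistent)

antibody = make_toy_antibody(1)
antigen = make_toy_antigen()
grid = RadialGrid(r_np=50.0, dr=0.5, n_layers=60)
spacers = generate_spacer_conformations(5, 200, seed=0)
ens = {sp: assemble_species_conformations(spacers, antibody, antigen, n, 20,
                                          grid, seed=n + 1, species=sp)
       for n, sp in ((0, "A"), (1, "Aa"), (2, "Aaa"))}
bulk = BulkSolution(concentrations={"a": 100e-9},
                    molecular_volumes={"a": antigen.total_volume})
for n_sites in (1_000, 20_000, 40_000):
    state = solve_self_consistent(ens, bulk, "covalent", n_sites,
                                  kd=1e-9, avidity_ratio=100.0)
    f = state.surface.fractions
    print(f"N_s={n_sites:>6}: captured={state.captured_antigen_count:8.1f} "
          f"per-antibody={state.captured_antigen_count / n_sites:.3f} "
          f"f_unbound={f['A']:.3f} residual={state.diagnostics['max_residual']:.1e}")
```

prints

```
N_s=  1000: captured=  1195.5 per-antibody=1.196 f_unbound=0.006 residual=2.2e-16
N_s= 20000: captured= 12860.4 per-antibody=0.643 f_unbound=0.360 residual=5.6e-15
N_s= 40000: captured= 12065.8 per-antibody=0.302 f_unbound=0.699 residual=5.3e-14
```

At low coverage nearly every antibody is active (1.2 antigens each — some
carry two).  Crowding then erodes the per-antibody yield; past the binding
maximum, doubling the antibody count *lowers* the total captured antigen
(12 860 → 12 066) while 70% of the antibodies sit unbound — the non-monotonic
capture curve that makes AcNP design non-trivial.  The packing residual
column confirms local incompressibility at the solver's 1e-8 tolerance.

Sweeps, including the streptavidin scheme with its bulk pre-equilibration,
run from the command line:

```bash
acnp run sweep.yaml --outdir out/      # binding curves as TSV + manifest
acnp equilibrate mixture.yaml          # bulk antibody–antigen equilibrium
acnp conformers sweep.yaml             # cache conformer ensembles (NPZ+JSON)
acnp selftest                          # built-in oracle comparisons
```

Real structures are supported through `read_alpha_carbon_beads`, which
coarse-grains any PDB chain selection to one bead per residue at the alpha
carbon; users supply their own antibody / antibody–antigen complex files.

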