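"""Parameter sweeps over coverage, concentration, affinity, spacer and radius.

Drives the full pipeline: conformer ensembles are generated once per
(radius, spacer, species) combination, the bulk mixture is pre-equilibrated
for the streptavidin scheme, the self-consistent field is solved at every
coverage point, and the resulting binding curves (captured antigen, species
breakdown, mean center-of-mass radii, free energy) are collected and written
out as TSV tables plus a JSON run manifest.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import dataclass, field as dc_field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import conformer_lab as cl
from . import theory_core as tc
from .bulk_chemistry import MixtureSpec, solve_mixture_equilibrium

log = logging.getLogger("acnp")
if not log.handlers:
    _h = logging.StreamHandler(sys.stderr)
    _h.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(_h)
log.setLevel(logging.INFO)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass
class SweepConfig:
    """One declarative sweep: the cartesian grid of conditions to solve.

    Concentrations are molar, lengths nm, coverage as absolute tether-site
    counts (the per-nm^2 coverage axis is derived per radius).  For the
    covalent scheme ``antigen_bulk`` lists antigen concentrations; for the
    streptavidin scheme ``mixtures`` lists initial {A_total, a_total} pairs
    that are pre-equilibrated in solution.
    """

    scheme: str = "covalent"
    r_np: list = dc_field(default_factory=lambda: [50.0])
    spacer_lengths: list = dc_field(default_factory=lambda: [50])
    kd: list = dc_field(default_factory=lambda: [1e-9])
    avidity_ratio: float = 100.0
    g_mode: int = 2
    kd_biotin: float = 1e-14
    antigen_bulk: list = dc_field(default_factory=lambda: [100e-9])
    mixtures: list = dc_field(default_factory=list)   # [{"A_total":..,"a_total":..}]
    n_sites: list = dc_field(default_factory=lambda: list(np.geomspace(10, 2e4, 25)))
    n_spacer_samples: int = 200
    n_orientations: int = 30
    arm_length: int = 5
    seed: int = 0
    dr: float = 0.5
    r_max_margin: float = 100.0
    v_w: float = tc.WATER_VOLUME_NM3
    solver_tol: float = 1e-8
    solver_max_iter: int = 4000
    solver_damping: float = 0.25
    outdir: str | None = None

    def __post_init__(self):
        if self.scheme not in ("covalent", "streptavidin"):
            raise ValueError(f"unknown scheme {self.scheme!r}")
        for name in ("r_np", "spacer_lengths", "kd", "n_sites"):
            if not list(getattr(self, name)):
                raise ValueError(f"sweep axis {name!r} is empty")
        if self.scheme == "covalent" and not list(self.antigen_bulk):
            raise ValueError("covalent scheme needs antigen_bulk values")
        if self.scheme == "streptavidin" and not self.mixtures:
            raise ValueError("streptavidin scheme needs mixtures")
        if min(self.r_np) <= 0 or min(self.kd) <= 0 or min(self.n_sites) < 0:
            raise ValueError("physical values must be positive")

    @classmethod
    def from_yaml(cls, path) -> "SweepConfig":
        import yaml

        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["n_sites"] = [float(x) for x in self.n_sites]
        return d


@dataclass
class BindingCurve:
    """One binding isotherm: captured antigen and composition vs coverage."""

    scheme: str
    r_np: float
    spacer: int
    kd: float
    bulk_label: str
    bulk_concentrations: dict
    n_sites: np.ndarray
    sigma: np.ndarray                 # tether sites per nm^2
    captured: np.ndarray              # antigens per particle
    captured_per_area: np.ndarray     # antigens per nm^2
    fractions: dict                   # species -> array over coverage
    r_com: dict                       # species -> array over coverage (nm)
    beta_free_energy: np.ndarray
    converged: np.ndarray             # bool flags; only converged points usable

    @property
    def usable(self) -> np.ndarray:
        return self.converged & np.isfinite(self.captured)

    def to_frame(self) -> pd.DataFrame:
        cols = {
            "n_sites": self.n_sites,
            "sigma_per_nm2": self.sigma,
            "captured_antigen": self.captured,
            "captured_per_nm2": self.captured_per_area,
            "beta_free_energy": self.beta_free_energy,
            "converged": self.converged.astype(int),
        }
        for sp, arr in self.fractions.items():
            cols[f"f_{sp}"] = arr
        for sp, arr in self.r_com.items():
            cols[f"r_com_{sp}_nm"] = arr
        return pd.DataFrame(cols)

    def tag(self) -> str:
        return (f"{self.scheme}_R{self.r_np:g}_sp{self.spacer}"
                f"_Kd{self.kd:.0e}_{self.bulk_label}")


# ---------------------------------------------------------------------------
# Ensemble preparation
# ---------------------------------------------------------------------------

def build_ensembles(r_np: float, spacer: int, config: SweepConfig,
                    antibody: cl.BeadModel | None = None,
                    antigen: cl.BeadModel | None = None) -> dict:
    """Ensembles for the three bound antibody states on one grid."""
    from .fixtures import make_toy_antigen

    if antibody is None:
        antibody = cl.make_toy_antibody(config.arm_length)
    if antigen is None:
        antigen = make_toy_antigen()
    n_layers = int(np.ceil(config.r_max_margin / config.dr))
    grid = tc.RadialGrid(r_np=r_np, dr=config.dr, n_layers=n_layers)
    spacers = cl.generate_spacer_conformations(
        spacer, config.n_spacer_samples, seed=config.seed)
    # without a spacer the single empty chain carries all the sampling, so
    # the orientation count takes over the full conformational budget
    n_orient = (config.n_orientations if spacer > 0 else
                min(config.n_orientations * config.n_spacer_samples, 50_000))
    out = {}
    for n_ant, sp in ((0, "A"), (1, "Aa"), (2, "Aaa")):
        out[sp] = cl.assemble_species_conformations(
            spacers, antibody, antigen, n_ant, n_orient,
            grid, seed=config.seed + 7 * (n_ant + 1), species=sp)
    out["_antigen_volume"] = antigen.total_volume
    return out


def _bulk_for(config: SweepConfig, kd: float, bulk_point, ensembles) -> tuple:
    """(BulkSolution, label, concentrations dict) for one bulk condition."""
    vol_a = ensembles["_antigen_volume"]
    if config.scheme == "covalent":
        c_a = float(bulk_point)
        bulk = tc.BulkSolution(
            concentrations={"a": c_a},
            molecular_volumes={"a": vol_a},
            v_w=config.v_w,
        )
        return bulk, f"ca{c_a:.0e}M", {"a": c_a}
    spec = MixtureSpec(A_total=float(bulk_point["A_total"]),
                       a_total=float(bulk_point["a_total"]),
                       kd=kd, avidity_ratio=config.avidity_ratio,
                       g_mode=config.g_mode)
    eq = solve_mixture_equilibrium(spec)
    conc = eq.as_dict()
    vols = {"a": vol_a,
            "A": ensembles["A"].molecular_volume,
            "Aa": ensembles["Aa"].molecular_volume,
            "Aaa": ensembles["Aaa"].molecular_volume}
    bulk = tc.BulkSolution(concentrations=conc, molecular_volumes=vols,
                           v_w=config.v_w)
    label = f"mixA{spec.A_total:.0e}a{spec.a_total:.0e}M"
    return bulk, label, conc


# ---------------------------------------------------------------------------
# Sweep driver
# ---------------------------------------------------------------------------

def run_sweep(config: SweepConfig,
              antibody: cl.BeadModel | None = None,
              antigen: cl.BeadModel | None = None) -> tuple:
    """Solve every grid point; returns (curves, manifest).

    Solver failures are recorded per point (non-converged flag) and in the
    manifest, never silently dropped.
    """
    t0 = time.time()
    curves = []
    failures = []
    bound_species = (("A", "Aa", "Aaa") if config.scheme == "covalent"
                     else ("S", "A", "Aa", "Aaa"))
    bulk_points = (config.antigen_bulk if config.scheme == "covalent"
                   else config.mixtures)

    for r_np in config.r_np:
        for spacer in config.spacer_lengths:
            ens = build_ensembles(r_np, spacer, config, antibody, antigen)
            area = 4.0 * np.pi * r_np**2
            for kd in config.kd:
                for bulk_point in bulk_points:
                    bulk, label, conc = _bulk_for(config, kd, bulk_point, ens)
                    ns = np.asarray(config.n_sites, dtype=float)
                    cap = np.full(ns.shape, np.nan)
                    bf = np.full(ns.shape, np.nan)
                    conv = np.zeros(ns.shape, dtype=bool)
                    fr = {sp: np.full(ns.shape, np.nan) for sp in bound_species}
                    rc = {sp: np.full(ns.shape, np.nan)
                          for sp in ("A", "Aa", "Aaa")}
                    x_warm = None  # continuation along the coverage axis
                    for i, n_sites in enumerate(ns):
                        try:
                            state = tc.solve_self_consistent(
                                {k: v for k, v in ens.items()
                                 if not k.startswith("_")},
                                bulk, config.scheme, n_sites, kd,
                                config.avidity_ratio, g_mode=config.g_mode,
                                kd_biotin=config.kd_biotin,
                                tol=config.solver_tol,
                                max_iter=config.solver_max_iter,
                                damping=config.solver_damping,
                                x0=x_warm)
                        except (tc.ConvergenceError, FloatingPointError) as exc:
                            failures.append({
                                "r_np": r_np, "spacer": spacer, "kd": kd,
                                "bulk": label, "n_sites": float(n_sites),
                                "error": str(exc)})
                            log.warning("point failed (N_s=%g): %s", n_sites, exc)
                            continue
                        x_warm = state.field.beta_pi
                        cap[i] = state.captured_antigen_count
                        bf[i] = state.beta_free_energy
                        conv[i] = True
                        for sp in bound_species:
                            fr[sp][i] = state.surface.fractions.get(sp, 0.0)
                        for sp, v in state.mean_com_radius.items():
                            rc[sp][i] = v
                    curve = BindingCurve(
                        scheme=config.scheme, r_np=r_np, spacer=spacer, kd=kd,
                        bulk_label=label, bulk_concentrations=conc,
                        n_sites=ns, sigma=ns / area, captured=cap,
                        captured_per_area=cap / area, fractions=fr,
                        r_com=rc, beta_free_energy=bf, converged=conv)
                    curves.append(curve)
                    log.info("curve %s: %d/%d points converged",
                             curve.tag(), int(conv.sum()), len(ns))

    manifest = {
        "config": config.to_dict(),
        "n_curves": len(curves),
        "n_failed_points": len(failures),
        "failures": failures,
        "elapsed_s": time.time() - t0,
        "maximum_method": "parabolic interpolation through the three points "
                          "bracketing the discrete argmax; ties broken at "
                          "the lowest coverage",
    }
    return curves, manifest


# ---------------------------------------------------------------------------
# Maxima
# ---------------------------------------------------------------------------

def find_binding_maximum(curve: BindingCurve, observable: str = "captured"):
    """Locate the coverage of maximum binding on one curve.

    Returns ``(coverage_at_max, max_value, boundary)``: coverage on the
    sigma axis (per nm^2).  Interior maxima are refined by parabolic
    interpolation through the three bracketing points; a maximum at either
    end of the usable range is returned as-is with ``boundary=True``.
    """
    use = curve.usable
    x = curve.sigma[use]
    if observable in curve.fractions:
        y = np.asarray(curve.fractions[observable])[use]
    else:
        y = np.asarray(getattr(curve, observable))[use]
    if len(x) < 3:
        raise ValueError("need at least 3 usable points to locate a maximum")
    k = int(np.argmax(y))  # np.argmax returns the first (lowest-coverage) tie
    if k == 0 or k == len(x) - 1:
        return float(x[k]), float(y[k]), True
    x3, y3 = x[k - 1:k + 2], y[k - 1:k + 2]
    denom = ((x3[0] - x3[1]) * (x3[0] - x3[2]) * (x3[1] - x3[2]))
    a = (x3[2] * (y3[1] - y3[0]) + x3[1] * (y3[0] - y3[2])
         + x3[0] * (y3[2] - y3[1])) / denom
    b = (x3[2]**2 * (y3[0] - y3[1]) + x3[1]**2 * (y3[2] - y3[0])
         + x3[0]**2 * (y3[1] - y3[2])) / denom
    if a >= 0:  # degenerate (flat or upward) parabola: keep the grid argmax
        return float(x[k]), float(y[k]), False
    xm = -b / (2 * a)
    xm = float(np.clip(xm, x3[0], x3[2]))
    c = y3[0] - a * x3[0]**2 - b * x3[0]
    return xm, float(a * xm**2 + b * xm + c), False


# ---------------------------------------------------------------------------
# Output
# ---------------------------------------------------------------------------

def write_outputs(curves, manifest, outdir, plots: bool = False) -> list:
    """Write per-curve TSVs and the run manifest; returns written paths.

    TSV columns: n_sites, sigma_per_nm2, captured_antigen, captured_per_nm2,
    beta_free_energy, converged, f_<species>, r_com_<species>_nm.  Identical
    configs and seeds produce byte-identical TSVs.
    """
    outdir = Path(outdir)
    try:
        outdir.mkdir(parents=True, exist_ok=True)
        written = []
        for curve in curves:
            path = outdir / f"curve_{curve.tag()}.tsv"
            curve.to_frame().to_csv(path, sep="\t", index=False,
                                    float_format="%.10g")
            written.append(path)
        mpath = outdir / "manifest.json"
        with open(mpath, "w") as fh:
            json.dump(manifest, fh, indent=2, default=float)
        written.append(mpath)
        if plots and curves:
            written += _plot_curves(curves, outdir)
        return written
    except OSError as exc:
        raise OSError(f"failed writing sweep outputs under {outdir}: {exc}") from exc


def read_curve_frame(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def _plot_curves(curves, outdir: Path) -> list:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for curve in curves:
        ax.plot(curve.sigma[curve.usable], curve.captured[curve.usable],
                marker="o", ms=3, label=curve.tag())
    ax.set_xlabel("coverage (sites/nm$^2$)")
    ax.set_ylabel("captured antigen")
    ax.legend(fontsize=6)
    fig.tight_layout()
    path = outdir / "binding_curves.png"
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return [path]
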