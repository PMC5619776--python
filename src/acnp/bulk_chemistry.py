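"""Homogeneous antibody-antigen solution equilibrium.

In the streptavidin conjugation scheme the biotinylated antibody equilibrates
with antigen in solution *before* anything adsorbs, so the surface
calculation needs the equilibrium concentrations of free antigen (a), free
antibody (A) and the one- and two-antigen complexes (Aa, Aaa) for given
initial (total) concentrations.  Biotin is carried 1:1 on every antibody and
is not a free solution species.

The two ligation steps share the statistical-factor convention of the
surface theory (``theory_core.ligation_factors``):

    c_Aa  = m1(c_a) * c_A
    c_Aaa = m2(c_a) * c_A

and both mass balances close.  The problem reduces to one monotone equation
in the free-antigen concentration, solved by safeguarded bracketed
root-finding.
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy.optimize import brentq

from .theory_core import ligation_factors


@dataclass(frozen=True)
class MixtureSpec:
    """Initial composition and constants of the solution mixture (molar)."""

    A_total: float
    a_total: float
    kd: float
    avidity_ratio: float = 100.0
    g_mode: int = 2

    def __post_init__(self):
        if self.A_total < 0 or self.a_total < 0:
            raise ValueError("total concentrations must be non-negative")
        if self.kd <= 0 or self.avidity_ratio <= 0:
            raise ValueError("kd and avidity_ratio must be positive")


@dataclass(frozen=True)
class MixtureEquilibrium:
    """Equilibrium concentrations (molar) of the four solution species."""

    c_a: float
    c_A: float
    c_Aa: float
    c_Aaa: float

    def as_dict(self) -> dict:
        return {"a": self.c_a, "A": self.c_A, "Aa": self.c_Aa, "Aaa": self.c_Aaa}


def _speciate(a: float, spec: MixtureSpec):
    """Concentrations of A, Aa, Aaa at a given free-antigen concentration."""
    m1, m2 = ligation_factors(a, spec.kd, spec.avidity_ratio, spec.g_mode)
    c_A = spec.A_total / (1.0 + m1 + m2)
    return c_A, m1 * c_A, m2 * c_A


def solve_mixture_equilibrium(spec: MixtureSpec) -> MixtureEquilibrium:
    """Equilibrate the antibody-antigen mixture.

    Root variable: the free-antigen concentration ``a``.  The antigen balance
    h(a) = a + c_Aa(a) + 2 c_Aaa(a) - a_total is strictly increasing with
    h(0) <= 0 <= h(a_total), so the bracketed root is unique.
    """
    if spec.A_total == 0.0 or spec.a_total == 0.0:
        return MixtureEquilibrium(c_a=spec.a_total, c_A=spec.A_total,
                                  c_Aa=0.0, c_Aaa=0.0)

    def h(a: float) -> float:
        _, c_aa, c_aaa = _speciate(a, spec)
        return a + c_aa + 2.0 * c_aaa - spec.a_total

    if h(spec.a_total) <= 0.0:  # binding negligible at full bracket edge
        a = spec.a_total
    else:
        a = brentq(h, 0.0, spec.a_total, xtol=1e-300, rtol=8.9e-16,
                   maxiter=300)
    c_A, c_Aa, c_Aaa = _speciate(a, spec)
    # close the antigen balance exactly: shift free antigen by the (machine-
    # level) root-finding remainder while keeping the complex speciation
    a = max(0.0, spec.a_total - c_Aa - 2.0 * c_Aaa)
    return MixtureEquilibrium(c_a=a, c_A=c_A, c_Aa=c_Aa, c_Aaa=c_Aaa)


def mass_balance_report(eq: MixtureEquilibrium, spec: MixtureSpec) -> tuple:
    """Relative mass-balance residuals (antibody, antigen)."""
    res_A = eq.c_A + eq.c_Aa + eq.c_Aaa - spec.A_total
    res_a = eq.c_a + eq.c_Aa + 2.0 * eq.c_Aaa - spec.a_total
    if spec.A_total > 0:
        res_A /= spec.A_total
    if spec.a_total > 0:
        res_a /= spec.a_total
    return res_A, res_a
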