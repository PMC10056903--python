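"""Closed-form analysis layer: next-generation numbers, R0 and equilibria.

The invasion analysis rests on two *next-generation numbers*: the expected
number of new adult females produced per female over one full life cycle,

    G0u = b_f * psi/(psi + mu_l) * delta/(delta + mu_eu) * phi_u/mu_fu
    G0w = v_w * b_f * psi/(psi + mu_l) * delta/(delta + mu_ew) * phi_w/mu_fw

for the uninfected and infected cohorts.  Their ratio is the basic
reproductive number of the *Wolbachia* infection near the wild-type
(disease-free) equilibrium,

    R0 = G0w / G0u = v_w * mu_fu * phi_w * (delta + mu_eu)
                     / (mu_fw * phi_u * (delta + mu_ew)),

which is below 1 whenever the symbiont carries a net fitness cost.  The
system then exhibits bistability: a stable disease-free equilibrium (DFE)
and — under perfect maternal transmission — a stable complete-infection
equilibrium (CIE) are separated by an unstable coexistence (endemic)
equilibrium whose female infected fraction is the invasion threshold.

The endemic equilibrium is parameterized by the infected-to-uninfected
larval ratio ``r_wu = L_w / L_u``, which satisfies a quadratic whose
coefficients involve the leakage ratio ``v_u / v_w``; at ``v_w = 1`` the
quadratic degenerates to the linear solution ``r_wu = (1 - R0) / R0``.
Closed forms here assume complete CI (``c_i = 1``) and equal male death
rates (``mu_mu = mu_mw``) for the endemic branch, matching the wAlbB
baseline.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .model import ModelParams, State, rhs

__all__ = [
    "EquilibriumReport",
    "next_generation_numbers",
    "basic_reproductive_number",
    "disease_free_equilibrium",
    "complete_infection_equilibrium",
    "endemic_ratio",
    "endemic_equilibrium",
    "threshold_female_fraction",
    "equilibrium_report",
]

logger = logging.getLogger("wolbsim")


def next_generation_numbers(params: ModelParams) -> tuple[float, float]:
    """Return ``(G0u, G0w)``, the per-generation female offspring numbers."""
    p = params
    common = p.b_f * p.psi / (p.psi + p.mu_l)
    g0u = common * p.delta / (p.delta + p.mu_eu) * p.phi_u / p.mu_fu
    g0w = p.v_w * common * p.delta / (p.delta + p.mu_ew) * p.phi_w / p.mu_fw
    return g0u, g0w


def basic_reproductive_number(params: ModelParams) -> float:
    """R0 of the infection: spectral radius of the next-generation matrix.

    Equals ``G0w / G0u`` identically.
    """
    p = params
    return (p.v_w * p.mu_fu * p.phi_w * (p.delta + p.mu_eu)
            / (p.mu_fw * p.phi_u * (p.delta + p.mu_ew)))


def disease_free_equilibrium(params: ModelParams) -> State:
    """Wild-type equilibrium with all infected compartments at zero.

    Requires ``G0u > 1`` for a positive population; otherwise the wild
    population cannot sustain itself and the origin is returned with a
    warning (bifurcation scans may legitimately cross this regime).
    """
    p = params
    g0u, _ = next_generation_numbers(params)
    if g0u <= 1:
        warnings.warn(
            f"G0u = {g0u:.4g} <= 1: wild population goes extinct; "
            "returning the origin as the disease-free state",
            stacklevel=2,
        )
        return State()
    L = p.K_l * (1.0 - 1.0 / g0u)
    F = p.b_f * p.psi / p.mu_fu * L
    M = p.b_m * p.psi / p.mu_mu * L
    E = p.b_f * p.psi / p.mu_fu * p.phi_u / (p.delta + p.mu_eu) * L
    return State(M_u=M, F_u=F, E_u=E, L_u=L)


def complete_infection_equilibrium(params: ModelParams) -> State:
    """Fully infected equilibrium; exists only under perfect transmission.

    Raises
    ------
    ValueError
        If ``v_w < 1`` (infected females then leak uninfected offspring and
        only a coexistence equilibrium exists) or ``G0w <= 1``.
    """
    p = params
    if p.v_w < 1.0:
        raise ValueError(
            "complete-infection equilibrium undefined for v_w < 1; "
            "use endemic_equilibrium"
        )
    _, g0w = next_generation_numbers(params)
    if g0w <= 1:
        raise ValueError(f"G0w = {g0w:.4g} <= 1: infected population cannot persist")
    L = p.K_l * (1.0 - 1.0 / g0w)
    F = p.b_f * p.psi / p.mu_fw * L
    M = p.b_m * p.psi / p.mu_mw * L
    E = p.b_f * p.psi * p.phi_w / ((p.delta + p.mu_ew) * p.mu_fw) * L
    return State(M_w=M, F_w=F, E_w=E, L_w=L)


def _quadratic_coefficients(params: ModelParams) -> tuple[float, float, float]:
    p = params
    r0 = basic_reproductive_number(params)
    a = (p.v_u / p.v_w) * (p.delta + p.mu_ew) / (p.delta + p.mu_eu)
    return a, a - 1.0, (1.0 - r0) / r0


def endemic_ratio(params: ModelParams) -> list[float]:
    """Positive roots ``r_wu = L_w/L_u`` of the coexistence quadratic.

    Returns the roots sorted ascending; the first element is the
    *threshold branch* — the root that stays finite as ``v_w -> 1`` and
    degenerates to ``(1 - R0)/R0`` there (the other root diverges like
    ``1/v_u``).  Empty if no positive real root exists.

    The quadratic is derived under equal male death rates (the male
    proportions then reduce to ``1/(1+r)`` and ``r/(1+r)``); male rates do
    not appear in it at all, so small perturbations of either are inert.
    A substantial mismatch triggers a warning since the closed form is
    then only approximate.
    """
    p = params
    if abs(p.mu_mu - p.mu_mw) > 1e-2 * max(p.mu_mu, p.mu_mw):
        warnings.warn(
            "endemic-ratio quadratic assumes mu_mu == mu_mw; result is "
            "approximate for unequal male death rates", stacklevel=2)
    if p.v_w == 0.0:
        return []
    a, b, c = _quadratic_coefficients(params)
    if a == 0.0:  # v_w == 1: linear degenerate case
        return [c] if c > 0 else ([0.0] if c == 0 else [])
    disc = b * b - 4.0 * a * c
    if disc < 0:
        return []
    sq = np.sqrt(disc)
    # stable evaluation: the small root via the rationalized form
    r_big = (-b + sq) / (2.0 * a)
    r_small = 2.0 * c / (-b + sq) if (-b + sq) != 0 else r_big
    roots = sorted(r for r in (r_small, r_big) if r > 0)
    return roots


def endemic_equilibrium(params: ModelParams, rwu: float) -> State:
    """Coexistence equilibrium for a given larval ratio ``rwu > 0``.

    All components scale off ``L_u* = K_l (1 - 1/G0w) / (1 + rwu)``; the
    identity ``E_w* = rwu * E_u*`` holds at any root of the quadratic.
    Assumes complete CI (the uninfected egg inflow uses the uninfected male
    proportion ``1/(1 + rwu)``).
    """
    if not rwu > 0:
        raise ValueError("rwu must be positive")
    p = params
    _, g0w = next_generation_numbers(params)
    Lu = p.K_l * (1.0 - 1.0 / g0w) / (1.0 + rwu)
    Lw = rwu * Lu
    Mu = p.b_m * p.psi / p.mu_mu * Lu
    Mw = rwu * p.b_m * p.psi / p.mu_mw * Lu
    Fu = p.b_f * p.psi / p.mu_fu * Lu
    Fw = rwu * p.b_f * p.psi / p.mu_fw * Lu
    Eu = (p.b_f * p.psi / (p.delta + p.mu_eu)
          * (p.phi_u / p.mu_fu / (1.0 + rwu) + p.v_u * p.phi_w / p.mu_fw * rwu)
          * Lu)
    Ew = (rwu * p.b_f * p.psi / (p.delta + p.mu_ew)
          * p.v_w * p.phi_w / p.mu_fw * Lu)
    return State(M_u=Mu, M_w=Mw, F_u=Fu, F_w=Fw, E_u=Eu, E_w=Ew, L_u=Lu, L_w=Lw)


def threshold_female_fraction(params: ModelParams) -> float | None:
    """Female infected fraction at the unstable coexistence equilibrium.

    This is the invasion threshold: a naturally-distributed infection
    started above it converges to the infected state, below it dies out.
    In closed form ``p* = c r / (1 + c r)`` with ``c = mu_fu / mu_fw`` and
    ``r`` the threshold-branch larval ratio.  Returns ``None`` when no
    coexistence equilibrium exists (e.g. ``R0 >= 1``).
    """
    r0 = basic_reproductive_number(params)
    if not (0.0 < r0 < 1.0):
        return None
    roots = endemic_ratio(params)
    if not roots:
        return None
    r = roots[0]
    c = params.mu_fu / params.mu_fw
    return c * r / (1.0 + c * r)


@dataclass
class EquilibriumReport:
    """Bundle of the analytic quantities at one parameter set."""

    params: ModelParams
    G0u: float
    G0w: float
    R0: float
    dfe: State
    cie: State | None
    rwu_roots: list[float]
    ee_states: list[State]
    threshold_female_fraction: float | None
    stability: dict = field(default_factory=dict)

    def residuals(self) -> dict:
        """Relative right-hand-side residual at each constructed state."""
        out = {}
        entries = [("dfe", self.dfe)]
        if self.cie is not None:
            entries.append(("cie", self.cie))
        entries += [(f"ee_{i}", s) for i, s in enumerate(self.ee_states)]
        for name, st in entries:
            y = st.to_array()
            scale = max(np.max(np.abs(y)), 1.0)
            out[name] = float(np.max(np.abs(rhs(0.0, y, self.params))) / scale)
        return out

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "G0u": self.G0u,
            "G0w": self.G0w,
            "R0": self.R0,
            "dfe": dict(zip(
                ("M_u", "M_w", "F_u", "F_w", "E_u", "E_w", "L_u", "L_w"),
                self.dfe.to_array().tolist())),
            "cie": None if self.cie is None else dict(zip(
                ("M_u", "M_w", "F_u", "F_w", "E_u", "E_w", "L_u", "L_w"),
                self.cie.to_array().tolist())),
            "rwu_roots": list(self.rwu_roots),
            "ee_states": [dict(zip(
                ("M_u", "M_w", "F_u", "F_w", "E_u", "E_w", "L_u", "L_w"),
                s.to_array().tolist())) for s in self.ee_states],
            "threshold_female_fraction": self.threshold_female_fraction,
            "stability": self.stability,
            "residuals": self.residuals(),
        }


def equilibrium_report(params: ModelParams, classify: bool = True) -> EquilibriumReport:
    """Assemble all equilibria, dimensionless numbers and stability labels."""
    g0u, g0w = next_generation_numbers(params)
    r0 = basic_reproductive_number(params)
    dfe = disease_free_equilibrium(params)
    cie = None
    if params.v_w == 1.0 and g0w > 1:
        cie = complete_infection_equilibrium(params)
    try:
        roots = endemic_ratio(params)
    except ValueError:
        roots = []
    ee_states = [endemic_equilibrium(params, r) for r in roots if r > 0]
    report = EquilibriumReport(
        params=params, G0u=g0u, G0w=g0w, R0=r0, dfe=dfe, cie=cie,
        rwu_roots=roots, ee_states=ee_states,
        threshold_female_fraction=threshold_female_fraction(params),
    )
    if classify:
        from .stability import classify as _classify  # deferred: avoids cycle
        labels = {}
        if np.any(dfe.to_array() > 0):
            labels["dfe"] = _classify(params, dfe).classification
        if cie is not None:
            labels["cie"] = _classify(params, cie).classification
        for i, st in enumerate(ee_states):
            labels[f"ee_{i}"] = _classify(params, st).classification
        report.stability = labels
    return report
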