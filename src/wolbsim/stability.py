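"""Linear stability analysis and the backward-bifurcation scan.

An equilibrium is classified through the eigenvalues of the Jacobian of the
vector field: stable if every real part is below ``-tol``, unstable if any
exceeds ``+tol``, and *marginal* when the largest real part sits inside the
tolerance band (eigenvalues cross zero exactly at bifurcation points, so a
marginal verdict is reported rather than silently calling the point
stable).

The expected picture at the wAlbB baseline is a backward bifurcation: for
``R0 < 1`` a stable wild-type equilibrium and a stable complete-infection
equilibrium coexist, separated by an unstable coexistence equilibrium whose
female infected fraction traces the invasion-threshold branch of the
bifurcation diagram as the wild egg-laying rate ``phi_u`` (and hence R0)
is varied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import ModelParams, State, rhs, female_infection_fraction
from .equilibria import (
    basic_reproductive_number,
    complete_infection_equilibrium,
    disease_free_equilibrium,
    endemic_equilibrium,
    endemic_ratio,
    next_generation_numbers,
    threshold_female_fraction,
)

__all__ = [
    "StabilityVerdict",
    "jacobian",
    "jacobian_fd",
    "classify",
    "bifurcation_scan",
    "phi_u_for_r0",
]

logger = logging.getLogger("wolbsim")

STABILITY_TOL = 1e-9


@dataclass
class StabilityVerdict:
    label: str
    eigenvalues: np.ndarray
    max_real_part: float
    classification: str  # "stable" | "unstable" | "marginal"


def jacobian(params: ModelParams, state: State | np.ndarray) -> np.ndarray:
    """Analytic 8x8 Jacobian of the right-hand side at a state.

    The only nonlinearities are the male-proportion weights in the
    uninfected-egg birth term and the shared capacity factor in the two
    larval inflows; everything else is linear.  When no males exist the
    proportion derivatives are taken as zero (matching the convention in
    the right-hand side).
    """
    y = state.to_array() if isinstance(state, State) else np.asarray(state, float)
    Mu, Mw, Fu, Fw, Eu, Ew, Lu, Lw = y
    p = params
    J = np.zeros((8, 8))
    # adults: linear in larvae and themselves
    J[0, 6] = p.b_m * p.psi
    J[0, 0] = -p.mu_mu
    J[1, 7] = p.b_m * p.psi
    J[1, 1] = -p.mu_mw
    J[2, 6] = p.b_f * p.psi
    J[2, 2] = -p.mu_fu
    J[3, 7] = p.b_f * p.psi
    J[3, 3] = -p.mu_fw
    # uninfected eggs: phi_u * (1 - c_i * Mw/(Mu+Mw)) * Fu + v_u phi_w Fw
    M = Mu + Mw
    if M > 0:
        mw = Mw / M
        J[4, 0] = p.phi_u * p.c_i * Fu * Mw / M**2
        J[4, 1] = -p.phi_u * p.c_i * Fu * Mu / M**2
    else:
        mw = 0.0
    J[4, 2] = p.phi_u * (1.0 - p.c_i * mw)
    J[4, 3] = p.v_u * p.phi_w
    J[4, 4] = -(p.delta + p.mu_eu)
    # infected eggs
    J[5, 3] = p.v_w * p.phi_w
    J[5, 5] = -(p.delta + p.mu_ew)
    # larvae: delta * K * E with K = 1 - (Lu+Lw)/K_l
    K = 1.0 - (Lu + Lw) / p.K_l
    J[6, 4] = p.delta * K
    J[6, 6] = -p.delta * Eu / p.K_l - (p.psi + p.mu_l)
    J[6, 7] = -p.delta * Eu / p.K_l
    J[7, 5] = p.delta * K
    J[7, 6] = -p.delta * Ew / p.K_l
    J[7, 7] = -p.delta * Ew / p.K_l - (p.psi + p.mu_l)
    return J


def jacobian_fd(params: ModelParams, state: State | np.ndarray,
                rel_step: float = 1e-6) -> np.ndarray:
    """Central-difference Jacobian, used as a cross-check of the analytic one."""
    y = state.to_array() if isinstance(state, State) else np.asarray(state, float)
    scale = max(float(np.max(np.abs(y))), 1.0)
    h = rel_step * scale
    J = np.zeros((8, 8))
    for j in range(8):
        e = np.zeros(8)
        e[j] = h
        J[:, j] = (rhs(0.0, y + e, params) - rhs(0.0, y - e, params)) / (2 * h)
    return J


def classify(params: ModelParams, state: State | np.ndarray,
             label: str = "", tol: float = STABILITY_TOL,
             residual_tol: float = 1e-6) -> StabilityVerdict:
    """Eigenvalue-based stability verdict at an (approximate) equilibrium.

    Raises
    ------
    ValueError
        If the state is not an equilibrium to within ``residual_tol``
        relative residual.
    """
    y = state.to_array() if isinstance(state, State) else np.asarray(state, float)
    scale = max(float(np.max(np.abs(y))), 1.0)
    res = float(np.max(np.abs(rhs(0.0, y, params)))) / scale
    if res > residual_tol:
        raise ValueError(
            f"state is not an equilibrium (relative residual {res:.3g})")
    eig = np.linalg.eigvals(jacobian(params, y))
    mrp = float(np.max(eig.real))
    if mrp < -tol:
        cls = "stable"
    elif mrp > tol:
        cls = "unstable"
    else:
        cls = "marginal"
    return StabilityVerdict(label=label, eigenvalues=eig,
                            max_real_part=mrp, classification=cls)


def phi_u_for_r0(params: ModelParams, r0: float) -> float:
    """Wild egg-laying rate giving a prescribed R0 (all else at ``params``)."""
    p = params
    return (p.v_w * p.mu_fu * p.phi_w * (p.delta + p.mu_eu)
            / (p.mu_fw * r0 * (p.delta + p.mu_ew)))


def default_phi_u_grid(params: ModelParams, n: int = 60,
                       r0_min: float = 0.3, r0_max: float = 1.5) -> np.ndarray:
    """Log-spaced phi_u grid covering R0 in [r0_min, r0_max]."""
    lo = phi_u_for_r0(params, r0_max)
    hi = phi_u_for_r0(params, r0_min)
    return np.geomspace(lo, hi, n)


def bifurcation_scan(params: ModelParams,
                     phi_u_grid: np.ndarray | None = None) -> pd.DataFrame:
    """Trace the equilibrium branches as the wild egg-laying rate varies.

    For each ``phi_u`` value the scan records R0, the wild-type branch
    (female infected fraction 0), the complete-infection branch (fraction
    1, requiring ``v_w = 1`` and ``G0w > 1``), and — where ``0 < R0 < 1``
    — the unstable interior branch at the threshold fraction, together
    with eigenvalue-based stability labels.  Together these reproduce the
    backward-bifurcation diagram.
    """
    if phi_u_grid is None:
        phi_u_grid = default_phi_u_grid(params)
    rows = []
    for phi in np.asarray(phi_u_grid, dtype=float):
        p = params.replace(phi_u=phi)
        g0u, g0w = next_generation_numbers(p)
        r0 = basic_reproductive_number(p)
        row = {"phi_u": phi, "R0": r0, "G0u": g0u, "G0w": g0w}
        # wild-type branch
        if g0u > 1:
            dfe = disease_free_equilibrium(p)
            row["dfe_fraction"] = 0.0
            row["dfe_stable"] = classify(p, dfe).classification
        else:
            row["dfe_fraction"] = np.nan
            row["dfe_stable"] = "absent"
        # complete-infection branch (independent of phi_u, but re-checked)
        if p.v_w == 1.0 and g0w > 1:
            cie = complete_infection_equilibrium(p)
            row["cie_fraction"] = 1.0
            row["cie_stable"] = classify(p, cie).classification
        else:
            row["cie_fraction"] = np.nan
            row["cie_stable"] = "absent"
        # interior (threshold) branch
        thr = threshold_female_fraction(p) if 0 < r0 < 1 and g0w > 1 else None
        if thr is not None:
            roots = endemic_ratio(p)
            ee = endemic_equilibrium(p, roots[0])
            row["ee_fraction"] = thr
            row["ee_stable"] = classify(p, ee).classification
        else:
            row["ee_fraction"] = np.nan
            row["ee_stable"] = "absent"
        rows.append(row)
    return pd.DataFrame(rows)


def mixed_state(dfe: State, cie: State, p: float) -> State:
    """Natural-distribution mixture ``(1-p)*DFE + p*CIE`` componentwise.

    This is the unique construction for which the infected fraction equals
    ``p`` in every life stage simultaneously (females included), matching
    the "natural distribution of infection" used to read the bifurcation
    diagram.
    """
    y = (1.0 - p) * dfe.to_array() + p * cie.to_array()
    return State.from_array(y)


def basin_threshold_by_bisection(params: ModelParams, resolution: float = 1e-3,
                                 horizon: float = 3000.0, rtol: float = 1e-8,
                                 probe: str = "ee-line") -> float:
    """Locate the basin-boundary female fraction by simulation.

    Bisects along a one-parameter family of initial states on establishment
    of the infection (final female infected fraction above 0.5 after
    ``horizon`` days) and returns the female infected fraction of the
    critical state.  Serves as the simulation-based oracle for the
    closed-form threshold; requires bistability (``v_w = 1``,
    ``0 < R0 < 1``, ``G0w > 1``).

    Probes
    ------
    ``"ee-line"`` (default)
        A short segment through the unstable coexistence equilibrium along
        the DFE-to-CIE direction.  Because the separatrix passes through
        that equilibrium, this probe recovers the closed-form fraction
        essentially exactly and verifies the separatrix locally.
    ``"dfe-cie"``
        The global convex mixture ``(1-p)*DFE + p*CIE``.  Its crossing of
        the separatrix carries a small curvature bias (~0.006 in fraction
        at baseline), so it checks the threshold only to about a
        percentage point.
    """
    from .model import simulate  # local import keeps module load light
    dfe = disease_free_equilibrium(params)
    cie = complete_infection_equilibrium(params)
    y0, yc = dfe.to_array(), cie.to_array()

    if probe == "dfe-cie":
        def state_at(a: float) -> np.ndarray:
            return (1.0 - a) * y0 + a * yc
    elif probe == "ee-line":
        roots = endemic_ratio(params)
        if not roots:
            raise ValueError("no coexistence equilibrium: basin probe undefined")
        ye = endemic_equilibrium(params, roots[0]).to_array()
        direction = 0.2 * (yc - y0)

        def state_at(a: float) -> np.ndarray:
            return np.maximum(ye + (a - 0.5) * direction, 0.0)
    else:
        raise ValueError(f"unknown probe {probe!r}")

    def establishes(a: float) -> bool:
        traj = simulate(params, state_at(a), horizon, rtol=rtol)
        return female_infection_fraction(traj.states[-1]) > 0.5

    lo, hi = 0.0, 1.0
    if establishes(lo) or not establishes(hi):
        raise ValueError("probe endpoints do not bracket the basin boundary")
    while hi - lo > resolution:
        mid = 0.5 * (lo + hi)
        if establishes(mid):
            hi = mid
        else:
            lo = mid
    return female_infection_fraction(state_at(0.5 * (lo + hi)))
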