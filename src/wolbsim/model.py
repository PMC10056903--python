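"""Core compartmental model of *Wolbachia* spread in a mosquito population.

The population is split into eight compartments by life stage, sex and
infection status: adult males (``M_u``, ``M_w``), adult females (``F_u``,
``F_w``), eggs (``E_u``, ``E_w``) and combined larvae/pupae (``L_u``,
``L_w``), where the ``u``/``w`` subscripts denote uninfected and
*Wolbachia*-infected cohorts.  The dynamics couple the two cohorts through

* maternal transmission: a fraction ``v_w`` of an infected female's eggs
  inherit the infection, independent of the father;
* cytoplasmic incompatibility (CI): a fraction ``c_i`` of the eggs laid by
  uninfected females mated with infected males are nonviable, so the
  uninfected birth rate is ``phi_u * (Mcal_u + (1 - c_i) * Mcal_w)`` per
  female, where ``Mcal_u``/``Mcal_w`` are the uninfected/infected male
  proportions;
* a logistic carrying-capacity factor ``K = 1 - (L_u + L_w)/K_l`` throttling
  the hatch inflow into the larval pool.

This module defines the parameter and state containers, evaluates the
right-hand side of the system, and integrates trajectories with optional
time-varying carrying capacity and impulsive additions of infected adults
(field releases).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

__all__ = [
    "ModelParams",
    "State",
    "DerivedFractions",
    "Trajectory",
    "IntegrationError",
    "STATE_NAMES",
    "derived_fractions",
    "rhs",
    "simulate",
    "female_infection_fraction",
    "adult_infection_fraction",
]

logger = logging.getLogger("wolbsim")

#: Canonical compartment ordering used for all array representations.
STATE_NAMES = ("M_u", "M_w", "F_u", "F_w", "E_u", "E_w", "L_u", "L_w")

#: Default integrator tolerances (relative; absolute on the count scale).
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-6


class IntegrationError(RuntimeError):
    """Raised when the ODE integrator fails or produces an invalid state."""


@dataclass(frozen=True)
class ModelParams:
    """Life-history and interaction parameters.

    All rates are per day.  Defaults are the baseline estimates for
    *Anopheles* mosquitoes carrying the wAlbB strain: eggs hatch in ~3 days,
    larvae/pupae take ~18 days to emerge, adult female lifespans are 13
    (uninfected) vs 15 (infected) days, males live ~7 days, and infection
    roughly halves egg survivorship (hatch fractions 73% vs 50%) while
    slightly lowering the daily egg-laying rate (3.8 vs 3.3 eggs/female).
    wAlbB shows essentially perfect maternal transmission and complete CI,
    hence ``v_w = c_i = 1`` at baseline.

    Attributes
    ----------
    delta : float
        Egg hatching rate (1/day).
    psi : float
        Larval emergence rate (1/day).
    mu_fu, mu_fw : float
        Death rates of uninfected / infected adult females.
    mu_mu, mu_mw : float
        Death rates of uninfected / infected adult males.
    mu_eu, mu_ew : float
        Death rates of uninfected / infected eggs.
    mu_l : float
        Larval/pupal death rate.
    phi_u, phi_w : float
        Per-capita egg-laying rates of uninfected / infected females
        (eggs per female per day).
    v_w : float
        Maternal transmission fraction in [0, 1]; ``v_u = 1 - v_w``.
    c_i : float
        Cytoplasmic-incompatibility fraction in [0, 1].
    b_f : float
        Fraction of emerging larvae that are female; ``b_m = 1 - b_f``.
    K_l : float
        Carrying capacity of the combined larvae/pupae stage (count).
    """

    delta: float = 1.0 / 3.0
    psi: float = 1.0 / 18.0
    mu_fu: float = 1.0 / 13.0
    mu_fw: float = 1.0 / 15.0
    mu_mu: float = 1.0 / 7.0
    mu_mw: float = 1.0 / 7.0
    mu_eu: float = 0.12
    mu_ew: float = 0.33
    mu_l: float = 0.01
    phi_u: float = 3.8
    phi_w: float = 3.3
    v_w: float = 1.0
    c_i: float = 1.0
    b_f: float = 0.5
    K_l: float = 2.0e5

    RATE_FIELDS = (
        "delta", "psi", "mu_fu", "mu_fw", "mu_mu", "mu_mw",
        "mu_eu", "mu_ew", "mu_l", "phi_u", "phi_w",
    )
    FRACTION_FIELDS = ("v_w", "c_i", "b_f")

    def __post_init__(self) -> None:
        for name in self.RATE_FIELDS:
            if not getattr(self, name) > 0:
                raise ValueError(f"rate parameter {name!r} must be > 0")
        for name in self.FRACTION_FIELDS:
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"fraction parameter {name!r} must lie in [0, 1]")
        if not self.K_l > 0:
            raise ValueError("carrying capacity K_l must be > 0")

    @property
    def v_u(self) -> float:
        return 1.0 - self.v_w

    @property
    def b_m(self) -> float:
        return 1.0 - self.b_f

    def replace(self, **updates: float) -> "ModelParams":
        """Return a copy with the given fields overridden (re-validated)."""
        return replace(self, **updates)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class State:
    """Compartment abundances (continuous counts, all nonnegative)."""

    M_u: float = 0.0
    M_w: float = 0.0
    F_u: float = 0.0
    F_w: float = 0.0
    E_u: float = 0.0
    E_w: float = 0.0
    L_u: float = 0.0
    L_w: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in STATE_NAMES], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "State":
        y = np.asarray(y, dtype=float)
        if y.shape != (8,):
            raise ValueError("state array must have shape (8,)")
        return cls(**dict(zip(STATE_NAMES, y)))

    def validate(self, params: ModelParams, tol: float = 0.0) -> None:
        """Check nonnegativity and the larval initialization guard.

        Initial conditions must satisfy ``L_u + L_w <= K_l`` so that the
        capacity factor ``K`` starts in [0, 1]; since larval inflow vanishes
        at ``K = 0`` and larvae only die otherwise, ``K`` then stays in
        [0, 1] along the trajectory and no clamping is needed.
        """
        y = self.to_array()
        if not np.all(np.isfinite(y)):
            raise ValueError("state contains non-finite components")
        if np.any(y < -tol):
            raise ValueError("state components must be nonnegative")
        if self.L_u + self.L_w > params.K_l * (1 + 1e-12):
            raise ValueError(
                "initial larval population exceeds carrying capacity "
                f"(L_u + L_w = {self.L_u + self.L_w:.6g} > K_l = {params.K_l:.6g})"
            )


@dataclass(frozen=True)
class DerivedFractions:
    """Male-infection proportions and the carrying-capacity factor."""

    male_uninfected_fraction: float
    male_infected_fraction: float
    K: float


def _kl_at(t: float, params: ModelParams, forcing) -> float:
    """Carrying capacity at time ``t`` (constant unless forcing is given)."""
    if forcing is None:
        return params.K_l
    return params.K_l * forcing.s(t)


def derived_fractions(state: State, params: ModelParams, t: float = 0.0,
                      forcing=None) -> DerivedFractions:
    """Compute the male proportions and capacity factor at a state.

    When no males exist the infected-male proportion is taken to be 0 (and
    the uninfected proportion 1); every birth term it multiplies vanishes
    with the female populations anyway, so the convention does not alter
    the dynamics.
    """
    y = state.to_array() if isinstance(state, State) else np.asarray(state, float)
    M = y[0] + y[1]
    if M > 0:
        mw = y[1] / M
        mu = y[0] / M
    else:
        mw, mu = 0.0, 1.0
    K = 1.0 - (y[6] + y[7]) / _kl_at(t, params, forcing)
    return DerivedFractions(male_uninfected_fraction=mu,
                            male_infected_fraction=mw, K=K)


def rhs(t: float, y: np.ndarray, params: ModelParams, forcing=None) -> np.ndarray:
    """Time derivatives of the eight compartments.

    The uninfected-egg birth term is ``phi_u * (Mcal_u + (1 - c_i) *
    Mcal_w) * F_u + v_u * phi_w * F_w``; at complete CI (``c_i = 1``) this
    reduces to ``phi_u * Mcal_u * F_u + v_u * phi_w * F_w``.

    Parameters
    ----------
    t : float
        Time in days (only used when ``forcing`` is given).
    y : ndarray, shape (8,)
        State in the :data:`STATE_NAMES` order.
    params : ModelParams
    forcing : SeasonalForcing, optional
        Periodic multiplier on the carrying capacity.

    Raises
    ------
    IntegrationError
        If any state component is non-finite (integrator blow-up).
    """
    y = np.asarray(y, dtype=float)
    if not np.all(np.isfinite(y)):
        raise IntegrationError(f"non-finite state at t={t}: {y}")
    Mu, Mw, Fu, Fw, Eu, Ew, Lu, Lw = y
    p = params
    M = Mu + Mw
    if M > 0:
        mw = Mw / M
        mu = Mu / M
    else:
        mw, mu = 0.0, 1.0
    K = 1.0 - (Lu + Lw) / _kl_at(t, p, forcing)
    egg_out_u = p.delta + p.mu_eu
    egg_out_w = p.delta + p.mu_ew
    larva_out = p.psi + p.mu_l
    return np.array([
        p.b_m * p.psi * Lu - p.mu_mu * Mu,
        p.b_m * p.psi * Lw - p.mu_mw * Mw,
        p.b_f * p.psi * Lu - p.mu_fu * Fu,
        p.b_f * p.psi * Lw - p.mu_fw * Fw,
        p.phi_u * (mu + (1.0 - p.c_i) * mw) * Fu + p.v_u * p.phi_w * Fw
        - egg_out_u * Eu,
        p.v_w * p.phi_w * Fw - egg_out_w * Ew,
        p.delta * K * Eu - larva_out * Lu,
        p.delta * K * Ew - larva_out * Lw,
    ])


@dataclass
class Trajectory:
    """An integrated solution: time grid, states and infection fractions.

    ``states`` has one row per time point in the :data:`STATE_NAMES` order.
    The dense solver output is retained per integration segment so that
    threshold-crossing times can be located to high precision.
    """

    times: np.ndarray
    states: np.ndarray
    segments: list = field(default_factory=list, repr=False)
    zero_denominator: bool = False

    @property
    def female_infected_fraction(self) -> np.ndarray:
        return _safe_fraction(self.states[:, 3], self.states[:, 2] + self.states[:, 3])

    @property
    def adult_infected_fraction(self) -> np.ndarray:
        adults = self.states[:, :4].sum(axis=1)
        return _safe_fraction(self.states[:, 1] + self.states[:, 3], adults)

    def value(self, t: float) -> np.ndarray:
        """Dense-output state at an arbitrary time inside the span."""
        for (t0, t1, sol) in self.segments:
            if t0 - 1e-9 <= t <= t1 + 1e-9:
                return sol(np.clip(t, t0, t1))
        raise ValueError(f"time {t} outside trajectory span "
                         f"[{self.times[0]}, {self.times[-1]}]")

    def fraction_at(self, t: float, metric: str = "female") -> float:
        y = self.value(t)
        if metric == "female":
            return female_infection_fraction(y)
        if metric == "adult":
            return adult_infection_fraction(y)
        raise ValueError(f"unknown metric {metric!r}")

    def final_state(self) -> State:
        return State.from_array(self.states[-1])

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: t, the eight compartments, the two fractions."""
        cols = {"t": self.times}
        for j, name in enumerate(("Mu", "Mw", "Fu", "Fw", "Eu", "Ew", "Lu", "Lw")):
            cols[name] = self.states[:, j]
        cols["frac_female"] = self.female_infected_fraction
        cols["frac_adult"] = self.adult_infected_fraction
        return pd.DataFrame(cols)


def _safe_fraction(num: np.ndarray, den: np.ndarray) -> np.ndarray:
    out = np.zeros_like(np.asarray(num, dtype=float))
    mask = np.asarray(den) > 0
    out[mask] = np.asarray(num)[mask] / np.asarray(den)[mask]
    return out


def female_infection_fraction(state) -> float:
    """``F_w / (F_u + F_w)``; 0 when no females exist."""
    y = state.to_array() if isinstance(state, State) else np.asarray(state, float)
    den = y[2] + y[3]
    return float(y[3] / den) if den > 0 else 0.0


def adult_infection_fraction(state) -> float:
    """``(F_w + M_w) / (F_u + F_w + M_u + M_w)``; 0 when no adults exist."""
    y = state.to_array() if isinstance(state, State) else np.asarray(state, float)
    den = y[:4].sum()
    return float((y[1] + y[3]) / den) if den > 0 else 0.0


def simulate(
    params: ModelParams,
    init: State | np.ndarray,
    t_end: float,
    forcing=None,
    impulses: Sequence[tuple[float, np.ndarray]] | None = None,
    t0: float = 0.0,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
    method: str = "LSODA",
    max_points_per_day: float = 1.0,
) -> Trajectory:
    """Integrate the system from ``t0`` to ``t_end``.

    Impulses — instantaneous additions to the state, used for releases of
    infected adults — are applied exactly: the integrator stops at each
    impulse time, the increment is added, and integration restarts.  This
    keeps the events sharp and reproducible instead of approximating them
    with stiff source terms.

    Parameters
    ----------
    params, init, t_end, t0 : model setup; ``t_end > t0`` required.
    forcing : SeasonalForcing, optional
        Time-varying carrying-capacity multiplier.
    impulses : sequence of (time, delta) pairs, optional
        ``delta`` is an 8-vector added to the state at ``time``.  Times must
        lie within ``[t0, t_end]``.
    rtol, atol : float
        Integrator tolerances (defaults 1e-8 / 1e-6 on the count scale).
    method : str
        Any stiff-capable ``solve_ivp`` method; LSODA by default.

    Returns
    -------
    Trajectory
        With dense output retained per segment.

    Raises
    ------
    IntegrationError
        On solver failure or if any component drops below
        ``-1e-6 * max(|init|)``.
    """
    if isinstance(init, State):
        init.validate(params)
        y = init.to_array()
    else:
        y = np.asarray(init, dtype=float).copy()
        State.from_array(y).validate(params)
    if not t_end > t0:
        raise ValueError("t_end must exceed t0")

    impulses = sorted(impulses or [], key=lambda item: item[0])
    for ti, _ in impulses:
        if not (t0 <= ti <= t_end):
            raise ValueError(f"impulse time {ti} outside [{t0}, {t_end}]")

    scale = max(float(np.max(np.abs(y))), 1.0)
    # apply impulses scheduled exactly at t0 before integrating
    pending = [(ti, d) for ti, d in impulses if ti > t0]
    for ti, d in impulses:
        if ti <= t0:
            y = y + np.asarray(d, dtype=float)

    breakpoints = [ti for ti, _ in pending] + [t_end]
    deltas = {ti: np.asarray(d, dtype=float) for ti, d in pending}

    times: list[np.ndarray] = []
    states: list[np.ndarray] = []
    segments = []
    t = t0
    for tb in breakpoints:
        if tb > t:
            n_eval = max(int(np.ceil((tb - t) * max_points_per_day)) + 1, 2)
            t_eval = np.linspace(t, tb, n_eval)
            sol = solve_ivp(
                rhs, (t, tb), y, args=(params, forcing), method=method,
                rtol=rtol, atol=atol, dense_output=True, t_eval=t_eval,
            )
            if not sol.success:
                raise IntegrationError(f"integration failed on [{t}, {tb}]: "
                                       f"{sol.message}")
            times.append(sol.t)
            states.append(sol.y.T)
            segments.append((t, tb, sol.sol))
            y = sol.y[:, -1].copy()
        if tb in deltas:
            y = y + deltas[tb]
            scale = max(scale, float(np.max(np.abs(y))))
        t = tb

    all_t = np.concatenate(times)
    all_y = np.vstack(states)
    if np.min(all_y) < -1e-6 * scale:
        raise IntegrationError(
            f"negative component beyond tolerance: min = {np.min(all_y):.3g}"
        )
    return Trajectory(times=all_t, states=all_y, segments=segments)
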