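"""Spatial operators for invasive cells and the time-stepping loop.

Invasive (I) cells migrate by two mechanisms:

* **Passive diffusion (PD)** — Fickian spread down the I-cell concentration
  gradient, faster along white-matter tracks: ``dI/dt = div(D grad I)`` with
  ``D = D0 * (1 + wm * (kappa_wm - 1))``.
* **Active transport (AT)** — bulk drift up the healthy-brain density
  gradient (toward oxygen and nutrients): flux ``J = gamma * I * grad(B)``.
  Where ``grad(B) = 0`` (uniform healthy brain) AT stops.

Both operators are discretised conservatively on faces of the grid with
zero flux across the brain-mask boundary (skin and bone are impermeable)
and across faces adjoining the necrotic core (dead tissue is not re-entered),
so the total I mass is invariant to round-off.  PD uses central (harmonic
face) fluxes; AT uses first-order donor-cell upwinding, trading accuracy
for guaranteed positivity at this grid scale.

The combined step applies, in order: local reactions, threshold
(angiogenesis) update, active transport, passive diffusion.  Operator
splitting differences are O(dt).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .domain_geometry import BrainDomain, seed_tumor
from .model_core import (ModelParameters, TissueState, reaction_step,
                         update_thresholds)
from .observables import SimulationResult, record_observables

__all__ = ["DiffusionField", "diffusion_field", "necrotic_region",
           "passive_diffusion_step", "active_transport_step", "stable_dt",
           "step", "run_simulation", "StabilityError"]

#: CFL safety factor applied by stable_dt
SAFETY = 0.9


class StabilityError(RuntimeError):
    """Raised when a transport step would violate its stability bound."""


@dataclass
class DiffusionField:
    """Per-cell passive-diffusion coefficient (length^2 / time).

    Zero outside the brain mask and inside the necrotic region, so invasive
    cells neither leave the brain nor re-enter the dead tumour core.
    """

    D: np.ndarray


def necrotic_region(state: TissueState, domain: BrainDomain,
                    params: ModelParameters) -> np.ndarray:
    """Boolean field: brain cells where >= ``necrosis_cutoff`` of the
    initial brain density has died."""
    dead = np.zeros(domain.shape, dtype=bool)
    m = domain.mask & (domain.B_init > 0)
    dead[m] = (domain.B_init[m] - state.B[m]) \
        >= params.necrosis_cutoff * domain.B_init[m]
    return dead


def diffusion_field(domain: BrainDomain, state: TissueState,
                    params: ModelParameters) -> DiffusionField:
    """White-matter-weighted diffusion coefficient with necrotic exclusion."""
    D = np.where(domain.mask,
                 params.D0 * (1.0 + domain.wm * (params.kappa_wm - 1.0)),
                 0.0)
    D[necrotic_region(state, domain, params)] = 0.0
    return DiffusionField(D=D)


# --------------------------------------------------------------------------
# Passive diffusion (conservative 5-point flux form)
# --------------------------------------------------------------------------

def _harmonic(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    s = a + b
    out = np.zeros_like(s)
    nz = s > 0
    out[nz] = 2.0 * a[nz] * b[nz] / s[nz]
    return out


def passive_diffusion_step(I: np.ndarray, D: DiffusionField | np.ndarray,
                           domain: BrainDomain, dt: float) -> np.ndarray:
    """One conservative explicit step of dI/dt = div(D grad I), in place.

    Face conductances are harmonic means of the adjacent cell coefficients,
    which vanishes whenever either side is impermeable (outside the mask or
    necrotic, where D = 0) — the zero-flux boundary comes for free.
    """
    Darr = D.D if isinstance(D, DiffusionField) else np.asarray(D)
    h2 = domain.h * domain.h
    dmax = float(Darr.max(initial=0.0))
    if dt * dmax / h2 > 0.25 + 1e-12:
        raise StabilityError(
            f"diffusion CFL violated: dt*D_max/h^2 = {dt * dmax / h2:.3f} "
            "> 0.25; reduce dt (see stable_dt)")

    # vertical faces between rows r and r+1; horizontal between cols c, c+1
    Dv = _harmonic(Darr[:-1, :], Darr[1:, :])
    Dh = _harmonic(Darr[:, :-1], Darr[:, 1:])
    Fv = Dv * (I[1:, :] - I[:-1, :]) / h2   # flux into row r from r+1
    Fh = Dh * (I[:, 1:] - I[:, :-1]) / h2

    I[:-1, :] += dt * Fv
    I[1:, :] -= dt * Fv
    I[:, :-1] += dt * Fh
    I[:, 1:] -= dt * Fh
    return I


# --------------------------------------------------------------------------
# Active transport (conservative donor-cell upwind advection)
# --------------------------------------------------------------------------

def active_transport_step(I: np.ndarray, B: np.ndarray, domain: BrainDomain,
                          params: ModelParameters, dt: float,
                          necrotic: np.ndarray | None = None) -> np.ndarray:
    """One conservative upwind step of dI/dt = -div(gamma * I * grad B).

    The drift velocity on each face is ``gamma`` times the across-face
    brain-density difference, pointing toward higher B; the donor cell
    supplies the mass.  Faces touching impermeable or necrotic cells carry
    no flux.
    """
    if params.gamma == 0.0:
        return I
    h = domain.h
    open_cell = domain.mask.copy()
    if necrotic is not None:
        open_cell &= ~necrotic

    # face velocities (positive = toward increasing index)
    vv = params.gamma * (B[1:, :] - B[:-1, :]) / h
    vh = params.gamma * (B[:, 1:] - B[:, :-1]) / h
    okv = open_cell[1:, :] & open_cell[:-1, :]
    okh = open_cell[:, 1:] & open_cell[:, :-1]
    vv = np.where(okv, vv, 0.0)
    vh = np.where(okh, vh, 0.0)

    vmax = max(np.abs(vv).max(initial=0.0), np.abs(vh).max(initial=0.0))
    if dt * vmax / h > 1.0 + 1e-12:
        raise StabilityError(
            f"advection CFL violated: dt*|v|_max/h = {dt * vmax / h:.3f} > 1; "
            "reduce dt (see stable_dt)")

    # donor-cell fluxes: v > 0 moves mass toward the higher-index cell
    Fv = np.where(vv > 0, vv * I[:-1, :], vv * I[1:, :]) / h
    Fh = np.where(vh > 0, vh * I[:, :-1], vh * I[:, 1:]) / h

    I[:-1, :] -= dt * Fv
    I[1:, :] += dt * Fv
    I[:, :-1] -= dt * Fh
    I[:, 1:] += dt * Fh
    return I


def stable_dt(params: ModelParameters, D_max: float, grad_B_max: float,
              h: float) -> float:
    """Largest admissible explicit time step for the transport operators.

    ``SAFETY * min(h^2 / (4 D_max), h / (gamma |grad B|_max))``, capped at
    the configured ``params.dt`` when both transport terms vanish (or in
    general — the configured dt is never exceeded).
    """
    if h <= 0:
        raise ValueError("h must be positive")
    bound = params.dt
    if D_max > 0:
        bound = min(bound, SAFETY * h * h / (4.0 * D_max))
    v = params.gamma * grad_B_max
    if v > 0:
        bound = min(bound, SAFETY * h / v)
    return bound


# --------------------------------------------------------------------------
# Full step and simulation loop
# --------------------------------------------------------------------------

def step(state: TissueState, domain: BrainDomain, params: ModelParameters,
         schedule=None, step_index: int = 0) -> TissueState:
    """Advance the state by one time step ``params.dt``.

    Order of operators: reactions -> threshold update (with the treatment
    schedule's AA flag and alpha multiplier) -> active transport (if
    ``gamma > 0``) -> passive diffusion (if ``D0 > 0``).
    """
    dt = params.dt
    if schedule is None:
        aa, mult = False, 1.0
    else:
        aa, mult = schedule.at(step_index)
    reaction_step(state, params, dt)
    update_thresholds(state, params, aa, dt, alpha_multiplier=mult)
    necro = None
    if params.gamma > 0 or params.D0 > 0:
        necro = necrotic_region(state, domain, params)
    if params.gamma > 0:
        active_transport_step(state.I, state.B, domain, params, dt,
                              necrotic=necro)
    if params.D0 > 0:
        D = np.where(domain.mask,
                     params.D0 * (1.0 + domain.wm * (params.kappa_wm - 1.0)),
                     0.0)
        D[necro] = 0.0
        passive_diffusion_step(state.I, D, domain, dt)
    state.t += dt
    return state


def run_simulation(domain: BrainDomain, params: ModelParameters,
                   schedule=None, n_steps: int = 5000,
                   record_every: int = 10,
                   seed_location: tuple[int, int] | None = None,
                   snapshot_every: int | None = None,
                   initial_state: TissueState | None = None
                   ) -> SimulationResult:
    """Run the model and return the recorded observable time series.

    Deterministic given its inputs (the dynamics contain no randomness).
    Observables are recorded at step 0 and every ``record_every`` steps
    thereafter (plus the final step); optional full state snapshots every
    ``snapshot_every`` steps.
    """
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    # validate dt against the worst-case stability bound up front:
    # D is bounded by D0*kappa_wm and |grad B| by B0/h (B only decreases).
    d_max = params.D0 * params.kappa_wm
    if params.dt > stable_dt(params, d_max, params.B0 / domain.h, domain.h):
        raise StabilityError(
            f"configured dt = {params.dt} exceeds the stability bound "
            f"{stable_dt(params, d_max, params.B0 / domain.h, domain.h):.4g}; "
            "reduce dt or the transport coefficients")

    state = (initial_state.copy() if initial_state is not None
             else seed_tumor(domain, seed_location, params))
    result = SimulationResult()
    record_observables(result, state, domain, params)
    if snapshot_every is not None:
        result.snapshots.append(state.copy())

    for k in range(n_steps):
        step(state, domain, params, schedule, k)
        if (k + 1) % record_every == 0 or (k + 1) == n_steps:
            record_observables(result, state, domain, params)
        if snapshot_every is not None and (k + 1) % snapshot_every == 0:
            result.snapshots.append(state.copy())

    result.final_state = state
    result.finalize()
    return result
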