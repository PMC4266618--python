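"""Local (per-grid-cell) kinetics of the go-or-grow glioblastoma model.

The tissue at every grid cell is described by four densities, all expressed
as fractions of a common carrying capacity:

* ``P`` — proliferative tumour cells (divide, do not move),
* ``I`` — invasive tumour cells (move, do not divide),
* ``B`` — healthy brain matter (does not divide or move),
* ``N`` — necrotic material (dead cells of any type).

Oxygen and nutrients are not modelled explicitly.  Instead the local
*hypoxic state* ``H`` is a monotone function of the total cell density
``C = P + I + B + N``: the more crowded a region, the less oxygen per cell.
Two spatially varying thresholds of ``H`` organise the kinetics:

* ``tau_h`` (hypoxic threshold) — above it mitosis slows and proliferative
  cells start switching to the invasive phenotype;
* ``tau_l`` (lethal threshold) — above it cells of every type begin to die,
  feeding the necrotic compartment.

Angiogenesis is modelled implicitly: wherever proliferative cells are
present, both thresholds drift upward toward their vascular ceilings
(``tau_h_cap``, ``tau_l_cap``), letting the tissue sustain a denser tumour.
Anti-angiogenic (AA) therapy suppresses that drift and relaxes the
thresholds back to their avascular baselines.

All rate shapes are monotone threshold responses and each sits behind a
single replaceable function: the hypoxia response and the two switch rates
use a configurable ramp profile (:data:`RAMP_FORMS`, piecewise linear by
default); the mitotic coefficient and the necrotic rate additionally offer
the forms discussed in their docstrings (``mitotic_form``,
``necrotic_form``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, fields, replace
from typing import Callable

import numpy as np

logger = logging.getLogger("gogrow")

__all__ = [
    "ModelParameters",
    "TissueState",
    "RAMP_FORMS",
    "total_density",
    "hypoxic_state",
    "mitotic_coefficient",
    "necrotic_rate",
    "switch_rate_PI",
    "switch_rate_IP",
    "update_thresholds",
    "reaction_step",
]


class ConfigError(ValueError):
    """Raised when parameter values violate the model's invariants."""


# --------------------------------------------------------------------------
# Replaceable ramp profiles
#
# A ramp maps a normalised coordinate x (0 at the lower threshold, 1 at the
# upper) to [0, 1], monotone non-decreasing, with ramp(0)=0 and ramp(1)=1.
# Every piecewise rate in the model is built from one of these, so an
# alternative response shape is a one-line configuration change.
# --------------------------------------------------------------------------

def _linear_ramp(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0)


def _smoothstep_ramp(x: np.ndarray) -> np.ndarray:
    x = np.clip(x, 0.0, 1.0)
    return x * x * (3.0 - 2.0 * x)


RAMP_FORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "linear": _linear_ramp,
    "smoothstep": _smoothstep_ramp,
}


@dataclass
class ModelParameters:
    """Kinetic, transport, angiogenesis and numerical constants.

    Rates are per unit model time; lengths are in grid-cell edge units;
    densities are fractions of carrying capacity (so dimensionless).
    Model time units are arbitrary, matching the dimensionless formulation.
    """

    #: maximal mitotic rate of P cells (1/time)
    M_max: float = 0.2
    #: maximal death rate of living cells under full anoxia (1/time)
    mu_max: float = 0.12
    #: maximal P -> I switch rate, reached at H = 1 (1/time)
    beta_PI: float = 0.2
    #: maximal I -> P switch rate, active in normoxia (1/time)
    beta_IP: float = 0.005
    #: base passive-diffusion coefficient of I cells in grey matter (len^2/time)
    D0: float = 0.015
    #: multiplier on D0 along white-matter tracks (dimensionless, >= 1)
    kappa_wm: float = 1.3
    #: active-transport coefficient: I-cell flux per unit grad(B) (len^2/time)
    gamma: float = 1.8
    #: angiogenic rate: threshold rise per unit P density (1/time)
    alpha: float = 2.0
    #: avascular hypoxic threshold
    tau_h0: float = 0.7
    #: avascular lethal threshold
    tau_l0: float = 0.85
    #: angiogenesis ceiling for tau_h
    tau_h_cap: float = 0.9
    #: angiogenesis ceiling for tau_l
    tau_l_cap: float = 0.97
    #: total density at which the hypoxic state saturates at 1
    C_ref: float = 1.0
    #: initial healthy-brain density inside the mask
    B0: float = 0.5
    #: fraction of initial brain dead that defines the necrotic region
    necrosis_cutoff: float = 0.90
    #: I density above which a cell counts as invaded
    invasion_cutoff: float = 1e-4
    #: P density above which a cell counts as enhancing on virtual MRI
    p_enh: float = 0.1
    #: P density above which a cell counts toward percent proliferation
    proliferation_cutoff: float = 1e-2
    #: P density seeded in the initial tumour cell
    p_seed: float = 1e-2
    #: I density seeded in the initial tumour cell
    i_seed: float = 1e-3
    #: time step of the explicit solver
    dt: float = 0.1
    #: relaxation rate of thresholds toward baseline under AA (inf = instant)
    relax_rate: float = math.inf
    #: name of the ramp profile used by the continuous piecewise rates
    ramp_form: str = "linear"
    #: shape of the mitotic response: "inverse" (reciprocal decay with a
    #: hard stop past tau_l) or "linear" (continuous ramp to 0 at tau_l)
    mitotic_form: str = "inverse"
    #: shape of the death response: "step" (rapid necrosis at mu_max as soon
    #: as H exceeds tau_l) or "linear" (ramp from 0 at tau_l to mu_max at 1)
    necrotic_form: str = "step"

    def __post_init__(self) -> None:
        self.validate()

    # ---- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.C_ref <= 0:
            raise ConfigError("C_ref must be positive")
        if not (0.0 < self.tau_h0 < self.tau_l0 <= self.tau_l_cap <= 1.0):
            raise ConfigError(
                "thresholds must satisfy 0 < tau_h0 < tau_l0 <= tau_l_cap <= 1 "
                f"(got tau_h0={self.tau_h0}, tau_l0={self.tau_l0}, "
                f"tau_l_cap={self.tau_l_cap})"
            )
        if not (self.tau_h0 <= self.tau_h_cap < self.tau_l_cap):
            raise ConfigError(
                "caps must satisfy tau_h0 <= tau_h_cap < tau_l_cap "
                f"(got tau_h_cap={self.tau_h_cap}, tau_l_cap={self.tau_l_cap})"
            )
        for name in ("M_max", "mu_max", "beta_PI", "beta_IP", "D0", "gamma",
                     "alpha", "relax_rate"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if self.kappa_wm < 1:
            raise ConfigError("kappa_wm must be >= 1 (white matter is faster)")
        if self.dt <= 0:
            raise ConfigError("dt must be positive")
        if self.B0 / self.C_ref >= self.tau_h0:
            raise ConfigError(
                "healthy tissue must be normoxic at start: require "
                f"H(B0) = {self.B0 / self.C_ref} < tau_h0 = {self.tau_h0}"
            )
        if self.ramp_form not in RAMP_FORMS:
            raise ConfigError(
                f"unknown ramp_form {self.ramp_form!r}; "
                f"choose from {sorted(RAMP_FORMS)}"
            )
        if self.mitotic_form not in ("inverse", "linear"):
            raise ConfigError(
                f"unknown mitotic_form {self.mitotic_form!r}; "
                "choose 'inverse' or 'linear'"
            )
        if self.necrotic_form not in ("step", "linear"):
            raise ConfigError(
                f"unknown necrotic_form {self.necrotic_form!r}; "
                "choose 'step' or 'linear'"
            )

    @property
    def ramp(self) -> Callable[[np.ndarray], np.ndarray]:
        return RAMP_FORMS[self.ramp_form]

    def with_(self, **kwargs) -> "ModelParameters":
        """A copy with some fields replaced (re-validated)."""
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class TissueState:
    """The simulator's evolving per-grid-cell state.

    All fields share one 2-D shape.  Densities are >= 0 everywhere, zero
    outside the brain mask; ``tau_h < tau_l`` pointwise; ``N`` never
    decreases in time.
    """

    P: np.ndarray
    I: np.ndarray
    B: np.ndarray
    N: np.ndarray
    tau_h: np.ndarray
    tau_l: np.ndarray
    t: float = 0.0

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.P, self.I, self.B, self.N,
                                    self.tau_h, self.tau_l)}
        if len(shapes) != 1:
            raise ValueError(f"state fields have mismatched shapes: {shapes}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.P.shape

    def copy(self) -> "TissueState":
        return TissueState(self.P.copy(), self.I.copy(), self.B.copy(),
                           self.N.copy(), self.tau_h.copy(),
                           self.tau_l.copy(), self.t)


# --------------------------------------------------------------------------
# Elementary fields
# --------------------------------------------------------------------------

def total_density(state: TissueState) -> np.ndarray:
    """Total cell density C = P + I + B + N (pointwise)."""
    return state.P + state.I + state.B + state.N


def hypoxic_state(C: np.ndarray, params: ModelParameters) -> np.ndarray:
    """Local hypoxic state H in [0, 1], increasing with crowding.

    H = ramp(C / C_ref): 0 in empty tissue, saturating at 1 when the total
    density reaches ``C_ref``.  Oxygen per cell is assumed inversely related
    to the total density, so H is a crowding proxy for hypoxia.
    """
    if params.C_ref <= 0:
        raise ConfigError("C_ref must be positive")
    return params.ramp(np.asarray(C) / params.C_ref)


def mitotic_coefficient(H: np.ndarray, tau_h: np.ndarray, tau_l: np.ndarray,
                        params: ModelParameters) -> np.ndarray:
    """Mitotic coefficient M(H): M_max in normoxia, 0 past the lethal threshold.

    P cells divide at M_max while ``H <= tau_h`` and stop entirely once
    ``H`` exceeds ``tau_l``.  In between, the default (``"inverse"``) shape
    decays reciprocally with the hypoxic state, ``M = M_max * tau_h / H``,
    staying positive up to and including ``tau_l``: proliferation persists
    right until the lethal threshold is crossed, which is what lets the
    tumour core outgrow its oxygen supply and turn necrotic in finite time.
    The alternative ``"linear"`` shape ramps continuously to 0 at ``tau_l``
    (no division exactly at the threshold, hence no necrosis onset from
    growth alone).
    """
    H = np.asarray(H)
    tau_h = np.asarray(tau_h)
    tau_l = np.asarray(tau_l)
    if np.any(tau_h >= tau_l):
        raise ValueError("invariant violated: tau_h >= tau_l somewhere")
    if params.mitotic_form == "linear":
        x = (H - tau_h) / (tau_l - tau_h)
        return params.M_max * (1.0 - params.ramp(x))
    decay = np.where(H > tau_h, tau_h / np.maximum(H, 1e-12), 1.0)
    return np.where(H > tau_l, 0.0, params.M_max * decay)


def necrotic_rate(H: np.ndarray, tau_l: np.ndarray,
                  params: ModelParameters) -> np.ndarray:
    """Death rate mu(H): 0 below the lethal threshold, mu_max past it.

    Crossing the lethal threshold activates rapid necrosis: the default
    (``"step"``) response dies at the full rate ``mu_max`` as soon as
    ``H > tau_l``.  Because dead material still occupies space (N counts
    toward the total density), death does not relieve the crowding that
    caused it, so a graded response proportional to the small excess over
    ``tau_l`` (the ``"linear"`` alternative, reaching ``mu_max`` at
    ``H = 1``) would leave tissue dying at a vanishing rate forever.
    Applied identically to P, I and B; dead material accumulates in N.
    """
    H = np.asarray(H)
    tau_l = np.asarray(tau_l)
    if params.necrotic_form == "linear":
        x = (H - tau_l) / np.maximum(1.0 - tau_l, 1e-12)
        return params.mu_max * params.ramp(x)
    return np.where(H > tau_l, params.mu_max, 0.0)


def switch_rate_PI(H: np.ndarray, tau_h: np.ndarray,
                   params: ModelParameters) -> np.ndarray:
    """P -> I phenotype-switch rate: silent in normoxia, beta_PI at H = 1."""
    tau_h = np.asarray(tau_h)
    x = (np.asarray(H) - tau_h) / np.maximum(1.0 - tau_h, 1e-12)
    return params.beta_PI * params.ramp(x)


def switch_rate_IP(H: np.ndarray, tau_h: np.ndarray, tau_l: np.ndarray,
                   params: ModelParameters) -> np.ndarray:
    """I -> P phenotype-switch rate: beta_IP in normoxia, 0 past tau_l.

    Invasive cells that reach low-density (nutrient-rich) tissue revert to
    the proliferative phenotype; under severe hypoxia they stay invasive.
    """
    tau_h = np.asarray(tau_h)
    tau_l = np.asarray(tau_l)
    x = (np.asarray(H) - tau_h) / (tau_l - tau_h)
    return params.beta_IP * (1.0 - params.ramp(x))


# --------------------------------------------------------------------------
# Threshold dynamics (angiogenesis / anti-angiogenic therapy)
# --------------------------------------------------------------------------

def update_thresholds(state: TissueState, params: ModelParameters,
                      aa_active: bool, dt: float,
                      alpha_multiplier: float = 1.0) -> None:
    """One explicit-Euler update of the threshold fields, in place.

    Without AA therapy both thresholds rise with the local proliferative
    density and saturate at their vascular ceilings:

        d(tau)/dt = alpha * P * (tau_cap - tau).

    Under AA therapy the angiogenic term is suppressed and the thresholds
    relax toward the avascular baselines (tau_h0, tau_l0) at ``relax_rate``
    (infinite rate = instant reset).  ``alpha_multiplier`` scales alpha,
    e.g. to emulate a transient vascular-normalisation window.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if params.tau_h_cap < params.tau_h0 or params.tau_l_cap < params.tau_l0:
        raise ConfigError("threshold caps must not be below initial values")
    if not aa_active:
        a = alpha_multiplier * params.alpha * state.P * dt
        state.tau_h += a * (params.tau_h_cap - state.tau_h)
        state.tau_l += a * (params.tau_l_cap - state.tau_l)
    else:
        if math.isinf(params.relax_rate):
            state.tau_h.fill(params.tau_h0)
            state.tau_l.fill(params.tau_l0)
        else:
            r = min(params.relax_rate * dt, 1.0)
            state.tau_h += r * (params.tau_h0 - state.tau_h)
            state.tau_l += r * (params.tau_l0 - state.tau_l)


# --------------------------------------------------------------------------
# Local reaction step
# --------------------------------------------------------------------------

_cap_warned = False


def reaction_step(state: TissueState, params: ModelParameters,
                  dt: float) -> TissueState:
    """One explicit-Euler update of the local kinetics, in place.

    Mitosis is the sole source term; phenotype switching and death are
    conservative transfers between compartments, so with ``M_max = 0`` the
    total density P+I+B+N is invariant to machine precision.  Per-cell
    outflows are capped at the available density so no field goes negative
    even for large ``dt`` (the event is logged once).
    """
    P, I, B, N = state.P, state.I, state.B, state.N
    C = P + I + B + N
    H = hypoxic_state(C, params)
    M = mitotic_coefficient(H, state.tau_h, state.tau_l, params)
    mu = necrotic_rate(H, state.tau_l, params)
    b_pi = switch_rate_PI(H, state.tau_h, params)
    b_ip = switch_rate_IP(H, state.tau_h, state.tau_l, params)

    # Cap total fractional outflow from each compartment at 1 per step.
    out_P = dt * (b_pi + mu)
    out_I = dt * (b_ip + mu)
    out_B = dt * mu
    cap = max(out_P.max(initial=0.0), out_I.max(initial=0.0),
              out_B.max(initial=0.0))
    if cap > 1.0:
        global _cap_warned
        if not _cap_warned:
            logger.warning(
                "reaction outflow exceeds available density "
                "(max fractional outflow %.3f > 1); capping. "
                "Consider a smaller dt.", cap)
            _cap_warned = True
        scale_P = np.minimum(1.0, 1.0 / np.maximum(out_P, 1e-300))
        scale_I = np.minimum(1.0, 1.0 / np.maximum(out_I, 1e-300))
        scale_B = np.minimum(1.0, 1.0 / np.maximum(out_B, 1e-300))
    else:
        scale_P = scale_I = scale_B = 1.0

    flow_PI = (dt * scale_P) * b_pi * P
    death_P = (dt * scale_P) * mu * P
    flow_IP = (dt * scale_I) * b_ip * I
    death_I = (dt * scale_I) * mu * I
    death_B = (dt * scale_B) * mu * B

    P += dt * M * P + flow_IP - flow_PI - death_P
    I += flow_PI - flow_IP - death_I
    B -= death_B
    N += death_P + death_I + death_B
    if cap > 1.0:  # exact-drain round-off can leave -1e-17-scale residues
        np.maximum(P, 0.0, out=P)
        np.maximum(I, 0.0, out=I)
        np.maximum(B, 0.0, out=B)
    return state
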