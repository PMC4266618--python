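"""Treatment scenarios and the matched-mass AT-vs-PD calibration.

Four scenarios are modelled:

* ``full`` — untreated, vascularised tumour (angiogenesis always on);
* ``aa`` — anti-angiogenic therapy from time 0 (e.g. bevacizumab given
  up front): the angiogenic threshold rise is suppressed for the whole run;
* ``treatment`` — the clinical sequence: untreated growth, AA applied over a
  step window (default [2500, 3500)), then lifted when the tumour acquires
  resistance — producing the characteristic rebound;
* ``normalization`` — transient vascular normalisation: the angiogenic rate
  is boosted for a short window at AA start, after which AA applies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .domain_geometry import BrainDomain
from .model_core import ModelParameters

__all__ = ["TreatmentSchedule", "make_schedule", "aa_active",
           "calibrate_matched_mass", "CalibrationError", "MODES"]

MODES = ("full", "aa", "treatment", "normalization")

#: default AA window of the treatment scenario (model steps)
DEFAULT_AA_START = 2500
DEFAULT_AA_STOP = 3500
#: default transient-normalisation boost
DEFAULT_BOOST_FACTOR = 2.0
DEFAULT_BOOST_WINDOW = 500


class CalibrationError(RuntimeError):
    """Raised when matched-mass calibration cannot bracket the target."""


@dataclass(frozen=True)
class TreatmentSchedule:
    """Which treatment applies at each time step.

    ``aa_start``/``aa_stop`` delimit the anti-angiogenic window in step
    indices (stop may be infinite).  During normalisation, ``boost_factor``
    multiplies the angiogenic rate for ``boost_window`` steps from
    ``aa_start`` before AA takes hold.
    """

    mode: str = "full"
    aa_start: int = DEFAULT_AA_START
    aa_stop: float = DEFAULT_AA_STOP
    boost_factor: float = DEFAULT_BOOST_FACTOR
    boost_window: int = DEFAULT_BOOST_WINDOW

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}, got {self.mode!r}")
        if self.mode == "treatment" and not self.aa_start < self.aa_stop:
            raise ValueError("treatment mode requires aa_start < aa_stop")
        if self.boost_factor < 1:
            raise ValueError("boost_factor must be >= 1")

    def at(self, step_index: int) -> tuple[bool, float]:
        """(AA active?, angiogenic-rate multiplier) at a step index."""
        return aa_active(self, step_index)


def make_schedule(mode: str = "full", **options) -> TreatmentSchedule:
    """Build a :class:`TreatmentSchedule` for a named scenario.

    * ``full``: AA never active.
    * ``aa``: AA active from step 0 onward.
    * ``treatment``: AA active on ``[aa_start, aa_stop)`` (default
      [2500, 3500)), angiogenesis before and after.
    * ``normalization``: angiogenic rate times ``boost_factor`` on
      ``[aa_start, aa_start + boost_window)``, AA active afterwards.
    """
    if mode == "aa":
        options.setdefault("aa_start", 0)
        options.setdefault("aa_stop", math.inf)
    elif mode == "normalization":
        options.setdefault("aa_stop", math.inf)
    return TreatmentSchedule(mode=mode, **options)


def aa_active(schedule: TreatmentSchedule, step_index: int
              ) -> tuple[bool, float]:
    """Pure function of (schedule, step index) -> (AA flag, alpha multiplier)."""
    if step_index < 0:
        raise ValueError("step_index must be >= 0")
    s = schedule
    if s.mode == "full":
        return False, 1.0
    if s.mode == "aa":
        return step_index >= s.aa_start, 1.0
    if s.mode == "treatment":
        return s.aa_start <= step_index < s.aa_stop, 1.0
    # normalization: transient boost, then AA
    if s.aa_start <= step_index < s.aa_start + s.boost_window:
        return False, s.boost_factor
    if step_index >= s.aa_start + s.boost_window:
        return True, 1.0
    return False, 1.0


# --------------------------------------------------------------------------
# Matched-mass calibration of AT-only vs PD-only
# --------------------------------------------------------------------------

def _final_P_mass(domain: BrainDomain, params: ModelParameters,
                  schedule, n_steps: int, record_every: int) -> float:
    from .spatial_solver import run_simulation
    res = run_simulation(domain, params, schedule=schedule, n_steps=n_steps,
                         record_every=record_every)
    return float(res.P_mass[-1])


def calibrate_matched_mass(domain: BrainDomain, params: ModelParameters,
                           transport_mode: str, reference_P_mass: float,
                           n_steps: int = 2000, tol: float = 0.05,
                           schedule=None, bracket: tuple[float, float] | None
                           = None, max_doublings: int = 12,
                           max_bisections: int = 40, record_every: int = 200
                           ) -> tuple[float, float]:
    """Calibrate the single transport coefficient of a one-mechanism model
    so its final proliferative mass matches a reference run.

    ``transport_mode='at'`` bisects the active-transport coefficient
    ``gamma`` with passive diffusion off; ``'pd'`` bisects ``D0`` with
    active transport off.  The response (final P mass vs the coefficient)
    is monotone non-decreasing on the synthetic brain, which underpins the
    bisection.  Returns ``(parameter, achieved_final_P_mass)`` with
    ``|achieved - reference| / reference <= tol``.
    """
    if transport_mode not in ("at", "pd"):
        raise ValueError("transport_mode must be 'at' or 'pd'")
    if reference_P_mass <= 0:
        raise ValueError("reference_P_mass must be positive")
    pname = "gamma" if transport_mode == "at" else "D0"
    zeroed = "D0" if transport_mode == "at" else "gamma"

    # largest coefficient the configured dt can integrate stably
    h = domain.h
    if transport_mode == "pd":
        v_cap = 0.9 * h * h / (4.0 * params.kappa_wm * params.dt)
    else:
        v_cap = 0.9 * h / (params.dt * max(params.B0 / h, 1e-12))

    def run(value: float) -> float:
        p = params.with_(**{pname: value, zeroed: 0.0})
        return _final_P_mass(domain, p, schedule, n_steps, record_every)

    if bracket is None:
        lo = 0.0
        hi = getattr(params, pname) or 1.0
    else:
        lo, hi = bracket
    m_lo, m_hi = run(lo), run(hi)

    def ok(m: float) -> bool:
        return abs(m - reference_P_mass) / reference_P_mass <= tol

    if ok(m_hi):
        return hi, m_hi
    if ok(m_lo):
        return lo, m_lo
    doublings = 0
    while m_hi < reference_P_mass:
        if doublings >= max_doublings or hi >= v_cap:
            raise CalibrationError(
                f"could not bracket reference P mass {reference_P_mass:.4g}: "
                f"{pname} in [{lo:.4g}, {hi:.4g}] gives masses "
                f"[{m_lo:.4g}, {m_hi:.4g}] "
                f"(doublings={doublings}, stability cap {v_cap:.4g})")
        lo, m_lo = hi, m_hi
        hi = min(max(hi * 2.0, 1e-6), v_cap)
        m_hi = run(hi)
        doublings += 1
        if ok(m_hi):
            return hi, m_hi
    if m_lo > reference_P_mass:
        raise CalibrationError(
            f"reference P mass {reference_P_mass:.4g} below the "
            f"{pname}={lo:.4g} response {m_lo:.4g}; no bracket exists")

    for _ in range(max_bisections):
        mid = 0.5 * (lo + hi)
        m_mid = run(mid)
        if ok(m_mid):
            return mid, m_mid
        if m_mid < reference_P_mass:
            lo, m_lo = mid, m_mid
        else:
            hi, m_hi = mid, m_mid
    raise CalibrationError(
        f"bisection on {pname} did not reach tolerance {tol} in "
        f"{max_bisections} iterations; last interval [{lo:.4g}, {hi:.4g}] "
        f"with masses [{m_lo:.4g}, {m_hi:.4g}]")
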