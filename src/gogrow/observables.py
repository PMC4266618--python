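"""Readouts of the simulator: masses, percent necrosis/invasion, layered
structure, cross-sections and virtual-MRI label maps.

Percentages are fractions of the brain mask (the full mask, including any
necrotic part, is the denominator throughout).  Masses integrate density
over area, ``sum(field) * h^2``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .domain_geometry import BrainDomain
from .model_core import ModelParameters, TissueState

__all__ = ["SimulationResult", "mass", "percent_necrosis", "percent_invasion",
           "percent_proliferation", "cross_section", "layer_radii",
           "virtual_mri", "record_observables", "MRI_LABELS"]


@dataclass
class SimulationResult:
    """Time series of the model's observables (plus optional snapshots)."""

    times: list = field(default_factory=list)
    P_mass: list = field(default_factory=list)
    I_mass: list = field(default_factory=list)
    pct_necrosis: list = field(default_factory=list)
    pct_invasion: list = field(default_factory=list)
    pct_proliferation: list = field(default_factory=list)
    snapshots: list = field(default_factory=list)
    final_state: TissueState | None = None

    _SERIES = ("times", "P_mass", "I_mass", "pct_necrosis", "pct_invasion",
               "pct_proliferation")

    def finalize(self) -> "SimulationResult":
        """Freeze the recorded series as numpy arrays."""
        for name in self._SERIES:
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        return self

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t": np.asarray(self.times),
            "P_mass": np.asarray(self.P_mass),
            "I_mass": np.asarray(self.I_mass),
            "pct_necrosis": np.asarray(self.pct_necrosis),
            "pct_invasion": np.asarray(self.pct_invasion),
            "pct_proliferation": np.asarray(self.pct_proliferation),
        })

    def to_csv(self, path: str | Path, header_lines: list[str] | None = None
               ) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for line in header_lines or []:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, index=False)


# --------------------------------------------------------------------------
# Scalar readouts
# --------------------------------------------------------------------------

def mass(field_arr: np.ndarray, domain: BrainDomain) -> float:
    """Total mass of a density field: sum over the mask times cell area."""
    return float(field_arr[domain.mask].sum() * domain.cell_area)


def percent_necrosis(state: TissueState, domain: BrainDomain,
                     params: ModelParameters) -> float:
    """Percent of brain cells where >= 90 % (``necrosis_cutoff``) of the
    initial brain density has died.  The boundary case counts as necrotic."""
    m = domain.mask & (domain.B_init > 0)
    if not m.any():
        return 0.0
    dead = (domain.B_init[m] - state.B[m]) \
        >= params.necrosis_cutoff * domain.B_init[m]
    return 100.0 * dead.sum() / domain.n_brain


def percent_invasion(state: TissueState, domain: BrainDomain,
                     params: ModelParameters) -> float:
    """Percent of brain cells with invasive density >= ``invasion_cutoff``."""
    inv = state.I[domain.mask] >= params.invasion_cutoff
    return 100.0 * inv.sum() / domain.n_brain


def percent_proliferation(state: TissueState, domain: BrainDomain,
                          params: ModelParameters) -> float:
    """Percent of brain cells with proliferative density >=
    ``proliferation_cutoff``."""
    pro = state.P[domain.mask] >= params.proliferation_cutoff
    return 100.0 * pro.sum() / domain.n_brain


def record_observables(result: SimulationResult, state: TissueState,
                       domain: BrainDomain, params: ModelParameters) -> None:
    """Append the current observables to a result-in-progress."""
    result.times.append(state.t)
    result.P_mass.append(mass(state.P, domain))
    result.I_mass.append(mass(state.I, domain))
    result.pct_necrosis.append(percent_necrosis(state, domain, params))
    result.pct_invasion.append(percent_invasion(state, domain, params))
    result.pct_proliferation.append(percent_proliferation(state, domain,
                                                          params))


# --------------------------------------------------------------------------
# Structure readouts
# --------------------------------------------------------------------------

def cross_section(state: TissueState, axis: int = 1, index: int | None = None
                  ) -> dict[str, np.ndarray]:
    """1-D profiles of P, I, B, N along a grid line.

    ``axis=0`` extracts row ``index`` (horizontal line); ``axis=1`` extracts
    column ``index`` (vertical line, the figure convention).  Default index
    is the central line.
    """
    ny, nx = state.shape
    if axis not in (0, 1):
        raise ValueError("axis must be 0 (row) or 1 (column)")
    if index is None:
        index = (nx // 2) if axis == 1 else (ny // 2)
    if axis == 0 and not 0 <= index < ny:
        raise IndexError(f"row index {index} out of range [0, {ny})")
    if axis == 1 and not 0 <= index < nx:
        raise IndexError(f"column index {index} out of range [0, {nx})")
    sel = (lambda f: f[index, :]) if axis == 0 else (lambda f: f[:, index])
    return {name: sel(getattr(state, name)).copy()
            for name in ("P", "I", "B", "N")}


class UndefinedStructureError(RuntimeError):
    """Raised when layer radii are requested but no tumour is present."""


def layer_radii(state: TissueState, domain: BrainDomain,
                params: ModelParameters,
                center: tuple[int, int] | None = None
                ) -> tuple[float, float, float]:
    """Radii of the tumour's three layers around ``center`` (the seed).

    Returns ``(r_necrosis, r_P_peak, r_I_peak)``:

    * ``r_necrosis`` — largest radius of any necrotic cell (0 if none),
    * ``r_P_peak`` — radius of the maximal azimuthally averaged P density,
    * ``r_I_peak`` — same for I.

    The expected multilayer ordering of a vascularised glioblastoma is
    ``r_necrosis < r_P_peak < r_I_peak``: necrotic core, proliferative rim,
    invasive margin.
    """
    if float(state.P[domain.mask].sum()) <= 0:
        raise UndefinedStructureError("no tumour present (P mass is zero)")
    if center is None:
        center = domain.center()
    rows, cols = np.nonzero(domain.mask)
    r = np.hypot(rows - center[0], cols - center[1]) * domain.h

    from .spatial_solver import necrotic_region
    necro = necrotic_region(state, domain, params)[domain.mask]
    r_necro = float(r[necro].max()) if necro.any() else 0.0

    bins = np.floor(r / domain.h).astype(int)
    nb = bins.max() + 1
    counts = np.bincount(bins, minlength=nb).astype(float)

    def peak_radius(f: np.ndarray) -> float:
        prof = np.bincount(bins, weights=f[domain.mask], minlength=nb) / counts
        return float(np.argmax(prof) * domain.h)

    return r_necro, peak_radius(state.P), peak_radius(state.I)


#: label codes of the virtual-MRI map
MRI_LABELS = {"normal": 0, "necrotic_core": 1, "enhancing_rim": 2,
              "flair_margin": 3}


def virtual_mri(state: TissueState, domain: BrainDomain,
                params: ModelParameters) -> np.ndarray:
    """Deterministic virtual-MRI label map of the current state.

    Mirrors the radiological reading of a glioblastoma: a necrotic core
    (>= ``necrosis_cutoff`` brain death), a contrast-enhancing rim
    (``P >= p_enh``), and a surrounding FLAIR-abnormal margin
    (``I >= invasion_cutoff``); everything else is normal brain.  Labels are
    mutually exclusive and exhaustive on the mask, with precedence
    core > rim > margin.
    """
    from .spatial_solver import necrotic_region
    labels = np.zeros(domain.shape, dtype=np.uint8)
    core = necrotic_region(state, domain, params)
    rim = domain.mask & (state.P >= params.p_enh) & ~core
    margin = domain.mask & (state.I >= params.invasion_cutoff) & ~core & ~rim
    labels[core] = MRI_LABELS["necrotic_core"]
    labels[rim] = MRI_LABELS["enhancing_rim"]
    labels[margin] = MRI_LABELS["flair_margin"]
    return labels
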