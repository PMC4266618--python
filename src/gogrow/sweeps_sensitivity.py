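"""Parameter-pair sensitivity sweeps and the necrosis-invasion association.

A sweep varies a pair of kinetic/transport parameters over small grids,
runs the model to a fixed horizon for every combination, and tabulates
Percent Proliferation, Percent Necrosis and Percent Invasion.  Across such
sweeps the model predicts a positive (rank) association between the area of
necrosis and the area of brain invasion — the association later sought in
patient images.

The default sweep is deliberately reduced (3-point grids per parameter,
64x64 phantom, 1500 steps) so it runs in seconds; pass explicit grids,
``shape`` and ``horizon_steps`` for full-scale sweeps.
"""

from __future__ import annotations

from dataclasses import fields

import numpy as np
import pandas as pd
from scipy import stats

from .domain_geometry import BrainDomain, synthetic_brain
from .model_core import ModelParameters
from .spatial_solver import run_simulation

__all__ = ["parameter_sweep", "default_sweep", "necrosis_invasion_association",
           "SWEEPABLE", "DEFAULT_PAIRS"]

#: parameters swept in the model's sensitivity analysis
SWEEPABLE = ("beta_PI", "beta_IP", "gamma", "D0", "M_max", "mu_max",
             "alpha", "tau_h0")

#: default parameter pairs (each swept jointly on a small grid)
DEFAULT_PAIRS = (("beta_PI", "beta_IP"), ("gamma", "D0"),
                 ("M_max", "mu_max"), ("alpha", "tau_h0"))


def _param_names() -> set[str]:
    return {f.name for f in fields(ModelParameters)}


def parameter_sweep(domain: BrainDomain, base_params: ModelParameters,
                    pair: tuple[str, str],
                    grids: tuple[np.ndarray, np.ndarray],
                    horizon_steps: int = 3000, schedule=None,
                    record_every: int = 500) -> pd.DataFrame:
    """Run the model over a grid of one parameter pair.

    Returns one row per grid point with columns ``param1, value1, param2,
    value2, pct_proliferation, pct_necrosis, pct_invasion, error`` (the
    metrics at the horizon).  Failed runs keep their row with NaN metrics
    and the error message in ``error``; nothing is dropped silently.
    """
    valid = _param_names()
    for name in pair:
        if name not in valid:
            raise ValueError(
                f"unknown parameter {name!r}; valid names: {sorted(valid)}")
    g1, g2 = (np.atleast_1d(np.asarray(g, dtype=float)) for g in grids)
    if g1.size == 0 or g2.size == 0:
        raise ValueError("sweep grids must be non-empty")

    rows = []
    for v1 in g1:
        for v2 in g2:
            row = {"param1": pair[0], "value1": v1,
                   "param2": pair[1], "value2": v2,
                   "pct_proliferation": np.nan, "pct_necrosis": np.nan,
                   "pct_invasion": np.nan, "error": ""}
            try:
                p = base_params.with_(**{pair[0]: v1, pair[1]: v2})
                res = run_simulation(domain, p, schedule=schedule,
                                     n_steps=horizon_steps,
                                     record_every=record_every)
                row["pct_proliferation"] = res.pct_proliferation[-1]
                row["pct_necrosis"] = res.pct_necrosis[-1]
                row["pct_invasion"] = res.pct_invasion[-1]
            except Exception as exc:  # recorded, not dropped
                row["error"] = f"{type(exc).__name__}: {exc}"
            rows.append(row)
    return pd.DataFrame(rows)


def default_sweep(seed: int = 0, shape: tuple[int, int] = (64, 64),
                  horizon_steps: int = 1500, n_grid: int = 3,
                  pairs: tuple[tuple[str, str], ...] = DEFAULT_PAIRS,
                  base_params: ModelParameters | None = None,
                  span: float = 4.0) -> pd.DataFrame:
    """The reduced default sensitivity sweep on the synthetic brain.

    Each pair in ``pairs`` is swept over ``n_grid`` log-spaced values from
    base/``span`` to base*``span`` (thresholds are varied additively within
    their admissible range instead).  Returns the concatenated sweep table.
    """
    base = base_params or ModelParameters()
    domain = synthetic_brain(shape=shape, seed=seed)

    def grid_for(name: str) -> np.ndarray:
        v = getattr(base, name)
        if name == "tau_h0":
            # keep H(B0) < tau_h0 < tau_l0
            lo = max(base.B0 / base.C_ref + 0.02, v - 0.1)
            hi = min(base.tau_l0 - 0.02, v + 0.1)
            return np.linspace(lo, hi, n_grid)
        if v == 0:
            return np.linspace(0.0, 1.0, n_grid)
        return np.geomspace(v / span, v * span, n_grid)

    tables = []
    for pair in pairs:
        tables.append(parameter_sweep(
            domain, base, pair, (grid_for(pair[0]), grid_for(pair[1])),
            horizon_steps=horizon_steps))
    return pd.concat(tables, ignore_index=True)


def necrosis_invasion_association(table: pd.DataFrame) -> float:
    """Spearman rank correlation of percent necrosis vs percent invasion
    across sweep rows (ties mid-ranked; failed runs excluded)."""
    ok = table[["pct_necrosis", "pct_invasion"]].dropna()
    if len(ok) < 3:
        raise ValueError("need at least 3 rows with finite metrics")
    rho = stats.spearmanr(ok["pct_necrosis"], ok["pct_invasion"]).statistic
    return float(rho)
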