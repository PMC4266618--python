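"""Brain-domain construction: raster import, synthetic phantom, tumour seeding.

The simulation domain is a 2-D raster (default 127x127) in which each cell
is either brain tissue or impermeable surroundings (skin, bone, background).
Inside the brain, a white-matter fraction field ``wm`` in [0, 1] modulates
passive diffusion, reflecting the faster migration of glioma cells along
axon bundles.

Raster convention: row-major, origin at the top-left; cell ``(0, 0)`` is the
first pixel of the image.  Coordinates are ``(row, col)`` throughout.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .model_core import ModelParameters, TissueState

__all__ = ["BrainDomain", "load_brain_slice", "synthetic_brain",
           "seed_tumor", "DomainError"]


class DomainError(ValueError):
    """Raised for inconsistent rasters, labels or seed locations."""


@dataclass
class BrainDomain:
    """Static geometry of a brain slice.

    ``mask`` is True inside brain tissue; ``wm`` is the white-matter
    fraction (0 = grey matter, 1 = white-matter track); ``B_init`` is the
    initial healthy-brain density; ``h`` is the cell edge length.  ``wm``
    and ``B_init`` are zero outside the mask.
    """

    mask: np.ndarray
    wm: np.ndarray
    B_init: np.ndarray
    h: float = 1.0

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        self.wm = np.asarray(self.wm, dtype=float)
        self.B_init = np.asarray(self.B_init, dtype=float)
        if not (self.mask.shape == self.wm.shape == self.B_init.shape):
            raise DomainError("mask, wm and B_init must share one shape")
        if self.h <= 0:
            raise DomainError("cell edge length h must be positive")
        outside = ~self.mask
        if np.any(self.wm[outside] != 0) or np.any(self.B_init[outside] != 0):
            raise DomainError("wm and B_init must vanish outside the mask")
        if np.any((self.wm < 0) | (self.wm > 1)):
            raise DomainError("white-matter fraction must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_brain(self) -> int:
        return int(self.mask.sum())

    @property
    def cell_area(self) -> float:
        return self.h * self.h

    def center(self) -> tuple[int, int]:
        """The brain cell closest to the mask's centroid."""
        rows, cols = np.nonzero(self.mask)
        cr, cc = rows.mean(), cols.mean()
        k = np.argmin((rows - cr) ** 2 + (cols - cc) ** 2)
        return int(rows[k]), int(cols[k])

    # ---- round-trip CSV export/import ------------------------------------
    def to_csv(self, directory: str | Path) -> None:
        """Export mask / wm / B_init as plain CSV grids (plus h)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savetxt(directory / "mask.csv", self.mask.astype(int),
                   fmt="%d", delimiter=",")
        np.savetxt(directory / "wm.csv", self.wm, delimiter=",")
        np.savetxt(directory / "B_init.csv", self.B_init, delimiter=",")
        (directory / "h.csv").write_text(f"{self.h!r}\n")

    @classmethod
    def from_csv(cls, directory: str | Path) -> "BrainDomain":
        directory = Path(directory)
        mask = np.loadtxt(directory / "mask.csv", delimiter=",").astype(bool)
        wm = np.loadtxt(directory / "wm.csv", delimiter=",")
        B_init = np.loadtxt(directory / "B_init.csv", delimiter=",")
        h = float((directory / "h.csv").read_text().strip())
        return cls(mask=mask, wm=wm, B_init=B_init, h=h)


# --------------------------------------------------------------------------
# Raster import
# --------------------------------------------------------------------------

#: default interpretation of anatomical labels: value is either the string
#: "outside" (impermeable) or a white-matter fraction in [0, 1].
DEFAULT_LABEL_MAP: dict[int, str | float] = {
    0: "outside",   # background
    1: "outside",   # skin
    2: "outside",   # bone / skull
    3: 0.0,         # grey matter
    4: 1.0,         # white matter
}


def _read_raster(raster: str | Path | np.ndarray) -> np.ndarray:
    if isinstance(raster, (str, Path)):
        path = Path(raster)
        if path.suffix.lower() == ".csv":
            with open(path, newline="") as fh:
                rows = [[int(float(v)) for v in row]
                        for row in csv.reader(fh) if row]
            return np.asarray(rows, dtype=int)
        import imageio.v3 as iio
        img = iio.imread(path)
        if img.ndim == 3:  # collapse identical RGB channels
            img = img[..., 0]
        return np.asarray(img, dtype=int)
    arr = np.asarray(raster)
    if arr.ndim != 2:
        raise DomainError(f"raster must be 2-D, got shape {arr.shape}")
    return arr.astype(int)


def load_brain_slice(raster: str | Path | np.ndarray,
                     label_map: dict[int, str | float] | None = None,
                     params: ModelParameters | None = None,
                     h: float = 1.0) -> BrainDomain:
    """Build a :class:`BrainDomain` from a labelled raster image.

    ``label_map`` maps each raster label either to ``"outside"``
    (background / skin / bone, impermeable to tumour cells) or to a
    white-matter fraction in [0, 1].  Unknown labels raise a
    :class:`DomainError` naming the offending label.
    """
    params = params or ModelParameters()
    label_map = DEFAULT_LABEL_MAP if label_map is None else label_map
    labels = _read_raster(raster)

    present = np.unique(labels)
    unknown = [int(v) for v in present if int(v) not in label_map]
    if unknown:
        raise DomainError(
            f"unknown raster label(s) {unknown}; "
            f"label_map covers {sorted(label_map)}")

    mask = np.zeros(labels.shape, dtype=bool)
    wm = np.zeros(labels.shape, dtype=float)
    for lab, meaning in label_map.items():
        where = labels == lab
        if isinstance(meaning, str):
            if meaning != "outside":
                raise DomainError(
                    f"label {lab}: unknown meaning {meaning!r} "
                    "(expected 'outside' or a white-matter fraction)")
            continue
        frac = float(meaning)
        if not (0.0 <= frac <= 1.0):
            raise DomainError(
                f"label {lab}: white-matter fraction {frac} outside [0, 1]")
        mask |= where
        wm[where] = frac

    if not mask.any():
        raise DomainError("no brain tissue: every raster label maps outside")
    B_init = np.where(mask, params.B0, 0.0)
    return BrainDomain(mask=mask, wm=wm, B_init=B_init, h=h)


# --------------------------------------------------------------------------
# Synthetic brain phantom
# --------------------------------------------------------------------------

def synthetic_brain(shape: tuple[int, int] = (127, 127), seed: int = 0,
                    params: ModelParameters | None = None,
                    h: float = 1.0) -> BrainDomain:
    """A deterministic elliptical brain phantom with white-matter tracks.

    Emulates the geometry of a single axial slice: an elliptical brain
    bounded by an impermeable rim (skin/bone), containing 2-4 curved
    white-matter bands.  The brain covers 30-70 % of the grid.  The phantom
    is fully determined by ``seed``.
    """
    ny, nx = shape
    if ny < 32 or nx < 32:
        raise DomainError("synthetic brain needs a grid of at least 32x32")
    params = params or ModelParameters()
    rng = np.random.default_rng(seed)

    rows, cols = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    # semi-axes jittered a little per seed; area fraction pi*a*b stays
    # comfortably inside [0.3, 0.7] of the grid
    a = (0.40 + 0.04 * rng.random()) * ny / 2 * 2  # rows semi-axis in cells
    b = (0.34 + 0.04 * rng.random()) * nx / 2 * 2  # cols semi-axis in cells
    mask = ((rows - cy) / a) ** 2 + ((cols - cx) / b) ** 2 <= 1.0

    wm = np.zeros(shape)
    n_tracks = int(rng.integers(2, 5))
    x = np.arange(nx)
    for k in range(n_tracks):
        offset = cy + (k - (n_tracks - 1) / 2) * a / (n_tracks + 0.5) * 1.2
        amp = rng.uniform(0.05, 0.18) * ny
        freq = rng.uniform(0.8, 1.6)
        phase = rng.uniform(0, 2 * np.pi)
        width = rng.uniform(0.015, 0.035) * ny + 1.0
        curve = offset + amp * np.sin(2 * np.pi * freq * x / nx + phase)
        dist = np.abs(rows - curve[None, :])
        wm[dist <= width] = 1.0
    wm[~mask] = 0.0

    B_init = np.where(mask, params.B0, 0.0)
    return BrainDomain(mask=mask, wm=wm, B_init=B_init, h=h)


# --------------------------------------------------------------------------
# Tumour seeding
# --------------------------------------------------------------------------

def seed_tumor(domain: BrainDomain, location: tuple[int, int] | None = None,
               params: ModelParameters | None = None) -> TissueState:
    """Initial tissue state with tumour seeded in a single grid cell.

    ``P = p_seed`` and ``I = i_seed`` at exactly one cell (default: the
    domain centre), healthy brain everywhere inside the mask, no necrosis,
    thresholds at their avascular baselines.
    """
    params = params or ModelParameters()
    if location is None:
        location = domain.center()
    r, c = int(location[0]), int(location[1])
    if not (0 <= r < domain.shape[0] and 0 <= c < domain.shape[1]) \
            or not domain.mask[r, c]:
        raise DomainError(f"seed location {location} is outside the brain mask")
    shape = domain.shape
    P = np.zeros(shape)
    I = np.zeros(shape)
    P[r, c] = params.p_seed
    I[r, c] = params.i_seed
    B = domain.B_init.copy()
    N = np.zeros(shape)
    tau_h = np.full(shape, params.tau_h0)
    tau_l = np.full(shape, params.tau_l0)
    return TissueState(P=P, I=I, B=B, N=N, tau_h=tau_h, tau_l=tau_l, t=0.0)
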