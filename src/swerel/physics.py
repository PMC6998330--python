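"""Shear-wave physics conversions and Q-box region-of-interest means.

Elastography scanners measure the shear-wave propagation speed *v*
(m/s) and report tissue stiffness as the shear modulus mu = rho * v^2,
with the tissue density rho conventionally fixed at 1000 kg/m^3 for
soft tissue.  With v in m/s and rho in kg/m^3, rho*v^2 is in Pa; the
functions below return kPa, the unit clinical elastography reports.

The Q-box is a freehand region of interest drawn over the muscle belly
on the stiffness map; the reported value is the arithmetic mean of the
pixels inside it.  Masks are pixel-boolean (a rasterised approximation
of the freehand trace) and can be round-tripped through a plain-text
run-length encoding for storage next to the map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import ElastogramMap

DEFAULT_DENSITY_KG_M3 = 1000.0


def modulus_from_velocity(v: float, rho: float = DEFAULT_DENSITY_KG_M3) -> float:
    """Shear modulus (kPa) from shear-wave speed (m/s): mu = rho*v^2."""
    if v < 0:
        raise ValueError("shear-wave speed must be non-negative")
    if rho <= 0:
        raise ValueError("density must be positive")
    return rho * v * v / 1000.0


def velocity_from_modulus(mu: float, rho: float = DEFAULT_DENSITY_KG_M3) -> float:
    """Shear-wave speed (m/s) from shear modulus (kPa): v = sqrt(mu/rho)."""
    if mu < 0:
        raise ValueError("shear modulus must be non-negative")
    if rho <= 0:
        raise ValueError("density must be positive")
    return float(np.sqrt(1000.0 * mu / rho))


@dataclass
class RoiMask:
    """Boolean pixel mask congruent with an elastogram grid."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not self.mask.any():
            raise ValueError("mask must select at least one pixel")

    @property
    def n_pixels(self) -> int:
        return int(self.mask.sum())

    def to_rle(self) -> str:
        """Row-major run-length encoding: 'rows cols v0 n0 n1 n2 ...'.

        ``v0`` is the first run's value (0/1); runs alternate.
        """
        flat = self.mask.ravel().astype(np.int8)
        change = np.flatnonzero(np.diff(flat)) + 1
        bounds = np.concatenate([[0], change, [flat.size]])
        runs = np.diff(bounds)
        head = f"{self.mask.shape[0]} {self.mask.shape[1]} {int(flat[0])}"
        return head + " " + " ".join(str(int(r)) for r in runs)

    @classmethod
    def from_rle(cls, text: str) -> "RoiMask":
        parts = text.split()
        rows, cols, v0 = int(parts[0]), int(parts[1]), int(parts[2])
        runs = [int(p) for p in parts[3:]]
        flat = np.empty(rows * cols, dtype=bool)
        pos, val = 0, bool(v0)
        for run in runs:
            flat[pos : pos + run] = val
            pos += run
            val = not val
        if pos != rows * cols:
            raise ValueError("run lengths do not cover the grid")
        return cls(flat.reshape(rows, cols))


def roi_mean(elastogram: ElastogramMap, roi: RoiMask) -> float:
    """Mean shear modulus (kPa) over the masked Q-box pixels."""
    if roi.mask.shape != elastogram.grid.shape:
        raise ValueError(
            f"mask shape {roi.mask.shape} does not match grid {elastogram.grid.shape}"
        )
    values = elastogram.grid[roi.mask]
    return float(values.sum() / values.size)
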