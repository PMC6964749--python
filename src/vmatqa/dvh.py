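"""Cumulative DVHs and plan-quality metrics (Dx, Vx, Dmean, HI, CI).

D_x is the minimum dose received by the hottest x% of a structure's volume
(linear interpolation on the cumulative curve); V_d is the percent volume
receiving at least d.  The homogeneity index follows the ICRU 83 definition
HI = (D2 - D98) / D50 and the conformity index the ICRU 62 style
CI = (body volume at or above the prescription dose) / (PTV volume); both
formulas are switchable via the ``formula`` arguments.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .grids import DoseGrid, StructureMask

__all__ = [
    "DVHCurve",
    "compute_dvh",
    "dvh_D",
    "dvh_V",
    "homogeneity_index",
    "conformity_index",
    "renormalize_to_d95",
    "mean_min_max",
    "structure_doses",
]


@dataclass
class DVHCurve:
    """Cumulative DVH: fraction of volume receiving >= each bin-edge dose."""

    dose_edges: np.ndarray       # Gy, uniform spacing, starting at 0
    cumulative: np.ndarray       # relative volume in [0, 1], non-increasing

    def __post_init__(self) -> None:
        self.dose_edges = np.asarray(self.dose_edges, float)
        self.cumulative = np.asarray(self.cumulative, float)
        if self.dose_edges.shape != self.cumulative.shape:
            raise ValueError("edges and cumulative arrays must align")
        if self.cumulative[0] != 1.0:
            raise ValueError("cumulative volume must start at 1 at 0 Gy")
        if np.any(np.diff(self.cumulative) > 1e-12):
            raise ValueError("cumulative volume must be non-increasing")

    @property
    def bin_width(self) -> float:
        return float(self.dose_edges[1] - self.dose_edges[0])

    def mean_dose(self) -> float:
        """Quadrature mean: integral of the cumulative curve over dose."""
        return float(np.trapezoid(self.cumulative, self.dose_edges))


def structure_doses(grid: DoseGrid, mask: StructureMask) -> np.ndarray:
    if mask.mask.shape != grid.values.shape:
        raise ValueError("mask shape must match dose grid")
    if mask.n_voxels == 0:
        raise ValueError(f"structure {mask.name!r} is empty")
    return grid.values[mask.mask]


def compute_dvh(grid: DoseGrid, mask: StructureMask, bin_width: float = 0.1) -> DVHCurve:
    doses = structure_doses(grid, mask)
    n_bins = int(np.ceil(doses.max() / bin_width)) + 2
    edges = bin_width * np.arange(n_bins)
    # fraction receiving >= edge; doses exactly at an edge count as receiving it
    counts = np.searchsorted(np.sort(doses), edges - 1e-12, side="left")
    cumulative = 1.0 - counts / doses.size
    return DVHCurve(edges, cumulative)


def dvh_D(curve: DVHCurve, x: float) -> float:
    """Minimum dose (Gy) received by the hottest x% of the volume."""
    if not 0.0 < x <= 100.0:
        raise ValueError("volume level must be in (0, 100]")
    q = x / 100.0
    cum, edges = curve.cumulative, curve.dose_edges
    below = np.nonzero(cum < q - 1e-15)[0]
    if below.size == 0:
        return float(edges[-1])
    i = int(below[0])
    if i == 0:
        return float(edges[0])
    c0, c1 = cum[i - 1], cum[i]
    return float(edges[i - 1] + (c0 - q) / (c0 - c1) * (edges[i] - edges[i - 1]))


def dvh_V(curve: DVHCurve, d: float) -> float:
    """Percent of the volume receiving >= d Gy."""
    if d > curve.dose_edges[-1]:
        return 0.0
    return 100.0 * float(np.interp(d, curve.dose_edges, curve.cumulative))


def homogeneity_index(curve: DVHCurve, formula: str = "icru83") -> float:
    """ICRU 83: (D2 - D98) / D50; 'ratio' alternative: D2 / D98."""
    d2, d50, d98 = dvh_D(curve, 2), dvh_D(curve, 50), dvh_D(curve, 98)
    if formula == "icru83":
        return (d2 - d98) / d50
    if formula == "ratio":
        return d2 / d98
    raise ValueError(f"unknown HI formula {formula!r}")


def conformity_index(grid: DoseGrid, ptv_mask: StructureMask,
                     body_mask: StructureMask, rx: float,
                     formula: str = "icru62") -> float:
    """Prescription-isodose volume (within the body) over PTV volume."""
    if formula != "icru62":
        raise ValueError(f"unknown CI formula {formula!r}")
    if ptv_mask.n_voxels == 0:
        raise ValueError("PTV mask is empty")
    isodose = int(np.sum(body_mask.mask & (grid.values >= rx)))
    return isodose / ptv_mask.n_voxels


def renormalize_to_d95(grid: DoseGrid, ptv_mask: StructureMask,
                       target: float = 76.0) -> DoseGrid:
    """Uniformly rescale so 95% of the PTV receives the target dose."""
    doses = structure_doses(grid, ptv_mask)
    if doses.max() <= 0:
        raise ValueError("PTV receives no dose; cannot renormalize")
    d95 = dvh_D(compute_dvh(grid, ptv_mask, bin_width=0.001), 95)
    if d95 <= 0:
        raise ValueError("PTV D95 is zero; cannot renormalize")
    return grid.scaled(target / d95)


def mean_min_max(grid: DoseGrid, mask: StructureMask) -> tuple[float, float, float]:
    """(Dmean, Dmin, Dmax) on voxel values directly (not DVH-interpolated)."""
    doses = structure_doses(grid, mask)
    return float(doses.mean()), float(doses.min()), float(doses.max())
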