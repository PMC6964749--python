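"""Gamma-index comparison of 2D dose planes.

For each reference point r above the low-dose threshold,

    gamma(r) = min over evaluated positions e of
               sqrt( |e - r|^2 / dta^2  +  (D_eval(e) - D_ref(r))^2 / dD^2 )

where ``dta`` is the distance-to-agreement criterion (mm) and ``dD`` the dose
difference criterion: under *global* normalization a fixed fraction of the
normalization dose (reference-plane maximum by default), under *local* the
same fraction of the reference dose at r.  gamma <= 1 passes; the passing
rate (GPR) is the percentage of evaluated points passing.

The minimization samples the evaluated plane bilinearly on a subgrid of
spacing <= dta / subgrid_factor within a disk of radius gamma_cap * dta;
points whose best achievable value exceeds ``gamma_cap`` are reported as
``gamma_cap``.  ``brute_force_gamma`` is an independent dense-grid oracle
used to validate the fast path.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace
from typing import Literal

import numpy as np

from .grids import DosePlane

__all__ = [
    "GammaCriteria",
    "GammaResult",
    "compute_gamma_map",
    "brute_force_gamma",
    "gamma_passing_rate",
    "apply_low_dose_threshold",
    "align_planes",
    "tg218_presets",
]


@dataclass(frozen=True)
class GammaCriteria:
    """One %DD / DTA criteria set."""

    dd_percent: float
    dta_mm: float
    normalization: Literal["global", "local"] = "global"
    threshold_fraction: float = 0.10
    gamma_cap: float = 2.0
    # annotations (informational): TG-218 style tolerance/action GPR limits
    tolerance_gpr: float | None = None
    action_gpr: float | None = None

    def __post_init__(self) -> None:
        if self.dd_percent <= 0 or self.dta_mm <= 0:
            raise ValueError("dose-difference and DTA criteria must be positive")
        if not 0.0 <= self.threshold_fraction < 1.0:
            raise ValueError("threshold_fraction must be in [0, 1)")
        if self.normalization not in ("global", "local"):
            raise ValueError("normalization must be 'global' or 'local'")

    @property
    def label(self) -> str:
        dd = f"{self.dd_percent:g}"
        dta = f"{self.dta_mm:g}"
        return f"{dd}%/{dta}mm {self.normalization}"


@dataclass
class GammaResult:
    gamma_map: np.ndarray          # NaN below threshold / outside detector mask
    passing_rate: float            # percent; NaN when nothing evaluated
    n_evaluated: int
    applied_shift: tuple[float, float] = (0.0, 0.0)

    @property
    def undefined(self) -> bool:
        return self.n_evaluated == 0


def apply_low_dose_threshold(reference: DosePlane, fraction: float,
                             normalization_dose: float | None = None) -> np.ndarray:
    """Mask of reference points with dose strictly above fraction * norm dose."""
    norm = reference.values.max() if normalization_dose is None else normalization_dose
    return reference.values > fraction * norm


def _evaluation_mask(reference: DosePlane, criteria: GammaCriteria,
                     normalization_dose: float) -> np.ndarray:
    mask = apply_low_dose_threshold(reference, criteria.threshold_fraction,
                                    normalization_dose)
    if reference.detector_mask is not None:
        mask &= reference.detector_mask
    return mask


def _check_overlap(reference: DosePlane, evaluated: DosePlane) -> None:
    rx = reference.extent()
    ex = evaluated.extent()
    if rx[1] < ex[0] or ex[1] < rx[0] or rx[3] < ex[2] or ex[3] < rx[2]:
        raise ValueError("reference and evaluated planes do not overlap spatially")


def _normalization_dose(reference: DosePlane, evaluated: DosePlane,
                        mode: str) -> float:
    if mode == "reference_max":
        return float(reference.values.max())
    if mode == "either_max":
        return float(max(reference.values.max(), evaluated.values.max()))
    raise ValueError(f"unknown normalization-dose mode {mode!r}")


def compute_gamma_map(reference: DosePlane, evaluated: DosePlane,
                      criteria: GammaCriteria, subgrid_factor: int = 5,
                      norm_dose_mode: str = "reference_max") -> GammaResult:
    """Vectorized gamma map at every above-threshold reference point.

    The reference points are fixed measurement sites; only the evaluated
    plane is interpolated (bilinear), mirroring diode-array practice.
    """
    _check_overlap(reference, evaluated)
    norm = _normalization_dose(reference, evaluated, norm_dose_mode)
    if norm <= 0:
        raise ValueError("reference maximum dose must be positive")
    mask = _evaluation_mask(reference, criteria, norm)
    gamma_map = np.full(reference.values.shape, np.nan)
    n_eval = int(mask.sum())
    if n_eval == 0:
        return GammaResult(gamma_map, float("nan"), 0)

    dta, cap = criteria.dta_mm, criteria.gamma_cap
    step = dta / subgrid_factor
    radius = cap * dta
    k = int(math.ceil(radius / step))
    offs = step * np.arange(-k, k + 1)
    ox, oy = np.meshgrid(offs, offs, indexing="xy")
    dist2 = ox ** 2 + oy ** 2
    keep = dist2 <= radius ** 2 + 1e-12   # truncate where distance term alone > cap
    ox, oy, dist2 = ox[keep], oy[keep], dist2[keep]

    rows, cols = np.nonzero(mask)
    rx = reference.x[cols]
    ry = reference.y[rows]
    d_ref = reference.values[rows, cols]
    # (n_points, n_offsets) evaluated dose samples
    ev = evaluated.sample(rx[:, None] + ox[None, :], ry[:, None] + oy[None, :])
    if criteria.normalization == "global":
        dd_abs = np.full(d_ref.shape, criteria.dd_percent / 100.0 * norm)
    else:
        dd_abs = criteria.dd_percent / 100.0 * d_ref
    with np.errstate(invalid="ignore", divide="ignore"):
        g2 = dist2[None, :] / dta ** 2 + \
            (ev - d_ref[:, None]) ** 2 / (dd_abs ** 2)[:, None]
        g = np.sqrt(np.min(np.where(np.isnan(g2), np.inf, g2), axis=1))
    g = np.minimum(g, cap)
    gamma_map[rows, cols] = g
    passing = 100.0 * float(np.sum(g <= 1.0)) / n_eval
    return GammaResult(gamma_map, passing, n_eval)


def brute_force_gamma(reference: DosePlane, evaluated: DosePlane,
                      criteria: GammaCriteria, oracle_subgrid: float | None = None,
                      norm_dose_mode: str = "reference_max") -> GammaResult:
    """Exhaustive oracle: dense per-point scan with hand-rolled interpolation.

    Independent of :func:`compute_gamma_map` (own interpolation and loop); by
    construction a coarser ``oracle_subgrid`` can never return a smaller
    gamma at any point, since it minimizes over a subset of positions.
    """
    _check_overlap(reference, evaluated)
    norm = _normalization_dose(reference, evaluated, norm_dose_mode)
    mask = _evaluation_mask(reference, criteria, norm)
    gamma_map = np.full(reference.values.shape, np.nan)
    n_eval = int(mask.sum())
    if n_eval == 0:
        return GammaResult(gamma_map, float("nan"), 0)

    dta, cap = criteria.dta_mm, criteria.gamma_cap
    step = dta / 20.0 if oracle_subgrid is None else oracle_subgrid
    radius = cap * dta
    k = int(math.ceil(radius / step))
    ev_vals = evaluated.values
    ny, nx = ev_vals.shape
    x0, y0 = evaluated.origin
    dx, dy = evaluated.spacing

    offs = step * np.arange(-k, k + 1)
    off_x, off_y = np.meshgrid(offs, offs)
    r2_lattice = (off_x ** 2 + off_y ** 2) / dta ** 2
    in_disk = r2_lattice <= cap ** 2 + 1e-12
    off_x, off_y, r2_lattice = off_x[in_disk], off_y[in_disk], r2_lattice[in_disk]

    def interp_many(px: np.ndarray, py: np.ndarray) -> np.ndarray:
        # hand-rolled bilinear sampling, NaN outside the lattice
        fx = (px - x0) / dx
        fy = (py - y0) / dy
        inside = (fx >= 0) & (fy >= 0) & (fx <= nx - 1) & (fy <= ny - 1)
        fx = np.clip(fx, 0, nx - 1)
        fy = np.clip(fy, 0, ny - 1)
        j0 = np.minimum(fx.astype(int), nx - 2) if nx > 1 else np.zeros_like(fx, int)
        i0 = np.minimum(fy.astype(int), ny - 2) if ny > 1 else np.zeros_like(fy, int)
        j1 = np.minimum(j0 + 1, nx - 1)
        i1 = np.minimum(i0 + 1, ny - 1)
        tx = fx - j0
        ty = fy - i0
        vals = ((1 - ty) * ((1 - tx) * ev_vals[i0, j0] + tx * ev_vals[i0, j1])
                + ty * ((1 - tx) * ev_vals[i1, j0] + tx * ev_vals[i1, j1]))
        return np.where(inside, vals, np.nan)

    for row, col in zip(*np.nonzero(mask)):
        px = reference.x[col]
        py = reference.y[row]
        d_ref = reference.values[row, col]
        dd_abs = criteria.dd_percent / 100.0 * (
            norm if criteria.normalization == "global" else d_ref)
        d_ev = interp_many(px + off_x, py + off_y)
        with np.errstate(invalid="ignore"):
            g2 = r2_lattice + (d_ev - d_ref) ** 2 / dd_abs ** 2
            best = np.nanmin(g2)
        gamma_map[row, col] = min(math.sqrt(best), cap) if math.isfinite(best) else cap
    g = gamma_map[mask]
    passing = 100.0 * float(np.sum(g <= 1.0)) / n_eval
    return GammaResult(gamma_map, passing, n_eval)


def gamma_passing_rate(result: GammaResult) -> float:
    """Percent of evaluated points with gamma <= 1 (boundary passes)."""
    if result.n_evaluated == 0:
        return float("nan")
    g = result.gamma_map[np.isfinite(result.gamma_map)]
    return 100.0 * float(np.sum(g <= 1.0)) / result.n_evaluated


def align_planes(reference: DosePlane, evaluated: DosePlane,
                 criteria: GammaCriteria, search_radius: float = 3.0,
                 step: float = 0.5, subgrid_factor: int = 5,
                 ) -> tuple[tuple[float, float], DosePlane]:
    """Grid-search the evaluated-plane shift maximizing GPR.

    Ties are broken by smallest shift magnitude, then lexicographically.
    Returns the chosen (dx, dy) and the shifted evaluated plane.
    """
    n = int(round(search_radius / step))
    best = None
    for di, dj in itertools.product(range(-n, n + 1), repeat=2):
        shift = (dj * step, di * step)
        res = compute_gamma_map(reference, evaluated.shifted(*shift), criteria,
                                subgrid_factor=subgrid_factor)
        gpr = -1.0 if res.undefined else res.passing_rate
        key = (-gpr, shift[0] ** 2 + shift[1] ** 2, shift)
        if best is None or key < best[0]:
            best = (key, shift)
    shift = best[1]
    return shift, evaluated.shifted(*shift)


def tg218_presets() -> list[GammaCriteria]:
    """The seven evaluated criteria: 3/3, 2/2, 1/1 (global+local), 3/2 global.

    All use a 10% low-dose threshold; annotations carry the TG-218 universal
    tolerance (95%) and action (90%) GPR limits.
    """
    out = []
    for dd, dta in ((3.0, 3.0), (3.0, 2.0), (2.0, 2.0), (1.0, 1.0)):
        out.append(GammaCriteria(dd, dta, "global", 0.10,
                                 tolerance_gpr=95.0, action_gpr=90.0))
    for dd, dta in ((3.0, 3.0), (2.0, 2.0), (1.0, 1.0)):
        out.append(GammaCriteria(dd, dta, "local", 0.10,
                                 tolerance_gpr=95.0, action_gpr=90.0))
    return out
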