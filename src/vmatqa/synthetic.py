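"""Synthetic cohort generator: anatomies, VMAT plans, dose products, and
perturbed "measured" planes.

Every stage of the analysis pipeline can be exercised offline: ellipsoidal
prostate-like anatomies on a 4 mm lattice, two-arc 360-degree VMAT plans with
4-degree control-point spacing whose apertures conform to the target
beam's-eye-view outline plus a tunable modulation perturbation (leaf speed
clipped to 7 mm/deg), a fluence-convolution dose surrogate (aperture
indicator x meterset weight back-projected per gantry angle, Gaussian
penumbra), and a measurement-perturbation model (systematic leaf offset,
proportional noise, setup shift, diode-array-like resampling).

The dose engine is a surrogate, not a physics engine; it is deterministic
given the plan and linear in meterset weight, which is what the complexity /
gamma / DVH machinery needs.  Reproducibility is total: every random draw
derives from the cohort seed, with no hidden global state.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .complexity import cp_meterset_fractions, in_jaw_pairs
from .grids import DoseGrid, DosePlane, StructureMask, write_plane_csv
from .rtplan import Arc, ControlPoint, MLCGeometry, VMATPlan, write_plan_json

__all__ = [
    "PerturbationModel",
    "DetectorSpec",
    "CohortSpec",
    "Anatomy",
    "SyntheticPatient",
    "Cohort",
    "generate_anatomy",
    "generate_plan",
    "render_plane",
    "render_grid",
    "perturb_measurement",
    "generate_cohort",
    "static_rectangle_plan",
]

GY_PER_MU = 0.004  # fixed output calibration of the dose surrogate


@dataclass(frozen=True)
class PerturbationModel:
    """Delivery/measurement error model applied to 'measured' planes."""

    noise_sigma_pct: float = 1.0     # proportional Gaussian noise, % of local dose
    leaf_offset_mm: float = 0.8      # systematic outward offset of open leaves
    setup_shift_mm: float = 0.5      # uniform random setup shift bound, each axis
    tongue_groove: float = 0.25      # side-edge fluence deficit fraction on delivery
    small_field_k: float = 0.30      # output deficit amplitude for narrow gaps
    small_field_g0: float = 20.0     # gap scale of the output deficit, mm


@dataclass(frozen=True)
class DetectorSpec:
    """Diode-array-like uniform sampling grid."""

    spacing_mm: float = 7.0
    extent_mm: float = 260.0         # square side, centred on the beam axis


@dataclass(frozen=True)
class CohortSpec:
    n_patients: int = 31
    seed: int = 0
    # anatomy parameter ranges, mm
    ptv_radius_range: tuple[float, float] = (26.0, 36.0)
    oar_radius_range: tuple[float, float] = (22.0, 32.0)
    oar_separation_range: tuple[float, float] = (-8.0, 6.0)  # surface gap; <0 overlaps
    # modulation levels per arm (reference drawn lower than the KBP-style arm)
    reference_modulation_range: tuple[float, float] = (0.10, 0.30)
    kbp_modulation_gap: tuple[float, float] = (0.30, 0.45)
    perturbation: PerturbationModel = PerturbationModel()
    detector: DetectorSpec = DetectorSpec()
    # dose lattice
    voxel_mm: float = 4.0
    grid_shape: tuple[int, int, int] = (64, 48, 64)
    n_replicates: int = 3
    rx_dose_per_fraction: float = 2.0
    n_fractions: int = 38            # 38 x 2 Gy = 76 Gy total

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("cohort needs at least one patient")
        for rng in (self.ptv_radius_range, self.oar_radius_range):
            if rng[0] <= 0 or rng[1] < rng[0]:
                raise ValueError(f"invalid positive range {rng}")


@dataclass
class Anatomy:
    """Structure masks on a shared dose lattice, centred on the isocenter."""

    grid: DoseGrid                      # zero dose placeholder carrying geometry
    masks: dict[str, StructureMask]     # ptv, bladder, rectum, body

    @property
    def ptv(self) -> StructureMask:
        return self.masks["ptv"]


def _ellipsoid(xx, yy, zz, center, radii) -> np.ndarray:
    return (((xx - center[0]) / radii[0]) ** 2
            + ((yy - center[1]) / radii[1]) ** 2
            + ((zz - center[2]) / radii[2]) ** 2) <= 1.0


def generate_anatomy(spec: CohortSpec, seed: int | np.random.Generator) -> Anatomy:
    """Ellipsoidal PTV with adjacent bladder (superior-anterior) and rectum
    (posterior), inside a cylindrical body; deterministic given the seed."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nx, ny, nz = spec.grid_shape
    v = spec.voxel_mm
    x = v * (np.arange(nx) - (nx - 1) / 2)
    y = v * (np.arange(ny) - (ny - 1) / 2)
    z = v * (np.arange(nz) - (nz - 1) / 2)
    xx, yy, zz = np.meshgrid(x, y, z, indexing="ij")

    r_ptv = rng.uniform(*spec.ptv_radius_range)
    ptv_radii = (r_ptv, r_ptv * rng.uniform(0.85, 1.1), r_ptv * rng.uniform(0.85, 1.1))
    ptv = _ellipsoid(xx, yy, zz, (0.0, 0.0, 0.0), ptv_radii)

    r_bla = rng.uniform(*spec.oar_radius_range)
    gap_b = rng.uniform(*spec.oar_separation_range)
    # bladder sits superior (+y) and anterior (+z) of the target
    d_b = ptv_radii[2] + r_bla + gap_b
    bladder = _ellipsoid(xx, yy, zz, (0.0, 0.45 * d_b, 0.85 * d_b),
                         (r_bla * 1.1, r_bla, r_bla)) & ~ptv

    r_rec = rng.uniform(*spec.oar_radius_range) * 0.65
    gap_r = rng.uniform(*spec.oar_separation_range)
    d_r = ptv_radii[2] + r_rec + gap_r
    rectum = _ellipsoid(xx, yy, zz, (0.0, -0.2 * d_r, -0.95 * d_r),
                        (r_rec, r_rec * 2.2, r_rec)) & ~ptv

    body = (xx ** 2 + zz ** 2) <= (0.46 * v * min(nx, nz)) ** 2

    grid = DoseGrid(np.zeros(spec.grid_shape), (v, v, v),
                    (float(x[0]), float(y[0]), float(z[0])))
    masks = {name: StructureMask(name, m & body if name != "body" else m)
             for name, m in (("ptv", ptv), ("bladder", bladder),
                             ("rectum", rectum), ("body", body))}
    return Anatomy(grid, masks)


# ---------------------------------------------------------------------------
# Plan generation


def _bev_outline(anatomy: Anatomy, geometry: MLCGeometry,
                 angles_deg: np.ndarray, margin: float) -> tuple[np.ndarray, np.ndarray]:
    """Per-(angle, pair) target extent along the leaf-travel axis.

    The beam's-eye-view lateral coordinate of a voxel at axial position
    (x, z) for gantry angle t is u = x cos(t) + z sin(t); the superior-
    inferior coordinate y is unchanged (coplanar arcs).  Returns (a, b)
    arrays of shape (n_angles, n_pairs); closed pairs hold a == b == 0.
    """
    m = anatomy.ptv.mask
    idx = np.nonzero(m)
    xs = anatomy.grid.axis_coords(0)[idx[0]]
    ys = anatomy.grid.axis_coords(1)[idx[1]]
    zs = anatomy.grid.axis_coords(2)[idx[2]]
    bounds = geometry.leaf_bound_positions
    pair_of_voxel = np.searchsorted(bounds, ys, side="right") - 1
    valid = (pair_of_voxel >= 0) & (pair_of_voxel < geometry.n_pairs)
    xs, zs, pair_of_voxel = xs[valid], zs[valid], pair_of_voxel[valid]

    n_pairs = geometry.n_pairs
    a = np.zeros((angles_deg.size, n_pairs))
    b = np.zeros((angles_deg.size, n_pairs))
    for i, t in enumerate(np.deg2rad(angles_deg)):
        u = xs * np.cos(t) + zs * np.sin(t)
        umin = np.full(n_pairs, np.inf)
        umax = np.full(n_pairs, -np.inf)
        np.minimum.at(umin, pair_of_voxel, u)
        np.maximum.at(umax, pair_of_voxel, u)
        open_p = np.isfinite(umin)
        a[i, open_p] = umin[open_p] - margin
        b[i, open_p] = umax[open_p] + margin
    return a, b


def generate_plan(anatomy: Anatomy, modulation_level: float, spec: CohortSpec,
                  seed: int | np.random.Generator, plan_id: str = "plan",
                  max_leaf_speed: float = 7.0, cp_spacing: float = 4.0,
                  aperture_margin: float = 5.0) -> VMATPlan:
    """Two full arcs conformal to the PTV outline plus band-limited modulation.

    ``modulation_level`` in [0, 1] scales smooth per-leaf perturbations and
    meterset-weight variation; leaf travel is clipped so no leaf ever exceeds
    ``max_leaf_speed`` mm per degree of gantry rotation, and MU grows with
    the modulation level.
    """
    if not 0.0 <= modulation_level <= 1.0:
        raise ValueError("modulation_level must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    geometry = MLCGeometry.default()
    n_cp = int(round(360.0 / cp_spacing)) + 1

    ptv_idx = np.nonzero(anatomy.ptv.mask)
    ys = anatomy.grid.axis_coords(1)[ptv_idx[1]]
    jaw_y = (float(ys.min() - 8.0), float(ys.max() + 8.0))

    arcs: list[Arc] = []
    total_mu = max(120.0, 450.0 + 260.0 * modulation_level + 25.0 * rng.standard_normal())
    for arc_i, direction in enumerate(("CW", "CCW")):
        if direction == "CW":
            angles = (cp_spacing * np.arange(n_cp)) % 360.0
        else:
            angles = (-cp_spacing * np.arange(n_cp)) % 360.0
        a, b = _bev_outline(anatomy, geometry, angles, aperture_margin)
        open_pairs = (b - a) > 0
        # park closed leaves at the aperture mid-line so they carry no motion
        mid = np.where(open_pairs.any(axis=1),
                       (a + b).sum(axis=1) / np.maximum(2 * open_pairs.sum(axis=1), 1),
                       0.0)
        a = np.where(open_pairs, a, mid[:, None])
        b = np.where(open_pairs, b, mid[:, None])

        if modulation_level > 0:
            def smooth_noise(shape, sig_cp=2.0, sig_pair=1.0):
                n = rng.standard_normal(shape)
                n = gaussian_filter1d(n, sigma=sig_cp, axis=0, mode="wrap")
                n = gaussian_filter1d(n, sigma=sig_pair, axis=1)
                return n / max(n.std(), 1e-9)

            # sliding-window modulation: the conformal gap narrows and its
            # centre wanders, with extra per-leaf jitter for edge irregularity
            gap = b - a
            center = 0.5 * (a + b)
            shrink = modulation_level * (0.50 + 0.18 * smooth_noise(a.shape))
            shrink = np.clip(shrink, 0.0, 0.85)
            wander = 0.40 * modulation_level * gap * smooth_noise(a.shape)
            jitter_a = 4.0 * modulation_level * smooth_noise(a.shape, 1.5, 0.8)
            jitter_b = 4.0 * modulation_level * smooth_noise(a.shape, 1.5, 0.8)
            half = 0.5 * gap * (1.0 - shrink)
            lo_lim, hi_lim = a + 1.0, b - 1.0  # stay inside the conformal outline
            a_new = np.clip(center + wander - half + jitter_a, lo_lim, hi_lim)
            b_new = np.clip(center + wander + half + jitter_b, lo_lim, hi_lim)
            a = np.where(open_pairs, a_new, a)
            b = np.where(open_pairs, np.maximum(a_new, b_new), b)

        max_step = max_leaf_speed * cp_spacing
        for arr in (a, b):
            for i in range(1, n_cp):
                np.clip(arr[i], arr[i - 1] - max_step, arr[i - 1] + max_step, out=arr[i])
        b = np.maximum(a, b)  # max of two speed-limited sequences is speed-limited

        jaw_x = (float(a.min() - 10.0), float(b.max() + 10.0))
        dw = np.ones(n_cp - 1)
        if modulation_level > 0:
            jitter = gaussian_filter1d(rng.standard_normal(n_cp - 1), sigma=2.0)
            dw += 0.9 * modulation_level * np.abs(jitter)
        w = np.concatenate([[0.0], np.cumsum(dw)])
        w /= w[-1]
        w[-1] = 1.0

        cps = [ControlPoint(float(angles[i]), float(w[i]), a[i], b[i], jaw_x, jaw_y)
               for i in range(n_cp)]
        arcs.append(Arc(cps, total_mu / 2.0, direction, cp_spacing))
    return VMATPlan(plan_id, arcs, spec.rx_dose_per_fraction, spec.n_fractions, geometry)


def static_rectangle_plan(half_width: float = 50.0, n_open_pairs: int = 20,
                          n_cp: int = 91, beam_mu: float = 400.0,
                          rx_per_fx: float = 2.0) -> VMATPlan:
    """A static fully-open rectangular arc (MCS = 1, LM = 0 by construction)."""
    geometry = MLCGeometry.default()
    centers = geometry.pair_centers
    order = np.argsort(np.abs(centers))
    open_mask = np.zeros(geometry.n_pairs, bool)
    open_mask[order[:n_open_pairs]] = True
    a = np.where(open_mask, -half_width, 0.0)
    b = np.where(open_mask, half_width, 0.0)
    y_open = geometry.leaf_bound_positions
    lo = y_open[:-1][open_mask].min()
    hi = y_open[1:][open_mask].max()
    cps = [ControlPoint(float((4.0 * i) % 360.0), i / (n_cp - 1), a, b,
                        (-half_width - 10, half_width + 10), (lo, hi))
           for i in range(n_cp)]
    return VMATPlan("static-rect", [Arc(cps, beam_mu, "CW")], rx_per_fx, 38)


# ---------------------------------------------------------------------------
# Dose surrogate


def _accumulate_plane(plan: VMATPlan, x: np.ndarray, y: np.ndarray,
                      tongue_groove: float = 0.0,
                      small_field_k: float = 0.0,
                      small_field_g0: float = 20.0) -> np.ndarray:
    """Raw MU-fluence on a coronal (x, y) lattice at the isocenter depth.

    Two optional delivery-side effects model what an idealised computation
    misses for complex apertures:

    * ``tongue_groove`` > 0: fluence deficit along exposed leaf-side edges —
      the lattice row of a pair bordering a differently shaped neighbour
      loses that fraction of the control point's fluence wherever only its
      own interval is open (deficit density ~ the edge metric).
    * ``small_field_k`` > 0: per-pair output deficit for narrow gaps; the
      contribution of a pair with gap g is scaled by
      ``1 - k * exp(-g / g0)``, so sliding-window (small-aperture) plans
      deliver coherently less than computed while wide conformal gaps are
      nearly unaffected.
    """
    dose = np.zeros((y.size, x.size))
    bounds = plan.mlc_geometry.leaf_bound_positions
    row_lo = np.searchsorted(y, bounds[:-1], side="left")
    row_hi = np.searchsorted(y, bounds[1:], side="left")
    n_pairs = plan.mlc_geometry.n_pairs
    for arc in plan.arcs:
        w_cp = cp_meterset_fractions(arc) * arc.beam_mu
        for cp, w in zip(arc.control_points, w_cp):
            if w == 0.0:
                continue
            theta = np.deg2rad(cp.gantry_angle)
            u = x * np.cos(theta)  # coronal plane lies at z = 0
            jl = np.searchsorted(y, cp.jaw_y[0], side="left")
            jh = np.searchsorted(y, cp.jaw_y[1], side="right")
            lo = np.maximum(cp.bank_a_positions, cp.jaw_x[0])
            hi = np.minimum(cp.bank_b_positions, cp.jaw_x[1])
            open_pairs = hi - lo > 0
            open_cols = (u[None, :] >= lo[:, None]) & (u[None, :] <= hi[:, None]) \
                & open_pairs[:, None]
            for p in np.nonzero(open_pairs)[0]:
                r0, r1 = max(row_lo[p], jl), min(row_hi[p], jh)
                if r1 <= r0:
                    continue
                w_p = w
                if small_field_k > 0.0:
                    gap = hi[p] - lo[p]
                    w_p = w * (1.0 - small_field_k * np.exp(-gap / small_field_g0))
                dose[r0:r1, open_cols[p]] += w_p
            if tongue_groove > 0.0:
                for p in np.nonzero(open_pairs)[0]:
                    # own-interval columns not shared with each neighbour row
                    if p > 0:
                        r = row_lo[p]
                        if jl <= r < jh:
                            dose[r, open_cols[p] & ~open_cols[p - 1]] -= tongue_groove * w
                    if p < n_pairs - 1:
                        r = row_hi[p] - 1
                        if jl <= r < jh:
                            dose[r, open_cols[p] & ~open_cols[p + 1]] -= tongue_groove * w
    return np.maximum(dose, 0.0)


def render_plane(plan: VMATPlan, spacing: float = 2.0, half_extent: float = 131.0,
                 penumbra_sigma: float = 3.0, tongue_groove: float = 0.0,
                 small_field_k: float = 0.0, small_field_g0: float = 20.0) -> DosePlane:
    """Coronal dose plane (Gy per fraction): fluence accumulation convolved
    with a Gaussian penumbra, at a fixed output calibration (linear in MU)."""
    n = int(round(2 * half_extent / spacing)) + 1
    x = -half_extent + spacing * np.arange(n)
    y = x.copy()
    dose = _accumulate_plane(plan, x, y, tongue_groove, small_field_k, small_field_g0)
    dose = gaussian_filter(dose, sigma=penumbra_sigma / spacing)
    return DosePlane(dose * GY_PER_MU, (spacing, spacing), (float(x[0]), float(y[0])))


def render_grid(plan: VMATPlan, anatomy: Anatomy, penumbra_sigma: float = 3.0,
                renormalize_d95: float | None = 76.0) -> DoseGrid:
    """3D dose surrogate on the anatomy lattice (total dose over all fractions).

    Fluence is back-projected per control point along the gantry direction
    (parallel beam, no attenuation), convolved with a Gaussian penumbra and,
    by default, renormalized so the PTV D95 equals 76 Gy.
    """
    grid = anatomy.grid
    xs = grid.axis_coords(0)
    ys = grid.axis_coords(1)
    zs = grid.axis_coords(2)
    dose = np.zeros(grid.values.shape)
    bounds = plan.mlc_geometry.leaf_bound_positions
    yi_lo = np.searchsorted(ys, bounds[:-1], side="left")
    yi_hi = np.searchsorted(ys, bounds[1:], side="left")
    xx, zz = np.meshgrid(xs, zs, indexing="ij")
    for arc in plan.arcs:
        w_cp = cp_meterset_fractions(arc) * arc.beam_mu
        for cp, w in zip(arc.control_points, w_cp):
            if w == 0.0:
                continue
            theta = np.deg2rad(cp.gantry_angle)
            u = xx * np.cos(theta) + zz * np.sin(theta)
            jl = np.searchsorted(ys, cp.jaw_y[0], side="left")
            jh = np.searchsorted(ys, cp.jaw_y[1], side="right")
            lo = np.maximum(cp.bank_a_positions, cp.jaw_x[0])
            hi = np.minimum(cp.bank_b_positions, cp.jaw_x[1])
            for p in np.nonzero(hi - lo > 0)[0]:
                r0, r1 = max(yi_lo[p], jl), min(yi_hi[p], jh)
                if r1 <= r0:
                    continue
                open_xz = (u >= lo[p]) & (u <= hi[p])
                dose[:, r0:r1, :] += w * open_xz[:, None, :]
    dose = gaussian_filter(dose, sigma=penumbra_sigma / np.asarray(grid.voxel_size))
    out = DoseGrid(dose * GY_PER_MU * plan.n_fractions, grid.voxel_size, grid.origin)
    if renormalize_d95 is not None:
        from .dvh import renormalize_to_d95
        out = renormalize_to_d95(out, anatomy.ptv, renormalize_d95)
    return out


# ---------------------------------------------------------------------------
# Measurement perturbation


def _with_leaf_offset(plan: VMATPlan, offset: float) -> VMATPlan:
    """Systematically widen (offset > 0) or narrow (< 0) every open pair by
    ``offset`` mm per bank; narrowed pairs close rather than cross."""
    if offset == 0.0:
        return plan
    arcs = []
    for arc in plan.arcs:
        cps = []
        for cp in arc.control_points:
            open_p = (cp.bank_b_positions - cp.bank_a_positions) > 1e-9
            a = cp.bank_a_positions - offset * open_p
            b = cp.bank_b_positions + offset * open_p
            mid = 0.5 * (a + b)
            cps.append(ControlPoint(
                cp.gantry_angle, cp.cumulative_meterset_weight,
                np.minimum(a, mid), np.maximum(b, mid),
                cp.jaw_x, cp.jaw_y))
        arcs.append(Arc(cps, arc.beam_mu, arc.gantry_direction, arc.nominal_cp_spacing))
    return VMATPlan(plan.plan_id, arcs, plan.rx_dose_per_fraction,
                    plan.n_fractions, plan.mlc_geometry)


def perturb_measurement(plan: VMATPlan, model: PerturbationModel,
                        seed: int | np.random.Generator,
                        detector: DetectorSpec = DetectorSpec(),
                        render_spacing: float = 2.0) -> DosePlane:
    """Emulated delivery + measurement of one fraction on the detector grid.

    Re-renders the plan with the systematic leaf offset, applies a random
    setup shift, samples onto the detector lattice, and adds proportional
    Gaussian noise per diode.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    plane = render_plane(_with_leaf_offset(plan, model.leaf_offset_mm),
                         spacing=render_spacing, tongue_groove=model.tongue_groove,
                         small_field_k=model.small_field_k,
                         small_field_g0=model.small_field_g0)
    shift = rng.uniform(-model.setup_shift_mm, model.setup_shift_mm, size=2)
    plane = plane.shifted(float(shift[0]), float(shift[1]))

    n_det = int(round(detector.extent_mm / detector.spacing_mm)) + 1
    coords = -detector.extent_mm / 2 + detector.spacing_mm * np.arange(n_det)
    gx, gy = np.meshgrid(coords, coords, indexing="xy")
    values = plane.sample(gx, gy, fill=0.0)
    noise = rng.standard_normal(values.shape) * model.noise_sigma_pct / 100.0
    values = np.maximum(values * (1.0 + noise), 0.0)
    return DosePlane(values, (detector.spacing_mm, detector.spacing_mm),
                     (float(coords[0]), float(coords[0])))


# ---------------------------------------------------------------------------
# Cohort assembly


@dataclass
class SyntheticPatient:
    patient_id: str
    anatomy: Anatomy
    plans: dict[str, VMATPlan]                    # reference | kbp
    modulation: dict[str, float]
    computed_planes: dict[str, DosePlane]
    measured_planes: dict[str, list[DosePlane]]   # replicates per arm
    dose_grids: dict[str, DoseGrid] = field(default_factory=dict)


@dataclass
class Cohort:
    spec: CohortSpec
    patients: list[SyntheticPatient]
    manifest: dict


def generate_cohort(spec: CohortSpec, include_grids: bool = False,
                    out_dir: str | Path | None = None) -> Cohort:
    """n patients x {reference, KBP-style} plans with computed planes and
    replicate 'measured' planes; the KBP-style arm draws strictly higher
    modulation so the cohort exhibits a complexity gap between arms."""
    patients: list[SyntheticPatient] = []
    manifest: dict = {"seed": spec.seed, "n_patients": spec.n_patients, "patients": []}
    for i in range(spec.n_patients):
        pid = f"pt{i:03d}"
        rng = np.random.default_rng([spec.seed, i])
        anatomy = generate_anatomy(spec, rng)
        mod_ref = rng.uniform(*spec.reference_modulation_range)
        mod_kbp = mod_ref + rng.uniform(*spec.kbp_modulation_gap)
        plans, computed, measured, grids = {}, {}, {}, {}
        for ai, (arm, mod) in enumerate((("reference", mod_ref), ("kbp", mod_kbp))):
            plan = generate_plan(anatomy, mod, spec, np.random.default_rng(
                [spec.seed, i, ai]), plan_id=f"{pid}-{arm}")
            plans[arm] = plan
            computed[arm] = render_plane(plan)
            measured[arm] = [
                perturb_measurement(plan, spec.perturbation,
                                    np.random.default_rng([spec.seed, i, ai, rep]),
                                    spec.detector)
                for rep in range(spec.n_replicates)]
            if include_grids:
                grids[arm] = render_grid(plan, anatomy)
        patients.append(SyntheticPatient(pid, anatomy, plans,
                                         {"reference": mod_ref, "kbp": mod_kbp},
                                         computed, measured, grids))
        manifest["patients"].append({
            "patient_id": pid, "seed_path": [spec.seed, i],
            "modulation": {"reference": mod_ref, "kbp": mod_kbp}})
    cohort = Cohort(spec, patients, manifest)
    if out_dir is not None:
        _write_cohort(cohort, Path(out_dir))
    return cohort


def _write_cohort(cohort: Cohort, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for pt in cohort.patients:
        pdir = out_dir / pt.patient_id
        pdir.mkdir(exist_ok=True)
        for arm, plan in pt.plans.items():
            write_plan_json(plan, pdir / f"{arm}.plan.json")
            write_plane_csv(pt.computed_planes[arm], pdir / f"{arm}.computed.csv")
            for rep, plane in enumerate(pt.measured_planes[arm]):
                write_plane_csv(plane, pdir / f"{arm}.measured{rep}.csv")
    blob = json.dumps(cohort.manifest, sort_keys=True).encode()
    cohort.manifest["manifest_sha256"] = hashlib.sha256(blob).hexdigest()
    (out_dir / "manifest.json").write_text(json.dumps(cohort.manifest, indent=1))
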