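"""VMAT plan model: MLC geometry, control points, arcs, validation and I/O.

Coordinate convention (IEC 61217 beam-limiting-device frame): leaf travel is
along X, leaf pairs are stacked along Y (inferior -> superior).  Bank A is the
negative-X bank, bank B the positive-X bank; a closed pair has bank_a ==
bank_b (gap 0, never negative).  All positions are mm projected to the
isocenter plane; gantry angles are degrees in [0, 360); meterset weights are
dimensionless cumulative fractions in [0, 1].

Plans are persisted in a versioned JSON schema (``vmatqa-plan/1``).  DICOM RT
Plan ingestion is available when :mod:`pydicom` is installed (optional
``vmatqa[dicom]`` extra).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

PLAN_SCHEMA = "vmatqa-plan/1"

__all__ = [
    "MLCGeometry",
    "ControlPoint",
    "Arc",
    "VMATPlan",
    "Violation",
    "PlanFormatError",
    "PlanValidationError",
    "validate_plan",
    "write_plan_json",
    "read_plan_json",
    "read_rtplan",
    "write_rtplan_dicom",
    "gantry_delta_deg",
]


class PlanFormatError(ValueError):
    """Raised when a plan file cannot be interpreted."""


class PlanValidationError(ValueError):
    """Raised when a structurally parsed plan violates a model invariant."""


def gantry_delta_deg(a: float, b: float) -> float:
    """Shortest signed gantry rotation from angle ``a`` to ``b`` (degrees).

    Handles wrap-around transitions such as 359 -> 3 (returns +4).
    """
    return (b - a + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class MLCGeometry:
    """Physical layout of the MLC leaf bank projected to isocenter."""

    n_pairs: int
    leaf_widths: np.ndarray
    leaf_bound_positions: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "leaf_widths", np.asarray(self.leaf_widths, float))
        object.__setattr__(
            self, "leaf_bound_positions", np.asarray(self.leaf_bound_positions, float)
        )
        if self.n_pairs < 1:
            raise PlanValidationError("MLC must have at least one leaf pair")
        if self.leaf_widths.shape != (self.n_pairs,):
            raise PlanValidationError("leaf_widths length must equal n_pairs")
        if self.leaf_bound_positions.shape != (self.n_pairs + 1,):
            raise PlanValidationError("need n_pairs + 1 leaf boundaries")
        if np.any(self.leaf_widths <= 0):
            raise PlanValidationError("leaf widths must be positive")
        if np.any(np.diff(self.leaf_bound_positions) <= 0):
            raise PlanValidationError("leaf boundaries must be strictly increasing")
        span = self.leaf_bound_positions[-1] - self.leaf_bound_positions[0]
        if abs(self.leaf_widths.sum() - span) > 1e-6:
            raise PlanValidationError("sum of widths must equal boundary span")

    @classmethod
    def default(cls, n_pairs: int = 80, width: float = 5.0) -> "MLCGeometry":
        """160-leaf head: 80 pairs x 5 mm, centred on the beam axis."""
        half = n_pairs * width / 2.0
        bounds = -half + width * np.arange(n_pairs + 1)
        return cls(n_pairs, np.full(n_pairs, width), bounds)

    @property
    def pair_centers(self) -> np.ndarray:
        b = self.leaf_bound_positions
        return 0.5 * (b[:-1] + b[1:])

    def to_dict(self) -> dict:
        return {
            "n_pairs": int(self.n_pairs),
            "leaf_widths": self.leaf_widths.tolist(),
            "leaf_bound_positions": self.leaf_bound_positions.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLCGeometry":
        return cls(d["n_pairs"], d["leaf_widths"], d["leaf_bound_positions"])


@dataclass
class ControlPoint:
    """One sampled machine state along an arc."""

    gantry_angle: float
    cumulative_meterset_weight: float
    bank_a_positions: np.ndarray
    bank_b_positions: np.ndarray
    jaw_x: tuple[float, float]
    jaw_y: tuple[float, float]

    def __post_init__(self) -> None:
        self.bank_a_positions = np.asarray(self.bank_a_positions, float)
        self.bank_b_positions = np.asarray(self.bank_b_positions, float)
        self.jaw_x = (float(self.jaw_x[0]), float(self.jaw_x[1]))
        self.jaw_y = (float(self.jaw_y[0]), float(self.jaw_y[1]))

    def to_dict(self) -> dict:
        return {
            "gantry_angle": float(self.gantry_angle),
            "cumulative_meterset_weight": float(self.cumulative_meterset_weight),
            "bank_a_positions": self.bank_a_positions.tolist(),
            "bank_b_positions": self.bank_b_positions.tolist(),
            "jaw_x": list(self.jaw_x),
            "jaw_y": list(self.jaw_y),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ControlPoint":
        return cls(
            d["gantry_angle"],
            d["cumulative_meterset_weight"],
            d["bank_a_positions"],
            d["bank_b_positions"],
            tuple(d["jaw_x"]),
            tuple(d["jaw_y"]),
        )


@dataclass
class Arc:
    control_points: list[ControlPoint]
    beam_mu: float
    gantry_direction: str  # "CW" | "CCW"
    nominal_cp_spacing: float = 4.0

    def to_dict(self) -> dict:
        return {
            "beam_mu": float(self.beam_mu),
            "gantry_direction": self.gantry_direction,
            "nominal_cp_spacing": float(self.nominal_cp_spacing),
            "control_points": [cp.to_dict() for cp in self.control_points],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Arc":
        return cls(
            [ControlPoint.from_dict(c) for c in d["control_points"]],
            d["beam_mu"],
            d["gantry_direction"],
            d.get("nominal_cp_spacing", 4.0),
        )


@dataclass
class VMATPlan:
    plan_id: str
    arcs: list[Arc]
    rx_dose_per_fraction: float
    n_fractions: int
    mlc_geometry: MLCGeometry = field(default_factory=MLCGeometry.default)

    @property
    def total_mu(self) -> float:
        return float(sum(a.beam_mu for a in self.arcs))

    @property
    def rx_total_dose(self) -> float:
        return self.rx_dose_per_fraction * self.n_fractions

    def to_dict(self) -> dict:
        return {
            "schema": PLAN_SCHEMA,
            "plan_id": self.plan_id,
            "rx_dose_per_fraction": float(self.rx_dose_per_fraction),
            "n_fractions": int(self.n_fractions),
            "mlc_geometry": self.mlc_geometry.to_dict(),
            "arcs": [a.to_dict() for a in self.arcs],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "VMATPlan":
        schema = d.get("schema")
        if schema != PLAN_SCHEMA:
            raise PlanFormatError(f"unknown plan schema {schema!r}, expected {PLAN_SCHEMA!r}")
        if not d["arcs"]:
            raise PlanValidationError("plan must contain at least one arc")
        return cls(
            d["plan_id"],
            [Arc.from_dict(a) for a in d["arcs"]],
            d["rx_dose_per_fraction"],
            d["n_fractions"],
            MLCGeometry.from_dict(d["mlc_geometry"]),
        )


# ---------------------------------------------------------------------------
# Validation


@dataclass(frozen=True)
class Violation:
    """One validity failure; violations are data, not exceptions."""

    arc_index: int
    cp_index: int
    leaf_index: int | None
    kind: str
    message: str


def _structural_violations(plan: VMATPlan) -> list[Violation]:
    out: list[Violation] = []
    n_pairs = plan.mlc_geometry.n_pairs
    if plan.total_mu <= 0:
        out.append(Violation(-1, -1, None, "plan", "total MU must be positive"))
    if plan.rx_dose_per_fraction <= 0:
        out.append(Violation(-1, -1, None, "plan", "prescription dose must be positive"))
    for ai, arc in enumerate(plan.arcs):
        cps = arc.control_points
        if len(cps) < 2:
            out.append(Violation(ai, -1, None, "arc", "arc needs at least 2 control points"))
            continue
        w = np.array([cp.cumulative_meterset_weight for cp in cps])
        if abs(w[0]) > 1e-9:
            out.append(Violation(ai, 0, None, "meterset", "first cumulative weight must be 0"))
        if abs(w[-1] - 1.0) > 1e-9:
            out.append(Violation(ai, len(cps) - 1, None, "meterset",
                                 "last cumulative weight must be 1"))
        for i in np.nonzero(np.diff(w) < -1e-12)[0]:
            out.append(Violation(ai, int(i) + 1, None, "meterset",
                                 f"cumulative weight decreases at CP {i + 1}"))
        sign = 1.0 if arc.gantry_direction == "CW" else -1.0
        for ci, cp in enumerate(cps):
            if cp.bank_a_positions.shape != (n_pairs,) or cp.bank_b_positions.shape != (n_pairs,):
                out.append(Violation(ai, ci, None, "mlc", "bank length != n_pairs"))
                continue
            bad = np.nonzero(cp.bank_b_positions - cp.bank_a_positions < -1e-9)[0]
            for li in bad:
                out.append(Violation(ai, ci, int(li), "mlc",
                                     f"bank B < bank A for pair {li}"))
            if cp.jaw_x[1] <= cp.jaw_x[0] or cp.jaw_y[1] <= cp.jaw_y[0]:
                out.append(Violation(ai, ci, None, "jaw", "degenerate jaw interval"))
            if ci:
                dg = gantry_delta_deg(cps[ci - 1].gantry_angle, cp.gantry_angle)
                if dg * sign < -1e-9:
                    out.append(Violation(ai, ci, None, "gantry",
                                         f"gantry step {dg:+.3f} deg opposes "
                                         f"{arc.gantry_direction} direction"))
    return out


def validate_plan(plan: VMATPlan, max_leaf_speed: float = 7.0) -> list[Violation]:
    """Check model invariants and the leaf-speed limit (mm per deg of gantry).

    Returns an empty list iff the plan is valid.  The violation list is
    deterministic (ordered by arc, control point, leaf), so the check is
    idempotent and order-stable.
    """
    out = _structural_violations(plan)
    for ai, arc in enumerate(plan.arcs):
        cps = arc.control_points
        for ci in range(1, len(cps)):
            dg = abs(gantry_delta_deg(cps[ci - 1].gantry_angle, cps[ci].gantry_angle))
            if dg < 1e-12:
                continue
            for bank_name in ("bank_a_positions", "bank_b_positions"):
                prev = getattr(cps[ci - 1], bank_name)
                cur = getattr(cps[ci], bank_name)
                if prev.shape != cur.shape:
                    continue
                speed = np.abs(cur - prev) / dg
                for li in np.nonzero(speed > max_leaf_speed + 1e-9)[0]:
                    out.append(Violation(
                        ai, ci, int(li), "leaf_speed",
                        f"leaf {li} ({bank_name[5]}-bank) moves {speed[li]:.3f} mm/deg "
                        f"> {max_leaf_speed} mm/deg between CP {ci - 1} and {ci}"))
    return out


# ---------------------------------------------------------------------------
# JSON round-trip


def write_plan_json(plan: VMATPlan, path: str | Path) -> None:
    Path(path).write_text(json.dumps(plan.to_dict(), indent=1))


def read_plan_json(path: str | Path) -> VMATPlan:
    try:
        d = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise PlanFormatError(f"cannot parse plan JSON {path}: {e}") from e
    if not isinstance(d, dict):
        raise PlanFormatError(f"plan JSON {path} is not an object")
    return VMATPlan.from_dict(d)


def plans_equal(a: VMATPlan, b: VMATPlan, tol: float = 1e-6) -> bool:
    """Field-wise equality with an absolute tolerance on positions (mm)."""
    if (a.plan_id != b.plan_id or len(a.arcs) != len(b.arcs)
            or a.n_fractions != b.n_fractions
            or abs(a.rx_dose_per_fraction - b.rx_dose_per_fraction) > tol):
        return False
    if not np.allclose(a.mlc_geometry.leaf_bound_positions,
                       b.mlc_geometry.leaf_bound_positions, atol=tol):
        return False
    for arc_a, arc_b in zip(a.arcs, b.arcs):
        if (abs(arc_a.beam_mu - arc_b.beam_mu) > tol
                or arc_a.gantry_direction != arc_b.gantry_direction
                or len(arc_a.control_points) != len(arc_b.control_points)):
            return False
        for ca, cb in zip(arc_a.control_points, arc_b.control_points):
            if (abs(gantry_delta_deg(ca.gantry_angle, cb.gantry_angle)) > tol
                    or abs(ca.cumulative_meterset_weight - cb.cumulative_meterset_weight) > tol
                    or not np.allclose(ca.bank_a_positions, cb.bank_a_positions, atol=tol)
                    or not np.allclose(ca.bank_b_positions, cb.bank_b_positions, atol=tol)
                    or not np.allclose(ca.jaw_x, cb.jaw_x, atol=tol)
                    or not np.allclose(ca.jaw_y, cb.jaw_y, atol=tol)):
                return False
    return True


# ---------------------------------------------------------------------------
# DICOM RT Plan (optional; requires pydicom)


def _require_pydicom():
    try:
        import pydicom
    except ImportError as e:  # pragma: no cover - exercised only without extra
        raise ImportError(
            "DICOM RT Plan support requires pydicom; install vmatqa[dicom]"
        ) from e
    return pydicom


def read_rtplan(path: str | Path, mlc_geometry: MLCGeometry | None = None) -> VMATPlan:
    """Read a DICOM RT Plan containing dynamic-arc beams with MLC sequences.

    Leaf positions are taken from the MLCX beam-limiting-device sequence
    (first half bank A, second half bank B, per the DICOM ordering), meterset
    weights are normalised by the final cumulative weight, and per-beam MU is
    taken from the fraction-group referenced beam sequence.
    """
    pydicom = _require_pydicom()
    ds = pydicom.dcmread(str(path))
    if getattr(ds, "Modality", None) != "RTPLAN":
        raise PlanFormatError(f"{path} is not an RT Plan (Modality={getattr(ds, 'Modality', None)})")

    beam_mus: dict[int, float] = {}
    n_fractions = 1
    for fg in getattr(ds, "FractionGroupSequence", []):
        n_fractions = int(getattr(fg, "NumberOfFractionsPlanned", 1) or 1)
        for rb in getattr(fg, "ReferencedBeamSequence", []):
            beam_mus[int(rb.ReferencedBeamNumber)] = float(getattr(rb, "BeamMeterset", 0.0))

    rx_per_fx = 2.0
    for dr in getattr(ds, "DoseReferenceSequence", []):
        target = getattr(dr, "TargetPrescriptionDose", None)
        if target is not None:
            rx_per_fx = float(target) / max(n_fractions, 1)

    arcs: list[Arc] = []
    geometry = mlc_geometry
    for beam in getattr(ds, "BeamSequence", []):
        name = getattr(beam, "BeamName", getattr(beam, "BeamNumber", "?"))
        if getattr(beam, "BeamType", "STATIC") != "DYNAMIC":
            raise PlanFormatError(f"beam {name}: not a dynamic arc (BeamType != DYNAMIC)")
        if geometry is None:
            for bld in getattr(beam, "BeamLimitingDeviceSequence", []):
                if bld.RTBeamLimitingDeviceType in ("MLCX", "MLCX1", "MLCX2"):
                    bounds = np.asarray(bld.LeafPositionBoundaries, float)
                    widths = np.diff(bounds)
                    geometry = MLCGeometry(len(widths), widths, bounds)
        cps_raw = list(beam.ControlPointSequence)
        final_w = float(getattr(beam, "FinalCumulativeMetersetWeight", 1.0) or 1.0)
        gantry = None
        direction = None
        jaw_x = jaw_y = None
        mlc_a = mlc_b = None
        cps: list[ControlPoint] = []
        for cp in cps_raw:
            if hasattr(cp, "GantryAngle"):
                gantry = float(cp.GantryAngle) % 360.0
            rot = getattr(cp, "GantryRotationDirection", None)
            if rot in ("CW", "CC"):
                direction = "CW" if rot == "CW" else "CCW"
            for bld in getattr(cp, "BeamLimitingDevicePositionSequence", []):
                kind = bld.RTBeamLimitingDeviceType
                pos = np.asarray(bld.LeafJawPositions, float)
                if kind in ("X", "ASYMX"):
                    jaw_x = (float(pos[0]), float(pos[1]))
                elif kind in ("Y", "ASYMY"):
                    jaw_y = (float(pos[0]), float(pos[1]))
                elif kind in ("MLCX", "MLCX1", "MLCX2"):
                    half = pos.size // 2
                    mlc_a, mlc_b = pos[:half].copy(), pos[half:].copy()
            if mlc_a is None:
                raise PlanFormatError(f"beam {name}: control point without MLC position sequence")
            if gantry is None or jaw_x is None or jaw_y is None:
                raise PlanFormatError(f"beam {name}: missing gantry or jaw state")
            w = float(cp.CumulativeMetersetWeight) / final_w
            cps.append(ControlPoint(gantry, w, mlc_a, mlc_b, jaw_x, jaw_y))
        weights = [c.cumulative_meterset_weight for c in cps]
        if np.any(np.diff(weights) < -1e-9):
            raise PlanValidationError(f"beam {name}: non-monotone cumulative meterset weight")
        arcs.append(Arc(cps, beam_mus.get(int(beam.BeamNumber), 0.0),
                        direction or "CW",
                        float(getattr(beam, "NominalCPSpacing", 4.0) or 4.0)))
    if not arcs:
        raise PlanFormatError(f"{path}: RT Plan contains no beams")
    if geometry is None:
        raise PlanFormatError(f"{path}: no MLCX leaf-boundary description found")
    return VMATPlan(str(getattr(ds, "RTPlanLabel", Path(path).stem)), arcs,
                    rx_per_fx, n_fractions, geometry)


def write_rtplan_dicom(plan: VMATPlan, path: str | Path) -> None:
    """Synthesise a minimal RT Plan dataset (round-trip fidelity, not clinical)."""
    pydicom = _require_pydicom()
    from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
    from pydicom.uid import ExplicitVRLittleEndian, generate_uid

    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.UID("1.2.840.10008.5.1.4.1.1.481.5")
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\x00" * 128)
    ds.Modality = "RTPLAN"
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.RTPlanLabel = plan.plan_id

    fg = Dataset()
    fg.NumberOfFractionsPlanned = plan.n_fractions
    fg.ReferencedBeamSequence = []
    dr = Dataset()
    dr.TargetPrescriptionDose = plan.rx_dose_per_fraction * plan.n_fractions
    ds.DoseReferenceSequence = [dr]

    ds.BeamSequence = []
    for bi, arc in enumerate(plan.arcs, start=1):
        beam = Dataset()
        beam.BeamNumber = bi
        beam.BeamName = f"{plan.plan_id}-arc{bi}"
        beam.BeamType = "DYNAMIC"
        beam.RadiationType = "PHOTON"
        bld = Dataset()
        bld.RTBeamLimitingDeviceType = "MLCX"
        bld.NumberOfLeafJawPairs = plan.mlc_geometry.n_pairs
        bld.LeafPositionBoundaries = [float(v) for v in plan.mlc_geometry.leaf_bound_positions]
        beam.BeamLimitingDeviceSequence = [bld]
        beam.FinalCumulativeMetersetWeight = 1.0
        beam.NumberOfControlPoints = len(arc.control_points)
        beam.ControlPointSequence = []
        for ci, cp in enumerate(arc.control_points):
            item = Dataset()
            item.ControlPointIndex = ci
            item.GantryAngle = cp.gantry_angle
            item.GantryRotationDirection = "CW" if arc.gantry_direction == "CW" else "CC"
            item.CumulativeMetersetWeight = cp.cumulative_meterset_weight
            seq = []
            for kind, vals in (
                ("ASYMX", list(cp.jaw_x)),
                ("ASYMY", list(cp.jaw_y)),
                ("MLCX", list(cp.bank_a_positions) + list(cp.bank_b_positions)),
            ):
                p = Dataset()
                p.RTBeamLimitingDeviceType = kind
                p.LeafJawPositions = [float(v) for v in vals]
                seq.append(p)
            item.BeamLimitingDevicePositionSequence = seq
            beam.ControlPointSequence.append(item)
        ds.BeamSequence.append(beam)
        rb = Dataset()
        rb.ReferencedBeamNumber = bi
        rb.BeamMeterset = arc.beam_mu
        fg.ReferencedBeamSequence.append(rb)
    ds.FractionGroupSequence = [fg]
    ds.save_as(str(path), enforce_file_format=True)
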