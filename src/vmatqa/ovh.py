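"""In-field overlap volume histograms and library-lookup dose-volume prediction.

The OVH of an organ at risk (OAR) with respect to a target gives, for each
signed expansion distance r (negative = inside the target), the fraction of
the OAR volume lying within distance r of the target surface.  The *in-field*
variant restricts both numerator and denominator to OAR voxels inside the
superior-inferior extent of the treatment fields.

Dose-volume prediction follows a library lookup: a queried patient receives,
at each relative volume level, the lowest dose achieved by any database entry
(clinical or Pareto) whose geometry at that level is at least as unfavorable
(OVH distance <= the query's).  With no eligible entry the nearest-distance
entry is used and flagged as a fallback.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy import ndimage

from .grids import DoseGrid, StructureMask

DEFAULT_LEVELS = (10.0, 30.0, 50.0, 65.0, 80.0)

__all__ = [
    "OVHCurve",
    "KBPDatabaseEntry",
    "DosePrediction",
    "signed_distance_field",
    "infield_mask",
    "compute_ovh",
    "ovh_distance_at",
    "predict_dose_volumes",
    "build_database",
    "write_database_jsonl",
    "read_database_jsonl",
    "DEFAULT_LEVELS",
]


@dataclass
class OVHCurve:
    distances: np.ndarray   # signed mm, increasing
    fractions: np.ndarray   # in [0, 1], non-decreasing, -> 1 at max distance

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, float)
        self.fractions = np.asarray(self.fractions, float)
        if self.distances.shape != self.fractions.shape:
            raise ValueError("distances and fractions must align")
        if np.any(np.diff(self.distances) <= 0):
            raise ValueError("distance lattice must be strictly increasing")
        if np.any(np.diff(self.fractions) < -1e-12):
            raise ValueError("OVH fractions must be non-decreasing")
        if np.any((self.fractions < -1e-12) | (self.fractions > 1 + 1e-12)):
            raise ValueError("OVH fractions must lie in [0, 1]")

    def to_dict(self) -> dict:
        return {"distances": self.distances.tolist(),
                "fractions": self.fractions.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "OVHCurve":
        return cls(d["distances"], d["fractions"])


def signed_distance_field(target_mask: StructureMask, grid: DoseGrid) -> np.ndarray:
    """Euclidean distance to the target surface, negative inside (mm).

    Computed on voxel centers: a voxel immediately adjacent to a target face
    gets +voxel size, the outermost in-target voxel layer -voxel size.
    """
    m = target_mask.mask
    if m.shape != grid.values.shape:
        raise ValueError("target mask shape must match grid")
    if not m.any():
        raise ValueError("target mask is empty")
    sampling = grid.voxel_size
    outside = ndimage.distance_transform_edt(~m, sampling=sampling)
    inside = ndimage.distance_transform_edt(m, sampling=sampling)
    return np.where(m, -inside, outside)


def infield_mask(oar_mask: StructureMask, grid: DoseGrid,
                 field_extent: tuple[float, float]) -> StructureMask:
    """OAR voxels whose superior-inferior (y) coordinate lies in the field."""
    y = grid.axis_coords(1)
    keep = (y >= field_extent[0]) & (y <= field_extent[1])
    out = oar_mask.mask & keep[None, :, None]
    if oar_mask.mask.any() and not out.any():
        import warnings
        warnings.warn(f"structure {oar_mask.name!r} has no in-field voxels",
                      stacklevel=2)
    return StructureMask(oar_mask.name, out)


def compute_ovh(target_mask: StructureMask, oar_mask: StructureMask,
                grid: DoseGrid, field_extent: tuple[float, float] | None = None,
                distance_step: float = 1.0) -> OVHCurve:
    """OVH(r) = fraction of in-field OAR voxels with signed distance <= r."""
    oar = (infield_mask(oar_mask, grid, field_extent)
           if field_extent is not None else oar_mask)
    if not oar.mask.any():
        raise ValueError(f"no in-field voxels for OAR {oar_mask.name!r}")
    sdf = signed_distance_field(target_mask, grid)[oar.mask]
    lo = np.floor(sdf.min() / distance_step) * distance_step
    hi = np.ceil(sdf.max() / distance_step) * distance_step
    distances = np.arange(lo, hi + distance_step / 2, distance_step)
    fractions = np.array([(sdf <= r).mean() for r in distances])
    return OVHCurve(distances, fractions)


def ovh_distance_at(curve: OVHCurve, v: float) -> float:
    """Smallest distance (mm) at which the OVH reaches v% volume (interpolated)."""
    if not 0.0 <= v <= 100.0:
        raise ValueError("volume level must be in [0, 100]")
    q = v / 100.0
    f, d = curve.fractions, curve.distances
    if q <= f[0]:
        return float(d[0])
    idx = np.nonzero(f >= q - 1e-15)[0]
    if idx.size == 0:
        return float(d[-1])
    i = int(idx[0])
    f0, f1 = f[i - 1], f[i]
    if f1 == f0:
        return float(d[i])
    return float(d[i - 1] + (q - f0) / (f1 - f0) * (d[i] - d[i - 1]))


@dataclass
class KBPDatabaseEntry:
    patient_id: str
    source: str  # "clinical" | "pareto"
    ovh_curves: dict[str, OVHCurve]             # per OAR
    achieved_doses: dict[str, dict[float, float]]  # per OAR: level% -> Gy

    def __post_init__(self) -> None:
        if self.source not in ("clinical", "pareto"):
            raise ValueError("source must be 'clinical' or 'pareto'")
        for oar, doses in self.achieved_doses.items():
            missing = set(DEFAULT_LEVELS) - set(doses)
            if missing:
                raise ValueError(f"entry {self.patient_id}/{oar} missing levels {missing}")
            if any(v <= 0 for v in doses.values()):
                raise ValueError(f"entry {self.patient_id}/{oar}: doses must be positive")

    def to_dict(self) -> dict:
        return {
            "patient_id": self.patient_id,
            "source": self.source,
            "ovh_curves": {k: c.to_dict() for k, c in self.ovh_curves.items()},
            "achieved_doses": {k: {str(l): v for l, v in d.items()}
                               for k, d in self.achieved_doses.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "KBPDatabaseEntry":
        return cls(
            d["patient_id"], d["source"],
            {k: OVHCurve.from_dict(c) for k, c in d["ovh_curves"].items()},
            {k: {float(l): v for l, v in doses.items()}
             for k, doses in d["achieved_doses"].items()},
        )


@dataclass
class DosePrediction:
    """Per-OAR predicted dose at each relative volume level, with provenance."""

    doses: dict[str, dict[float, float]]
    provenance: dict[str, dict[float, dict]]

    def to_dict(self) -> dict:
        return {"doses": {k: {str(l): v for l, v in d.items()}
                          for k, d in self.doses.items()},
                "provenance": {k: {str(l): p for l, p in d.items()}
                               for k, d in self.provenance.items()}}


def predict_dose_volumes(query: dict[str, OVHCurve],
                         db: Sequence[KBPDatabaseEntry],
                         levels: Iterable[float] = DEFAULT_LEVELS) -> DosePrediction:
    """Lowest achieved dose among entries with geometry at least as unfavorable.

    An entry is eligible at level v when its OVH distance at v does not exceed
    the query's (its OAR sits at least as close to the target).  The minimum
    runs over clinical and Pareto entries alike.
    """
    if not db:
        raise ValueError("KBP database is empty")
    doses: dict[str, dict[float, float]] = {}
    provenance: dict[str, dict[float, dict]] = {}
    for oar, q_curve in query.items():
        doses[oar] = {}
        provenance[oar] = {}
        candidates = [e for e in db if oar in e.ovh_curves and oar in e.achieved_doses]
        if not candidates:
            raise ValueError(f"no database entry carries OAR {oar!r}")
        for v in levels:
            q_d = ovh_distance_at(q_curve, v)
            entry_d = {e.patient_id: ovh_distance_at(e.ovh_curves[oar], v)
                       for e in candidates}
            eligible = [e for e in candidates if entry_d[e.patient_id] <= q_d + 1e-12]
            if eligible:
                best = min(eligible, key=lambda e: e.achieved_doses[oar][v])
                doses[oar][v] = best.achieved_doses[oar][v]
                provenance[oar][v] = {
                    "matched": [e.patient_id for e in eligible],
                    "selected": best.patient_id, "fallback": False}
            else:
                nearest = min(candidates,
                              key=lambda e: abs(entry_d[e.patient_id] - q_d))
                doses[oar][v] = nearest.achieved_doses[oar][v]
                provenance[oar][v] = {"matched": [], "selected": nearest.patient_id,
                                      "fallback": True}
    return DosePrediction(doses, provenance)


def build_database(cohort: Iterable[tuple[str, str, dict[str, OVHCurve],
                                          dict[str, dict[float, float]]]]
                   ) -> list[KBPDatabaseEntry]:
    """Assemble entries from (patient_id, source, ovh curves, achieved doses)."""
    return [KBPDatabaseEntry(pid, source, curves, achieved)
            for pid, source, curves, achieved in cohort]


def write_database_jsonl(db: Sequence[KBPDatabaseEntry], path: str | Path) -> None:
    with open(path, "w") as fh:
        for entry in db:
            fh.write(json.dumps(entry.to_dict()) + "\n")


def read_database_jsonl(path: str | Path) -> list[KBPDatabaseEntry]:
    out = []
    with open(path) as fh:
        for line in fh:
            if line.strip():
                out.append(KBPDatabaseEntry.from_dict(json.loads(line)))
    return out
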