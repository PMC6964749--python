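"""Plan complexity metrics: normalized MU, MCS, edge metric, and leaf motion.

All four metrics are computed from the control-point sequences of a
:class:`~vmatqa.rtplan.VMATPlan`:

* ``mu_per_gy`` — total planned MU normalized by the fractional prescription.
* ``compute_mcs`` — modulation complexity score in [0, 1] (1 = unmodulated),
  the meterset-weighted product of leaf-sequence variability (LSV) and
  aperture-area variability (AAV) averaged over adjacent control points.
* ``compute_edge_metric`` — meterset-weighted ratio of aperture perimeter
  components to aperture area, ``(C1 * L_end + C2 * L_side) / A`` with
  default scaling factors C1 = 0, C2 = 1 (units 1/mm).
* ``compute_leaf_motion`` — mean absolute leaf displacement per degree of
  gantry rotation over all in-jaw leaves and control-point transitions
  (mm/deg).

A leaf pair is "within the jaws" when its Y interval overlaps the Y jaw
opening by more than 0.5 mm.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .rtplan import Arc, ControlPoint, MLCGeometry, VMATPlan, gantry_delta_deg

logger = logging.getLogger(__name__)

__all__ = [
    "Aperture",
    "ComplexityReport",
    "mu_per_gy",
    "segment_aperture",
    "in_jaw_pairs",
    "compute_lsv",
    "compute_aav",
    "compute_mcs",
    "compute_edge_metric",
    "compute_leaf_motion",
    "complexity_report",
    "cp_meterset_fractions",
]

JAW_OVERLAP_MIN = 0.5  # mm of Y overlap required for a pair to count as in-jaw


@dataclass
class Aperture:
    """Per-pair open intervals of one control point, clipped to the jaws."""

    lo: np.ndarray        # clipped bank-A edge per in-jaw pair, mm
    hi: np.ndarray        # clipped bank-B edge per in-jaw pair, mm
    widths: np.ndarray    # leaf widths of the in-jaw pairs, mm
    pair_indices: np.ndarray  # indices into the full MLC pair list
    raw_a: np.ndarray     # unclipped bank positions (for LSV)
    raw_b: np.ndarray

    @property
    def gaps(self) -> np.ndarray:
        return np.maximum(self.hi - self.lo, 0.0)

    @property
    def area(self) -> float:
        return float(np.sum(self.gaps * self.widths))


def in_jaw_pairs(cp: ControlPoint, geometry: MLCGeometry) -> np.ndarray:
    """Indices of leaf pairs whose Y span overlaps jaw_y by > 0.5 mm."""
    b = geometry.leaf_bound_positions
    overlap = np.minimum(b[1:], cp.jaw_y[1]) - np.maximum(b[:-1], cp.jaw_y[0])
    return np.nonzero(overlap > JAW_OVERLAP_MIN)[0]


def segment_aperture(cp: ControlPoint, geometry: MLCGeometry) -> Aperture:
    """Open interval per in-jaw pair: [max(bank_A, x1), min(bank_B, x2)]."""
    idx = in_jaw_pairs(cp, geometry)
    lo = np.maximum(cp.bank_a_positions[idx], cp.jaw_x[0])
    hi = np.minimum(cp.bank_b_positions[idx], cp.jaw_x[1])
    return Aperture(lo, hi, geometry.leaf_widths[idx], idx,
                    cp.bank_a_positions[idx], cp.bank_b_positions[idx])


# ---------------------------------------------------------------------------
# MCS components


def compute_lsv(aperture: Aperture) -> float:
    """Leaf-sequence variability of one aperture, in [0, 1].

    Per bank: sum over adjacent in-jaw pairs of (pos_max - |p_n - p_{n+1}|)
    over (N - 1) * pos_max, where pos_max is the spread (max - min) of that
    bank's positions.  A bank with zero spread contributes 1 by convention.
    The LSV is the product of the two bank terms.
    """
    if aperture.raw_a.size < 2:
        raise ValueError("LSV needs at least 2 in-jaw leaf pairs")
    out = 1.0
    for pos in (aperture.raw_a, aperture.raw_b):
        pos_max = float(pos.max() - pos.min())
        if pos_max == 0.0:
            continue
        n = pos.size
        out *= float(np.sum(pos_max - np.abs(np.diff(pos)))) / ((n - 1) * pos_max)
    return out


def _arc_max_gaps(arc: Arc, geometry: MLCGeometry) -> np.ndarray:
    """Per-pair maximal opening over the arc (leaf extremes, jaw-clipped)."""
    a = np.stack([cp.bank_a_positions for cp in arc.control_points])
    b = np.stack([cp.bank_b_positions for cp in arc.control_points])
    jaw_lo = min(cp.jaw_x[0] for cp in arc.control_points)
    jaw_hi = max(cp.jaw_x[1] for cp in arc.control_points)
    lo = np.maximum(a.min(axis=0), jaw_lo)
    hi = np.minimum(b.max(axis=0), jaw_hi)
    return np.maximum(hi - lo, 0.0)


def compute_aav(aperture: Aperture, arc_max_gaps: np.ndarray) -> float:
    """Aperture-area variability: aperture opening over the arc-maximal opening.

    ``arc_max_gaps`` holds, for every pair of the full MLC, the gap defined by
    that leaf's extreme positions over all control points of the arc.  An arc
    whose maximal aperture is empty has AAV = 1 by convention.
    """
    denom = float(np.sum(arc_max_gaps[aperture.pair_indices] * aperture.widths))
    if denom == 0.0:
        return 1.0
    return float(np.sum(aperture.gaps * aperture.widths)) / denom


def cp_meterset_fractions(arc: Arc) -> np.ndarray:
    """Per-control-point meterset weight: half the adjacent interval deltas."""
    w = np.array([cp.cumulative_meterset_weight for cp in arc.control_points])
    dw = np.diff(w)
    out = np.zeros(w.size)
    out[:-1] += dw / 2.0
    out[1:] += dw / 2.0
    return out


def _arc_mcs(arc: Arc, geometry: MLCGeometry) -> float:
    cps = arc.control_points
    if len(cps) < 2:
        raise ValueError("MCS needs at least 2 control points per arc")
    max_gaps = _arc_max_gaps(arc, geometry)
    aps = [segment_aperture(cp, geometry) for cp in cps]
    lsv = np.array([compute_lsv(ap) for ap in aps])
    aav = np.array([compute_aav(ap, max_gaps) for ap in aps])
    w = np.diff([cp.cumulative_meterset_weight for cp in cps])
    return float(np.sum(0.5 * (aav[:-1] + aav[1:]) * 0.5 * (lsv[:-1] + lsv[1:]) * w))


def compute_mcs(plan: VMATPlan) -> float:
    """Plan MCS: MU-weighted mean of the per-arc scores; in [0, 1]."""
    scores = np.array([_arc_mcs(arc, plan.mlc_geometry) for arc in plan.arcs])
    mus = np.array([arc.beam_mu for arc in plan.arcs])
    return float(np.sum(scores * mus) / np.sum(mus))


# ---------------------------------------------------------------------------
# Edge metric


def _interval_symdiff(lo1, hi1, lo2, hi2) -> float:
    """Length of the symmetric difference of two (possibly empty) intervals."""
    len1 = max(hi1 - lo1, 0.0)
    len2 = max(hi2 - lo2, 0.0)
    if len1 == 0.0 or len2 == 0.0:
        return len1 + len2
    inter = max(min(hi1, hi2) - max(lo1, lo2), 0.0)
    return len1 + len2 - 2.0 * inter


def aperture_edge_lengths(aperture: Aperture) -> tuple[float, float]:
    """(L_end, L_side): leaf-end and leaf-side perimeter components, mm.

    Leaf ends run along the leaf-side axis (one per bank per open pair, each
    of the pair's width).  Leaf sides run along the travel axis: between
    adjacent rows they contribute the symmetric difference of the two open
    intervals; a row bordering a closed pair or the top/bottom of the in-jaw
    stack contributes its full gap length.
    """
    gaps = aperture.gaps
    open_rows = gaps > 0
    l_end = float(np.sum(2.0 * aperture.widths[open_rows]))
    lo = np.where(open_rows, aperture.lo, 0.0)
    hi = np.where(open_rows, aperture.hi, 0.0)
    l_side = 0.0
    n = gaps.size
    for i in range(n + 1):  # boundaries between rows, incl. virtual empty ends
        lo1, hi1 = (lo[i - 1], hi[i - 1]) if i > 0 else (0.0, 0.0)
        lo2, hi2 = (lo[i], hi[i]) if i < n else (0.0, 0.0)
        # non-adjacent pair indices (jaw split) also break contiguity
        if 0 < i < n and aperture.pair_indices[i] != aperture.pair_indices[i - 1] + 1:
            l_side += max(hi1 - lo1, 0.0) + max(hi2 - lo2, 0.0)
        else:
            l_side += _interval_symdiff(lo1, hi1, lo2, hi2)
    return l_end, l_side


def compute_edge_metric(plan: VMATPlan, c1: float = 0.0, c2: float = 1.0) -> float:
    """Meterset-weighted (C1*L_end + C2*L_side)/area over all control points.

    Control points carrying meterset weight but a degenerate (zero-area)
    aperture are excluded from the weighted sum with a logged warning.
    """
    total = 0.0
    total_mu = plan.total_mu
    for ai, arc in enumerate(plan.arcs):
        w_cp = cp_meterset_fractions(arc) * (arc.beam_mu / total_mu)
        for ci, cp in enumerate(arc.control_points):
            if w_cp[ci] == 0.0:
                continue
            ap = segment_aperture(cp, plan.mlc_geometry)
            area = ap.area
            if area <= 0.0:
                logger.warning("arc %d CP %d: zero-area aperture with weight %.4g "
                               "excluded from edge metric", ai, ci, w_cp[ci])
                continue
            l_end, l_side = aperture_edge_lengths(ap)
            total += w_cp[ci] * (c1 * l_end + c2 * l_side) / area
    return total


# ---------------------------------------------------------------------------
# Leaf motion


def compute_leaf_motion(plan: VMATPlan) -> float:
    """Mean |leaf travel| per degree of gantry rotation, mm/deg.

    Pools every (transition, in-jaw leaf end) sample across both banks and
    all arcs with equal weight.  In-jaw membership is taken at the earlier
    control point of each transition.
    """
    samples: list[np.ndarray] = []
    for arc in plan.arcs:
        cps = arc.control_points
        for i in range(1, len(cps)):
            dg = abs(gantry_delta_deg(cps[i - 1].gantry_angle, cps[i].gantry_angle))
            if dg < 1e-12:
                raise ValueError(f"zero gantry increment between control points "
                                 f"{i - 1} and {i}")
            idx = in_jaw_pairs(cps[i - 1], plan.mlc_geometry)
            da = np.abs(cps[i].bank_a_positions[idx] - cps[i - 1].bank_a_positions[idx])
            db = np.abs(cps[i].bank_b_positions[idx] - cps[i - 1].bank_b_positions[idx])
            samples.append(np.concatenate([da, db]) / dg)
    if not samples:
        raise ValueError("leaf motion needs at least 2 control points")
    return float(np.concatenate(samples).mean())


# ---------------------------------------------------------------------------
# Aggregate report


def mu_per_gy(plan: VMATPlan) -> float:
    """Total MU normalized by the fractional prescription dose (MU/Gy)."""
    if plan.rx_dose_per_fraction <= 0:
        raise ValueError("prescription dose per fraction must be positive")
    return plan.total_mu / plan.rx_dose_per_fraction


@dataclass
class ComplexityReport:
    plan_id: str
    mu_per_gy: float
    mcs: float
    em: float
    lm: float
    per_arc: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.mcs <= 1.0 + 1e-12):
            raise ValueError(f"MCS {self.mcs} outside [0, 1]")
        if self.em < 0 or self.lm < 0 or self.mu_per_gy <= 0:
            raise ValueError("EM/LM must be >= 0 and MU/Gy > 0")

    def to_dict(self) -> dict:
        return {"plan_id": self.plan_id, "mu_per_gy": self.mu_per_gy,
                "mcs": self.mcs, "em": self.em, "lm": self.lm,
                "per_arc": self.per_arc}

    @classmethod
    def from_dict(cls, d: dict) -> "ComplexityReport":
        return cls(d["plan_id"], d["mu_per_gy"], d["mcs"], d["em"], d["lm"],
                   d.get("per_arc", []))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))


def complexity_report(plan: VMATPlan, c1: float = 0.0, c2: float = 1.0) -> ComplexityReport:
    per_arc = []
    for ai, arc in enumerate(plan.arcs):
        single = VMATPlan(plan.plan_id, [arc], plan.rx_dose_per_fraction,
                          plan.n_fractions, plan.mlc_geometry)
        per_arc.append({
            "arc_index": ai,
            "beam_mu": arc.beam_mu,
            "mcs": _arc_mcs(arc, plan.mlc_geometry),
            "em": compute_edge_metric(single, c1, c2),
            "lm": compute_leaf_motion(single),
        })
    return ComplexityReport(plan.plan_id, mu_per_gy(plan), compute_mcs(plan),
                            compute_edge_metric(plan, c1, c2),
                            compute_leaf_motion(plan), per_arc)
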