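import json

import numpy as np
import pytest
from scipy.stats import spearmanr

from vmatqa.complexity import (
    ComplexityReport,
    aperture_edge_lengths,
    compute_aav,
    compute_edge_metric,
    compute_leaf_motion,
    compute_lsv,
    compute_mcs,
    complexity_report,
    mu_per_gy,
    segment_aperture,
)
from vmatqa.rtplan import Arc, MLCGeometry, VMATPlan
from vmatqa.synthetic import generate_plan, static_rectangle_plan

from .conftest import make_cp, make_plan, tiny_geometry


class TestMuPerGy:
    def test_examples(self, modulated_plan):
        plan = make_plan([make_cp(0, 0, [0] * 3, [10] * 3),
                          make_cp(4, 1, [0] * 3, [10] * 3)], beam_mu=600.0, rx=2.0)
        assert mu_per_gy(plan) == pytest.approx(300.0)
        plan.arcs[0].beam_mu = 450.0
        assert mu_per_gy(plan) == pytest.approx(225.0)

    def test_scale_invariance(self):
        plan = make_plan([make_cp(0, 0, [0] * 3, [10] * 3),
                          make_cp(4, 1, [0] * 3, [10] * 3)], beam_mu=600.0, rx=2.0)
        k = 3.7
        scaled = make_plan([make_cp(0, 0, [0] * 3, [10] * 3),
                            make_cp(4, 1, [0] * 3, [10] * 3)],
                           beam_mu=600.0 * k, rx=2.0 * k)
        assert mu_per_gy(plan) == pytest.approx(mu_per_gy(scaled))

    def test_zero_prescription_raises(self):
        plan = make_plan([make_cp(0, 0, [0] * 3, [10] * 3),
                          make_cp(4, 1, [0] * 3, [10] * 3)], rx=0.0)
        with pytest.raises(ValueError):
            mu_per_gy(plan)


class TestSegmentAperture:
    def test_pair_behind_jaw_excluded(self):
        # tiny geometry: pair y-bands are [-15,-5], [-5,5], [5,15]
        cp = make_cp(0, 0, [-20, -20, -20], [20, 20, 20], jaw_y=(-5.0, 15.0))
        ap = segment_aperture(cp, tiny_geometry())
        assert list(ap.pair_indices) == [1, 2]

    def test_unclipped_pair_passes_through(self):
        cp = make_cp(0, 0, [-20, -20, -20], [20, 20, 20])
        ap = segment_aperture(cp, tiny_geometry())
        assert np.allclose(ap.gaps, 40.0)

    def test_jaw_bisecting_gap_halves_length(self):
        cp = make_cp(0, 0, [-20, -20, -20], [20, 20, 20], jaw_x=(-20.0, 0.0))
        ap = segment_aperture(cp, tiny_geometry())
        assert np.allclose(ap.gaps, 20.0)


class TestLsvAav:
    def test_uniform_bank_gives_one(self):
        cp = make_cp(0, 0, [5, 5, 5], [20, 20, 20])
        assert compute_lsv(segment_aperture(cp, tiny_geometry())) == pytest.approx(1.0)

    def test_hand_example(self):
        # one bank {0, 5, 10}, other constant -> [(10-5)+(10-5)]/(2*10) = 0.5
        cp = make_cp(0, 0, [0, 5, 10], [30, 30, 30])
        assert compute_lsv(segment_aperture(cp, tiny_geometry())) == pytest.approx(0.5)

    def test_static_arc_aav_is_one(self):
        cps = [make_cp(4.0 * i, i / 2, [0, -5, 0], [10, 25, 10]) for i in range(3)]
        plan = make_plan(cps)
        from vmatqa.complexity import _arc_max_gaps

        max_gaps = _arc_max_gaps(plan.arcs[0], plan.mlc_geometry)
        for cp in cps:
            assert compute_aav(segment_aperture(cp, plan.mlc_geometry),
                               max_gaps) == pytest.approx(1.0)


def brute_force_mcs(plan):
    """Independent transcription of the MCS formula with explicit loops."""
    total = 0.0
    total_mu = sum(a.beam_mu for a in plan.arcs)
    bounds = plan.mlc_geometry.leaf_bound_positions
    for arc in plan.arcs:
        cps = arc.control_points
        lsv, aav = [], []
        # arc-maximal opening per pair from leaf extremes, clipped to jaws
        jaw_lo = min(c.jaw_x[0] for c in cps)
        jaw_hi = max(c.jaw_x[1] for c in cps)
        max_gap = {}
        for p in range(plan.mlc_geometry.n_pairs):
            lo = max(min(c.bank_a_positions[p] for c in cps), jaw_lo)
            hi = min(max(c.bank_b_positions[p] for c in cps), jaw_hi)
            max_gap[p] = max(hi - lo, 0.0)
        for cp in cps:
            in_jaw = [p for p in range(plan.mlc_geometry.n_pairs)
                      if min(bounds[p + 1], cp.jaw_y[1])
                      - max(bounds[p], cp.jaw_y[0]) > 0.5]
            term = 1.0
            for bank in (cp.bank_a_positions, cp.bank_b_positions):
                pos = [bank[p] for p in in_jaw]
                pos_max = max(pos) - min(pos)
                if pos_max > 0:
                    s = sum(pos_max - abs(pos[i] - pos[i + 1])
                            for i in range(len(pos) - 1))
                    term *= s / ((len(pos) - 1) * pos_max)
            lsv.append(term)
            num = den = 0.0
            for p in in_jaw:
                w = bounds[p + 1] - bounds[p]
                gap = max(min(cp.bank_b_positions[p], cp.jaw_x[1])
                          - max(cp.bank_a_positions[p], cp.jaw_x[0]), 0.0)
                num += gap * w
                den += max_gap[p] * w
            aav.append(num / den if den > 0 else 1.0)
        arc_mcs = 0.0
        for i in range(len(cps) - 1):
            dw = (cps[i + 1].cumulative_meterset_weight
                  - cps[i].cumulative_meterset_weight)
            arc_mcs += ((aav[i] + aav[i + 1]) / 2) * ((lsv[i] + lsv[i + 1]) / 2) * dw
        total += arc_mcs * arc.beam_mu / total_mu
    return total


class TestMcs:
    def test_static_rectangle_is_one(self):
        assert compute_mcs(static_rectangle_plan()) == pytest.approx(1.0, abs=1e-9)

    def test_bounds_on_generator_plans(self, conformal_plan, modulated_plan):
        for plan in (conformal_plan, modulated_plan):
            assert 0.0 <= compute_mcs(plan) <= 1.0

    def test_hand_built_three_cp_arc_matches_oracle(self):
        cps = [
            make_cp(0.0, 0.0, [-30, -10, -20], [10, 30, 15]),
            make_cp(4.0, 0.4, [-25, -15, -10], [5, 20, 25]),
            make_cp(8.0, 1.0, [-10, -20, -15], [15, 10, 20]),
        ]
        plan = make_plan(cps)
        assert compute_mcs(plan) == pytest.approx(brute_force_mcs(plan), abs=1e-9)

    def test_modulation_decreases_mcs(self, conformal_plan, modulated_plan):
        assert compute_mcs(modulated_plan) < compute_mcs(conformal_plan)

    def test_jitter_monotonically_decreases_mcs(self, anatomy, spec):
        rng_scores = []
        for level in (0.0, 0.25, 0.5, 0.75, 1.0):
            scores = [compute_mcs(generate_plan(anatomy, level, spec, s))
                      for s in range(40, 44)]
            rng_scores.append(np.mean(scores))
        rho = spearmanr([0.0, 0.25, 0.5, 0.75, 1.0], rng_scores).statistic
        assert rho < 0


class TestEdgeMetric:
    def test_single_open_pair(self):
        # w = 10 mm, g = 20 mm, C1 = 0, C2 = 1 -> 2g/(wg) = 0.2 /mm
        cps = [make_cp(0, 0, [0, -10, 0], [0, 10, 0]),
               make_cp(4, 1, [0, -10, 0], [0, 10, 0])]
        assert compute_edge_metric(make_plan(cps)) == pytest.approx(0.2)

    def test_two_identical_adjacent_pairs(self):
        cps = [make_cp(0, 0, [-10, -10, 0], [10, 10, 0]),
               make_cp(4, 1, [-10, -10, 0], [10, 10, 0])]
        assert compute_edge_metric(make_plan(cps)) == pytest.approx(0.1)

    def test_zero_scaling_factors(self, modulated_plan):
        assert compute_edge_metric(modulated_plan, c1=0.0, c2=0.0) == 0.0

    def test_c1_counts_leaf_ends(self):
        cps = [make_cp(0, 0, [0, -10, 0], [0, 10, 0]),
               make_cp(4, 1, [0, -10, 0], [0, 10, 0])]
        # L_end = 2w = 20, L_side = 2g = 40, A = 200
        assert compute_edge_metric(make_plan(cps), c1=1.0, c2=1.0) == \
            pytest.approx((20 + 40) / 200)

    def test_translation_invariance(self, modulated_plan):
        shifted = VMATPlan(
            modulated_plan.plan_id,
            [Arc([make_cp(c.gantry_angle, c.cumulative_meterset_weight,
                          c.bank_a_positions + 7.0, c.bank_b_positions + 7.0,
                          (c.jaw_x[0] + 7.0, c.jaw_x[1] + 7.0), c.jaw_y)
                  for c in a.control_points], a.beam_mu, a.gantry_direction)
             for a in modulated_plan.arcs],
            modulated_plan.rx_dose_per_fraction, modulated_plan.n_fractions,
            modulated_plan.mlc_geometry)
        assert compute_edge_metric(shifted) == pytest.approx(
            compute_edge_metric(modulated_plan), rel=1e-9)

    def test_magnification_scales_inverse(self):
        def plan_at_scale(s):
            geo = tiny_geometry(width=10.0 * s)
            cps = [make_cp(0, 0, np.array([-30, -10, -20.]) * s,
                           np.array([10, 30, 15.]) * s,
                           jaw_x=(-100 * s, 100 * s), jaw_y=(-100 * s, 100 * s)),
                   make_cp(4, 1, np.array([-30, -10, -20.]) * s,
                           np.array([10, 30, 15.]) * s,
                           jaw_x=(-100 * s, 100 * s), jaw_y=(-100 * s, 100 * s))]
            return make_plan(cps, geometry=geo)

        em1 = compute_edge_metric(plan_at_scale(1.0))
        em2 = compute_edge_metric(plan_at_scale(2.0))
        assert em2 == pytest.approx(em1 / 2.0, rel=1e-9)


class TestLeafMotion:
    def test_static_leaves_zero(self):
        assert compute_leaf_motion(static_rectangle_plan()) == 0.0

    def test_single_moving_leaf_mean(self):
        # 10 in-jaw pairs (20 leaf ends); one end moves 8 mm over 4 deg
        geo = tiny_geometry(n_pairs=10, width=10.0)
        a0 = np.zeros(10)
        b0 = np.full(10, 20.0)
        a1 = a0.copy()
        a1[4] = 8.0
        cps = [make_cp(0.0, 0.0, a0, b0), make_cp(4.0, 1.0, a1, b0)]
        plan = make_plan(cps, geometry=geo)
        assert compute_leaf_motion(plan) == pytest.approx((8.0 / 4.0) / 20.0)

    def test_generator_respects_limit(self, modulated_plan):
        assert compute_leaf_motion(modulated_plan) <= 7.0

    def test_reversed_arc_identical(self, modulated_plan):
        arc = modulated_plan.arcs[0]
        n = len(arc.control_points)
        rev_cps = [make_cp(c.gantry_angle, 1.0 - arc.control_points[n - 1 - i]
                           .cumulative_meterset_weight,
                           arc.control_points[n - 1 - i].bank_a_positions,
                           arc.control_points[n - 1 - i].bank_b_positions,
                           arc.control_points[n - 1 - i].jaw_x,
                           arc.control_points[n - 1 - i].jaw_y)
                   for i, c in enumerate(arc.control_points)]
        fwd = VMATPlan("f", [arc], 2.0, 38, modulated_plan.mlc_geometry)
        rev = VMATPlan("r", [Arc(rev_cps, arc.beam_mu, "CCW")], 2.0, 38,
                       modulated_plan.mlc_geometry)
        assert compute_leaf_motion(rev) == pytest.approx(compute_leaf_motion(fwd))

    def test_zero_gantry_increment_raises(self):
        cps = [make_cp(10.0, 0.0, [0] * 3, [10] * 3),
               make_cp(10.0, 1.0, [0] * 3, [12] * 3)]
        with pytest.raises(ValueError):
            compute_leaf_motion(make_plan(cps))


class TestReport:
    def test_matches_individual_metrics(self, modulated_plan):
        rep = complexity_report(modulated_plan)
        assert rep.mu_per_gy == pytest.approx(mu_per_gy(modulated_plan))
        assert rep.mcs == pytest.approx(compute_mcs(modulated_plan))
        assert rep.em == pytest.approx(compute_edge_metric(modulated_plan))
        assert rep.lm == pytest.approx(compute_leaf_motion(modulated_plan))
        assert len(rep.per_arc) == len(modulated_plan.arcs)

    def test_json_round_trip(self, modulated_plan, tmp_path):
        rep = complexity_report(modulated_plan)
        path = tmp_path / "report.json"
        rep.to_json(path)
        back = ComplexityReport.from_dict(json.loads(path.read_text()))
        assert back == rep

    def test_batch_over_cohort(self, spec):
        from vmatqa.synthetic import generate_anatomy

        rows = []
        for i in range(5):
            anatomy = generate_anatomy(spec, i)
            plan = generate_plan(anatomy, 0.4, spec, i, plan_id=f"p{i}")
            rows.append(complexity_report(plan).to_dict())
        assert len(rows) == 5
        assert all(0 <= r["mcs"] <= 1 for r in rows)
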