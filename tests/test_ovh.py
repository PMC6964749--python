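import numpy as np
import pytest

from vmatqa.grids import DoseGrid, StructureMask
from vmatqa.ovh import (
    DEFAULT_LEVELS,
    KBPDatabaseEntry,
    OVHCurve,
    build_database,
    compute_ovh,
    infield_mask,
    ovh_distance_at,
    predict_dose_volumes,
    read_database_jsonl,
    signed_distance_field,
    write_database_jsonl,
)


def cube_grid(n=20, voxel=2.0):
    return DoseGrid(np.zeros((n, n, n)), (voxel, voxel, voxel))


def cube_mask(n, lo, hi, name="m"):
    m = np.zeros((n, n, n), bool)
    m[lo:hi, lo:hi, lo:hi] = True
    return StructureMask(name, m)


class TestSignedDistance:
    def test_adjacent_voxel_positive_one_voxel(self):
        grid = cube_grid()
        target = cube_mask(20, 8, 12)
        sdf = signed_distance_field(target, grid)
        assert sdf[12, 9, 9] == pytest.approx(2.0)  # one voxel outside a face

    def test_interior_negative(self):
        grid = cube_grid()
        target = cube_mask(20, 6, 14)
        sdf = signed_distance_field(target, grid)
        assert sdf[10, 10, 10] < 0

    def test_empty_target_raises(self):
        grid = cube_grid()
        with pytest.raises(ValueError):
            signed_distance_field(cube_mask(20, 0, 0), grid)


class TestInfieldMask:
    def test_full_field_identity(self):
        grid = cube_grid()
        oar = cube_mask(20, 5, 15)
        out = infield_mask(oar, grid, (-1000.0, 1000.0))
        assert np.array_equal(out.mask, oar.mask)

    def test_slab_excluding_superior_third(self):
        grid = cube_grid(n=30, voxel=2.0)  # y coords -29..29
        oar = StructureMask("oar", np.ones((30, 30, 30), bool))
        y = grid.axis_coords(1)
        cut = y[20] - 1e-9  # keep first 20 of 30 y-slices
        out = infield_mask(oar, grid, (y[0], cut))
        assert out.n_voxels == pytest.approx(oar.n_voxels * 2 / 3)

    def test_empty_intersection_warns(self):
        grid = cube_grid()
        oar = cube_mask(20, 5, 15)
        with pytest.warns(UserWarning):
            out = infield_mask(oar, grid, (1000.0, 2000.0))
        assert out.n_voxels == 0


def brute_force_ovh(target, oar, grid, distances):
    """Per-voxel oracle: nearest-surface distance by direct minimization."""
    vs = grid.voxel_size
    coords = [grid.axis_coords(i) for i in range(3)]
    t_idx = np.argwhere(target.mask)
    o_idx = np.argwhere(oar.mask)
    t_pts = np.stack([coords[i][t_idx[:, i]] for i in range(3)], axis=1)
    not_t = np.argwhere(~target.mask)
    nt_pts = np.stack([coords[i][not_t[:, i]] for i in range(3)], axis=1)
    sdf = []
    for idx in o_idx:
        p = np.array([coords[i][idx[i]] for i in range(3)])
        if target.mask[tuple(idx)]:
            sdf.append(-np.sqrt(((nt_pts - p) ** 2).sum(axis=1)).min())
        else:
            sdf.append(np.sqrt(((t_pts - p) ** 2).sum(axis=1)).min())
    sdf = np.array(sdf)
    return np.array([(sdf <= r).mean() for r in distances])


class TestComputeOvh:
    def test_oar_inside_target(self):
        grid = cube_grid()
        target = cube_mask(20, 4, 16, "t")
        oar = cube_mask(20, 8, 12, "o")
        curve = compute_ovh(target, oar, grid)
        assert np.interp(0.0, curve.distances, curve.fractions) == pytest.approx(1.0)

    def test_disjoint_zero_below_min_distance(self):
        grid = cube_grid(n=30)
        target = cube_mask(30, 2, 8, "t")
        oar = cube_mask(30, 12, 18, "o")  # >= 8 mm surface gap at 2 mm voxels
        curve = compute_ovh(target, oar, grid)
        below = curve.distances < 8.0
        assert np.all(curve.fractions[below] == 0.0)

    def test_concentric_cubes_match_brute_force(self):
        grid = cube_grid(n=14, voxel=2.0)
        target = cube_mask(14, 5, 9, "t")
        shell = cube_mask(14, 3, 11, "o").mask & ~cube_mask(14, 5, 9).mask
        oar = StructureMask("shell", shell)
        curve = compute_ovh(target, oar, grid)
        expected = brute_force_ovh(target, oar, grid, curve.distances)
        assert np.allclose(curve.fractions, expected, atol=1e-12)

    def test_monotone_and_reaches_one(self):
        grid = cube_grid()
        target = cube_mask(20, 8, 12, "t")
        oar = cube_mask(20, 3, 18, "o")
        curve = compute_ovh(target, oar, grid)
        assert np.all(np.diff(curve.fractions) >= 0)
        assert curve.fractions[-1] == pytest.approx(1.0)


class TestDistanceAt:
    def test_v100_max_distance(self):
        curve = OVHCurve([0.0, 1.0, 2.0], [0.2, 0.7, 1.0])
        assert ovh_distance_at(curve, 100.0) == 2.0

    def test_interpolated_midpoint(self):
        curve = OVHCurve([0.0, 1.0], [0.0, 1.0])
        assert ovh_distance_at(curve, 50.0) == pytest.approx(0.5)

    def test_v0_min_distance(self):
        curve = OVHCurve([-3.0, 0.0, 2.0], [0.1, 0.5, 1.0])
        assert ovh_distance_at(curve, 0.0) == -3.0


def entry(pid, source, dist, dose, oar="bladder"):
    """One-OAR entry whose OVH reaches every level at distance ``dist``."""
    curve = OVHCurve([dist - 1e-6, dist], [0.0, 1.0])
    return KBPDatabaseEntry(pid, source, {oar: curve},
                            {oar: {lv: dose for lv in DEFAULT_LEVELS}})


class TestPredict:
    def test_eligibility_rule(self):
        db = [entry("a", "clinical", 10.0, 40.0), entry("b", "clinical", 15.0, 35.0)]
        query = {"bladder": OVHCurve([12.0 - 1e-6, 12.0], [0.0, 1.0])}
        pred = predict_dose_volumes(query, db, [30.0])
        assert pred.doses["bladder"][30.0] == 40.0
        assert pred.provenance["bladder"][30.0]["matched"] == ["a"]

    def test_pareto_entry_lowers_objective(self):
        db = [entry("a", "clinical", 10.0, 40.0), entry("b", "clinical", 15.0, 35.0),
              entry("p", "pareto", 8.0, 30.0)]
        query = {"bladder": OVHCurve([12.0 - 1e-6, 12.0], [0.0, 1.0])}
        pred = predict_dose_volumes(query, db, [30.0])
        assert pred.doses["bladder"][30.0] == 30.0

    def test_self_membership_bound(self):
        db = [entry("a", "clinical", 10.0, 40.0), entry("b", "clinical", 15.0, 35.0)]
        query = dict(db[1].ovh_curves)
        pred = predict_dose_volumes(query, db)
        for lv in DEFAULT_LEVELS:
            assert pred.doses["bladder"][lv] <= db[1].achieved_doses["bladder"][lv]

    def test_fallback_flagged(self):
        db = [entry("a", "clinical", 10.0, 40.0)]
        query = {"bladder": OVHCurve([5.0 - 1e-6, 5.0], [0.0, 1.0])}
        pred = predict_dose_volumes(query, db, [30.0])
        assert pred.provenance["bladder"][30.0]["fallback"]

    def test_superset_never_increases(self):
        rng = np.random.default_rng(0)
        db = [entry(f"e{i}", "clinical", rng.uniform(5, 25), rng.uniform(20, 60))
              for i in range(10)]
        query = {"bladder": OVHCurve([14.0 - 1e-6, 14.0], [0.0, 1.0])}
        small = predict_dose_volumes(query, db[:5])
        big = predict_dose_volumes(query, db)
        for lv in DEFAULT_LEVELS:
            assert big.doses["bladder"][lv] <= small.doses["bladder"][lv]

    def test_geometry_monotonicity(self):
        rng = np.random.default_rng(1)
        db = [entry(f"e{i}", "clinical", rng.uniform(5, 25), rng.uniform(20, 60))
              for i in range(12)]
        near = predict_dose_volumes({"bladder": OVHCurve([8 - 1e-6, 8], [0, 1])}, db)
        far = predict_dose_volumes({"bladder": OVHCurve([20 - 1e-6, 20], [0, 1])}, db)
        for lv in DEFAULT_LEVELS:
            assert far.doses["bladder"][lv] <= near.doses["bladder"][lv]

    def test_leave_one_out_lower_bound(self):
        rng = np.random.default_rng(2)
        # dose trends up with overlap but with planner-to-planner scatter
        entries = []
        for i in range(15):
            d = rng.uniform(5, 25)
            entries.append(entry(f"e{i}", "clinical", d,
                                 80.0 - 2.0 * d + rng.normal(0, 8)))
        by_id = {e.patient_id: e for e in entries}
        checked = 0
        for i, held in enumerate(entries):
            rest = entries[:i] + entries[i + 1:]
            pred = predict_dose_volumes(dict(held.ovh_curves), rest)
            for lv in DEFAULT_LEVELS:
                prov = pred.provenance["bladder"][lv]
                if prov["fallback"]:
                    continue
                own = held.achieved_doses["bladder"][lv]
                eligible_doses = [by_id[pid].achieved_doses["bladder"][lv]
                                  for pid in prov["matched"]]
                assert pred.doses["bladder"][lv] == pytest.approx(min(eligible_doses))
                if min(eligible_doses) <= own:
                    checked += 1
                    assert pred.doses["bladder"][lv] <= own + 1e-9
        assert checked > 0

    def test_empty_db_raises(self):
        with pytest.raises(ValueError):
            predict_dose_volumes({"bladder": OVHCurve([0, 1], [0, 1])}, [])


class TestDatabase:
    def test_jsonl_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        rows = []
        for i in range(30):
            source = "pareto" if i % 3 == 0 else "clinical"
            d = rng.uniform(5, 25)
            rows.append((f"p{i}", source,
                         {"bladder": OVHCurve([d - 1, d], [0.0, 1.0])},
                         {"bladder": {lv: float(rng.uniform(20, 60))
                                      for lv in DEFAULT_LEVELS}}))
        db = build_database(rows)
        path = tmp_path / "db.jsonl"
        write_database_jsonl(db, path)
        back = read_database_jsonl(path)
        assert len(back) == 30
        assert [e.source for e in back] == [e.source for e in db]
        for a, b in zip(db, back):
            assert a.achieved_doses == b.achieved_doses
            assert np.allclose(a.ovh_curves["bladder"].distances,
                               b.ovh_curves["bladder"].distances)

    def test_incomplete_levels_rejected(self):
        with pytest.raises(ValueError):
            KBPDatabaseEntry("x", "clinical",
                             {"bladder": OVHCurve([0, 1], [0, 1])},
                             {"bladder": {10.0: 40.0}})

    def test_bad_source_rejected(self):
        with pytest.raises(ValueError):
            KBPDatabaseEntry("x", "tps", {}, {})
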