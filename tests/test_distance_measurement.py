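"""Distance maps, point sampling, manual-axial emulation, step-down measurement."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import cdist

from tractgap.distance_measurement import (
    MeasurementRecord,
    TractMasks,
    compute_distance_map,
    distance_at_point,
    manual_axial_distance,
    measure_contact,
    oracle_point_to_mask,
    read_measurements_frame,
    records_to_frame,
    write_measurements_csv,
)
from tractgap.synthetic_data import make_grid
from tractgap.thresholding import BinaryMask
from tractgap.volume_io import ContactRecord, Volume3D, WorldPoint, voxel_to_world


def _mask(shape, true_idx, spacing=(2.0, 2.0, 2.0)):
    grid = make_grid(shape, spacing)
    data = np.zeros(shape, dtype=bool)
    for idx in true_idx:
        data[idx] = True
    return BinaryMask(data=data, affine=grid.affine)


def _center(mask, idx):
    vol = Volume3D(data=mask.data.astype(float), affine=mask.affine)
    return np.array(voxel_to_world(vol, idx))


class TestComputeDistanceMap:
    def test_single_voxel_analytic_neighbors(self):
        mask = _mask((9, 9, 9), [(4, 4, 4)])
        dm = compute_distance_map(mask)
        assert dm.data[4, 4, 4] == 0.0
        assert dm.data[5, 4, 4] == pytest.approx(2.0)
        assert dm.data[5, 5, 4] == pytest.approx(2.828427, abs=1e-6)
        assert dm.data[5, 5, 5] == pytest.approx(3.464102, abs=1e-6)

    def test_full_mask_all_zero(self):
        mask = _mask((4, 4, 4), [idx for idx in np.ndindex(4, 4, 4)])
        dm = compute_distance_map(mask)
        assert np.all(dm.data == 0.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            compute_distance_map(_mask((4, 4, 4), []))

    def test_matches_brute_force_on_anisotropic_grid(self, rng):
        shape, spacing = (15, 15, 15), (1.5, 1.5, 3.0)
        data = rng.random(shape) < 0.02
        data[7, 7, 7] = True  # ensure non-empty
        mask = BinaryMask(data=data, affine=make_grid(shape, spacing).affine)
        dm = compute_distance_map(mask)
        idx = np.indices(shape).reshape(3, -1).T.astype(float)
        centers = idx @ mask.affine[:3, :3].T + mask.affine[:3, 3]
        brute = cdist(centers, mask.voxel_coords_mm()).min(axis=1).reshape(shape)
        assert np.max(np.abs(dm.data - brute)) < 1e-6

    def test_invariant_under_zero_padding(self):
        mask = _mask((9, 9, 9), [(4, 4, 4), (6, 2, 7)])
        dm = compute_distance_map(mask)
        padded_data = np.pad(mask.data, ((0, 4), (0, 0), (0, 0)))
        affine = mask.affine.copy()  # padding slabs appended on the high side only
        padded = BinaryMask(data=padded_data, affine=affine)
        dm_pad = compute_distance_map(padded)
        assert np.allclose(dm_pad.data[:9], dm.data)


class TestDistanceAtPoint:
    def test_zero_at_mask_voxel_center(self):
        mask = _mask((9, 9, 9), [(4, 4, 4)])
        dm = compute_distance_map(mask)
        assert distance_at_point(dm, _center(mask, (4, 4, 4))) == 0.0

    def test_nearest_neighbor_sampling_convention(self):
        # point 3 mm off the mask voxel center on a 2 mm grid reads the
        # neighboring voxel's stored distance (2.0), not the exact 3.0
        mask = _mask((9, 9, 9), [(4, 4, 4)])
        dm = compute_distance_map(mask)
        p = _center(mask, (4, 4, 4)) + np.array([3.0, 0.0, 0.0])
        d = distance_at_point(dm, p)
        assert d == pytest.approx(2.0)
        exact = oracle_point_to_mask(mask, p)
        assert exact == pytest.approx(3.0)
        half_diag = 0.5 * np.linalg.norm(mask.spacing)
        assert abs(d - exact) <= half_diag + 1e-12

    def test_sampling_error_bounded_by_half_voxel_diagonal(self, rng):
        shape, spacing = (12, 12, 12), (2.0, 2.0, 2.0)
        data = rng.random(shape) < 0.05
        data[6, 6, 6] = True
        mask = BinaryMask(data=data, affine=make_grid(shape, spacing).affine)
        dm = compute_distance_map(mask)
        half_diag = 0.5 * np.linalg.norm(mask.spacing)
        lo = mask.affine[:3, 3]
        hi = lo + (np.array(shape) - 1) * np.array(spacing)
        for _ in range(50):
            p = rng.uniform(lo, hi)
            assert abs(distance_at_point(dm, p) - oracle_point_to_mask(mask, p)) <= half_diag + 1e-12

    def test_out_of_bounds_rejected(self):
        dm = compute_distance_map(_mask((9, 9, 9), [(4, 4, 4)]))
        with pytest.raises(ValueError, match="outside"):
            distance_at_point(dm, (1000.0, 0.0, 0.0))

    def test_trilinear_option_interpolates(self):
        mask = _mask((9, 9, 9), [(4, 4, 4)])
        dm = compute_distance_map(mask)
        p = _center(mask, (4, 4, 4)) + np.array([1.0, 0.0, 0.0])  # halfway to neighbor
        assert distance_at_point(dm, p, interpolate=True) == pytest.approx(1.0)


class TestOraclePointToMask:
    def test_minimum_of_candidates(self):
        mask = _mask((9, 9, 9), [(4, 4, 4), (4, 4, 7)])
        p = _center(mask, (4, 4, 4)) + np.array([0.0, 0.0, 4.0])  # 4 mm from first, 2 from second
        assert oracle_point_to_mask(mask, p) == pytest.approx(2.0)

    def test_agrees_with_distance_map_at_every_grid_point(self):
        mask = _mask((10, 10, 10), [(2, 3, 4), (7, 7, 1), (5, 0, 9)])
        dm = compute_distance_map(mask)
        vol = Volume3D(data=mask.data.astype(float), affine=mask.affine)
        for idx in np.ndindex(10, 10, 10):
            p = np.array(voxel_to_world(vol, idx))
            assert dm.data[idx] == pytest.approx(oracle_point_to_mask(mask, p), abs=1e-9)


class TestManualAxialDistance:
    def test_in_slice_distance(self):
        mask = _mask((12, 12, 12), [(5, 8, 6)])
        p = _center(mask, (5, 6, 6))  # same slice k=6, 4 mm along y
        assert manual_axial_distance(mask, p) == pytest.approx(4.0)

    def test_tract_absent_on_slice_not_measurable(self):
        mask = _mask((12, 12, 12), [(5, 5, 3)])
        p = _center(mask, (5, 5, 8))
        assert manual_axial_distance(mask, p) is None

    def test_worked_three_voxel_example(self):
        """Axial restriction error: auto 2.0 mm vs manual 8.0 mm, difference 6.0."""
        mask = _mask((16, 16, 16), [(10, 10, 10), (10, 14, 11)])
        contact = _center(mask, (10, 10, 11))
        dm = compute_distance_map(mask)
        d_auto = distance_at_point(dm, contact)
        d_manual = manual_axial_distance(mask, contact)
        assert d_auto == pytest.approx(2.0)
        assert d_manual == pytest.approx(8.0)
        assert d_manual - d_auto == pytest.approx(6.0)

    def test_jitter_floors_at_zero_and_is_seeded(self):
        mask = _mask((12, 12, 12), [(5, 5, 6)])
        p = _center(mask, (5, 5, 6))  # true distance 0
        d1 = manual_axial_distance(mask, p, jitter_mm=0.5, rng=np.random.default_rng(1))
        d2 = manual_axial_distance(mask, p, jitter_mm=0.5, rng=np.random.default_rng(1))
        assert d1 == d2 and d1 >= 0.0

    def test_dominates_full_3d_oracle(self, rng):
        for _ in range(20):
            data = rng.random((10, 10, 10)) < 0.05
            if not data.any():
                continue
            mask = BinaryMask(data=data, affine=make_grid((10, 10, 10), (2, 2, 2)).affine)
            lo = mask.affine[:3, 3]
            hi = lo + 18.0
            p = rng.uniform(lo, hi)
            d_manual = manual_axial_distance(mask, p)
            if d_manual is not None:
                assert d_manual >= oracle_point_to_mask(mask, p) - 1e-9


def _stepdown_masksets():
    """Crafted volume: robust range (0, 10); tract voxels at 90 and 70 so the
    800% mask holds only the far voxel and the 600% mask adds a near one."""
    shape = (32, 32, 32)
    grid = make_grid(shape, (2.0, 2.0, 2.0))
    data = np.zeros(shape)
    data[0:10, 0:10, 0:10] = 10.0  # ~3% background -> robust range (0, 10)
    data[11, 5, 5] = 90.0  # 12 mm from the contact at voxel (5,5,5)
    data[7, 5, 5] = 70.0  # 4 mm from the contact
    vol = Volume3D(data=data, affine=grid.affine)
    return {"c-DRTT": TractMasks(vol, [400, 600, 800, 1000], source_id="crafted")}, vol


class TestMeasureContact:
    def test_no_step_when_within_cutoff(self):
        tms, vol = _stepdown_masksets()
        contact = ContactRecord(
            "p0", "left", 0, WorldPoint(*voxel_to_world(vol, (7, 5, 5)))
        )
        # at 800% the mask is {(11,5,5)}: distance 8 mm <= 10 -> no step
        rec = measure_contact(tms, contact, 800.0, [400, 600, 800, 1000])[0]
        assert not rec.stepped_down and rec.p_final == 800.0
        assert rec.d_auto == pytest.approx(8.0)

    def test_step_down_once_when_exceeding_cutoff(self):
        tms, vol = _stepdown_masksets()
        contact = ContactRecord(
            "p0", "left", 0, WorldPoint(*voxel_to_world(vol, (5, 5, 5)))
        )
        rec = measure_contact(tms, contact, 800.0, [400, 600, 800, 1000])[0]
        # 12 mm at 800% -> re-measure once at 600%, where (7,5,5) is 4 mm away
        assert rec.stepped_down and rec.p_initial == 800.0 and rec.p_final == 600.0
        assert rec.d_auto == pytest.approx(4.0)

    def test_no_step_available_at_lowest(self):
        tms, vol = _stepdown_masksets()
        contact = ContactRecord(
            "p0", "left", 0, WorldPoint(*voxel_to_world(vol, (25, 25, 25)))
        )
        rec = measure_contact(tms, contact, 400.0, [400, 600, 800, 1000])[0]
        assert not rec.stepped_down and rec.p_final == 400.0
        assert rec.d_auto > 10.0  # recorded as-is, flag visible through the value

    def test_record_invariant_enforced(self):
        with pytest.raises(ValueError, match="p_final"):
            MeasurementRecord(
                patient_id="p0",
                hemisphere="left",
                tract="c-DRTT",
                contact_index=0,
                p_initial=600.0,
                p_final=600.0,
                stepped_down=True,
                d_auto=1.0,
                d_manual=None,
            )


def test_measurements_csv_round_trip(tmp_path):
    recs = [
        MeasurementRecord("p0", "left", "c-DRTT", 0, 800.0, 600.0, True, 4.0, 5.5),
        MeasurementRecord("p0", "left", "nd-DRTT", 0, 800.0, 800.0, False, 2.0, None),
    ]
    path = tmp_path / "m.csv"
    write_measurements_csv(recs, path)
    df = read_measurements_frame(path)
    assert len(df) == 2
    assert df.manual_measurable.tolist() == [True, False]
    assert math.isnan(df.d_manual_mm.iloc[1])
    assert df.d_auto_mm.tolist() == [4.0, 2.0]
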