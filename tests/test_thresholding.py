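"""Robust range, percentage binarization, discrimination selection, step-down."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tractgap.synthetic_data import make_grid
from tractgap.thresholding import (
    RobustRange,
    binarize_thrp,
    dice,
    robust_range,
    select_discrimination_threshold,
    step_down,
    threshold_value,
)
from tractgap.volume_io import Volume3D


def _vol(values, shape=None):
    arr = np.asarray(values, dtype=float)
    if shape is not None:
        arr = arr.reshape(shape)
    if arr.ndim == 1:
        arr = arr.reshape(-1, 1, 1)
    return Volume3D(data=arr, affine=np.eye(4))


class TestRobustRange:
    def test_constant_volume_degenerate(self):
        rr = robust_range(_vol(np.full(64, 5.0)))
        assert (rr.rmin, rr.rmax) == (5.0, 5.0)

    def test_linear_interpolation_rule(self):
        rr = robust_range(_vol(np.arange(100.0)))
        assert rr.rmin == pytest.approx(1.98)
        assert rr.rmax == pytest.approx(97.02)

    def test_extreme_value_ignored(self):
        data = np.zeros(10**6)
        data[0] = 5000.0
        rr = robust_range(_vol(data, shape=(100, 100, 100)))
        assert (rr.rmin, rr.rmax) == (0.0, 0.0)

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError, match="all-NaN"):
            robust_range(_vol(np.full(8, np.nan)))

    def test_nonzero_only_variant(self):
        data = np.concatenate([np.zeros(900), np.full(100, 10.0)])
        vol = _vol(data, shape=(10, 10, 10))
        assert robust_range(vol).rmax == 10.0
        assert robust_range(vol).rmin == 0.0
        rr_nz = robust_range(vol, nonzero_only=True)
        assert (rr_nz.rmin, rr_nz.rmax) == (10.0, 10.0)


@settings(derandomize=True, deadline=None, max_examples=60)
@given(
    st.lists(st.floats(0, 1e4, allow_nan=False), min_size=2, max_size=200),
    st.randoms(use_true_random=False),
)
def test_robust_range_matches_sort_oracle_and_permutation_invariant(values, rnd):
    """Hand-rolled sorted linear-interpolation percentile as the oracle."""

    def oracle(vals, q):
        s = sorted(vals)
        pos = q / 100.0 * (len(s) - 1)
        lo, hi = int(np.floor(pos)), int(np.ceil(pos))
        frac = pos - lo
        return s[lo] * (1 - frac) + s[hi] * frac

    rr = robust_range(_vol(np.array(values)))
    assert rr.rmin == pytest.approx(oracle(values, 2.0), abs=1e-9, rel=1e-9)
    assert rr.rmax == pytest.approx(oracle(values, 98.0), abs=1e-9, rel=1e-9)
    shuffled = list(values)
    rnd.shuffle(shuffled)
    rr2 = robust_range(_vol(np.array(shuffled)))
    assert (rr2.rmin, rr2.rmax) == (rr.rmin, rr.rmax)


class TestBinarize:
    def test_threshold_arithmetic(self):
        rr = RobustRange(0.0, 10.0)
        assert threshold_value(rr, 400.0) == 40.0
        vol = _vol([5.0, 39.0, 40.0, 100.0])
        mask = binarize_thrp(vol, 400.0, rr=rr)
        assert mask.data.ravel().tolist() == [False, False, True, True]
        assert mask.threshold_value == 40.0

    def test_constant_volume_full_mask(self):
        vol = _vol(np.full(27, 7.0), shape=(3, 3, 3))
        mask = binarize_thrp(vol, 1000.0)
        assert mask.threshold_value == 7.0
        assert mask.data.all()  # >= comparison keeps voxels exactly at threshold

    def test_invalid_percent_rejected(self):
        with pytest.raises(ValueError, match="> 0"):
            binarize_thrp(_vol([1.0, 2.0]), 0.0)

    def test_nestedness_on_phantom(self, default_cohort):
        vol = default_cohort.patients[0].volumes[("left", "c-DRTT")]
        rr = robust_range(vol)
        prev = binarize_thrp(vol, 400.0, rr=rr)
        for p in (600.0, 800.0, 1000.0):
            cur = binarize_thrp(vol, p, rr=rr)
            assert not np.any(cur.data & ~prev.data)  # mask(p2) subset of mask(p1)
            prev = cur

    def test_rerun_bit_identical(self, default_cohort):
        vol = default_cohort.patients[0].volumes[("right", "nd-DRTT")]
        m1 = binarize_thrp(vol, 600.0)
        m2 = binarize_thrp(vol, 600.0)
        assert np.array_equal(m1.data, m2.data)


def _block_volume(blocks, shape=(12, 12, 12)):
    """Volume with given {(slice_ijk): value} blocks on a 2 mm grid."""
    grid = make_grid(shape, (2.0, 2.0, 2.0))
    data = np.zeros(shape)
    for sl, v in blocks:
        data[sl] = v
    return Volume3D(data=data, affine=grid.affine)


class TestSelectDiscriminationThreshold:
    def _quads(self, c_val, nd_val, overlap=False):
        """Four volumes whose masks are non-empty only where values exceed thresholds."""
        # robust range is (0, 1) by construction: 3% of voxels at 1.0
        shape = (12, 12, 12)

        def vol(core_val, pos):
            data = np.zeros(shape)
            data.ravel()[:52] = 1.0  # 3% background at 1.0 -> rmax 1.0
            data[pos] = core_val
            return Volume3D(data=data, affine=np.eye(4))

        c = [vol(c_val, (slice(6, 9), slice(6, 9), slice(6, 9))) for _ in range(2)]
        pos_nd = (slice(7, 10), slice(7, 10), slice(7, 10)) if overlap else (
            slice(2, 4),
            slice(2, 4),
            slice(2, 4),
        )
        nd = [vol(nd_val, pos_nd) for _ in range(2)]
        return c[0], c[1], nd[0], nd[1]

    def test_singleton_feasible_set(self):
        # nd cores vanish above 400%: value 5 >= thresholds 4 only
        c_l, c_r, nd_l, nd_r = self._quads(c_val=100.0, nd_val=5.0)
        sel = select_discrimination_threshold(c_l, c_r, nd_l, nd_r, [400, 600, 800, 1000])
        assert sel.percent == 400.0 and sel.feasible
        assert [p for p, ok in sel.nonempty.items() if ok] == [400.0]

    def test_zero_overlap_ties_resolve_to_lowest(self):
        c_l, c_r, nd_l, nd_r = self._quads(c_val=100.0, nd_val=100.0, overlap=False)
        sel = select_discrimination_threshold(c_l, c_r, nd_l, nd_r, [400, 600, 800, 1000])
        assert sel.percent == 400.0 and sel.feasible
        assert all(v == 0.0 for v in sel.mean_dice.values())

    def test_empty_candidates_rejected(self):
        c_l, c_r, nd_l, nd_r = self._quads(100.0, 100.0)
        with pytest.raises(ValueError, match="empty"):
            select_discrimination_threshold(c_l, c_r, nd_l, nd_r, [])

    def test_matches_brute_force_dice_on_phantom(self, default_cohort):
        """Independent voxel-counting Dice per candidate on converging tracts."""
        p = default_cohort.patients[0]
        vols = {
            "c_left": p.volumes[("left", "c-DRTT")],
            "c_right": p.volumes[("right", "c-DRTT")],
            "nd_left": p.volumes[("left", "nd-DRTT")],
            "nd_right": p.volumes[("right", "nd-DRTT")],
        }
        candidates = [400.0, 600.0, 800.0, 1000.0]
        sel = select_discrimination_threshold(
            vols["c_left"], vols["c_right"], vols["nd_left"], vols["nd_right"], candidates
        )
        best_p, best_d = None, np.inf
        for p_ in candidates:
            masks = {k: binarize_thrp(v, p_) for k, v in vols.items()}
            if any(m.is_empty for m in masks.values()):
                continue
            ds = []
            for hemi in ("left", "right"):
                a, b = masks[f"c_{hemi}"].data, masks[f"nd_{hemi}"].data
                ds.append(2 * np.sum(a & b) / (np.sum(a) + np.sum(b)))
            d = float(np.mean(ds))
            if d < best_d:
                best_p, best_d = p_, d
        assert sel.percent == best_p
        assert sel.mean_dice[best_p] == pytest.approx(best_d)


class TestStepDown:
    @pytest.mark.parametrize(
        "p, expected", [(800.0, 600.0), (1000.0, 800.0), (600.0, 400.0), (400.0, None)]
    )
    def test_one_step_lower(self, p, expected):
        assert step_down(p, [400, 600, 800, 1000]) == expected

    def test_unknown_threshold_rejected(self):
        with pytest.raises(ValueError, match="not among"):
            step_down(500.0, [400, 600, 800, 1000])
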