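"""Agreement metrics against closed forms and brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pancparts as pp
from pancparts.exceptions import GridError

from conftest import make_cylinder_x


def _mask(vox, spacing=(1.0, 1.0, 1.0)):
    return pp.BinaryMask3D(np.asarray(vox, dtype=np.uint8), spacing,
                           np.diag(list(spacing) + [1.0]))


def _random_pair(rng, shape=(16, 16, 16), spacing=(1.0, 1.2, 0.8)):
    a = _mask((rng.random(shape) < 0.25).astype(np.uint8), spacing)
    b = _mask((rng.random(shape) < 0.25).astype(np.uint8), spacing)
    return a, b


def brute_force_hd95(a, b):
    """O(n^2) oracle: pooled directed boundary distances, 95th percentile."""
    from scipy.ndimage import binary_erosion, generate_binary_structure

    def boundary(m):
        fg = m.voxels.astype(bool)
        er = binary_erosion(fg, generate_binary_structure(3, 1), border_value=0)
        return m.voxel_to_world(np.argwhere(fg & ~er))

    pa, pb = boundary(a), boundary(b)
    d_ab = [min(np.linalg.norm(p - q) for q in pb) for p in pa]
    d_ba = [min(np.linalg.norm(p - q) for q in pa) for p in pb]
    return float(np.percentile(np.asarray(d_ab + d_ba), 95))


class TestDice:
    def test_identical_masks(self):
        vox = np.zeros((4, 4, 4))
        vox[1:3, 1:3, 1:3] = 1
        assert pp.dice(_mask(vox), _mask(vox)) == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((4, 4, 4)); a[0, 0, 0] = 1
        b = np.zeros((4, 4, 4)); b[3, 3, 3] = 1
        assert pp.dice(_mask(a), _mask(b)) == 0.0

    def test_half_overlap_of_shifted_squares(self):
        # 2x2x1 square vs its 1-voxel shift: |A|=|B|=4, overlap 2 -> 0.5
        a = np.zeros((5, 5, 1)); a[1:3, 1:3, 0] = 1
        b = np.zeros((5, 5, 1)); b[2:4, 1:3, 0] = 1
        assert pp.dice(_mask(a), _mask(b)) == 0.5

    def test_both_empty_is_one_with_warning(self):
        e = _mask(np.zeros((3, 3, 3)))
        with pytest.warns(UserWarning):
            assert pp.dice(e, e.copy()) == 1.0

    def test_symmetry_and_joint_translation_invariance(self):
        rng = np.random.default_rng(6)
        for _ in range(5):
            a, b = _random_pair(rng, shape=(10, 10, 10))
            assert pp.dice(a, b) == pp.dice(b, a)
            ta = _mask(np.roll(a.voxels, 2, axis=1), a.spacing)
            tb = _mask(np.roll(b.voxels, 2, axis=1), b.spacing)
            assert pp.dice(ta, tb) == pytest.approx(pp.dice(a, b), abs=1e-12)

    def test_grid_mismatch_rejected(self):
        with pytest.raises(GridError):
            pp.dice(_mask(np.zeros((3, 3, 3))), _mask(np.zeros((4, 4, 4))))


class TestHD95:
    def test_self_distance_zero(self):
        m = make_cylinder_x(shape=(20, 12, 12), x_range=(2, 18), radius_mm=6)
        assert pp.hd95(m, m) == 0.0

    def test_two_voxels_five_mm_apart(self):
        a = np.zeros((8, 3, 3)); a[1, 1, 1] = 1
        b = np.zeros((8, 3, 3)); b[6, 1, 1] = 1
        assert pp.hd95(_mask(a), _mask(b)) == pytest.approx(5.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(5):
            a, b = _random_pair(rng)
            if a.n_foreground == 0 or b.n_foreground == 0:
                continue
            assert pp.hd95(a, b) == pytest.approx(brute_force_hd95(a, b),
                                                  abs=1e-9)

    def test_symmetric(self):
        rng = np.random.default_rng(8)
        a, b = _random_pair(rng)
        assert abs(pp.hd95(a, b) - pp.hd95(b, a)) < 1e-9

    def test_empty_rejected(self):
        a = np.zeros((3, 3, 3)); a[1, 1, 1] = 1
        with pytest.raises(ValueError):
            pp.hd95(_mask(a), _mask(np.zeros((3, 3, 3))))


class TestVolume:
    def test_empty(self):
        assert pp.volume_ml(_mask(np.zeros((3, 3, 3)))) == 0.0

    def test_iso_2mm(self):
        vox = np.zeros((10, 10, 10)); vox[:10, :10, :10] = 1
        assert pp.volume_ml(_mask(vox, (2, 2, 2))) == pytest.approx(8.0)

    def test_anisotropic_dixon_voxels(self):
        vox = np.zeros((5, 5, 5)); vox.ravel()[:125] = 1
        got = pp.volume_ml(_mask(vox, (2.23, 2.23, 4.5)))
        assert got == pytest.approx(2.7973, abs=1e-3)


class TestBlandAltman:
    def test_zero_differences(self):
        ba = pp.bland_altman([(1, 1), (2, 2), (3, 3)])
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_plus_minus_one(self):
        # differences {+1, -1}: SD = sqrt(2), LoA = +/- 1.96 sqrt(2)
        ba = pp.bland_altman([(1, 0), (0, 1)])
        assert ba.bias == pytest.approx(0.0)
        assert ba.loa_high == pytest.approx(1.96 * np.sqrt(2), abs=1e-9)
        assert ba.loa_low == pytest.approx(-1.96 * np.sqrt(2), abs=1e-9)

    def test_single_pair_rejected(self):
        with pytest.raises(ValueError):
            pp.bland_altman([(1, 2)])

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)),
                    min_size=2, max_size=40),
           st.floats(-100, 100))
    def test_shift_of_both_series_leaves_everything_unchanged(self, pairs, c):
        # adding a constant to both series leaves bias and LoA unchanged
        base = pp.bland_altman(pairs)
        shifted = pp.bland_altman([(a + c, b + c) for a, b in pairs])
        assert shifted.bias == pytest.approx(base.bias, abs=1e-6)
        assert shifted.loa_low == pytest.approx(base.loa_low, abs=1e-6)
        assert shifted.loa_high == pytest.approx(base.loa_high, abs=1e-6)
        assert base.loa_low <= base.bias <= base.loa_high

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.floats(-1e3, 1e3), st.floats(-1e3, 1e3)),
                    min_size=2, max_size=40))
    def test_swapping_series_negates_bias(self, pairs):
        fwd = pp.bland_altman(pairs)
        rev = pp.bland_altman([(b, a) for a, b in pairs])
        assert rev.bias == pytest.approx(-fwd.bias, abs=1e-9)
        assert rev.loa_low == pytest.approx(-fwd.loa_high, abs=1e-9)

    def test_matches_direct_formula(self):
        rng = np.random.default_rng(9)
        pairs = rng.normal(size=(30, 2))
        ba = pp.bland_altman(pairs)
        d = pairs[:, 0] - pairs[:, 1]
        assert ba.bias == pytest.approx(d.mean())
        assert ba.loa_high - ba.bias == pytest.approx(1.96 * d.std(ddof=1))


class TestCompareParts:
    def test_self_comparison(self, cohort10):
        labels = cohort10[0][1]
        agreement = pp.compare_parts(labels, labels.copy())
        assert all(v == 1.0 for v in agreement.dsc.values())
        assert all(v == 0.0 for v in agreement.hd95_mm.values())
        assert all(v == 0.0 for v in agreement.volume_delta_ml.values())

    def test_missing_part_flagged_absent(self, cohort10):
        labels = cohort10[0][1]
        no_tail = labels.labels.copy()
        no_tail[no_tail == 3] = 2
        other = pp.PartsLabelMap(no_tail, labels.spacing.copy(),
                                 labels.affine.copy())
        agreement = pp.compare_parts(labels, other)
        assert agreement.absent == ["tail"]
        assert "tail" not in agreement.dsc

    def test_matches_per_part_single_computations(self):
        # rater-style perturbation: planes shifted 4 mm
        cyl = make_cylinder_x()
        pt_a = pp.annotate_parts(cyl, pp.Plane3D((30, 0, 0), (1, 0, 0)),
                                 pp.Plane3D((70, 0, 0), (1, 0, 0)))
        pt_b = pp.annotate_parts(cyl, pp.Plane3D((34, 0, 0), (1, 0, 0)),
                                 pp.Plane3D((66, 0, 0), (1, 0, 0)))
        agreement = pp.compare_parts(pt_a.parts, pt_b.parts)
        for lab, name in ((1, "head"), (2, "body"), (3, "tail")):
            ma, mb = pt_a.parts.part_mask(lab), pt_b.parts.part_mask(lab)
            assert agreement.dsc[name] == pp.dice(ma, mb)
            assert agreement.hd95_mm[name] == pp.hd95(ma, mb)
            assert agreement.volume_delta_ml[name] == pytest.approx(
                pp.volume_ml(ma) - pp.volume_ml(mb))
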