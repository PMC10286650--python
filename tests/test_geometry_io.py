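"""Container invariants, world geometry and NIfTI/DICOM round trips."""

import nibabel as nib
import numpy as np
import pytest

import pancparts as pp
from pancparts.exceptions import DimensionalityError, GeometryError
from pancparts.geometry import write_pdff_slice


def _random_mask(rng, shape=(12, 10, 9)):
    return (rng.random(shape) < 0.3).astype(np.uint8)


class TestMaskIO:
    def test_roundtrip_identity(self, tmp_path):
        rng = np.random.default_rng(0)
        mask = pp.BinaryMask3D(_random_mask(rng), (2.0, 2.0, 2.0),
                               np.diag([2.0, 2.0, 2.0, 1.0]))
        path = tmp_path / "m.nii.gz"
        pp.write_mask(mask, path)
        back = pp.read_mask(path)
        assert np.array_equal(back.voxels, mask.voxels)
        assert np.allclose(back.spacing, mask.spacing, atol=1e-6)
        assert np.allclose(back.affine, mask.affine, atol=1e-6)

    def test_all_zero_volume_reads_empty(self, tmp_path):
        path = tmp_path / "z.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros((8, 8, 8), dtype=np.uint8), np.eye(4)),
                 path)
        assert pp.read_mask(path).n_foreground == 0

    def test_0_255_encoding_thresholds_at_half(self, tmp_path):
        rng = np.random.default_rng(1)
        raw = np.where(rng.random((10, 10, 10)) < 0.4, 255, 0).astype(np.uint8)
        path = tmp_path / "m255.nii.gz"
        nib.save(nib.Nifti1Image(raw, np.eye(4)), path)
        mask = pp.read_mask(path)
        assert np.array_equal(mask.voxels, (raw.astype(float) > 0.5).astype(np.uint8))

    @pytest.mark.parametrize("shape", [(8, 8), (8, 8, 8, 2)])
    def test_wrong_dimensionality_rejected(self, tmp_path, shape):
        path = tmp_path / "bad.nii.gz"
        nib.save(nib.Nifti1Image(np.zeros(shape, dtype=np.uint8), np.eye(4)), path)
        with pytest.raises(DimensionalityError):
            pp.read_mask(path)

    def test_unreadable_file_raises_oserror(self, tmp_path):
        path = tmp_path / "junk.nii"
        path.write_bytes(b"this is not a nifti")
        with pytest.raises(OSError):
            pp.read_mask(path)


class TestLabelsIO:
    def test_roundtrip_preserves_values_and_oblique_affine(self, tmp_path):
        rng = np.random.default_rng(2)
        labels = rng.integers(0, 4, size=(11, 9, 8)).astype(np.uint8)
        theta = 0.3
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0],
                        [0, 0, 1.0]])
        affine = np.eye(4)
        affine[:3, :3] = rot * 2.0
        affine[:3, 3] = (5.0, -7.0, 3.0)
        lm = pp.PartsLabelMap(labels, (2.0, 2.0, 2.0), affine)
        path = tmp_path / "lab.nii.gz"
        pp.write_labels(lm, path)
        back = pp.read_labels(path)
        assert np.array_equal(back.labels, labels)
        assert set(np.unique(back.labels)) == set(np.unique(labels))
        assert np.allclose(back.affine, affine, atol=1e-6)

    def test_label_values_restricted(self):
        with pytest.raises(ValueError):
            pp.PartsLabelMap(np.full((4, 4, 4), 5, dtype=np.uint8),
                             (1, 1, 1), np.eye(4))


class TestWorldGeometry:
    def test_affine_corners_match_hand_computation(self):
        affine = np.array([[0.0, -2.0, 0.0, 10.0],
                           [1.5, 0.0, 0.0, -4.0],
                           [0.0, 0.0, 3.0, 2.5],
                           [0.0, 0.0, 0.0, 1.0]])
        mask = pp.BinaryMask3D(np.ones((4, 5, 6), dtype=np.uint8),
                               (1.5, 2.0, 3.0), affine)
        for ijk in [(0, 0, 0), (3, 0, 5), (3, 4, 5)]:
            i, j, k = ijk
            by_hand = np.array([
                affine[0, 0] * i + affine[0, 1] * j + affine[0, 2] * k + affine[0, 3],
                affine[1, 0] * i + affine[1, 1] * j + affine[1, 2] * k + affine[1, 3],
                affine[2, 0] * i + affine[2, 1] * j + affine[2, 2] * k + affine[2, 3],
            ])
            assert np.allclose(mask.voxel_to_world([ijk])[0], by_hand, atol=1e-6)

    def test_world_to_voxel_inverts(self):
        rng = np.random.default_rng(3)
        affine = np.eye(4)
        affine[:3, :3] = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        affine[:3, 3] = rng.normal(size=3)
        mask = pp.BinaryMask3D(np.ones((3, 3, 3), dtype=np.uint8), (1, 1, 1), affine)
        ijk = rng.random((10, 3)) * 2
        assert np.allclose(mask.world_to_voxel(mask.voxel_to_world(ijk)), ijk,
                           atol=1e-9)

    def test_degenerate_affine_rejected(self):
        bad = np.zeros((4, 4))
        with pytest.raises(GeometryError):
            pp.BinaryMask3D(np.zeros((3, 3, 3), dtype=np.uint8), (1, 1, 1), bad)

    def test_nonpositive_spacing_rejected(self):
        with pytest.raises(GeometryError):
            pp.BinaryMask3D(np.zeros((3, 3, 3), dtype=np.uint8), (1, 0, 1), np.eye(4))


class TestPlane:
    def test_normal_is_normalized(self):
        plane = pp.Plane3D((0, 0, 0), (0, 3, 4))
        assert abs(np.linalg.norm(plane.normal) - 1.0) < 1e-9

    def test_signed_distance_sides(self):
        plane = pp.Plane3D((10, 0, 0), (1, 0, 0))
        d = plane.signed_distance([(12, 5, 5), (7, -1, 0)])
        assert d[0] == pytest.approx(2.0) and d[1] == pytest.approx(-3.0)

    def test_zero_normal_rejected(self):
        with pytest.raises(GeometryError):
            pp.Plane3D((0, 0, 0), (0, 0, 0))


class TestPDFFIO:
    def test_nifti_roundtrip_single_slice(self, tmp_path):
        rng = np.random.default_rng(4)
        vals = rng.random((16, 14)) * 40
        pdff = pp.PDFFSlice(vals, (2.5, 2.5, 6.0), np.diag([2.5, 2.5, 6.0, 1.0]))
        path = tmp_path / "pdff.nii.gz"
        write_pdff_slice(pdff, path)
        back = pp.read_pdff_slice(path)
        assert back.values.shape == vals.shape
        assert np.allclose(back.values, vals, atol=1e-5)

    def test_implausible_values_rejected(self):
        with pytest.raises(ValueError):
            pp.PDFFSlice(np.full((4, 4), 500.0), (1, 1, 1), np.eye(4))

    def test_dicom_geometry_and_rescale(self, tmp_path):
        import pydicom
        from pydicom.dataset import FileDataset, FileMetaDataset
        from pydicom.uid import ExplicitVRLittleEndian

        meta = FileMetaDataset()
        meta.MediaStorageSOPClassUID = pydicom.uid.MRImageStorage
        meta.MediaStorageSOPInstanceUID = pydicom.uid.generate_uid()
        meta.TransferSyntaxUID = ExplicitVRLittleEndian
        ds = FileDataset(str(tmp_path / "s.dcm"), {}, file_meta=meta,
                         preamble=b"\0" * 128)
        rng = np.random.default_rng(5)
        raw = rng.integers(0, 1000, size=(8, 6)).astype(np.uint16)
        ds.Rows, ds.Columns = raw.shape
        ds.BitsAllocated, ds.BitsStored, ds.HighBit = 16, 16, 15
        ds.PixelRepresentation = 0
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.PixelData = raw.tobytes()
        ds.RescaleSlope, ds.RescaleIntercept = 0.1, -5.0
        ds.ImagePositionPatient = [100.0, -50.0, 20.0]
        ds.ImageOrientationPatient = [0.0, 1.0, 0.0, 0.0, 0.0, -1.0]
        ds.PixelSpacing = [2.5, 3.0]
        ds.SliceThickness = 6.0
        ds.save_as(str(tmp_path / "s.dcm"), enforce_file_format=True)

        pdff = pp.read_pdff_dicom(tmp_path / "s.dcm")
        assert np.allclose(pdff.values, raw * 0.1 - 5.0)
        # pixel (i=row, j=col) -> IPP + i*rowspacing*coldir + j*colspacing*rowdir
        i, j = 3, 4
        expect = (np.array([100.0, -50.0, 20.0])
                  + i * 2.5 * np.array([0.0, 0.0, -1.0])
                  + j * 3.0 * np.array([0.0, 1.0, 0.0]))
        assert np.allclose(pdff.pixel_to_world([(i, j)])[0], expect, atol=1e-9)


class TestPartition:
    def test_partition_checks_grid_and_support(self, cohort10):
        mask, labels = cohort10[0]
        assert pp.check_partition(mask, labels)
        broken = labels.labels.copy()
        fg = np.argwhere(broken > 0)
        broken[tuple(fg[0])] = 0
        assert not pp.check_partition(
            mask, pp.PartsLabelMap(broken, labels.spacing, labels.affine))
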