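"""Reference selection, alignment QC, max fusion and canonical reconstruction."""

import numpy as np
import pytest

from vetbrain.errors import VetbrainError
from vetbrain.geometry import ImageVolume
from vetbrain.phantom import ellipsoid_mask_on_grid, sample_plane, truth_mask_on_grid
from vetbrain.reconstruction import (
    alignment_report,
    fuse_max,
    reconstruct,
    select_reference,
)
from vetbrain.evaluation import score
from vetbrain.geometry import BrainMask

from conftest import small_spec


def qc_volume(shape=(40, 40, 40), box=(slice(10, 20), slice(10, 20), slice(10, 20)), spacing=1.0):
    """Two-level volume whose QC foreground (>60th pct of nonzero) is exactly `box`."""
    data = np.full(shape, 1.0)
    data[box] = 2.0
    aff = np.diag([spacing, spacing, spacing, 1.0])
    return ImageVolume(data, aff)


class TestSelectReference:
    def test_tra_preferred(self):
        assert select_reference(["SAG", "TRA", "DOR"]) == "TRA"

    def test_fallback_priority(self):
        assert select_reference(["SAG", "DOR"]) == "DOR"
        assert select_reference(["SAG"]) == "SAG"

    def test_empty_rejected(self):
        with pytest.raises(VetbrainError):
            select_reference([])


class TestAlignmentReport:
    def test_identity(self):
        v = qc_volume()
        rep = alignment_report(v, v)
        assert rep.center_offset_mm == pytest.approx(0.0)
        assert rep.overlap_fraction == pytest.approx(1.0)
        assert not rep.flagged

    def test_known_translation_recovered(self):
        ref = qc_volume(spacing=1.0)
        cand = qc_volume(spacing=1.0)
        cand.voxels[:] = np.roll(ref.voxels, 15, axis=0)  # 15 mm shift
        rep = alignment_report(cand, ref)
        assert rep.center_offset_mm == pytest.approx(15.0, abs=1e-9)
        assert rep.flagged

    def test_exactly_10mm_not_flagged(self):
        # 5-voxel shift at 2 mm spacing: offset exactly 10 mm, overlap 0.5
        ref = qc_volume(spacing=2.0)
        cand = qc_volume(spacing=2.0)
        cand.voxels[:] = np.roll(ref.voxels, 5, axis=0)
        rep = alignment_report(cand, ref)
        assert rep.center_offset_mm == pytest.approx(10.0, abs=1e-9)
        assert rep.overlap_fraction == pytest.approx(0.5)
        assert not rep.flagged  # "greater than 10 mm" is strict

    def test_exactly_30pct_overlap_not_flagged(self):
        # 7-voxel shift at 0.5 mm: offset 3.5 mm, overlap exactly 0.30
        ref = qc_volume(spacing=0.5)
        cand = qc_volume(spacing=0.5)
        cand.voxels[:] = np.roll(ref.voxels, 7, axis=0)
        rep = alignment_report(cand, ref)
        assert rep.overlap_fraction == pytest.approx(0.30)
        assert not rep.flagged

    def test_low_overlap_flagged(self):
        ref = qc_volume(spacing=0.5)
        cand = qc_volume(spacing=0.5)
        cand.voxels[:] = np.roll(ref.voxels, 8, axis=0)  # overlap 0.2
        rep = alignment_report(cand, ref)
        assert rep.overlap_fraction == pytest.approx(0.20)
        assert rep.flagged


class TestFuseMax:
    def test_single_input_identity(self, rng):
        from conftest import random_volume

        v = random_volume(rng)
        out = fuse_max([v])
        assert np.array_equal(out.voxels, v.voxels)

    def test_max_with_zero_is_identity(self, rng):
        from conftest import random_volume

        v = random_volume(rng)
        zero = ImageVolume(np.zeros(v.shape), v.affine)
        assert np.array_equal(fuse_max([v, zero]).voxels, v.voxels)

    def test_matches_per_voxel_loop(self, rng):
        vols = [ImageVolume(rng.random((6, 6, 6)), np.eye(4)) for _ in range(3)]
        fused = fuse_max(vols)
        for i in range(6):
            for j in range(6):
                for k in range(6):
                    assert fused.voxels[i, j, k] == max(v.voxels[i, j, k] for v in vols)
        for v in vols:
            assert np.all(fused.voxels >= v.voxels)

    def test_commutative_and_idempotent(self, rng):
        from conftest import random_volume

        a, b = random_volume(rng), random_volume(rng)
        assert np.array_equal(fuse_max([a, b]).voxels, fuse_max([b, a]).voxels)
        assert np.array_equal(fuse_max([a, a]).voxels, a.voxels)

    def test_mismatched_grids_rejected(self, rng):
        a = ImageVolume(rng.random((6, 6, 6)), np.eye(4))
        b = ImageVolume(rng.random((6, 6, 7)), np.eye(4))
        with pytest.raises(VetbrainError):
            fuse_max([a, b])


class TestReconstruct:
    def test_single_plane_study(self, clean_study):
        spec, stacks, truth, meta = clean_study
        tra = [s for s in stacks if s.plane == "TRA"]
        study = reconstruct(tra, side=64)
        assert study.fused.shape == (64, 64, 64)
        assert study.reference_plane == "TRA"
        assert study.reports == []

    def test_canonical_cube_las_isotropic(self, clean_study):
        spec, stacks, truth, meta = clean_study
        study = reconstruct(stacks)
        assert study.fused.shape == (128, 128, 128)
        assert study.fused.axcodes == ("L", "A", "S")
        sp = study.fused.spacing
        assert np.all(np.abs(sp - sp[0]) < 1e-6)
        assert set(study.per_plane_originals) == {"TRA", "DOR", "SAG"}

    def test_aligned_planes_not_flagged(self, clean_study):
        spec, stacks, truth, meta = clean_study
        study = reconstruct(stacks)
        assert [r.flagged for r in study.reports] == [False, False]

    def test_fused_foreground_matches_truth_head(self, clean_study):
        # noise-free aligned phantom: fused supra-threshold foreground vs
        # analytic head ellipsoid, resampling loss only.  The threshold sits
        # at half the dominant (subcutaneous) tissue intensity — the midpoint
        # of the tissue-to-air interpolation ramp, where the resampled surface
        # crosses the true one — and the head foreground is the filled
        # supra-threshold support (a head region includes its darker skull
        # interior).
        from scipy import ndimage

        spec, stacks, truth, meta = clean_study
        study = reconstruct(stacks)
        head = ellipsoid_mask_on_grid(spec.head_axes_mm, study.fused.affine, study.fused.shape)
        thr = spec.head_intensity[0] / 2
        filled = ndimage.binary_fill_holes(study.fused.voxels > thr)
        fg = BrainMask(filled.astype(np.uint8), study.fused.affine)
        assert score(fg, head).dice >= 0.98

    def test_fused_bounding_box_matches_phantom_truth(self, clean_study):
        spec, stacks, truth, meta = clean_study
        study = reconstruct(stacks)
        head = ellipsoid_mask_on_grid(spec.head_axes_mm, study.fused.affine, study.fused.shape)
        thr = spec.head_intensity[0] / 2
        got = np.argwhere(study.fused.voxels > thr)
        want = np.argwhere(head.voxels > 0)
        assert np.all(np.abs(got.min(axis=0) - want.min(axis=0)) <= 1)
        assert np.all(np.abs(got.max(axis=0) - want.max(axis=0)) <= 1)

    def test_offset_plane_flagged_and_excluded(self, clean_phantom):
        spec, ref, truth = clean_phantom
        tra = sample_plane(ref, "TRA", 3.0, 0.6)
        dor = sample_plane(ref, "DOR", 4.0, 0.6, offset_mm=(15.0, 0.0, 0.0))
        study = reconstruct([tra, dor])
        (rep,) = study.reports
        assert rep.plane == "DOR"
        assert rep.flagged
        # canonical-FOV clipping can only shrink the measured offset, never
        # inflate it: the estimate lies between the QC threshold and the truth
        assert 10.0 < rep.center_offset_mm <= 15.5
        assert rep.note == "reprocess separately"
        assert "DOR" in study.flagged_planes
        # fused is the reference-only reconstruction: brain dice vs truth high
        tra_only = reconstruct([tra])
        assert np.allclose(study.fused.voxels, tra_only.fused.voxels, atol=1e-6)

    def test_too_many_planes_rejected(self, clean_study):
        spec, stacks, truth, meta = clean_study
        with pytest.raises(VetbrainError):
            reconstruct(stacks + stacks)
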