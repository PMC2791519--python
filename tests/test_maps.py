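"""Tests for voxel-wise map construction, smoothing, thresholding and I/O."""

import nibabel as nib
import numpy as np
import pytest

from bmsmaps import (
    Cuboid,
    EvidenceVolumeSet,
    LogEvidenceMatrix,
    ffx_posterior,
    read_evidence_volumes,
    rfx_fit,
    simulate_evidence_volumes,
    smooth_volumes,
    threshold_map,
    to_log_odds,
    voxelwise_ffx,
    voxelwise_rfx,
    write_maps,
)


def _write_nii(path, data, affine=None):
    if affine is None:
        affine = np.diag([3.0, 3.0, 3.0, 1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), path)
    return str(path)


@pytest.fixture
def volume_files(tmp_path, rng):
    paths = []
    for i in range(2):
        row = []
        for j in range(2):
            row.append(
                _write_nii(tmp_path / f"s{i}m{j}.nii", rng.normal(size=(4, 4, 4)))
            )
        paths.append(row)
    return paths


class TestReadEvidenceVolumes:
    def test_derived_mask_excludes_nonfinite(self, tmp_path, volume_files, rng):
        data = rng.normal(size=(4, 4, 4))
        data[1, 2, 3] = np.nan
        volume_files[1][0] = _write_nii(tmp_path / "bad.nii", data)
        evset = read_evidence_volumes(volume_files)
        assert not evset.mask[1, 2, 3]
        assert evset.mask.sum() == 63

    def test_explicit_mask_restricts_analysis(self, tmp_path, volume_files):
        mask = np.zeros((4, 4, 4))
        mask.ravel()[:10] = 1
        mask_path = _write_nii(tmp_path / "mask.nii", mask)
        evset = read_evidence_volumes(volume_files, mask_path=mask_path)
        assert evset.mask.sum() == 10
        maps = voxelwise_rfx(evset)
        assert maps.metadata["n_analysed"] == 10
        assert np.sum(np.isfinite(maps.ppm[0])) == 10

    def test_grid_mismatch_names_file(self, tmp_path, volume_files, rng):
        bad = _write_nii(tmp_path / "wrong_grid.nii", rng.normal(size=(5, 4, 4)))
        volume_files[0][1] = bad
        with pytest.raises(ValueError, match="wrong_grid"):
            read_evidence_volumes(volume_files)

    def test_affine_mismatch_names_file(self, tmp_path, volume_files, rng):
        bad = _write_nii(
            tmp_path / "wrong_affine.nii",
            rng.normal(size=(4, 4, 4)),
            affine=np.diag([2.0, 3.0, 3.0, 1.0]),
        )
        volume_files[1][1] = bad
        with pytest.raises(ValueError, match="wrong_affine"):
            read_evidence_volumes(volume_files)


class TestSmoothVolumes:
    def test_zero_fwhm_is_identity(self, small_volume_set):
        evset, _ = small_volume_set
        out = smooth_volumes(evset, [0.0, 0.0, 0.0])
        assert out.data is evset.data

    def test_constant_volume_unchanged(self):
        data = np.full((1, 2, 8, 8, 8), 3.7)
        evset = EvidenceVolumeSet(
            data=data,
            affine=np.diag([3.0, 3.0, 3.0, 1.0]),
            mask=np.ones((8, 8, 8), bool),
            subject_ids=("s1",),
            model_names=("m1", "m2"),
        )
        out = smooth_volumes(evset, 8.0)
        assert np.allclose(out.data, 3.7, atol=1e-10)

    def test_impulse_mass_conserved(self):
        data = np.zeros((1, 2, 21, 21, 21))
        data[:, :, 10, 10, 10] = 5.0
        evset = EvidenceVolumeSet(
            data=data,
            affine=np.diag([2.0, 2.0, 2.0, 1.0]),
            mask=np.ones((21, 21, 21), bool),
            subject_ids=("s1",),
            model_names=("m1", "m2"),
        )
        out = smooth_volumes(evset, 4.0)  # FWHM = 2 voxels
        assert out.data[0, 0].sum() == pytest.approx(5.0, abs=1e-6)
        assert out.data[0, 0, 10, 10, 10] < 5.0

    def test_mask_renormalisation_no_dilution(self):
        # half the grid masked out at a different value must not leak in
        data = np.zeros((1, 2, 10, 10, 10))
        data[:, :, :5] = 2.0
        data[:, :, 5:] = -100.0
        mask = np.zeros((10, 10, 10), bool)
        mask[:5] = True
        evset = EvidenceVolumeSet(
            data=data,
            affine=np.eye(4),
            mask=mask,
            subject_ids=("s1",),
            model_names=("m1", "m2"),
        )
        out = smooth_volumes(evset, 2.0)
        assert np.allclose(out.data[0, 0][mask], 2.0, atol=1e-8)

    def test_negative_fwhm_rejected(self, small_volume_set):
        evset, _ = small_volume_set
        with pytest.raises(ValueError, match="non-negative"):
            smooth_volumes(evset, [-1.0, 0.0, 0.0])


class TestVoxelwiseEngines:
    def test_indifferent_data_uniform_everywhere(self):
        data = np.zeros((3, 2, 3, 3, 3))
        evset = EvidenceVolumeSet(
            data=data,
            affine=np.eye(4),
            mask=np.ones((3, 3, 3), bool),
            subject_ids=("a", "b", "c"),
            model_names=("m1", "m2"),
        )
        rfx = voxelwise_rfx(evset)
        ffx = voxelwise_ffx(evset)
        assert np.allclose(rfx.ppm, 0.5, atol=1e-8)
        assert np.allclose(ffx.ppm, 0.5, atol=1e-12)

    def test_active_cuboid_detected(self):
        evset, truth = simulate_evidence_volumes(
            (5, 5, 5), 3.0, Cuboid((1, 1, 1), (4, 4, 4)),
            [1.0, 0.0], [0.5, 0.5], 12,
            effect_mean=3.0, effect_sd=0.0, noise_sd=0.0, seed=3,
        )
        maps = voxelwise_rfx(evset)
        inside = truth["region"]
        assert np.all(maps.ppm[0][inside] > 0.5)

    def test_single_voxel_matches_direct_core_call(self, small_volume_set):
        """Map orchestration at a one-voxel mask equals a direct core fit."""
        evset, _ = small_volume_set
        mask = np.zeros(evset.grid_shape, bool)
        mask[2, 3, 4] = True
        sub = EvidenceVolumeSet(
            data=evset.data,
            affine=evset.affine,
            mask=mask,
            subject_ids=evset.subject_ids,
            model_names=evset.model_names,
        )
        maps = voxelwise_rfx(sub, seed=0)
        direct = rfx_fit(LogEvidenceMatrix(evset.data[:, :, 2, 3, 4]))
        assert maps.ppm[:, 2, 3, 4] == pytest.approx(direct.expected_r, abs=1e-12)
        assert maps.epm[:, 2, 3, 4] == pytest.approx(direct.exceedance, abs=1e-12)

        fmaps = voxelwise_ffx(sub)
        fdirect = ffx_posterior(LogEvidenceMatrix(evset.data[:, :, 2, 3, 4]))
        assert fmaps.ppm[:, 2, 3, 4] == pytest.approx(fdirect.posterior, abs=1e-12)

    def test_mask_monotonicity(self, small_volume_set):
        """Shrinking the mask never changes values at shared voxels."""
        evset, _ = small_volume_set
        full = voxelwise_rfx(evset, seed=1)
        mask = evset.mask.copy()
        mask[3:] = False
        sub = EvidenceVolumeSet(
            data=evset.data,
            affine=evset.affine,
            mask=mask,
            subject_ids=evset.subject_ids,
            model_names=evset.model_names,
        )
        part = voxelwise_rfx(sub, seed=1)
        assert np.array_equal(part.ppm[:, mask], full.ppm[:, mask])
        assert np.array_equal(part.epm[:, mask], full.epm[:, mask])

    def test_ppm_normalised_and_nan_outside(self, small_volume_set):
        evset, _ = small_volume_set
        mask = evset.mask.copy()
        mask[0] = False
        sub = EvidenceVolumeSet(
            data=evset.data, affine=evset.affine, mask=mask,
            subject_ids=evset.subject_ids, model_names=evset.model_names,
        )
        maps = voxelwise_rfx(sub)
        assert np.allclose(maps.ppm.sum(axis=0)[mask], 1.0, atol=1e-8)
        assert np.allclose(maps.epm.sum(axis=0)[mask], 1.0, atol=1e-12)
        assert np.isnan(maps.ppm[:, ~mask]).all()

    def test_nonfinite_voxel_skipped_not_fatal(self, small_volume_set):
        evset, _ = small_volume_set
        data = evset.data.copy()
        data[0, 0, 1, 1, 1] = np.nan
        sub = EvidenceVolumeSet(
            data=data, affine=evset.affine, mask=evset.mask,
            subject_ids=evset.subject_ids, model_names=evset.model_names,
        )
        maps = voxelwise_rfx(sub)
        assert maps.metadata["n_failed"] == 1
        assert np.isnan(maps.ppm[:, 1, 1, 1]).all()

    def test_ffx_at_least_rfx_when_unanimous(self):
        """FFX saturates where all subjects favour the same model."""
        data = np.zeros((8, 2, 2, 2, 2))
        data[:, 0] = 2.0  # everyone favours model 1 by 2 nats
        evset = EvidenceVolumeSet(
            data=data, affine=np.eye(4), mask=np.ones((2, 2, 2), bool),
            subject_ids=tuple(f"s{i}" for i in range(8)),
            model_names=("m1", "m2"),
        )
        ffx = voxelwise_ffx(evset)
        rfx = voxelwise_rfx(evset)
        assert np.all(ffx.ppm[0][evset.mask] >= rfx.ppm[0][evset.mask])


class TestThresholdAndLogOdds:
    def test_threshold_strictly_greater(self):
        vol = np.array([[[0.6, 0.8, np.nan]]])
        out = threshold_map(vol, 0.75)
        assert np.isnan(out[0, 0, 0])
        assert out[0, 0, 1] == 0.8
        assert np.isnan(out[0, 0, 2])

    def test_threshold_edges(self):
        vol = np.array([[[0.2, 0.9]]])
        assert np.isfinite(threshold_map(vol, 0.0)).all()
        assert np.isnan(threshold_map(vol, 1.0)).all()
        with pytest.raises(ValueError):
            threshold_map(vol, 1.2)
        with pytest.raises(ValueError):
            threshold_map(vol, -0.1)

    def test_log_odds_values(self):
        vol = np.array([[[0.5, 0.95, 0.0, 1.0]]])
        out = to_log_odds(vol)
        assert out[0, 0, 0] == pytest.approx(0.0, abs=1e-12)
        assert out[0, 0, 1] == pytest.approx(np.log(19), rel=1e-12)
        assert out[0, 0, 2] == -np.inf
        assert out[0, 0, 3] == np.inf

    def test_log_odds_monotone(self, rng):
        p = np.sort(rng.uniform(0.01, 0.99, size=50))
        lo = to_log_odds(p)
        assert np.all(np.diff(lo) > 0)


class TestWriteMaps:
    def test_manifest_and_roundtrip(self, tmp_path, small_volume_set):
        evset, _ = small_volume_set
        maps = voxelwise_rfx(evset, gamma=0.75)
        manifest = write_maps(maps, tmp_path / "out")
        assert len(manifest["ppm"]) == 2
        assert len(manifest["epm"]) == 2
        assert len(manifest["alpha"]) == 2
        assert (tmp_path / "out" / "bms_run.json").exists()

        img = nib.load(manifest["ppm"][0])
        back = np.asarray(img.get_fdata())
        finite = np.isfinite(maps.ppm[0])
        assert np.allclose(back[finite], maps.ppm[0][finite], atol=1e-6)
        assert np.allclose(img.affine, evset.affine)

    def test_ffx_writes_no_epm(self, tmp_path, small_volume_set):
        evset, _ = small_volume_set
        manifest = write_maps(voxelwise_ffx(evset), tmp_path / "ffx")
        assert manifest["epm"] == []
        assert manifest["alpha"] == []
        assert len(manifest["ppm"]) == 2
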