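"""Voxel-wise group BMS over co-registered log-evidence volumes.

Reads one 3-D NIfTI log-evidence image per subject per model (all on a
shared grid and affine — inputs must be pre-registered, e.g. spatially
normalised), optionally smooths them, runs the FFX or RFX engine at every
in-mask voxel, and writes posterior probability maps (PPMs, per-model
``<r_k>``), exceedance probability maps (EPMs, ``phi_k``) and Dirichlet
count maps as NIfTI volumes. Voxels outside the analysis mask, or whose
data fail validation, carry NaN so "not analysed" is distinguishable from
"probability ~ 0".
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

from .core import (
    LogEvidenceMatrix,
    ffx_posterior,
    rfx_fit,
)

__all__ = [
    "EvidenceVolumeSet",
    "BmsMaps",
    "read_evidence_volumes",
    "smooth_volumes",
    "voxelwise_rfx",
    "voxelwise_ffx",
    "threshold_map",
    "to_log_odds",
    "write_maps",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
AFFINE_ATOL = 1e-4


@dataclass(frozen=True)
class EvidenceVolumeSet:
    """Co-registered log-evidence volumes for N subjects and K models.

    ``data`` has shape (N, K, X, Y, Z); ``mask`` is a boolean (X, Y, Z)
    volume restricting the analysis; ``affine`` maps voxel indices to world
    (mm) coordinates and is shared by all volumes.
    """

    data: np.ndarray
    affine: np.ndarray
    mask: np.ndarray
    subject_ids: tuple[str, ...]
    model_names: tuple[str, ...]

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=float)
        if data.ndim != 5:
            raise ValueError("data must have shape (subjects, models, X, Y, Z)")
        mask = np.asarray(self.mask, dtype=bool)
        if mask.shape != data.shape[2:]:
            raise ValueError(
                f"mask shape {mask.shape} does not match grid {data.shape[2:]}"
            )
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "affine", affine)
        object.__setattr__(self, "subject_ids", tuple(self.subject_ids))
        object.__setattr__(self, "model_names", tuple(self.model_names))

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_models(self) -> int:
        return self.data.shape[1]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return self.data.shape[2:]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel size derived from the affine column norms."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))


@dataclass(frozen=True)
class BmsMaps:
    """Per-model probability volumes produced by a group BMS run.

    ``ppm[k]`` holds ``<r_k>`` (RFX) or the FFX posterior probability,
    ``epm[k]`` the exceedance probability ``phi_k`` (RFX only) and
    ``alpha_maps[k]`` the fitted Dirichlet counts. Un-analysed voxels are
    NaN. ``metadata`` records the run parameters (gamma, smoothing FWHM,
    seed, iteration statistics).
    """

    ppm: np.ndarray
    epm: np.ndarray | None
    alpha_maps: np.ndarray | None
    method: str
    gamma: float
    affine: np.ndarray
    model_names: tuple[str, ...]
    metadata: dict = field(default_factory=dict)


def _load_volume(path: str | os.PathLike) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return data, np.asarray(img.affine, dtype=float)


def read_evidence_volumes(
    paths: Sequence[Sequence[str | os.PathLike]],
    mask_path: str | os.PathLike | None = None,
    subject_ids: Sequence[str] | None = None,
    model_names: Sequence[str] | None = None,
) -> EvidenceVolumeSet:
    """Load an N x K table of log-evidence volume files into a validated set.

    ``paths[n][k]`` is the file for subject n, model k. All volumes must
    share grid shape and affine (affines compared elementwise to 1e-4).
    Without an explicit mask the analysis mask is the set of voxels finite
    in every volume; with a mask file, voxels where it is non-zero.
    """
    n = len(paths)
    if n < 1:
        raise ValueError("at least one subject row of paths is required")
    k = len(paths[0])
    if k < 2:
        raise ValueError("model selection requires at least 2 models")
    if any(len(row) != k for row in paths):
        raise ValueError("every subject must have the same number of model volumes")

    ref_path = paths[0][0]
    ref_data, ref_affine = _load_volume(ref_path)
    grid = ref_data.shape
    data = np.empty((n, k) + grid, dtype=float)
    for i, row in enumerate(paths):
        for j, p in enumerate(row):
            vol, aff = _load_volume(p)
            if vol.shape != grid:
                raise ValueError(
                    f"{p}: grid shape {vol.shape} does not match {ref_path} {grid}"
                )
            if not np.allclose(aff, ref_affine, atol=AFFINE_ATOL):
                raise ValueError(f"{p}: affine does not match {ref_path}")
            data[i, j] = vol

    if mask_path is not None:
        mask_vol, mask_aff = _load_volume(mask_path)
        if mask_vol.shape != grid:
            raise ValueError(
                f"{mask_path}: mask grid {mask_vol.shape} does not match {grid}"
            )
        if not np.allclose(mask_aff, ref_affine, atol=AFFINE_ATOL):
            raise ValueError(f"{mask_path}: mask affine does not match {ref_path}")
        mask = mask_vol != 0
    else:
        mask = np.isfinite(data).all(axis=(0, 1))
    if not mask.any():
        raise ValueError("analysis mask is empty (no finite in-mask voxels)")

    if subject_ids is None:
        subject_ids = [f"sub{i + 1}" for i in range(n)]
    if model_names is None:
        model_names = [f"model{j + 1}" for j in range(k)]
    return EvidenceVolumeSet(
        data=data,
        affine=ref_affine,
        mask=mask,
        subject_ids=tuple(subject_ids),
        model_names=tuple(model_names),
    )


def smooth_volumes(
    evset: EvidenceVolumeSet, fwhm_mm: Sequence[float] | float
) -> EvidenceVolumeSet:
    """Gaussian-smooth every log-evidence volume, mask-renormalised.

    ``sigma_axis = FWHM_axis / (2 sqrt(2 ln 2))`` in mm, converted to voxels
    through the affine. Smoothing convolves masked data and the mask
    separately and divides, so voxels outside the mask do not dilute in-mask
    values near the mask boundary. ``fwhm = 0`` on every axis returns the
    input unchanged.
    """
    fwhm = np.broadcast_to(np.asarray(fwhm_mm, dtype=float), (3,)).copy()
    if np.any(fwhm < 0):
        raise ValueError("FWHM must be non-negative on every axis")
    if np.all(fwhm == 0):
        return evset
    sigma_vox = fwhm * FWHM_TO_SIGMA / evset.voxel_size_mm
    mask_f = evset.mask.astype(float)
    sm_mask = gaussian_filter(mask_f, sigma=sigma_vox, mode="constant", cval=0.0)
    out = np.full_like(evset.data, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(evset.n_subjects):
            for j in range(evset.n_models):
                vol = np.where(evset.mask, evset.data[i, j], 0.0)
                sm = gaussian_filter(vol, sigma=sigma_vox, mode="constant", cval=0.0)
                out[i, j] = np.where(evset.mask, sm / sm_mask, np.nan)
    return EvidenceVolumeSet(
        data=out,
        affine=evset.affine,
        mask=evset.mask,
        subject_ids=evset.subject_ids,
        model_names=evset.model_names,
    )


def _voxel_seed(seed: int, flat_index: int) -> int:
    """Deterministic per-voxel seed, independent of traversal order."""
    ss = np.random.SeedSequence(entropy=seed, spawn_key=(flat_index,))
    return int(ss.generate_state(1)[0] % (2**31))


def voxelwise_rfx(
    evset: EvidenceVolumeSet,
    alpha0: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 64,
    ep_samples: int = 1_000_000,
    seed: int = 0,
    gamma: float = 0.0,
) -> BmsMaps:
    """Run the RFX engine at every in-mask voxel.

    Every voxel is fit independently from ``alpha0``; the Monte-Carlo seed
    for K > 2 exceedance probabilities is derived deterministically from
    ``(seed, flat voxel index)`` so results do not depend on traversal
    order. Voxels whose N x K matrix fails validation (e.g. non-finite
    entries inside an explicit mask) are left NaN and counted in the
    metadata rather than aborting the run.
    """
    k = evset.n_models
    grid = evset.grid_shape
    ppm = np.full((k,) + grid, np.nan)
    epm = np.full((k,) + grid, np.nan)
    alpha_maps = np.full((k,) + grid, np.nan)
    n_failed = 0
    n_analysed = 0
    n_not_converged = 0
    iteration_counts = []
    voxels = np.argwhere(evset.mask)
    for idx in voxels:
        x, y, z = idx
        flat = int(np.ravel_multi_index((x, y, z), grid))
        matrix = evset.data[:, :, x, y, z]
        try:
            logev = LogEvidenceMatrix(
                matrix, subject_ids=evset.subject_ids, model_names=evset.model_names
            )
        except ValueError:
            n_failed += 1
            continue
        res = rfx_fit(
            logev,
            alpha0=alpha0,
            tol=tol,
            max_iter=max_iter,
            ep_samples=ep_samples,
            seed=_voxel_seed(seed, flat),
        )
        ppm[:, x, y, z] = res.expected_r
        epm[:, x, y, z] = res.exceedance
        alpha_maps[:, x, y, z] = res.posterior.alpha
        iteration_counts.append(res.iterations)
        n_not_converged += 0 if res.converged else 1
        n_analysed += 1
    metadata = {
        "alpha0": list(np.ones(k) if alpha0 is None else np.asarray(alpha0, float)),
        "tol": tol,
        "max_iter": max_iter,
        "ep_samples": ep_samples,
        "seed": seed,
        "n_analysed": n_analysed,
        "n_failed": n_failed,
        "n_not_converged": n_not_converged,
        "mean_iterations": float(np.mean(iteration_counts)) if iteration_counts else None,
        "max_iterations": int(np.max(iteration_counts)) if iteration_counts else None,
    }
    return BmsMaps(
        ppm=ppm,
        epm=epm,
        alpha_maps=alpha_maps,
        method="rfx",
        gamma=gamma,
        affine=evset.affine,
        model_names=evset.model_names,
        metadata=metadata,
    )


def voxelwise_ffx(evset: EvidenceVolumeSet, gamma: float = 0.0) -> BmsMaps:
    """Run the FFX engine at every in-mask voxel.

    Log-evidence images are summed over subjects per model; posterior model
    probabilities follow by exponentiating the sums and normalising to
    unity. FFX defines no exceedance probability, so ``epm`` is None.
    """
    k = evset.n_models
    grid = evset.grid_shape
    ppm = np.full((k,) + grid, np.nan)
    n_failed = 0
    n_analysed = 0
    for x, y, z in np.argwhere(evset.mask):
        matrix = evset.data[:, :, x, y, z]
        try:
            logev = LogEvidenceMatrix(
                matrix, subject_ids=evset.subject_ids, model_names=evset.model_names
            )
        except ValueError:
            n_failed += 1
            continue
        ppm[:, x, y, z] = ffx_posterior(logev).posterior
        n_analysed += 1
    metadata = {"n_analysed": n_analysed, "n_failed": n_failed}
    return BmsMaps(
        ppm=ppm,
        epm=None,
        alpha_maps=None,
        method="ffx",
        gamma=0.0,
        affine=evset.affine,
        model_names=evset.model_names,
        metadata=metadata,
    )


def threshold_map(volume: np.ndarray, gamma: float) -> np.ndarray:
    """Retain voxels with value strictly greater than gamma; others NaN.

    NaN (not zero) marks sub-threshold and un-analysed voxels so that a
    thresholded map never conflates "below gamma" with "probability 0".
    """
    if not 0.0 <= gamma <= 1.0:
        raise ValueError("gamma must lie in [0, 1]")
    volume = np.asarray(volume, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(volume > gamma, volume, np.nan)


def to_log_odds(volume: np.ndarray) -> np.ndarray:
    """Natural-log odds ``ln(p / (1 - p))`` per voxel.

    Values of exactly 0 or 1 map to -inf / +inf; NaN propagates.
    """
    volume = np.asarray(volume, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.log(volume) - np.log1p(-volume)


def write_maps(maps: BmsMaps, out_dir: str | os.PathLike) -> dict[str, list[str]]:
    """Write per-model map volumes and a JSON run sidecar to ``out_dir``.

    One NIfTI file per model per available map type (``ppm_<model>.nii``,
    ``epm_<model>.nii``, ``alpha_<model>.nii``), all carrying the input
    affine, plus ``bms_run.json`` with method, gamma and run metadata.
    Returns a manifest of written paths keyed by map type.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, list[str]] = {"ppm": [], "epm": [], "alpha": []}
    stacks = {"ppm": maps.ppm, "epm": maps.epm, "alpha": maps.alpha_maps}
    for kind, stack in stacks.items():
        if stack is None:
            continue
        for j, name in enumerate(maps.model_names):
            path = out_dir / f"{kind}_{name}.nii"
            nib.save(nib.Nifti1Image(stack[j].astype(np.float64), maps.affine), path)
            manifest[kind].append(str(path))
    sidecar = {
        "method": maps.method,
        "gamma": maps.gamma,
        "model_names": list(maps.model_names),
        "metadata": maps.metadata,
        "files": manifest,
    }
    sidecar_path = out_dir / "bms_run.json"
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    manifest["sidecar"] = [str(sidecar_path)]
    return manifest
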