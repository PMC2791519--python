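"""Synthetic log-evidence data under the RFX generative model.

Emulates the hierarchical generative process behind random-effects group
BMS: population model frequencies ``r`` on the simplex, a per-subject model
assignment ``m_n ~ Multinomial(1, r)``, and per-subject log evidences in
which the generating model receives a Normal(effect_mean, effect_sd)
advantage (nats) over the others, which receive Normal(0, noise_sd).
Everything is reproducible from an explicit seed.

Defaults (effect_mean=3 nats, effect_sd=1, noise_sd=1) emulate moderate
single-subject evidence with between-subject variability of the same order
— the regime hierarchical RFX inference is designed for. Real log-evidence
images additionally carry spatial correlation and model-specific evidence
scales that this generator does not emulate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .core import LogEvidenceMatrix
from .maps import EvidenceVolumeSet

__all__ = [
    "GroupSimTruth",
    "Cuboid",
    "Sphere",
    "simulate_group_logev",
    "make_outlier_scenario",
    "simulate_evidence_volumes",
]


@dataclass(frozen=True)
class GroupSimTruth:
    """Ground truth of a simulated group.

    ``assignments[n]`` is the 0-based index of the model that generated
    subject n's data; ``effect_nats[n]`` the realised log-evidence advantage
    of that model for subject n.
    """

    r_true: np.ndarray
    assignments: np.ndarray
    effect_nats: np.ndarray
    seed: int


@dataclass(frozen=True)
class Cuboid:
    """Axis-aligned voxel-index cuboid, inclusive lower / exclusive upper."""

    lo: tuple[int, int, int]
    hi: tuple[int, int, int]

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        lo, hi = np.asarray(self.lo), np.asarray(self.hi)
        if np.any(lo < 0) or np.any(hi > grid_shape) or np.any(lo >= hi):
            raise ValueError(f"cuboid {self.lo}..{self.hi} not inside grid {grid_shape}")
        m = np.zeros(grid_shape, dtype=bool)
        m[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] = True
        return m


@dataclass(frozen=True)
class Sphere:
    """Voxel-index sphere: centre (x, y, z) and radius, in voxels."""

    center: tuple[float, float, float]
    radius: float

    def mask(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        c = np.asarray(self.center, dtype=float)
        if np.any(c < 0) or np.any(c >= grid_shape) or self.radius <= 0:
            raise ValueError(f"sphere {self} not inside grid {grid_shape}")
        coords = np.indices(grid_shape, dtype=float)
        d2 = sum((coords[i] - c[i]) ** 2 for i in range(3))
        return d2 <= self.radius**2


def _check_simplex(r: Sequence[float], k_models: int | None = None) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or r.shape[0] < 2:
        raise ValueError("model frequencies must be a vector of length >= 2")
    if k_models is not None and r.shape[0] != k_models:
        raise ValueError(f"expected {k_models} model frequencies, got {r.shape[0]}")
    if np.any(r < 0) or not np.isclose(r.sum(), 1.0, atol=1e-8):
        raise ValueError("model frequencies must be non-negative and sum to 1")
    return r / r.sum()


def _fill_rows(
    rng: np.random.Generator,
    assignments: np.ndarray,
    k: int,
    effect_mean: float,
    effect_sd: float,
    noise_sd: float,
) -> tuple[np.ndarray, np.ndarray]:
    n = assignments.shape[0]
    values = rng.normal(0.0, noise_sd, size=(n, k)) if noise_sd > 0 else np.zeros((n, k))
    effects = (
        rng.normal(effect_mean, effect_sd, size=n)
        if effect_sd > 0
        else np.full(n, float(effect_mean))
    )
    values[np.arange(n), assignments] = effects
    return values, effects


def simulate_group_logev(
    r_true: Sequence[float],
    n_subjects: int,
    k_models: int | None = None,
    effect_mean: float = 3.0,
    effect_sd: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
) -> tuple[LogEvidenceMatrix, GroupSimTruth]:
    """Draw one group's N x K log-evidence matrix plus its ground truth.

    Per subject: ``m_n ~ Multinomial(1, r_true)``; the generating model's
    log evidence is drawn from Normal(effect_mean, effect_sd) and every
    other model's from Normal(0, noise_sd). Only within-subject differences
    matter downstream, so the non-generating baseline at 0 is a convention,
    not a constraint.
    """
    r = _check_simplex(r_true, k_models)
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if effect_sd < 0 or noise_sd < 0:
        raise ValueError("effect_sd and noise_sd must be >= 0")
    k = r.shape[0]
    rng = np.random.default_rng(seed)
    assignments = rng.choice(k, size=n_subjects, p=r)
    values, effects = _fill_rows(rng, assignments, k, effect_mean, effect_sd, noise_sd)
    logev = LogEvidenceMatrix(values)
    truth = GroupSimTruth(
        r_true=r, assignments=assignments, effect_nats=effects, seed=seed
    )
    return logev, truth


def make_outlier_scenario(
    n_subjects: int = 12,
    majority_logbf: float = -1.0,
    outlier_logbf: float = 30.0,
) -> LogEvidenceMatrix:
    """Two-model group with one outlying subject (the last row).

    ``n_subjects - 1`` subjects carry a log Bayes factor of
    ``majority_logbf`` for model 1 over model 2 (negative values favour
    model 2); the final subject carries ``outlier_logbf``. The canonical
    case — eleven subjects at -1 and one at +30 — makes FFX select model 1
    on the strength of the single outlier while RFX still favours model 2.
    """
    if n_subjects < 2:
        raise ValueError("n_subjects must be >= 2")
    values = np.zeros((n_subjects, 2))
    values[:-1, 0] = majority_logbf
    values[-1, 0] = outlier_logbf
    return LogEvidenceMatrix(values)


def simulate_evidence_volumes(
    grid_shape: tuple[int, int, int],
    voxel_size_mm: float | Sequence[float],
    active_region: Cuboid | Sphere,
    r_true_inside: Sequence[float],
    r_true_outside: Sequence[float],
    n_subjects: int,
    effect_mean: float = 3.0,
    effect_sd: float = 1.0,
    noise_sd: float = 1.0,
    seed: int = 0,
    per_voxel_assignments: bool = False,
) -> tuple[EvidenceVolumeSet, dict]:
    """Simulate a volume set with an active region of shifted model frequencies.

    Inside ``active_region`` per-voxel log-evidence rows are generated under
    ``r_true_inside``; elsewhere under ``r_true_outside``. By default each
    subject draws ONE model assignment per region — the model a subject uses
    is a subject-level property — with independent per-voxel evidence noise.
    ``per_voxel_assignments=True`` instead redraws assignments independently
    at every voxel; this breaks the subject-level coupling and is offered
    only as a stress test.

    Returns the volume set and a truth dict with the region mask volume,
    the frequencies, and the drawn assignments.
    """
    r_in = _check_simplex(r_true_inside)
    r_out = _check_simplex(r_true_outside, r_in.shape[0])
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    k = r_in.shape[0]
    region = active_region.mask(tuple(grid_shape))  # validates bounds
    rng = np.random.default_rng(seed)

    vox = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    affine = np.diag(list(vox) + [1.0])
    data = np.empty((n_subjects, k) + tuple(grid_shape), dtype=float)

    flat_region = region.ravel()
    n_vox = flat_region.shape[0]
    truth_assignments: dict[str, np.ndarray] = {}
    if per_voxel_assignments:
        assign = np.empty((n_subjects, n_vox), dtype=int)
        for where, r in (("inside", r_in), ("outside", r_out)):
            sel = flat_region if where == "inside" else ~flat_region
            assign[:, sel] = rng.choice(
                k, size=(n_subjects, int(sel.sum())), p=r
            )
        truth_assignments["per_voxel"] = assign.reshape((n_subjects,) + tuple(grid_shape))
    else:
        a_in = rng.choice(k, size=n_subjects, p=r_in)
        a_out = rng.choice(k, size=n_subjects, p=r_out)
        assign = np.where(flat_region[None, :], a_in[:, None], a_out[:, None])
        truth_assignments["inside"] = a_in
        truth_assignments["outside"] = a_out

    # independent per-voxel evidence draws given the assignments
    noise = (
        rng.normal(0.0, noise_sd, size=(n_subjects, k, n_vox))
        if noise_sd > 0
        else np.zeros((n_subjects, k, n_vox))
    )
    effects = (
        rng.normal(effect_mean, effect_sd, size=(n_subjects, n_vox))
        if effect_sd > 0
        else np.full((n_subjects, n_vox), float(effect_mean))
    )
    sub_idx = np.arange(n_subjects)[:, None]
    vox_idx = np.arange(n_vox)[None, :]
    noise[sub_idx, assign, vox_idx] = effects
    data[:] = noise.reshape((n_subjects, k) + tuple(grid_shape))

    evset = EvidenceVolumeSet(
        data=data,
        affine=affine,
        mask=np.ones(tuple(grid_shape), dtype=bool),
        subject_ids=tuple(f"sub{i + 1}" for i in range(n_subjects)),
        model_names=tuple(f"model{j + 1}" for j in range(k)),
    )
    truth = {
        "region": region,
        "r_true_inside": r_in,
        "r_true_outside": r_out,
        "assignments": truth_assignments,
        "seed": seed,
    }
    return evset, truth
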