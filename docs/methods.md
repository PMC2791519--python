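# Methods

## Inference model

The package performs group-level Bayesian model selection from per-subject
log model evidences `log p(y_n | m_nk)` (natural logarithm; in practice a
variational free-energy approximation estimated upstream). Two engines are
provided.

**Fixed effects.** One model is assumed to generate all subjects' data.
Per-model log evidences are summed over subjects; the pairwise log group
Bayes factor is the difference of sums, and posterior model probabilities
are the softmax of the sums (uniform priors). The softmax subtracts the
per-vector maximum before exponentiation, so arbitrarily large log-evidence
differences (hundreds of nats are common in imaging data) cannot overflow.

**Random effects.** Each subject's generating model is a latent multinomial
draw from population frequencies `r` with conjugate prior `Dir(r; α₀)`.
The posterior `p(r|Y) = Dir(r; α)` is obtained by a variational fixed-point
scheme alternating assignment responsibilities

    g_nk ∝ exp( log p(y_n|m_nk) + Ψ(α_k) − Ψ(α_S) ),   α_S = Σ_k α_k,

expected counts `β_k = Σ_n g_nk`, and the count update `α = α₀ + β`. Inside
the responsibility exponent the per-subject maximum is subtracted before
exponentiation — a mathematical no-op on `g` that prevents overflow. Every
completed fit satisfies `Σ_k β_k = N` and `Σ_k α_k = Σ_k α₀_k + N`; the
test suite asserts these identities, together with label-permutation
equivariance and invariance to per-subject constant offsets (only
within-subject evidence differences are informative).

Summary quantities: expected model frequencies `⟨r_k⟩ = α_k/α_S`
(posterior probability that model k is used by a randomly chosen subject)
and exceedance probabilities `φ_k = p(r_k > r_j ∀ j≠k | Y)` (belief that
model k is the most frequent).

## Parameters and defaults

| parameter | default | meaning |
|---|---|---|
| `alpha0` | `[1, …, 1]` | prior Dirichlet counts: each model observed once; configurable for sensitivity analyses |
| `tol` | `1e-4` | convergence threshold on `max_k |Δα_k|` between sweeps; α entries are bounded by N, so this is effectively a relative criterion |
| `max_iter` | `64` | iteration cap; non-convergence sets a flag on the result rather than raising |
| `ep_samples` | `1e6` | Dirichlet Monte-Carlo draws for φ when K > 2 (closed form used for K = 2); below 10⁴ a warning is logged |
| `gamma` | — | display threshold on PPM/EPM values, strictly greater-than (`value > γ` survives, so γ-equal edge cases are well defined) |
| `fwhm_mm` | `0` | per-axis Gaussian smoothing FWHM in mm; `σ = FWHM/(2√(2 ln 2))`, converted to voxels through the affine |

The convergence tolerance, iteration cap and Monte-Carlo sample count are
this package's choices; nothing in the underlying theory fixes them. With
`tol = 1e-4` typical fits converge in 5–20 sweeps.

For K = 2, `φ₁ = p(r₁ > 0.5)` is the upper tail of the Beta(α₁, α₂)
marginal via the regularised incomplete beta function, so `φ₁ + φ₂ = 1`
exactly and the RFX engine is fully deterministic. For K > 2 the
Monte-Carlo argmax discards exactly-tied draws (a measure-zero event under
the continuous density). Exceedance maps can be re-expressed on a
natural-log-odds scale via `to_log_odds` (base e is this package's
convention).

## Voxel-wise maps

`voxelwise_rfx`/`voxelwise_ffx` assemble the N×K matrix at every voxel of
the analysis mask and run the corresponding engine independently — no
information is shared between voxels, and each voxel restarts from α₀.
Per-voxel Monte-Carlo seeds are derived deterministically from the run seed
and the flat voxel index (`numpy SeedSequence` spawning), so outputs are
independent of traversal order and reproducible; shrinking the mask never
changes values at voxels common to both analyses. Voxels whose matrix fails
validation (e.g. non-finite values inside an explicit mask) are recorded as
un-analysed and carry NaN — distinct from a genuinely small probability —
rather than aborting the run.

Inputs must already be on a common grid and affine (pre-registered /
spatially normalised data); no resampling is performed, and affines are
compared elementwise to 1e-4. Without an explicit mask, the mask is the set
of voxels finite in every volume.

**Smoothing** is applied to the log-evidence volumes *before* the group
analysis, as is standard for evidence maps. The kernel is axis-separable
Gaussian with zero-padded boundaries, and the result is mask-renormalised:
the masked data and the mask are convolved separately and divided, so
out-of-mask (zero-filled) voxels do not dilute in-mask values near the mask
edge. Plain zero-padding would bias boundary voxels toward indifference;
renormalisation keeps constant volumes exactly constant. A FWHM of 0
returns the input unchanged.

## Synthetic data generator

`simulate_group_logev` draws each subject's generating model
`m_n ~ Multinomial(1, r_true)`, gives that model a log-evidence advantage
drawn from `Normal(effect_mean, effect_sd)` nats and every other model
`Normal(0, noise_sd)`. This is the minimal parameterisation in which
evidence strength (`effect_mean`), between-subject heterogeneity
(`effect_sd`) and nuisance variability (`noise_sd`) can be controlled
independently. Defaults — `effect_mean = 3`, `effect_sd = 1`,
`noise_sd = 1` — emulate moderate single-subject evidence (posterior
~0.95 for the generating model at 3 nats) with heterogeneity of the same
order, the regime hierarchical RFX inference is designed for.

`simulate_evidence_volumes` wraps this in a 3-D scenario with an active
region (cuboid or sphere) whose frequencies differ from the background. By
default a subject's model assignment is drawn **once per region** — the
model a subject uses is a subject-level property, not a voxel-level one —
with independent per-voxel evidence noise; `per_voxel_assignments=True`
redraws assignments at every voxel and is labelled a stress test. A
consequence of the subject-level coupling is that detection statistics are
spatially correlated: in a given realisation the whole background shares
one assignment draw, so pooled false-positive rates across seeds are more
variable than voxel-count intuition suggests.

What the generator does **not** emulate: spatial autocorrelation of the
evidence noise, model-specific evidence scales and offsets, registration
error, and the heavy-tailed evidence distributions real first-level fits
can produce. Passing tests therefore demonstrate correctness of the
inference machinery under the stated generative model, not performance on
real imaging data.

## Simulation-study sizes

The packaged studies use desk-scale problems: the parameter-recovery study
runs 100 replicates of N = 200 subjects with decisive 5-nat evidence; the
map-level study runs 20 realisations of an 8×8×8 grid (512 voxels, 12
subjects, 3×3×3 active cuboid with r = [0.9, 0.1] against a [0.5, 0.5]
background, γ = 0.75). Both complete in seconds.

A note on recovery accuracy: with N = 200 the posterior mean ⟨r₁⟩ tracks
the *realised* assignment frequencies almost exactly (decisive evidence
makes `g` one-hot), so its deviation from the population value 0.7 is
dominated by multinomial sampling noise, `SD ≈ √(0.7·0.3/200) ≈ 0.032`.
The probability that a single replicate lands within ±0.05 of 0.7 is
therefore capped at `P(130 ≤ X ≤ 150) ≈ 0.895` for `X ~ Bin(200, 0.7)`,
for any inference procedure; observed success rates near 90% are the
sampling ceiling, not an inference deficiency.

## Known limitations

- No spatial model: voxels are fit independently; no spatial priors on
  `r`, cluster-level inference or multiple-comparison control.
- The RFX fixed point is a variational approximation; α is a point
  estimate of the Dirichlet parameters, not a full hyper-posterior.
- Volumes are read whole into memory; grids beyond ~10⁶ voxels with many
  subjects/models may need chunking.
- K = 1 inputs are rejected: model selection needs at least two models.
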