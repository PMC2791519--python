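"""Statistical engine for group-level Bayesian model selection (BMS).

Given an N-subjects x K-models matrix of log model evidences
``log p(y_n | m_nk)`` (natural-log units, nats), two group inferences are
available:

* **Fixed effects (FFX)** — assumes one model generated every subject's
  data. Log evidences are summed over subjects; the group Bayes factor
  between models i and j is ``exp(sum_i - sum_j)``, and posterior model
  probabilities follow by exponentiating and normalising the sums
  (uniform model priors).

* **Random effects (RFX)** — treats the model used by each subject as a
  draw from unknown population frequencies ``r`` with a conjugate
  Dirichlet prior ``Dir(r; alpha0)``. A variational fixed-point scheme
  alternates between the posterior assignment beliefs ``g_nk``
  (multinomial responsibilities, which involve digamma functions of the
  current Dirichlet counts) and the Dirichlet update
  ``alpha = alpha0 + beta`` with ``beta_k = sum_n g_nk``. The fitted
  Dirichlet yields expected model frequencies ``<r_k> = alpha_k / sum(alpha)``
  and exceedance probabilities ``phi_k = p(r_k > r_j for all j != k)``.

The RFX scheme accommodates between-subject heterogeneity and is robust to
outlying subjects, whereas FFX posteriors saturate and can be driven by a
single extreme subject.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import betainc, digamma

__all__ = [
    "LogEvidenceMatrix",
    "DirichletPosterior",
    "AssignmentPosterior",
    "RfxResult",
    "FfxResult",
    "ffx_posterior",
    "rfx_update_assignments",
    "rfx_fit",
    "expected_model_probs",
    "exceedance_probs",
    "posterior_from_bayes_factor",
    "evidence_strength",
]

logger = logging.getLogger(__name__)

# Monte-Carlo sample counts below this emit a warning (estimates get noisy).
EP_SAMPLE_FLOOR = 10_000


def _as_labels(labels: Sequence[str] | None, n: int, prefix: str) -> tuple[str, ...]:
    if labels is None:
        return tuple(f"{prefix}{i + 1}" for i in range(n))
    labels = tuple(str(x) for x in labels)
    if len(labels) != n:
        raise ValueError(f"expected {n} {prefix} labels, got {len(labels)}")
    return labels


@dataclass(frozen=True)
class LogEvidenceMatrix:
    """N x K matrix of log model evidences (nats), one row per subject.

    Entries must be finite; only within-subject differences carry
    information, so any per-subject constant offset is irrelevant.
    """

    values: np.ndarray
    subject_ids: tuple[str, ...] = field(default=None)  # type: ignore[assignment]
    model_names: tuple[str, ...] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            raise ValueError("log-evidence values must be a 2-D (subjects x models) array")
        n, k = values.shape
        if n < 1:
            raise ValueError("at least one subject is required")
        if k < 2:
            raise ValueError("model selection requires at least 2 models")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "subject_ids", _as_labels(self.subject_ids, n, "sub"))
        object.__setattr__(self, "model_names", _as_labels(self.model_names, k, "model"))
        bad = ~np.isfinite(values)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"non-finite log evidence for subject {self.subject_ids[i]!r}, "
                f"model {self.model_names[j]!r}"
            )

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_models(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class DirichletPosterior:
    """Dirichlet posterior ``p(r | Y) = Dir(r; alpha)`` over model frequencies.

    ``alpha0`` holds the prior counts (default: each model 'observed' once)
    and ``n_subjects`` the number of subjects the posterior absorbed, so a
    completed fit satisfies ``sum(alpha) == sum(alpha0) + n_subjects``.
    """

    alpha: np.ndarray
    alpha0: np.ndarray
    n_subjects: int

    def __post_init__(self) -> None:
        alpha = np.asarray(self.alpha, dtype=float)
        alpha0 = np.asarray(self.alpha0, dtype=float)
        if alpha.ndim != 1 or alpha0.shape != alpha.shape:
            raise ValueError("alpha and alpha0 must be 1-D vectors of equal length")
        if not np.all(alpha > 0) or not np.all(alpha0 > 0):
            raise ValueError("Dirichlet parameters must be strictly positive")
        object.__setattr__(self, "alpha", alpha)
        object.__setattr__(self, "alpha0", alpha0)

    @property
    def n_models(self) -> int:
        return self.alpha.shape[0]


@dataclass(frozen=True)
class AssignmentPosterior:
    """Per-subject model-assignment beliefs.

    ``g[n, k]`` is the normalised posterior belief that model k generated
    subject n's data (rows sum to 1); ``u`` holds the unnormalised beliefs
    after the per-row max-shift applied for numerical stability (the shift
    cancels in ``g``).
    """

    g: np.ndarray
    u: np.ndarray


@dataclass(frozen=True)
class FfxResult:
    """Fixed-effects group inference.

    ``log_group_evidence[k]`` is the log evidence summed over subjects,
    ``posterior`` the normalised posterior model probabilities (uniform
    priors), and ``log_gbf[i, j]`` the log group Bayes factor of model i
    over model j (antisymmetric, zero diagonal).
    """

    log_group_evidence: np.ndarray
    posterior: np.ndarray
    log_gbf: np.ndarray
    model_names: tuple[str, ...]


@dataclass(frozen=True)
class RfxResult:
    """Random-effects group inference.

    ``expected_r`` is the posterior mean model frequency ``<r_k>``,
    ``exceedance`` the exceedance probability ``phi_k``, ``beta`` the
    expected model counts, and ``assignment`` the final per-subject beliefs.
    """

    posterior: DirichletPosterior
    expected_r: np.ndarray
    exceedance: np.ndarray
    assignment: AssignmentPosterior
    beta: np.ndarray
    iterations: int
    converged: bool
    model_names: tuple[str, ...]


def ffx_posterior(logev: LogEvidenceMatrix) -> FfxResult:
    """Fixed-effects posterior from summed log evidences.

    Sums each model's log evidence over subjects, exponentiates with a
    max-shift for stability and normalises to unit sum. Equivalent to
    multiplying per-subject Bayes factors into a group Bayes factor.
    """
    total = logev.values.sum(axis=0)
    shifted = total - total.max()
    w = np.exp(shifted)
    posterior = w / w.sum()
    log_gbf = total[:, None] - total[None, :]
    return FfxResult(
        log_group_evidence=total,
        posterior=posterior,
        log_gbf=log_gbf,
        model_names=logev.model_names,
    )


def _check_alpha(alpha: np.ndarray, k: int, name: str = "alpha") -> np.ndarray:
    alpha = np.asarray(alpha, dtype=float)
    if alpha.shape != (k,):
        raise ValueError(f"{name} must have length {k}, got shape {alpha.shape}")
    if not np.all(np.isfinite(alpha)) or not np.all(alpha > 0):
        raise ValueError(f"every element of {name} must be finite and > 0")
    return alpha


def rfx_update_assignments(
    logev: LogEvidenceMatrix, alpha: np.ndarray
) -> AssignmentPosterior:
    """One responsibility update of the RFX scheme.

    Computes ``u_nk = exp(log p(y_n|m_nk) + psi(alpha_k) - psi(sum alpha))``
    and the row-normalised beliefs ``g_nk = u_nk / sum_k u_nk``. The
    per-subject maximum of the exponent is subtracted before exponentiation;
    this leaves ``g`` unchanged and prevents overflow for large log-evidence
    differences.
    """
    alpha = _check_alpha(alpha, logev.n_models)
    log_u = logev.values + (digamma(alpha) - digamma(alpha.sum()))
    log_u -= log_u.max(axis=1, keepdims=True)
    u = np.exp(log_u)
    g = u / u.sum(axis=1, keepdims=True)
    return AssignmentPosterior(g=g, u=u)


def rfx_fit(
    logev: LogEvidenceMatrix,
    alpha0: np.ndarray | None = None,
    tol: float = 1e-4,
    max_iter: int = 64,
    ep_samples: int = 1_000_000,
    seed: int | None = 0,
) -> RfxResult:
    """Fit the hierarchical RFX model by the Dirichlet fixed-point iteration.

    Starting from ``alpha = alpha0`` (default ``[1, ..., 1]``: each model
    observed once a priori), iterate

        g  <- responsibilities given alpha
        beta_k <- sum_n g_nk
        alpha  <- alpha0 + beta

    until ``max_k |delta alpha_k| < tol`` or ``max_iter`` sweeps. Convergence
    failure is reported via the ``converged`` flag, not an exception.

    Parameters
    ----------
    tol : float
        Convergence threshold on the largest absolute change of any
        ``alpha_k`` between sweeps.
    ep_samples, seed : int
        Monte-Carlo settings for the exceedance probabilities when K > 2
        (a closed form is used for K = 2).
    """
    k = logev.n_models
    if alpha0 is None:
        alpha0 = np.ones(k)
    alpha0 = _check_alpha(alpha0, k, "alpha0")
    if tol <= 0:
        raise ValueError("tol must be > 0")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")

    alpha = alpha0.copy()
    converged = False
    iterations = 0
    assignment = None
    beta = np.zeros(k)
    for iterations in range(1, max_iter + 1):
        assignment = rfx_update_assignments(logev, alpha)
        beta = assignment.g.sum(axis=0)
        alpha_new = alpha0 + beta
        if np.max(np.abs(alpha_new - alpha)) < tol:
            alpha = alpha_new
            converged = True
            break
        alpha = alpha_new

    posterior = DirichletPosterior(
        alpha=alpha, alpha0=alpha0, n_subjects=logev.n_subjects
    )
    return RfxResult(
        posterior=posterior,
        expected_r=expected_model_probs(posterior),
        exceedance=exceedance_probs(posterior, n_samples=ep_samples, seed=seed),
        assignment=assignment,
        beta=beta,
        iterations=iterations,
        converged=converged,
        model_names=logev.model_names,
    )


def expected_model_probs(posterior: DirichletPosterior) -> np.ndarray:
    """Expected model frequencies ``<r_k> = alpha_k / sum_j alpha_j``."""
    return posterior.alpha / posterior.alpha.sum()


def exceedance_probs(
    posterior: DirichletPosterior,
    n_samples: int = 1_000_000,
    seed: int | None = None,
) -> np.ndarray:
    """Exceedance probabilities ``phi_k = p(r_k > r_j for all j != k | Y)``.

    For K = 2 the marginal of ``r_1`` is Beta(alpha_1, alpha_2) and
    ``phi_1 = p(r_1 > 0.5)`` is evaluated in closed form via the regularised
    incomplete beta function, so ``phi_1 + phi_2 = 1`` exactly. For K > 2,
    ``phi`` is estimated by Monte-Carlo: draw Dirichlet samples and count,
    per model, the fraction of draws in which it is strictly largest
    (exact ties occur with probability zero and are discarded).
    """
    alpha = posterior.alpha
    k = alpha.shape[0]
    if k == 2:
        phi1 = 1.0 - betainc(alpha[0], alpha[1], 0.5)
        return np.array([phi1, 1.0 - phi1])
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if n_samples < EP_SAMPLE_FLOOR:
        logger.warning(
            "exceedance probabilities for K=%d estimated from only %d Monte-Carlo "
            "samples (floor %d); expect noisy values",
            k,
            n_samples,
            EP_SAMPLE_FLOOR,
        )
    rng = np.random.default_rng(seed)
    samples = rng.dirichlet(alpha, size=n_samples)
    top = samples.max(axis=1, keepdims=True)
    is_top = samples == top
    untied = is_top.sum(axis=1) == 1
    wins = (is_top & untied[:, None]).sum(axis=0)
    n_untied = untied.sum()
    if n_untied == 0:  # pragma: no cover - measure-zero event
        return np.full(k, 1.0 / k)
    return wins / n_untied


def posterior_from_bayes_factor(bf: float) -> float:
    """Two-model posterior probability ``bf / (1 + bf)`` under uniform priors.

    A Bayes factor of 20 gives posterior 20/21 ~ 0.952, the conventional
    'strong evidence' boundary.
    """
    if not np.isfinite(bf) or bf <= 0:
        raise ValueError("Bayes factor must be a finite positive number")
    return bf / (1.0 + bf)


def evidence_strength(bf: float) -> str:
    """Conventional strength-of-evidence label for a Bayes factor.

    Follows the usual stratification: > 20 'strong', 3-20 'positive',
    otherwise 'weak'.
    """
    if not np.isfinite(bf) or bf <= 0:
        raise ValueError("Bayes factor must be a finite positive number")
    if bf > 20:
        return "strong"
    if bf > 3:
        return "positive"
    return "weak"
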