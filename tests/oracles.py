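"""Independent reference implementations used only as test oracles.

Deliberately naive transcriptions (scalar loops, no vectorisation, no
stabilisation tricks) so that agreement with the package is a meaningful
cross-check rather than a tautology.
"""

import math

from scipy.integrate import dblquad
from scipy.special import digamma
from scipy.stats import dirichlet


def naive_rfx_fit(values, alpha0, tol=1e-10, max_iter=10_000):
    """Literal scalar-loop transcription of the Dirichlet fixed-point scheme.

    Safe only for small log-evidence differences (no overflow protection).
    Returns (alpha, g, beta, iterations).
    """
    n = len(values)
    k = len(values[0])
    alpha = list(alpha0)
    g = [[0.0] * k for _ in range(n)]
    beta = [0.0] * k
    for it in range(1, max_iter + 1):
        alpha_s = sum(alpha)
        for i in range(n):
            u_row = [
                math.exp(values[i][j] + digamma(alpha[j]) - digamma(alpha_s))
                for j in range(k)
            ]
            u_n = sum(u_row)
            for j in range(k):
                g[i][j] = u_row[j] / u_n
        beta = [sum(g[i][j] for i in range(n)) for j in range(k)]
        new_alpha = [alpha0[j] + beta[j] for j in range(k)]
        if max(abs(new_alpha[j] - alpha[j]) for j in range(k)) < tol:
            return new_alpha, g, beta, it
        alpha = new_alpha
    return alpha, g, beta, max_iter


def exceedance_k3_by_integration(alpha):
    """phi_1 for a 3-model Dirichlet via 2-D quadrature over the simplex.

    phi_1 = P(r_1 > r_2 and r_1 > r_3) with r_3 = 1 - r_1 - r_2; the
    constraint region is r_1 > 1/3, max(0, 1 - 2 r_1) < r_2 < min(r_1, 1 - r_1).
    """
    d = dirichlet(alpha)

    def pdf(r2, r1):
        r3 = 1.0 - r1 - r2
        if r3 <= 0:
            return 0.0
        return d.pdf([r1, r2, r3])

    val, _ = dblquad(
        pdf,
        1.0 / 3.0,
        1.0,
        lambda r1: max(0.0, 1.0 - 2.0 * r1),
        lambda r1: min(r1, 1.0 - r1),
        epsabs=1e-10,
        epsrel=1e-10,
    )
    return val
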