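"""Independent oracles used by the test suite.

The oddity psychometric oracle integrates the differencing decision rule
numerically instead of simulating it: deviations from the grand mean are
jointly Gaussian, so conditioning on the target's deviation reduces the
probability that every non-target deviation is smaller to one- or
two-dimensional Gaussian integrals.
"""

import numpy as np
from scipy import integrate
from scipy.stats import norm

_GL_NODES, _GL_WEIGHTS = np.polynomial.legendre.leggauss(200)


def oddity_pc_quadrature(d_prime: float, m: int) -> float:
    """P(correct) for the farthest-from-the-mean oddity rule, by quadrature.

    Internal responses: target ~ N(d', 1), non-targets ~ N(0, 1).  With
    deviations d_i = x_i - mean(x), the observer is correct when
    |d_target| > |d_j| for all non-targets.  The deviations have mean
    d'(1 - 1/m) (target) and -d'/m (non-targets) and covariance I - J/m;
    conditioning on the target deviation v leaves a chain of univariate
    normal integrals because the non-target deviations must also sum to -v.
    """
    if m not in (3, 4):
        raise ValueError("m must be 3 or 4")
    mu_t = d_prime * (1 - 1 / m)
    mu_nt = -d_prime / m
    var_t = 1 - 1 / m

    if m == 3:

        def inner(v):
            a = abs(v)
            lo = max(-a, -v - a)
            hi = min(a, -v + a)
            if hi <= lo:
                return 0.0
            mu = mu_nt - (v - mu_t) / 2.0
            s = np.sqrt(0.5)
            return norm.cdf(hi, mu, s) - norm.cdf(lo, mu, s)

    else:

        def inner(v):
            a = abs(v)
            if a == 0.0:
                return 0.0
            muc = mu_nt - (v - mu_t) / 3.0
            s2 = 2.0 / 3.0
            rho = -0.5
            d1 = 0.5 * (_GL_NODES + 1) * (2 * a) - a
            w = _GL_WEIGHTS * a
            m2 = muc + rho * (d1 - muc)
            sd2 = np.sqrt(s2 * (1 - rho**2))
            lo = np.maximum(-a, -v - a - d1)
            hi = np.minimum(a, -v + a - d1)
            p2 = np.clip(norm.cdf(hi, m2, sd2) - norm.cdf(lo, m2, sd2), 0, None)
            f1 = norm.pdf(d1, muc, np.sqrt(s2))
            return float(np.sum(w * f1 * p2))

    val, _ = integrate.quad(
        lambda v: norm.pdf(v, mu_t, np.sqrt(var_t)) * inner(v),
        -12,
        12,
        points=[0.0],
        limit=200,
    )
    return float(val)


def ward_scalar_oracle(rho_d, rho_s, alpha, theta_i, phi_i, theta_o, phi_o):
    """Direct scalar transcription of the Ward reflectance formula."""
    import math

    wi = np.array(
        [
            math.sin(theta_i) * math.cos(phi_i),
            math.sin(theta_i) * math.sin(phi_i),
            math.cos(theta_i),
        ]
    )
    wo = np.array(
        [
            math.sin(theta_o) * math.cos(phi_o),
            math.sin(theta_o) * math.sin(phi_o),
            math.cos(theta_o),
        ]
    )
    h = wi + wo
    h = h / np.linalg.norm(h)
    delta = math.acos(min(1.0, h[2]))
    return rho_d / math.pi + rho_s * math.exp(
        -math.tan(delta) ** 2 / alpha**2
    ) / (4 * math.pi * alpha**2 * math.sqrt(math.cos(theta_i) * math.cos(theta_o)))
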