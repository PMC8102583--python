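"""Numerical-integration oracles for the BGe marginal likelihood.

Independent brute-force references: the closed-form score is checked against
direct integration over the Normal-Wishart prior (no shared code paths).
"""

import numpy as np
from scipy import integrate
from scipy.special import gammaln, multigammaln


def numeric_marginal_1d(x, d, alpha_mu, alpha_w, t):
    """Brute-force log p(D) for one column: integrate over (mu, tau).

    tau ~ Gamma((alpha_w - d + 1)/2, rate t/2) (the 1-D Wishart subset
    prior), mu | tau ~ N(0, 1/(alpha_mu tau)).
    """
    n = len(x)
    nu = alpha_w - d + 1

    def integrand(mu, tau):
        loglik = (n / 2) * np.log(tau / (2 * np.pi)) - tau / 2 * np.sum((x - mu) ** 2)
        logpmu = 0.5 * np.log(alpha_mu * tau / (2 * np.pi)) - alpha_mu * tau / 2 * mu ** 2
        logptau = (
            (nu / 2) * np.log(t / 2)
            - gammaln(nu / 2)
            + (nu / 2 - 1) * np.log(tau)
            - t / 2 * tau
        )
        return np.exp(loglik + logpmu + logptau)

    val, _ = integrate.dblquad(
        integrand, 0, np.inf, -np.inf, np.inf, epsabs=1e-13, epsrel=1e-11
    )
    return np.log(val)


def numeric_marginal_2d(x, alpha_mu, nu, t):
    """Brute-force log p(D) for a 2-column block.

    The location is integrated analytically; the 2x2 precision is integrated
    numerically over its Bartlett factors W = L L^T (an exact
    reparameterization of the Wishart prior with dof ``nu``, scale (tI)^-1).
    """
    n, d = x.shape
    assert d == 2
    xbar = x.mean(axis=0)
    c = x - xbar
    m_mat = c.T @ c + (n * alpha_mu / (n + alpha_mu)) * np.outer(xbar, xbar)
    const = (-n * d / 2) * np.log(2 * np.pi) + (d / 2) * np.log(
        alpha_mu / (n + alpha_mu)
    )
    lognorm = (nu / 2) * d * np.log(t) - (nu * d / 2) * np.log(2) - multigammaln(
        nu / 2, d
    )

    def logf(l11, l21, l22):
        w = np.array([[l11 * l11, l11 * l21], [l11 * l21, l21 * l21 + l22 * l22]])
        logdet_w = 2 * (np.log(l11) + np.log(l22))
        prior = ((nu - d - 1) / 2) * logdet_w - 0.5 * t * (
            l11 ** 2 + l21 ** 2 + l22 ** 2
        )
        lik = (n / 2) * logdet_w - 0.5 * np.trace(w @ m_mat)
        jac = np.log(4) + 2 * np.log(l11) + np.log(l22)
        return prior + lik + jac

    grid = np.linspace(0.05, 3.0, 16)
    shift = max(
        logf(a, b, c3)
        for a in grid
        for b in np.linspace(-3, 3, 16)
        for c3 in grid
    )
    val, _ = integrate.tplquad(
        lambda l22, l21, l11: np.exp(logf(l11, l21, l22) - shift),
        1e-6, 8, -8, 8, 1e-6, 8, epsabs=1e-10, epsrel=1e-8,
    )
    return const + lognorm + shift + np.log(val)
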