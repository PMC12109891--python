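"""Deterministic grid-quadrature oracle for tiny panel-logit posteriors.

Computes posterior means of (beta, mu_alpha, sigma_alpha^2) for a
single-covariate random-intercept logit by direct numerical integration:
each respondent's intercept is integrated out on a dense grid, then the
(beta, mu_alpha, log sigma_alpha^2) posterior is normalized by summation.
Completely independent of the Gibbs sampler — no augmentation, no
randomness.
"""

import numpy as np
from scipy import stats


def grid_posterior_means(data, priors, nb=161, nm=81, ns=61, na=321,
                         b_lim=6.0, m_lim=7.0, s2_range=(0.02, 30.0), a_lim=9.0):
    assert data.K == 1, "oracle supports a single covariate"
    x = data.X[:, 0]
    y = data.y
    ridx = data.respondent_index

    b = np.linspace(-b_lim, b_lim, nb)
    m = np.linspace(-m_lim, m_lim, nm)
    ls = np.linspace(np.log(s2_range[0]), np.log(s2_range[1]), ns)
    s2 = np.exp(ls)
    a = np.linspace(-a_lim, a_lim, na)
    da = a[1] - a[0]

    # N(a | m, s2) weights on the intercept grid: (na, nm, ns)
    wnorm = np.exp(
        -0.5 * np.log(2 * np.pi * s2)[None, None, :]
        - 0.5 * (a[:, None, None] - m[None, :, None]) ** 2 / s2[None, None, :]
    )

    log_joint = np.zeros((nb, nm, ns))
    for r in range(data.R):
        rows = ridx == r
        psi = a[:, None, None] + x[rows][None, :, None] * b[None, None, :]
        ll = (y[rows][None, :, None] * psi - np.logaddexp(0, psi)).sum(axis=1)  # (na, nb)
        marg = np.einsum("ab,ams->bms", np.exp(ll), wnorm) * da
        log_joint += np.log(marg)

    log_joint += stats.norm.logpdf(b, priors.mu_beta[0], np.sqrt(1 / priors.A_beta[0, 0]))[:, None, None]
    log_joint += stats.norm.logpdf(m, priors.mu0, np.sqrt(priors.sigma0_sq))[None, :, None]
    # integrate over log sigma^2: density picks up the Jacobian s2
    log_joint += (
        stats.invgamma.logpdf(s2, priors.nu0 / 2, scale=priors.lambda0 / 2) + np.log(s2)
    )[None, None, :]

    post = np.exp(log_joint - log_joint.max())
    post /= post.sum()
    e_beta = float((post.sum(axis=(1, 2)) * b).sum())
    e_mu = float((post.sum(axis=(0, 2)) * m).sum())
    e_s2 = float((post.sum(axis=(0, 1)) * s2).sum())
    return e_beta, e_mu, e_s2
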