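"""Prior log-density for the hierarchical CJS model.

The sampler works on the logit scale for the probability intercepts; the
uniform(0,1) priors on alpha and delta are therefore carried through the
inverse-logit Jacobian, giving a standard-logistic density on each logit
intercept.  Covariate slopes get Normal(0, 1); random-effect values get
Normal(0, sigma) given their standard deviation; the three standard
deviations get uniform(0.1, 10).  Outside any support the density is
-inf.  Normalising constants are included so closed-form checks are
exact.
"""

from __future__ import annotations

import numpy as np

from .params import CJSParameters, SIGMA_LO, SIGMA_HI

__all__ = ["log_prior"]

_LOG_SIGMA_RANGE = np.log(SIGMA_HI - SIGMA_LO)
_HALF_LOG_2PI = 0.5 * np.log(2.0 * np.pi)


def _logistic_logpdf(x):
    """log density of logit(U) for U ~ Uniform(0,1): sigma(x)(1-sigma(x))."""
    ax = np.abs(x)
    return -ax - 2.0 * np.log1p(np.exp(-ax))


def _normal_logpdf(x, sd):
    return -0.5 * (np.asarray(x) / sd) ** 2 - np.log(sd) - _HALF_LOG_2PI


def log_prior(params: CJSParameters) -> float:
    """Joint prior log-density on the sampling scale (logit intercepts)."""
    for s in (params.sigma_gamma, params.sigma_phi_eps, params.sigma_p_eps):
        if not (SIGMA_LO <= s <= SIGMA_HI):
            return -np.inf
    for v in (params.alpha, params.delta_seen, params.delta_unseen):
        if np.any((v <= 0.0) | (v >= 1.0)):
            return -np.inf
    from scipy.special import logit

    lp = 0.0
    for v in (params.alpha, params.delta_seen, params.delta_unseen):
        lp += _logistic_logpdf(logit(v)).sum()
    if params.beta is not None:
        lp += _normal_logpdf(params.beta, 1.0).sum()
    lp += _normal_logpdf(params.gamma, params.sigma_gamma).sum()
    lp += _normal_logpdf(params.eps_phi, params.sigma_phi_eps).sum()
    lp += _normal_logpdf(params.eps_p, params.sigma_p_eps).sum()
    lp += -_LOG_SIGMA_RANGE * 3.0  # uniform(0.1, 10) on each SD
    return float(lp)
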