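"""Parameter container for the hierarchical CJS model.

Linear predictors (logit link throughout):

    logit phi[c, t] = logit(alpha_c) + beta_c * W_t + gamma_t + eps_phi[c, t]
    logit p_seen[c, t]   = logit(delta_seen_c)   + eps_p[c, t]
    logit p_unseen[c, t] = logit(delta_unseen_c) + eps_p[c, t]

gamma_t is the year effect shared across colonies (synchronous),
eps_phi[c, t] the colony-specific deviation (asynchronous), and
eps_p[c, t] a colony-year recapture effect added to both trap-response
intercepts.  Intercepts alpha/delta are stored on the probability scale;
slopes and random effects live on the logit scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit, logit

__all__ = ["CJSParameters", "SIGMA_LO", "SIGMA_HI"]

# prior support for the random-effect standard deviations (logit scale)
SIGMA_LO = 0.1
SIGMA_HI = 10.0


@dataclass
class CJSParameters:
    alpha: np.ndarray          # (C,) survival intercepts, probability scale
    delta_seen: np.ndarray     # (C,) recapture intercept | detected year before
    delta_unseen: np.ndarray   # (C,) recapture intercept | not detected year before
    gamma: np.ndarray          # (n_int,) shared year effect
    eps_phi: np.ndarray        # (C, n_int) colony-year survival deviation
    eps_p: np.ndarray          # (C, n_int) colony-year recapture deviation
    sigma_gamma: float
    sigma_phi_eps: float
    sigma_p_eps: float
    beta: np.ndarray | None = None  # (C,) wind slopes (logit scale), or None

    def __post_init__(self):
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.delta_seen = np.asarray(self.delta_seen, dtype=float)
        self.delta_unseen = np.asarray(self.delta_unseen, dtype=float)
        self.gamma = np.asarray(self.gamma, dtype=float)
        self.eps_phi = np.atleast_2d(np.asarray(self.eps_phi, dtype=float))
        self.eps_p = np.atleast_2d(np.asarray(self.eps_p, dtype=float))
        if self.beta is not None:
            self.beta = np.asarray(self.beta, dtype=float)

    @property
    def n_colonies(self) -> int:
        return len(self.alpha)

    @property
    def n_intervals(self) -> int:
        return len(self.gamma)

    def validate(self) -> None:
        for name in ("alpha", "delta_seen", "delta_unseen"):
            v = getattr(self, name)
            if np.any((v <= 0) | (v >= 1)):
                raise ValueError(f"{name} must lie strictly in (0, 1)")
        for name in ("sigma_gamma", "sigma_phi_eps", "sigma_p_eps"):
            s = getattr(self, name)
            if not (SIGMA_LO <= s <= SIGMA_HI):
                raise ValueError(f"{name}={s} outside prior support [{SIGMA_LO}, {SIGMA_HI}]")
        C, n = self.n_colonies, self.n_intervals
        if self.eps_phi.shape != (C, n) or self.eps_p.shape != (C, n):
            raise ValueError("random-effect arrays must be (n_colonies, n_intervals)")
        if self.beta is not None and len(self.beta) != C:
            raise ValueError("beta must have one slope per colony")

    # -- derived probabilities ------------------------------------------
    def survival_probs(self, wind_centered=None) -> np.ndarray:
        """(C, n_int) survival probabilities from the linear predictor."""
        lp = logit(self.alpha)[:, None] + self.gamma[None, :] + self.eps_phi
        if self.beta is not None:
            if wind_centered is None:
                raise ValueError("wind covariate required: parameters carry beta slopes")
            W = np.asarray(wind_centered, dtype=float)
            if len(W) != self.n_intervals:
                raise ValueError("wind covariate length != number of intervals")
            lp = lp + self.beta[:, None] * W[None, :]
        elif wind_centered is not None:
            raise ValueError("wind covariate supplied but parameters carry no beta")
        return expit(lp)

    def recapture_probs(self) -> tuple[np.ndarray, np.ndarray]:
        """(p_seen, p_unseen), each (C, n_int), at occasions 1..T-1."""
        ps = expit(logit(self.delta_seen)[:, None] + self.eps_p)
        pu = expit(logit(self.delta_unseen)[:, None] + self.eps_p)
        return ps, pu

    def permuted(self, order) -> "CJSParameters":
        """Same parameters with colonies re-ordered (label-symmetry checks)."""
        order = list(order)
        return replace(
            self,
            alpha=self.alpha[order],
            delta_seen=self.delta_seen[order],
            delta_unseen=self.delta_unseen[order],
            eps_phi=self.eps_phi[order],
            eps_p=self.eps_p[order],
            beta=None if self.beta is None else self.beta[order],
        )
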