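"""One-breakpoint piecewise-linear regression with bootstrap restarting.

Fits y = b0 + b1 x + b2 (x - psi)_+ by iterative linearization: at each
step the working design adds the hinge U = (x - psi)_+ and the indicator
V = -1{x > psi}; the OLS ratio of their coefficients updates psi
(step-halved so the residual sum of squares never increases on an
accepted step).  Sensitivity to the starting value is handled by
bootstrap restarting: resampled refits propose alternative breakpoints
from which the original data are refitted, keeping the best fit.  The
breakpoint's standard error comes from the Delta method on the
coefficient ratio V/U using the OLS coefficient covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm

__all__ = ["BreakpointFit", "fit_piecewise", "breakpoint_ci"]


@dataclass
class BreakpointFit:
    psi: float
    psi_se: float | None
    psi_ci: tuple | None
    intercept: float
    slope_left: float
    slope_right: float
    se_left: float
    se_right: float
    converged: bool
    degenerate: bool
    n_iter: int
    rss: float
    n_bootstrap_restarts: int
    message: str = ""


def _ols(x, y, psi):
    U = np.clip(x - psi, 0.0, None)
    V = -(x > psi).astype(float)
    X = sm.add_constant(np.column_stack([x, U, V]))
    res = sm.OLS(y, X).fit()
    return res


def _rss_at(x, y, psi):
    U = np.clip(x - psi, 0.0, None)
    X = sm.add_constant(np.column_stack([x, U]))
    res = sm.OLS(y, X).fit()
    return float(res.ssr), res


def _muggeo(x, y, psi0, max_iter, tol, hinge_floor):
    """Core iteration from one start; returns (psi, rss, n_iter, converged, degenerate)."""
    lo, hi = float(np.min(x)), float(np.max(x))
    psi = float(psi0)
    rss, _ = _rss_at(x, y, psi)
    converged = False
    degenerate = False
    for it in range(1, max_iter + 1):
        res = _ols(x, y, psi)
        b_u, b_v = res.params[2], res.params[3]
        if abs(b_u) < hinge_floor:
            degenerate = True
            break
        step = b_v / b_u
        # step-halving keeps the RSS non-increasing on accepted iterations
        h = 1.0
        accepted = False
        for _ in range(30):
            cand = psi + h * step
            if lo < cand < hi:
                cand_rss, _ = _rss_at(x, y, cand)
                if cand_rss <= rss + 1e-12:
                    psi, rss = cand, cand_rss
                    accepted = True
                    break
            h *= 0.5
        if not accepted:
            converged = True  # no admissible improving step: stationary
            break
        if abs(h * step) < tol:
            converged = True
            break
    return psi, rss, it, converged, degenerate


def fit_piecewise(x, y, psi0: float | None = None, n_bootstrap: int = 10,
                  max_iter: int = 100, tol: float = 1e-8,
                  seed: int = 0, hinge_floor: float = 1e-8) -> BreakpointFit:
    """Fit the one-breakpoint model with bootstrap restarting.

    ``psi0`` defaults to the covariate median; if the iteration stalls or
    the hinge coefficient vanishes, restarts from a quantile grid are
    attempted before flagging the fit degenerate/non-converged.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D arrays")
    if len(x) < 6:
        raise ValueError("need at least 6 points for a breakpoint fit")
    lo, hi = float(np.min(x)), float(np.max(x))
    if psi0 is None:
        psi0 = float(np.median(x))
    if not lo < psi0 < hi:
        raise ValueError("psi0 must lie strictly inside the range of x")

    # rescale the hinge floor to the data
    floor = hinge_floor * max(1.0, float(np.std(y)) / max(np.ptp(x), 1e-12))

    starts = [psi0] + [float(np.quantile(x, q)) for q in (0.25, 0.5, 0.75)]
    best_ok = None   # best converged, non-degenerate
    best_any = None
    for s in starts:
        if not lo < s < hi:
            continue
        psi, rss, it, conv, degen = _muggeo(x, y, s, max_iter, tol, floor)
        cand = (rss, psi, it, conv, degen)
        if best_any is None or rss < best_any[0]:
            best_any = cand
        if conv and not degen and (best_ok is None or rss < best_ok[0]):
            best_ok = cand
    best = best_ok if best_ok is not None else best_any
    rss, psi, n_iter, converged, degenerate = best

    # bootstrap restarting (pairwise resampling with replacement)
    rng = np.random.default_rng(seed)
    n = len(x)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) <= 0:
            continue
        sb = min(max(psi, float(np.min(xb)) + 1e-9), float(np.max(xb)) - 1e-9)
        try:
            psi_b, _, _, conv_b, degen_b = _muggeo(xb, yb, sb, max_iter, tol, floor)
        except Exception:
            continue
        if not (lo < psi_b < hi):
            continue
        psi_r, rss_r, it_r, conv_r, degen_r = _muggeo(x, y, psi_b, max_iter, tol, floor)
        if conv_r and not degen_r and rss_r < rss - 1e-12:
            psi, rss, n_iter, converged, degenerate = psi_r, rss_r, it_r, conv_r, degen_r

    final_rss, final = _rss_at(x, y, psi)
    b0, b1, b2 = final.params
    se = final.bse
    fitobj = BreakpointFit(
        psi=float(psi), psi_se=None, psi_ci=None,
        intercept=float(b0), slope_left=float(b1),
        slope_right=float(b1 + b2),
        se_left=float(se[1]), se_right=float(np.sqrt(final.cov_params()[1, 1]
                                                     + final.cov_params()[2, 2]
                                                     + 2 * final.cov_params()[1, 2])),
        converged=bool(converged and not degenerate),
        degenerate=bool(degenerate),
        n_iter=int(n_iter), rss=float(final_rss),
        n_bootstrap_restarts=int(n_bootstrap),
        message="hinge coefficient indistinguishable from zero" if degenerate else "",
    )
    if fitobj.converged:
        try:
            fitobj.psi_se, fitobj.psi_ci = breakpoint_ci(fitobj, x, y)
        except ValueError as e:
            fitobj.message = str(e)
    return fitobj


def breakpoint_ci(fit: BreakpointFit, x, y, level: float = 0.95):
    """Delta-method SE and CI for the breakpoint.

    At the fitted psi the model is re-linearized with the hinge and
    indicator terms; SE(psi) follows from first-order propagation of the
    OLS covariance through the ratio beta_V / beta_U.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = _ols(x, y, fit.psi)
    b_u, b_v = res.params[2], res.params[3]
    cov = res.cov_params()
    var_u, var_v, cov_uv = cov[2, 2], cov[3, 3], cov[2, 3]
    if abs(b_u) < 1e-10 * max(1.0, abs(b_v)):
        raise ValueError("breakpoint CI undefined: hinge slope indistinguishable from zero")
    r = b_v / b_u
    var_psi = (var_v - 2.0 * r * cov_uv + r * r * var_u) / (b_u * b_u)
    se = float(np.sqrt(max(var_psi, 0.0)))
    from scipy import stats
    # t quantile on the residual df, matching standard segmented-regression
    # practice; at n=44 the normal quantile is ~3% narrower
    q = stats.t.ppf(0.5 + level / 2.0, df=max(len(x) - res.df_model - 1, 1))
    return se, (float(fit.psi - q * se), float(fit.psi + q * se))
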