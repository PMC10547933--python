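"""Synchrony metrics and wind-attributable variance decomposition.

The intra-class correlation ICC = sigma_gamma^2 / (sigma_gamma^2 +
sigma_eps^2) measures the share of between-year survival variance that
is synchronous across colonies.  Adding a covariate to the survival
function leaves residual random-effect variances; the fraction it
"explains" is omega = 1 - residual/total, computed separately for the
synchronous and asynchronous components from a paired no-covariate /
covariate model fit.  omega can be negative (the covariate models noise)
and is reported as-is.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .cjs.draws import PosteriorDraws, summarize

__all__ = ["icc", "posterior_icc", "omega", "decompose",
           "VarianceDecomposition", "slope_posterior_summary"]


def icc(sigma2_gamma: float, sigma2_eps: float) -> float:
    """Intra-class correlation from synchronous/asynchronous variances."""
    if sigma2_gamma < 0 or sigma2_eps < 0:
        raise ValueError("variances must be non-negative")
    tot = sigma2_gamma + sigma2_eps
    if tot == 0:
        raise ValueError("ICC undefined when both variances are zero")
    return float(sigma2_gamma / tot)


def omega(total: float, residual: float) -> float:
    """Fraction of a variance component attributed to the covariate.

    May be negative when the covariate model imputes *more* residual
    variance than the covariate-free model; negative values are
    informative (model stochasticity) and are not clipped.
    """
    if total <= 0:
        raise ValueError("total variance must be > 0")
    if residual < 0:
        raise ValueError("residual variance must be >= 0")
    return float(1.0 - residual / total)


def _variance_draws(draws: PosteriorDraws, which: str) -> np.ndarray:
    name = {"gamma": "sigma_gamma", "eps": "sigma_phi_eps"}[which]
    if name not in draws.params:
        raise ValueError(f"draws carry no {name} (model without that term?)")
    return draws.stacked(name) ** 2


def posterior_icc(draws: PosteriorDraws) -> dict:
    """Per-draw ICC summarized by median and central 95% interval.

    The reported ICC is a posterior summary of the per-draw statistic;
    because the ICC is nonlinear this generally differs from the ICC of
    the posterior-median variances (Jensen gap), which is returned
    alongside under ``icc_of_medians``.
    """
    s2g = _variance_draws(draws, "gamma")
    s2e = _variance_draws(draws, "eps")
    per_draw = s2g / (s2g + s2e)
    out = summarize(per_draw)
    out["icc_of_medians"] = icc(float(np.median(s2g)), float(np.median(s2e)))
    return out


@dataclass
class VarianceDecomposition:
    """Paired-model variance bookkeeping (no-covariate vs covariate fit)."""

    sigma2_gamma_total: dict
    sigma2_eps_total: dict
    sigma2_gamma_res: dict
    sigma2_eps_res: dict
    icc_total: dict
    icc_res: dict
    omega_gamma: float
    omega_eps: float
    summed_median_variance_total: float
    summed_median_variance_res: float
    omega_gamma_draws: dict | None = None  # per-draw extension, clearly labelled
    omega_eps_draws: dict | None = None

    def to_table(self) -> pd.DataFrame:
        """Two-row table: model, variance kind, medians and intervals, ICC."""
        def fmt(s):
            return s["median"], s["lo"], s["hi"]

        rows = []
        for model, s2g, s2e, i in (
            ("no_wind", self.sigma2_gamma_total, self.sigma2_eps_total, self.icc_total),
            ("wind", self.sigma2_gamma_res, self.sigma2_eps_res, self.icc_res),
        ):
            g, glo, ghi = fmt(s2g)
            e, elo, ehi = fmt(s2e)
            ic, iclo, ichi = fmt(i)
            rows.append({"model": model,
                         "variances": "total" if model == "no_wind" else "residual",
                         "sigma2_gamma_median": g, "sigma2_gamma_lo": glo, "sigma2_gamma_hi": ghi,
                         "sigma2_eps_median": e, "sigma2_eps_lo": elo, "sigma2_eps_hi": ehi,
                         "icc_median": ic, "icc_lo": iclo, "icc_hi": ichi})
        return pd.DataFrame(rows)

    def to_json(self, path) -> None:
        from pathlib import Path
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def decompose(no_wind: PosteriorDraws, with_wind: PosteriorDraws,
              per_draw_omega: bool = True) -> VarianceDecomposition:
    """Wind-attributable fractions of synchronous/asynchronous variance.

    Point estimates of omega use the ratio of posterior-median variances
    from the paired fits; a per-draw omega distribution (pairing draws by
    index) is offered as a labelled extension.
    """
    fp_a = no_wind.meta.get("data_fingerprint")
    fp_b = with_wind.meta.get("data_fingerprint")
    if fp_a is not None and fp_b is not None and fp_a != fp_b:
        raise ValueError("the two fits are not on the same dataset/year range")
    if no_wind.has_beta:
        raise ValueError("first argument must be the model WITHOUT the covariate")
    if not with_wind.has_beta:
        raise ValueError("second argument must be the model WITH the covariate")

    s2g_tot = _variance_draws(no_wind, "gamma")
    s2e_tot = _variance_draws(no_wind, "eps")
    s2g_res = _variance_draws(with_wind, "gamma")
    s2e_res = _variance_draws(with_wind, "eps")

    icc_tot = (lambda g, e: summarize(g / (g + e)))(s2g_tot, s2e_tot)
    icc_res = (lambda g, e: summarize(g / (g + e)))(s2g_res, s2e_res)

    med = lambda x: float(np.median(x))
    out = VarianceDecomposition(
        sigma2_gamma_total=summarize(s2g_tot),
        sigma2_eps_total=summarize(s2e_tot),
        sigma2_gamma_res=summarize(s2g_res),
        sigma2_eps_res=summarize(s2e_res),
        icc_total=icc_tot,
        icc_res=icc_res,
        omega_gamma=omega(med(s2g_tot), med(s2g_res)),
        omega_eps=omega(med(s2e_tot), med(s2e_res)),
        summed_median_variance_total=med(s2g_tot) + med(s2e_tot),
        summed_median_variance_res=med(s2g_res) + med(s2e_res),
    )
    if per_draw_omega:
        n = min(len(s2g_tot), len(s2g_res))
        out.omega_gamma_draws = summarize(1.0 - s2g_res[:n] / s2g_tot[:n])
        out.omega_eps_draws = summarize(1.0 - s2e_res[:n] / s2e_tot[:n])
    return out


def slope_posterior_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Per-colony wind-slope medians, 95% CrI and P(beta < 0)."""
    if not draws.has_beta:
        raise ValueError("no covariate slopes in these draws (no-wind model)")
    beta = draws.stacked("beta")  # (n, C)
    rows = []
    for c, name in enumerate(draws.colonies):
        b = beta[:, c]
        s = summarize(b)
        rows.append({"colony": name, "beta_median": s["median"],
                     "beta_lo": s["lo"], "beta_hi": s["hi"],
                     "fraction_below_zero": float(np.mean(b < 0))})
    return pd.DataFrame(rows)
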