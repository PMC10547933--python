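"""Summer wind-speed covariate from monthly gridded component tables.

The covariate is the mean summer (May-August by default) wind speed over
a set of grid cells, computed as the hypotenuse of the *month-averaged*
signed northerly and easterly components per cell, then averaged over
cells and centred on zero over the fitted year range.  Averaging months
before taking the hypotenuse follows the covariate's definition; the
reverse order differs on anisotropic inputs and is deliberately not
offered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["WindCovariate", "compute_wind_covariate", "rank_correlation"]

DEFAULT_MONTHS = (5, 6, 7, 8)


@dataclass(frozen=True)
class WindCovariate:
    """Per-year centred covariate W_t with provenance."""

    years: np.ndarray
    W_raw: np.ndarray
    W_centered: np.ndarray
    cells_used: tuple
    months_used: tuple

    def __post_init__(self):
        object.__setattr__(self, "years", np.asarray(self.years, dtype=int))
        object.__setattr__(self, "W_raw", np.asarray(self.W_raw, dtype=float))
        object.__setattr__(self, "W_centered", np.asarray(self.W_centered, dtype=float))
        if len(self.W_raw) != len(self.years) or len(self.W_centered) != len(self.years):
            raise ValueError("years and wind series lengths disagree")
        if np.any(self.W_raw < 0):
            raise ValueError("raw wind speeds must be non-negative")
        if len(self.years) and abs(self.W_centered.mean()) > 1e-9:
            raise ValueError("centred covariate does not average to zero")

    def subset(self, years) -> "WindCovariate":
        """Restrict to ``years`` and re-centre on that range."""
        years = np.asarray(years, dtype=int)
        idx = {y: i for i, y in enumerate(self.years)}
        missing = [int(y) for y in years if y not in idx]
        if missing:
            raise ValueError(f"years missing from covariate: {missing}")
        raw = self.W_raw[[idx[y] for y in years]]
        return WindCovariate(years, raw, raw - raw.mean(),
                             self.cells_used, self.months_used)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"year": self.years, "W_raw": self.W_raw,
                             "W_centered": self.W_centered})


def compute_wind_covariate(components: pd.DataFrame, cells=None,
                           months=DEFAULT_MONTHS, years=None) -> WindCovariate:
    """Build the covariate from a (year, month, cell, u_mean, v_mean) table.

    Per cell and year, speed = sqrt(u_bar^2 + v_bar^2) with u_bar, v_bar the
    means of the signed monthly components over ``months``; W_raw averages
    those speeds over ``cells`` and W_centered subtracts its mean.
    """
    req = {"year", "month", "cell", "u_mean", "v_mean"}
    if not req <= set(components.columns):
        raise ValueError(f"component table must have columns {sorted(req)}")
    if cells is None:
        cells = sorted(components["cell"].unique())
    if years is None:
        years = sorted(components["year"].unique())
    months = tuple(months)
    sub = components[components["cell"].isin(cells)
                     & components["month"].isin(months)
                     & components["year"].isin(years)]
    have = set(zip(sub["year"], sub["month"], sub["cell"]))
    missing = [(int(y), int(m), c) for y in years for m in months for c in cells
               if (y, m, c) not in have]
    if missing:
        raise ValueError(f"missing (year, month, cell) rows: {missing[:10]}"
                         + ("..." if len(missing) > 10 else ""))
    means = (sub.groupby(["cell", "year"], sort=True)[["u_mean", "v_mean"]]
             .mean())
    speed = np.hypot(means["u_mean"], means["v_mean"])
    W_raw = (speed.groupby(level="year").mean()
             .reindex(years).to_numpy(dtype=float))
    return WindCovariate(np.asarray(years, dtype=int), W_raw, W_raw - W_raw.mean(),
                         tuple(cells), months)


def rank_correlation(series_a, series_b) -> float:
    """Spearman rank correlation (average ranks on ties).

    Raises ``ValueError`` on constant input, where the statistic is
    undefined.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 3:
        raise ValueError("need two equal-length 1-D series of length >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        raise ValueError("rank correlation undefined for a constant series")
    rho = stats.spearmanr(a, b).statistic
    return float(rho)
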