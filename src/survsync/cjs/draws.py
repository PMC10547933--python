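"""Posterior draw container, summaries and serialization."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["PosteriorDraws", "summarize"]


def summarize(x, axis=None) -> dict:
    """Median and central 95% credible interval of an array of draws."""
    x = np.asarray(x, dtype=float)
    return {
        "median": float(np.median(x)) if axis is None else np.median(x, axis=axis),
        "lo": float(np.quantile(x, 0.025)) if axis is None else np.quantile(x, 0.025, axis=axis),
        "hi": float(np.quantile(x, 0.975)) if axis is None else np.quantile(x, 0.975, axis=axis),
    }


@dataclass
class PosteriorDraws:
    """Chain-indexed posterior draws plus derived annual survival.

    ``params`` maps parameter names to arrays with leading dimensions
    (chains, draws); vector parameters append a colony axis, matrix
    parameters (random effects, derived survival) append (colony, year).
    Intercepts are stored on the probability scale, slopes and random
    effects on the logit scale, SDs on their natural scale.
    """

    params: dict
    derived_phi: np.ndarray          # (chains, draws, C, n_int)
    colonies: tuple
    interval_years: np.ndarray       # terminal year label per survival interval
    diagnostics: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)

    @property
    def n_chains(self) -> int:
        return self.derived_phi.shape[0]

    @property
    def n_draws(self) -> int:
        return self.derived_phi.shape[1]

    @property
    def n_total(self) -> int:
        return self.n_chains * self.n_draws

    @property
    def has_beta(self) -> bool:
        return "beta" in self.params

    def stacked(self, name: str) -> np.ndarray:
        """Draws of one parameter with chains flattened into the first axis."""
        x = np.asarray(self.params[name])
        return x.reshape(-1, *x.shape[2:])

    def phi_stacked(self) -> np.ndarray:
        """(chains*draws, C, n_int) derived survival."""
        x = self.derived_phi
        return x.reshape(-1, *x.shape[2:])

    def phi_median(self) -> np.ndarray:
        """(C, n_int) posterior-median annual survival."""
        return np.median(self.phi_stacked(), axis=0)

    def phi_interval(self, q=(0.025, 0.975)) -> np.ndarray:
        return np.quantile(self.phi_stacked(), q, axis=0)

    def summary(self, name: str) -> dict:
        return summarize(self.stacked(name), axis=0 if self.params[name].ndim > 2 else None)

    def phi_frame(self) -> pd.DataFrame:
        """Tidy per colony-year survival summaries."""
        med = self.phi_median()
        lo, hi = self.phi_interval()
        rows = []
        for c, name in enumerate(self.colonies):
            for j, year in enumerate(self.interval_years):
                rows.append({"colony": name, "year": int(year),
                             "phi_median": med[c, j], "phi_lo": lo[c, j],
                             "phi_hi": hi[c, j]})
        return pd.DataFrame(rows)

    def to_tidy_frame(self) -> pd.DataFrame:
        """Long (chain, iteration, parameter, value) table of all draws."""
        recs = []
        for name, arr in self.params.items():
            arr = np.asarray(arr)
            if arr.ndim == 2:
                labels = [name]
                flat = arr[..., None]
            elif arr.ndim == 3 and name == "gamma":  # shared year effect
                labels = [f"{name}[{int(y)}]" for y in self.interval_years]
                flat = arr
            elif arr.ndim == 3:
                labels = [f"{name}[{self.colonies[c]}]" for c in range(arr.shape[2])]
                flat = arr
            else:
                labels = [f"{name}[{self.colonies[c]},{int(y)}]"
                          for c in range(arr.shape[2]) for y in self.interval_years]
                flat = arr.reshape(arr.shape[0], arr.shape[1], -1)
            for k, lab in enumerate(labels):
                for ch in range(arr.shape[0]):
                    recs.append(pd.DataFrame({
                        "chain": ch,
                        "iteration": np.arange(arr.shape[1]),
                        "parameter": lab,
                        "value": flat[ch, :, k],
                    }))
        return pd.concat(recs, ignore_index=True)

    def to_csv(self, path) -> None:
        self.to_tidy_frame().to_csv(path, index=False)
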