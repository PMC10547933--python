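"""Pre-breeding-census Leslie-matrix projections with demographic stochasticity.

Female-only, five-age-class matrix (age at first breeding 5): recruitment
into age class 1 is b * (f/2) * phi_j per breeding female (breeding
propensity times halved fecundity times first-year survival, the latter a
fixed scalar of adult survival); classes advance with adult survival and
adults persist in the final class.  Deterministic mode multiplies
matrices; stochastic mode draws every survival transition (and, by
default, recruitment) as a binomial count.  Parameter uncertainty enters
by resampling complete survival time series from a joint posterior, both
colonies always taken from the same draw so cross-colony correlation is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cjs.draws import PosteriorDraws

__all__ = ["LeslieConfig", "ProjectionResult", "build_matrix",
           "stable_age_distribution", "project", "counterfactual_ratio",
           "project_from_posterior"]


@dataclass(frozen=True)
class LeslieConfig:
    fecundity: float = 0.64            # chicks fledged per pair per year
    breeding_propensity: float = 0.87  # probability a mature female breeds
    juvenile_scalar: float = 0.5       # phi_j / phi_a
    age_first_breeding: int = 5
    initial_breeders: int = 4000       # breeding pairs = females (1:1 sex ratio)
    n_iterations: int = 1000
    stochastic: bool = True
    recruit_mode: str = "binomial"     # or "expected" (stochastic survival only)
    ratio_classes: str = "total"       # or "breeders"
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fecundity <= 1 or not 0 < self.breeding_propensity <= 1:
            raise ValueError("fecundity and breeding propensity must lie in (0, 1]")
        if not 0 < self.juvenile_scalar <= 1:
            raise ValueError("juvenile_scalar must lie in (0, 1]")
        if self.age_first_breeding < 2:
            raise ValueError("age_first_breeding must be >= 2")
        if self.initial_breeders <= 0 or self.n_iterations <= 0:
            raise ValueError("initial_breeders and n_iterations must be positive")
        if self.recruit_mode not in ("binomial", "expected"):
            raise ValueError("recruit_mode must be 'binomial' or 'expected'")
        if self.ratio_classes not in ("total", "breeders"):
            raise ValueError("ratio_classes must be 'total' or 'breeders'")

    def recruitment_prob(self, phi_a: float) -> float:
        return self.breeding_propensity * (self.fecundity / 2.0) * \
            (self.juvenile_scalar * phi_a)


def build_matrix(phi_a: float, config: LeslieConfig = LeslieConfig()) -> np.ndarray:
    """k x k pre-breeding-census Leslie matrix for one year's adult survival."""
    if not 0.0 < phi_a < 1.0:
        raise ValueError("adult survival must lie strictly in (0, 1)")
    k = config.age_first_breeding
    A = np.zeros((k, k))
    A[0, k - 1] = config.recruitment_prob(phi_a)
    for i in range(1, k):
        A[i, i - 1] = phi_a
    A[k - 1, k - 1] = phi_a
    return A


def stable_age_distribution(A: np.ndarray) -> np.ndarray:
    """Dominant right eigenvector normalized to proportions.

    Raises for reducible/degenerate matrices (e.g. zero fecundity), where
    no strictly positive stable structure exists.
    """
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1] or np.any(A < 0):
        raise ValueError("need a square non-negative matrix")
    vals, vecs = np.linalg.eig(A)
    i = int(np.argmax(np.abs(vals)))
    lam = vals[i]
    if abs(lam.imag) > 1e-10 or lam.real <= 0:
        raise ValueError("degenerate matrix: no positive dominant eigenvalue")
    v = np.real(vecs[:, i])
    v = v * np.sign(v.sum())
    if np.any(v <= 1e-12 * max(1.0, v.max())):
        raise ValueError("matrix is reducible/not primitive: eigenvector not strictly positive")
    return v / v.sum()


def dominant_eigenvalue(A: np.ndarray) -> float:
    vals = np.linalg.eigvals(np.asarray(A, dtype=float))
    return float(np.max(np.abs(vals)))


@dataclass
class ProjectionResult:
    """Per-iteration, per-year age-structured female abundances."""

    abundances: np.ndarray     # (iterations, n_years + 1, k)
    lambda_annual: np.ndarray  # (iterations, n_years) dominant eigenvalue per year
    years: np.ndarray          # labels for projected steps (length n_years)
    config: LeslieConfig
    extinct: np.ndarray        # (iterations,) bool flag
    meta: dict = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return self.abundances.shape[0]

    def totals(self) -> np.ndarray:
        """(iterations, n_years + 1) female population size used for ratios."""
        if self.config.ratio_classes == "breeders":
            return self.abundances[:, :, -1]
        return self.abundances.sum(axis=2)

    def to_frame(self) -> pd.DataFrame:
        it, ny, k = self.abundances.shape
        years = np.concatenate([[self.years[0] - 1], self.years])
        recs = {
            "iteration": np.repeat(np.arange(it), ny * k),
            "year": np.tile(np.repeat(years, k), it),
            "age_class": np.tile(np.arange(1, k + 1), it * ny),
            "N": self.abundances.reshape(-1),
        }
        return pd.DataFrame(recs)


def _initial_vector(phi_series, config: LeslieConfig) -> np.ndarray:
    A_mean = build_matrix(float(np.mean(phi_series)), config)
    sad = stable_age_distribution(A_mean)
    v0 = sad / sad[-1] * config.initial_breeders
    return v0


def _project_one(v0, phi_series, config: LeslieConfig, rng) -> tuple[np.ndarray, bool]:
    k = config.age_first_breeding
    ny = len(phi_series)
    N = np.empty((ny + 1, k))
    if config.stochastic:
        v = np.rint(v0).astype(np.int64)
    else:
        v = np.asarray(v0, dtype=float)
    N[0] = v
    extinct = False
    for t, phi in enumerate(phi_series):
        if config.stochastic:
            nxt = np.zeros(k, dtype=np.int64)
            for i in range(1, k):
                nxt[i] = rng.binomial(int(v[i - 1]), phi)
            nxt[k - 1] += rng.binomial(int(v[k - 1]), phi)
            pr = config.recruitment_prob(phi)
            if config.recruit_mode == "binomial":
                nxt[0] = rng.binomial(int(v[k - 1]), pr)
            else:
                nxt[0] = int(np.rint(v[k - 1] * pr))
            v = nxt
            if v.sum() == 0:
                extinct = True
        else:
            v = build_matrix(float(phi), config) @ v
        N[t + 1] = v
    return N, extinct


def project(phi_series, config: LeslieConfig = LeslieConfig(),
            years=None) -> ProjectionResult:
    """Project one colony under a per-year adult-survival series.

    The initial vector is the stable age distribution of the mean-survival
    matrix scaled so the breeding class equals ``initial_breeders``.
    Deterministic mode returns a single trajectory; stochastic mode runs
    ``n_iterations`` independent binomial realizations.
    """
    phi_series = np.asarray(phi_series, dtype=float)
    if np.any((phi_series <= 0) | (phi_series >= 1)):
        raise ValueError("survival values must lie strictly in (0, 1)")
    ny = len(phi_series)
    years = np.arange(1, ny + 1) if years is None else np.asarray(years)
    v0 = _initial_vector(phi_series, config)
    n_it = config.n_iterations if config.stochastic else 1
    rng = np.random.default_rng(config.seed)
    k = config.age_first_breeding
    ab = np.empty((n_it, ny + 1, k))
    ext = np.zeros(n_it, dtype=bool)
    for i in range(n_it):
        ab[i], ext[i] = _project_one(v0, phi_series, config, rng)
    lam = np.array([dominant_eigenvalue(build_matrix(p, config)) for p in phi_series])
    return ProjectionResult(ab, np.tile(lam, (n_it, 1)), years, config, ext)


def counterfactual_ratio(result_a: ProjectionResult,
                         result_b: ProjectionResult) -> pd.DataFrame:
    """Per-year ratio of population sizes a/b with mean and 95% band.

    Ratios pair iteration i of ``result_a`` with iteration i of
    ``result_b``; iteration-years with a zero denominator are excluded
    and counted.
    """
    ta, tb = result_a.totals(), result_b.totals()
    if ta.shape != tb.shape or not np.array_equal(result_a.years, result_b.years):
        raise ValueError("projections must share year range and iteration count")
    years = np.concatenate([[result_a.years[0] - 1], result_a.years])
    rows = []
    for j, year in enumerate(years):
        den = tb[:, j]
        ok = den > 0
        r = ta[ok, j] / den[ok]
        rows.append({"year": int(year),
                     "mean": float(np.mean(r)) if len(r) else np.nan,
                     "median": float(np.median(r)) if len(r) else np.nan,
                     "lo": float(np.quantile(r, 0.025)) if len(r) else np.nan,
                     "hi": float(np.quantile(r, 0.975)) if len(r) else np.nan,
                     "n_excluded": int((~ok).sum())})
    return pd.DataFrame(rows)


def project_from_posterior(draws: PosteriorDraws,
                           config: LeslieConfig = LeslieConfig()) -> dict:
    """Stochastic projections with parameter uncertainty from the posterior.

    Each iteration samples one joint posterior draw index and projects
    *every* colony under that same draw's survival series, preserving the
    cross-colony correlation that the synchrony structure induces.
    Returns {colony: ProjectionResult}; a flag in ``meta`` records when
    draws were re-used (fewer posterior draws than iterations).
    """
    phi = draws.phi_stacked()      # (n_total, C, n_int)
    n_total = phi.shape[0]
    rng = np.random.default_rng(config.seed)
    with_replacement = n_total < config.n_iterations
    idx = rng.choice(n_total, size=config.n_iterations, replace=with_replacement)
    k = config.age_first_breeding
    results = {}
    for c, colony in enumerate(draws.colonies):
        series_mean = phi[:, c, :].mean(axis=0)
        v0 = _initial_vector(series_mean, config)
        ny = phi.shape[2]
        ab = np.empty((config.n_iterations, ny + 1, k))
        ext = np.zeros(config.n_iterations, dtype=bool)
        lam = np.empty((config.n_iterations, ny))
        cfg = replace(config, stochastic=True)
        for i, d in enumerate(idx):
            series = phi[d, c, :]
            ab[i], ext[i] = _project_one(v0, series, cfg, rng)
            lam[i] = [dominant_eigenvalue(build_matrix(p, cfg)) for p in series]
        results[colony] = ProjectionResult(
            ab, lam, np.asarray(draws.interval_years), cfg, ext,
            meta={"sampled_with_replacement": bool(with_replacement),
                  "draw_indices_shared_across_colonies": True})
    return results
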