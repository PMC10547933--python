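"""MCMC contract tests: determinism, diagnostics, model variants.

Deeper statistical checks (parameter recovery, synchrony-regime
recovery, posterior equivalence to the constant-survival MLE) live in
the acceptance suite; these tests keep fits tiny.
"""

import numpy as np
import pytest

from survsync.cjs import (ConvergenceWarning, MCMCSettings, fit,
                          compare_with_independent_fits)
from survsync.wind import WindCovariate

TINY = MCMCSettings(chains=2, iterations=400, burnin=150, thin=5, seed=3)


def wind_for(data, truth):
    years = data.occasions[:-1]
    return WindCovariate(years, truth.wind_raw,
                         truth.wind_raw - truth.wind_raw.mean(),
                         ("sim",), (5, 6, 7, 8))


class TestFitContract:
    def test_same_seed_gives_identical_draws(self, tiny_sim):
        _, data, _ = tiny_sim
        with pytest.warns(ConvergenceWarning):
            a = fit(data, None, TINY)
        with pytest.warns(ConvergenceWarning):
            b = fit(data, None, TINY)
        for k in a.params:
            assert np.array_equal(a.params[k], b.params[k])
        assert np.array_equal(a.derived_phi, b.derived_phi)

    def test_short_chains_warn_on_low_ess(self, tiny_sim):
        """With ~50 retained draws/chain the effective sample size cannot
        reach the 300 threshold, so the fit must warn, not fail."""
        _, data, _ = tiny_sim
        with pytest.warns(ConvergenceWarning, match="effective sample size"):
            fit(data, None, TINY)

    def test_draw_shapes_and_derived_phi_consistency(self, tiny_sim):
        cfg, data, truth = tiny_sim
        with pytest.warns(ConvergenceWarning):
            res = fit(data, wind_for(data, truth), TINY)
        C, n_int = data.n_colonies, data.n_occasions - 1
        assert res.params["alpha"].shape == (2, res.n_draws, C)
        assert res.derived_phi.shape == (2, res.n_draws, C, n_int)
        # derived phi must reproduce its own draw's linear predictor
        from scipy.special import expit, logit
        k = (0, 0)
        W = wind_for(data, truth).W_centered
        lp = (logit(res.params["alpha"][k])[:, None]
              + res.params["beta"][k][:, None] * W[None, :]
              + res.params["gamma"][k][None, :]
              + res.params["eps_phi"][k])
        assert np.allclose(res.derived_phi[k], expit(lp), atol=1e-12)

    def test_probabilities_within_bounds(self, tiny_sim):
        _, data, _ = tiny_sim
        with pytest.warns(ConvergenceWarning):
            res = fit(data, None, TINY)
        assert np.all((res.derived_phi > 0) & (res.derived_phi < 1))
        for name in ("alpha", "delta_seen", "delta_unseen"):
            assert np.all((res.params[name] > 0) & (res.params[name] < 1))
        for name in ("sigma_gamma", "sigma_phi_eps", "sigma_p_eps"):
            s = res.params[name]
            assert np.all((s >= 0.1) & (s <= 10.0))

    def test_empty_dataset_rejected(self, tiny_sim):
        _, data, _ = tiny_sim
        with pytest.raises(ValueError):
            fit(data.subset(np.zeros(data.n_individuals, dtype=bool)), None, TINY)

    def test_wind_year_mismatch_rejected(self, tiny_sim):
        _, data, _ = tiny_sim
        wc = WindCovariate(np.arange(1800, 1805), np.full(5, 2.0),
                           np.zeros(5), ("x",), (5,))
        with pytest.raises(ValueError, match="years"):
            fit(data, wc, TINY)

    def test_tidy_csv_round_trip(self, tiny_sim, tmp_path):
        _, data, _ = tiny_sim
        with pytest.warns(ConvergenceWarning):
            res = fit(data, None, TINY)
        path = tmp_path / "draws.csv"
        res.to_csv(path)
        import pandas as pd
        back = pd.read_csv(path)
        assert set(back.columns) == {"chain", "iteration", "parameter", "value"}
        a = back[back.parameter == f"alpha[{data.colonies[0]}]"]
        assert len(a) == res.n_chains * res.n_draws


class TestIndependentFits:
    def test_report_has_one_row_per_colony_year(self, tiny_sim):
        cfg, data, truth = tiny_sim
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            rep = compare_with_independent_fits(data, None, TINY)
        n_int = data.n_occasions - 1
        assert len(rep["per_colony_year"]) == data.n_colonies * n_int
        assert rep["max_abs_difference"] >= 0.0

    def test_low_synchrony_limit_matches_joint_fit(self):
        """With the synchronous SD at the prior floor the joint and
        independent models coincide up to Monte-Carlo error."""
        import warnings
        from survsync.simulate import SimulationConfig, simulate_dataset

        cfg = SimulationConfig(n_occasions=10, entry_totals=(400, 400),
                               sigma_gamma=0.1, sigma_phi_eps=0.3,
                               sigma_p_eps=0.3, alpha=(0.9, 0.88),
                               delta_seen=(0.5, 0.6), delta_unseen=(0.4, 0.45),
                               transient_fraction=0.0, use_wind=False, seed=21)
        data, _ = simulate_dataset(cfg)
        st = MCMCSettings(chains=2, iterations=3000, burnin=1000, thin=4, seed=9)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            rep = compare_with_independent_fits(data, None, st)
        assert rep["max_abs_difference"] < 0.06


class TestReductionToConstantCJS:
    def test_posterior_medians_approach_constant_mle_at_prior_floor(self):
        """Data generated with both effect SDs tiny and no covariate is a
        constant-per-colony CJS; the hierarchical posterior medians of
        alpha must approach the constant-model maximum-likelihood estimate
        computed by direct optimisation (independent route)."""
        import warnings
        import numpy as np
        from scipy.optimize import minimize
        from scipy.special import expit
        from survsync.simulate import SimulationConfig, simulate_dataset
        from survsync.cjs.likelihood import sufficient_stats, loglik_from_stats

        cfg = SimulationConfig(n_occasions=12, entry_totals=(500, 500),
                               sigma_gamma=0.1, sigma_phi_eps=0.1, sigma_p_eps=0.1,
                               alpha=(0.9, 0.85), delta_seen=(0.5, 0.6),
                               delta_unseen=(0.4, 0.45), use_wind=False,
                               transient_fraction=0.0, seed=13)
        data, _ = simulate_dataset(cfg)
        stats = sufficient_stats(data)
        n_int = data.n_occasions - 1

        def nll(x):
            phi = np.tile(expit(x[:2])[:, None], (1, n_int))
            ps = np.tile(expit(x[2:4])[:, None], (1, n_int))
            pu = np.tile(expit(x[4:6])[:, None], (1, n_int))
            return -loglik_from_stats(stats, phi, ps, pu)

        mle = minimize(nll, np.zeros(6), method="Nelder-Mead",
                       options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8})
        alpha_mle = expit(mle.x[:2])

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = fit(data, None, MCMCSettings(chains=2, iterations=4000,
                                               burnin=1500, thin=5, seed=4))
        alpha_post = res.summary("alpha")["median"]
        assert np.all(np.abs(alpha_post - alpha_mle) < 0.02)
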