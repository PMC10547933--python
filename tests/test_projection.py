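"""Leslie-matrix structure, eigen-oracles and stochastic projection."""

import numpy as np
import pytest

from survsync.cjs.draws import PosteriorDraws
from survsync.projection import (LeslieConfig, build_matrix,
                                 counterfactual_ratio, project,
                                 project_from_posterior,
                                 stable_age_distribution)


class TestBuildMatrix:
    def test_structure_six_nonzero_entries(self):
        A = build_matrix(0.9)
        assert A.shape == (5, 5)
        assert np.count_nonzero(A) == 6
        assert A[0, 4] > 0  # recruitment sits in the top-right corner

    def test_recruitment_entry_arithmetic(self):
        """b * (f/2) * phi_j with phi_j = 0.5 * 0.94: 0.87*0.32*0.47."""
        A = build_matrix(0.94, LeslieConfig())
        assert A[0, 4] == pytest.approx(0.87 * 0.32 * 0.47, abs=1e-12)

    def test_subdiagonal_and_adult_persistence(self):
        phi = 0.88
        A = build_matrix(phi)
        for i in range(1, 5):
            assert A[i, i - 1] == phi
        assert A[4, 4] == phi

    def test_out_of_range_survival_rejected(self):
        with pytest.raises(ValueError):
            build_matrix(1.0)

    def test_zero_fecundity_immortals_have_eigenvalue_one(self):
        # survival ~1, no recruitment: population neither grows nor shrinks
        cfg = LeslieConfig(fecundity=1e-12)
        A = build_matrix(1 - 1e-12, cfg)
        lam = np.max(np.abs(np.linalg.eigvals(A)))
        assert lam == pytest.approx(1.0, abs=1e-9)


class TestStableAge:
    def test_eigen_residual(self):
        A = build_matrix(0.93)
        v = stable_age_distribution(A)
        lam = np.max(np.abs(np.linalg.eigvals(A)))
        assert np.allclose(A @ v, lam * v, atol=1e-10)

    def test_components_positive_and_sum_to_one(self):
        v = stable_age_distribution(build_matrix(0.9))
        assert v.sum() == pytest.approx(1.0)
        assert (v > 0).all()

    def test_pure_survival_matrix_flagged_degenerate(self):
        A = build_matrix(0.9)
        A[0, 4] = 0.0  # no recruitment: reducible
        with pytest.raises(ValueError):
            stable_age_distribution(A)


class TestProject:
    def test_deterministic_growth_converges_to_dominant_eigenvalue(self):
        phi = 0.94
        cfg = LeslieConfig(stochastic=False)
        res = project(np.full(60, phi), cfg)
        tot = res.abundances[0].sum(axis=1)
        lam = res.lambda_annual[0, 0]
        ratios = tot[1:] / tot[:-1]
        assert abs(ratios[-1] - lam) < 1e-6

    def test_deterministic_equals_ordered_matrix_product(self, rng):
        phis = rng.uniform(0.85, 0.97, 10)
        cfg = LeslieConfig(stochastic=False)
        res = project(phis, cfg)
        v = res.abundances[0, 0].copy()
        for p in phis:
            v = build_matrix(p, cfg) @ v
        assert np.allclose(res.abundances[0, -1], v, rtol=1e-12)

    def test_stochastic_mean_tracks_deterministic(self):
        phis = np.full(20, 0.9)
        det = project(phis, LeslieConfig(stochastic=False))
        sto = project(phis, LeslieConfig(stochastic=True, n_iterations=1000, seed=3))
        mean_traj = sto.abundances.sum(axis=2).mean(axis=0)
        det_traj = det.abundances[0].sum(axis=1)
        sd = sto.abundances.sum(axis=2).std(axis=0, ddof=1)
        se = sd / np.sqrt(sto.n_iterations)
        # binomial thinning is unbiased: stochastic mean within 3 SE
        assert np.all(np.abs(mean_traj[1:] - det_traj[1:]) <= 3 * np.maximum(se[1:], 1e-9))

    def test_zero_fecundity_breeders_decay_geometrically(self):
        phi = 0.8
        cfg = LeslieConfig(fecundity=1e-9, stochastic=False)
        res = project(np.full(10, phi), cfg)
        breeders = res.abundances[0, :, -1]
        assert np.allclose(breeders[1:] / breeders[:-1], phi, atol=1e-6)

    def test_total_population_non_increasing_without_recruitment(self):
        cfg = LeslieConfig(fecundity=1e-9, stochastic=True, n_iterations=20, seed=1)
        res = project(np.full(15, 0.9), cfg)
        totals = res.abundances.sum(axis=2)
        assert np.all(np.diff(totals, axis=1) <= 0)

    def test_survival_bounds_enforced(self):
        with pytest.raises(ValueError):
            project([0.9, 1.1], LeslieConfig())


class TestCounterfactual:
    def test_identical_inputs_ratio_one(self):
        res = project(np.full(10, 0.92), LeslieConfig(stochastic=False))
        out = counterfactual_ratio(res, res)
        assert np.allclose(out["mean"], 1.0)

    def test_deterministic_ratio_grows_at_eigenvalue_ratio(self):
        cfg = LeslieConfig(stochastic=False)
        ra = project(np.full(80, 0.95), cfg)
        rb = project(np.full(80, 0.90), cfg)
        out = counterfactual_ratio(ra, rb)
        lam_a, lam_b = ra.lambda_annual[0, 0], rb.lambda_annual[0, 0]
        growth = out["mean"].to_numpy()[1:] / out["mean"].to_numpy()[:-1]
        assert growth[-1] == pytest.approx(lam_a / lam_b, abs=1e-6)

    def test_band_contains_median(self):
        cfg_a = LeslieConfig(stochastic=True, n_iterations=200, seed=0)
        cfg_b = LeslieConfig(stochastic=True, n_iterations=200, seed=1)
        ra = project(np.full(10, 0.94), cfg_a)
        rb = project(np.full(10, 0.9), cfg_b)
        out = counterfactual_ratio(ra, rb)
        assert ((out["lo"] <= out["median"]) & (out["median"] <= out["hi"])).all()


def _posterior_from_phi(phi_draws, colonies=("a", "b")):
    """Minimal PosteriorDraws carrying only derived survival."""
    ch, n, C, n_int = phi_draws.shape
    return PosteriorDraws(params={"alpha": np.full((ch, n, C), 0.9)},
                          derived_phi=phi_draws, colonies=colonies,
                          interval_years=np.arange(2001, 2001 + n_int))


class TestProjectFromPosterior:
    def test_degenerate_posterior_reduces_to_plain_projection(self):
        phi = np.tile(np.linspace(0.9, 0.95, 8), (1, 30, 2, 1))
        draws = _posterior_from_phi(phi)
        cfg = LeslieConfig(n_iterations=50, seed=5)
        out = project_from_posterior(draws, cfg)
        direct = project(phi[0, 0, 0], cfg)
        # same generative process: compare the mean trajectories loosely
        m1 = out["a"].totals().mean(axis=0)
        m2 = direct.totals().mean(axis=0)
        assert np.allclose(m1, m2, rtol=0.05)

    def test_colonies_share_draw_indices(self, rng):
        """Cross-colony correlation is preserved: with perfectly correlated
        posterior series the counterfactual band is far narrower than under
        independent resampling."""
        n = 200
        base = rng.uniform(0.85, 0.97, size=(1, n, 1, 6))
        phi = np.concatenate([base, base], axis=2)  # identical colonies, draw-wise
        draws = _posterior_from_phi(phi)
        cfg = LeslieConfig(n_iterations=100, seed=2, initial_breeders=20_000)
        out = project_from_posterior(draws, cfg)
        ratio = counterfactual_ratio(out["a"], out["b"])
        band = (ratio["hi"] - ratio["lo"]).iloc[-1]
        # independent draws for each colony: shuffle one colony's series
        phi_ind = phi.copy()
        phi_ind[0, :, 1, :] = phi[0, rng.permutation(n), 1, :]
        out_ind = project_from_posterior(_posterior_from_phi(phi_ind), cfg)
        ratio_ind = counterfactual_ratio(out_ind["a"], out_ind["b"])
        band_ind = (ratio_ind["hi"] - ratio_ind["lo"]).iloc[-1]
        assert band < band_ind

    def test_sample_with_replacement_flagged(self):
        phi = np.full((1, 10, 2, 5), 0.9)
        out = project_from_posterior(_posterior_from_phi(phi),
                                     LeslieConfig(n_iterations=50, seed=1))
        assert out["a"].meta["sampled_with_replacement"] is True
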