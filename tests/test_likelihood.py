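"""CJS likelihood: closed forms, enumeration oracle, aggregation identities."""

import itertools

import numpy as np
import pytest
from scipy.special import logit

from survsync.capture import CaptureDataset
from survsync.cjs import (CJSParameters, dataset_loglik, history_loglik,
                          loglik_from_stats, sufficient_stats)


def enumerate_loglik(y, phi, p_seen, p_unseen):
    """Brute-force sum over all latent alive/dead paths.

    The latent trajectory is fully described by the death interval: alive
    through occasion a (the last occasion alive), dead after.  Detections
    use the trap-response probability chosen by the observed detection at
    the preceding occasion.
    """
    y = np.asarray(y)
    T = len(y)
    f = int(np.argmax(y == 1))
    total = 0.0
    for a in range(f, T):  # a = last occasion alive (a == T-1: survived throughout)
        pr = 1.0
        for t in range(f, a):
            pr *= phi[t]
        if a < T - 1:
            pr *= 1.0 - phi[a]
        for t in range(f + 1, T):
            p = p_seen[t - 1] if y[t - 1] == 1 else p_unseen[t - 1]
            if t <= a:
                pr *= p if y[t] == 1 else (1.0 - p)
            elif y[t] == 1:
                pr = 0.0
        total += pr
    return np.log(total) if total > 0 else -np.inf


class TestHistoryLoglik:
    def test_closed_form_released_then_seen(self):
        # history (1,1): survive one interval and be recaptured
        phi, p = 0.8, 0.6
        ll = history_loglik([1, 1], [phi], [p], [0.3])
        assert ll == pytest.approx(np.log(phi * p))

    def test_closed_form_released_never_seen(self):
        # history (1,0): died, or survived and was missed
        phi, p = 0.8, 0.6
        ll = history_loglik([1, 0], [phi], [p], [0.3])
        assert ll == pytest.approx(np.log((1 - phi) + phi * (1 - p)))

    def test_release_at_final_occasion_contributes_nothing(self):
        assert history_loglik([0, 0, 1], [0.5, 0.5], [0.5, 0.5], [0.5, 0.5]) == 0.0

    def test_matches_exhaustive_latent_path_enumeration(self, rng):
        """All 2^5 post-release patterns of a length-6 history, random rates."""
        phi = rng.uniform(0.2, 0.95, 5)
        ps = rng.uniform(0.2, 0.9, 5)
        pu = rng.uniform(0.05, 0.7, 5)
        for pat in itertools.product([0, 1], repeat=5):
            y = np.array([1, *pat])
            expected = enumerate_loglik(y, phi, ps, pu)
            assert history_loglik(y, phi, ps, pu) == pytest.approx(expected, abs=1e-12)

    def test_trap_response_uses_seen_probability_after_release(self):
        # (1,1) must use p_seen (detected at release), not p_unseen
        ll = history_loglik([1, 1], [0.5], [0.9], [0.1])
        assert ll == pytest.approx(np.log(0.5 * 0.9))


def _params_from_truth(cfg, truth, with_beta=True):
    return CJSParameters(
        alpha=np.array(cfg.alpha), delta_seen=np.array(cfg.delta_seen),
        delta_unseen=np.array(cfg.delta_unseen),
        beta=np.array(cfg.beta) if with_beta else None,
        gamma=truth.gamma, eps_phi=truth.eps_phi, eps_p=truth.eps_p,
        sigma_gamma=cfg.sigma_gamma, sigma_phi_eps=cfg.sigma_phi_eps,
        sigma_p_eps=cfg.sigma_p_eps)


class TestDatasetLoglik:
    def test_sufficient_statistics_match_per_history_sum(self, small_sim):
        cfg, data, truth = small_sim
        stats = sufficient_stats(data)
        ll = loglik_from_stats(stats, truth.phi, truth.p_seen, truth.p_unseen)
        ll_sum = sum(
            history_loglik(data.Y[i], truth.phi[c], truth.p_seen[c], truth.p_unseen[c])
            for i, c in enumerate(data.colony_index))
        assert ll == pytest.approx(ll_sum, abs=1e-8)

    def test_reduces_to_constant_cjs_without_random_effects(self):
        """With all effects zero and no covariate the model is a constant
        per-colony CJS; compare against an independent direct computation."""
        Y = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 0], [0, 1, 1]], dtype=np.int8)
        data = CaptureDataset([2000, 2001, 2002], ("a",), list("wxyz"),
                              [0, 0, 0, 0], Y)
        phi, p = 0.8, 0.5
        params = CJSParameters(
            alpha=[phi], delta_seen=[p], delta_unseen=[p], beta=None,
            gamma=np.zeros(2), eps_phi=np.zeros((1, 2)), eps_p=np.zeros((1, 2)),
            sigma_gamma=1.0, sigma_phi_eps=1.0, sigma_p_eps=1.0)
        # direct constant-CJS probability per history
        chi = (1 - phi) + phi * (1 - p)  # never seen after a final-interval release
        expected = (np.log(phi * p * phi * p)          # 111
                    + np.log(phi * (1 - p) * phi * p)  # 101
                    + np.log(phi * p) + np.log(chi)    # 110
                    + np.log(phi * p))                 # 011
        assert dataset_loglik(data, params) == pytest.approx(expected, abs=1e-12)

    def test_duplicating_individuals_doubles_loglik(self, small_sim):
        cfg, data, truth = small_sim
        params = _params_from_truth(cfg, truth, with_beta=False)
        doubled = CaptureDataset(
            data.occasions, data.colonies,
            np.concatenate([data.ids, [f"{i}b" for i in data.ids]]),
            np.concatenate([data.colony_index, data.colony_index]),
            np.vstack([data.Y, data.Y]))
        assert dataset_loglik(doubled, params) == pytest.approx(
            2 * dataset_loglik(data, params), rel=1e-12)

    def test_permutation_invariance(self, small_sim, rng):
        cfg, data, truth = small_sim
        params = _params_from_truth(cfg, truth, with_beta=False)
        perm = rng.permutation(data.n_individuals)
        shuffled = data.subset(perm)
        assert dataset_loglik(shuffled, params) == pytest.approx(
            dataset_loglik(data, params), rel=1e-12)

    def test_colony_label_symmetry(self, small_sim):
        """Permuting colony labels permutes nothing observable: the joint
        likelihood is invariant when data and parameters are permuted
        together."""
        cfg, data, truth = small_sim
        params = _params_from_truth(cfg, truth, with_beta=False)
        swapped_data = CaptureDataset(
            data.occasions, (data.colonies[1], data.colonies[0]), data.ids,
            1 - data.colony_index, data.Y)
        assert dataset_loglik(swapped_data, params.permuted([1, 0])) == pytest.approx(
            dataset_loglik(data, params), rel=1e-12)

    def test_wind_required_iff_beta_present(self, small_sim):
        cfg, data, truth = small_sim
        with pytest.raises(ValueError):
            dataset_loglik(data, _params_from_truth(cfg, truth, with_beta=True),
                           wind=None)
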