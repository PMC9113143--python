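"""Rejection ABC: prior constraints, acceptance bookkeeping, summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mitobottleneck import (
    ABCConfig,
    PriorSpec,
    SimParams,
    abc_reject,
    model_select_mu,
    posterior_predictive,
    posterior_summary,
    sample_prior,
    simulate_observed_cohort,
)
from mitobottleneck.abc import Posterior, summarize_observed
from mitobottleneck.wrightfisher import bottleneck_size, cohort_spectrum_counts


@pytest.fixture(scope="module")
def tiny_observed():
    params = SimParams(alpha=0.85, Td=15, Ta=25, n_cells=100, seed=101)
    return simulate_observed_cohort(params)


@pytest.fixture(scope="module")
def tiny_posterior(tiny_observed):
    cfg = ABCConfig(K=2000, eta=0.01, n_cells=20, seed=7)
    return abc_reject(tiny_observed, cfg, return_all_distances=True)


class TestPrior:
    def test_all_draws_satisfy_constraints(self):
        spec = PriorSpec()
        rng = np.random.default_rng(0)
        a, td, ta = sample_prior(spec, rng, size=5000)
        assert (spec.N0 * a**td > 10).all()
        assert (ta >= td).all()
        assert ((0 <= td) & (td <= 30)).all()
        assert ((10 <= ta) & (ta <= 40)).all()

    def test_single_draw(self):
        a, td, ta = sample_prior(PriorSpec(), np.random.default_rng(1))
        assert 0 < a < 1 and ta >= td

    def test_infeasible_draws_resampled(self):
        # alpha = 0.7, Td = 20 gives Nb = 500 * 0.7**20 ~ 0.4 < 10, so such
        # draws must be resampled: every returned Td stays under the bound
        assert bottleneck_size(500, 0.7, 20) < 10
        spec = PriorSpec(alpha_range=(0.69, 0.71))
        a, td, _ = sample_prior(spec, np.random.default_rng(2), size=500)
        assert (500 * a**td > 10).all()
        assert td.max() < 20

    def test_infeasible_spec_errors_after_bounded_retries(self):
        spec = PriorSpec(alpha_range=(0.0, 0.01), td_range=(30, 30))
        with pytest.raises(RuntimeError, match="feasible"):
            sample_prior(spec, np.random.default_rng(3), size=10)

    def test_td_marginal_uniform_when_alpha_unconstraining(self):
        # with alpha ~ 1, Nb > 10 never binds and Ta >= Td rarely binds for
        # Td <= 10, so the Td marginal restricted there is uniform
        spec = PriorSpec(alpha_range=(0.995, 1.0), td_range=(0, 10))
        rng = np.random.default_rng(4)
        _, td, _ = sample_prior(spec, rng, size=20_000)
        observed = np.bincount(td, minlength=11)
        chi2 = stats.chisquare(observed)
        assert chi2.pvalue > 1e-3

    def test_invalid_ranges_rejected(self):
        with pytest.raises(ValueError):
            PriorSpec(alpha_range=(0.9, 0.5))
        with pytest.raises(ValueError):
            PriorSpec(td_range=(-1, 30))


class TestConfig:
    def test_eta_bounds(self):
        with pytest.raises(ValueError):
            ABCConfig(eta=1.5)
        with pytest.raises(ValueError):
            ABCConfig(eta=0.0)

    def test_k_eta_must_accept_at_least_one(self):
        with pytest.raises(ValueError):
            ABCConfig(K=10, eta=0.001)

    def test_accept_count(self):
        assert ABCConfig(K=2000, eta=0.01).n_accept == 20


class TestRejection:
    def test_accepted_count_is_floor_k_eta(self, tiny_posterior):
        assert len(tiny_posterior) == 20

    def test_accepted_distances_are_a_prefix_of_sorted(self, tiny_posterior):
        d = tiny_posterior.draws["distance"].to_numpy()
        all_d = np.sort(tiny_posterior.all_distances)
        assert np.allclose(np.sort(d), all_d[: len(d)])
        assert d.max() <= tiny_posterior.max_rejected_distance_below

    def test_all_accepted_draws_satisfy_retention(self, tiny_posterior):
        assert (tiny_posterior.draws["Nb"] > 10).all()

    def test_deterministic_given_seed(self, tiny_observed):
        cfg = ABCConfig(K=500, eta=0.02, n_cells=10, seed=42)
        a = abc_reject(tiny_observed, cfg)
        b = abc_reject(tiny_observed, cfg)
        pd.testing.assert_frame_equal(a.draws, b.draws)

    def test_distances_reproducible_from_components(self, tiny_observed):
        """Replay the draw stream and recompute the first distances from the
        public cohort-spectrum API - the kernel loop must match."""
        cfg = ABCConfig(K=200, eta=0.05, n_cells=10, seed=9)
        prior = PriorSpec()
        post = abc_reject(tiny_observed, cfg, prior, return_all_distances=True)
        rng = np.random.default_rng(cfg.seed)
        alphas, tds, tas = sample_prior(prior, rng, size=cfg.K)
        seeds = rng.integers(0, 2**32, size=cfg.K).astype(np.int64)
        obs = summarize_observed(tiny_observed)
        for i in range(5):
            params = SimParams(
                alpha=float(alphas[i]), Td=int(tds[i]), Ta=int(tas[i]),
                n_cells=cfg.n_cells, mu=cfg.mu, seed=int(seeds[i]),
            )
            counts = cohort_spectrum_counts(params)
            expected = np.linalg.norm(counts / cfg.n_cells - obs)
            assert post.all_distances[i] == pytest.approx(expected)

    def test_observed_must_have_19_bins(self):
        from mitobottleneck.spectra import VAFSpectrum

        with pytest.raises(ValueError):
            VAFSpectrum(np.zeros(10), n_cells=5)


class TestSummary:
    def test_identical_draws_collapse_ci(self):
        draws = pd.DataFrame(
            {"alpha": [0.8] * 50, "Td": [10] * 50, "Ta": [20] * 50,
             "Nb": [500 * 0.8**10] * 50, "distance": [0.1] * 50}
        )
        post = Posterior(draws=draws, config=ABCConfig(K=100, eta=0.5), prior=PriorSpec())
        s = posterior_summary(post).set_index("parameter")
        assert s.loc["alpha", "ci_low"] == s.loc["alpha", "ci_high"] == 0.8

    def test_percentiles_match_naive_sort(self, tiny_posterior):
        s = posterior_summary(tiny_posterior).set_index("parameter")
        nb = np.sort(tiny_posterior.draws["Nb"].to_numpy())
        lo, hi = np.percentile(nb, [2.5, 97.5])
        assert s.loc["Nb", "ci_low"] == pytest.approx(lo)
        assert s.loc["Nb", "ci_high"] == pytest.approx(hi)

    def test_nb_consistent_with_alpha_td(self, tiny_posterior):
        d = tiny_posterior.draws
        assert np.allclose(d["Nb"], 500 * d["alpha"] ** d["Td"])

    def test_empty_posterior_rejected(self):
        post = Posterior(
            draws=pd.DataFrame(columns=["alpha", "Td", "Ta", "Nb", "distance"]),
            config=ABCConfig(K=100, eta=0.5),
            prior=PriorSpec(),
        )
        with pytest.raises(ValueError):
            posterior_summary(post)


class TestModelSelection:
    def test_single_candidate_returned(self, tiny_observed):
        cfg = ABCConfig(K=300, eta=0.05, n_cells=10, mu_candidates=(1e-7,), seed=5)
        mu, scores = model_select_mu(tiny_observed, cfg)
        assert mu == 1e-7 and len(scores) == 1

    def test_scores_deterministic(self, tiny_observed):
        cfg = ABCConfig(K=300, eta=0.05, n_cells=10, seed=5)
        _, s1 = model_select_mu(tiny_observed, cfg)
        _, s2 = model_select_mu(tiny_observed, cfg)
        pd.testing.assert_frame_equal(s1, s2)

    def test_recovers_generating_mutation_rate(self, tiny_observed):
        # observed data were generated at mu = 1e-7
        cfg = ABCConfig(K=1500, eta=0.01, n_cells=50, seed=6)
        mu, scores = model_select_mu(tiny_observed, cfg)
        assert mu == 1e-7
        assert scores["mean_accepted_distance"].idxmin() == 1


class TestPosteriorPredictive:
    def test_single_rep_is_one_cohort(self, tiny_posterior):
        mean, spread = posterior_predictive(tiny_posterior, n_reps=1, seed=1)
        assert (spread == 0).all()
        assert mean.counts.shape == (19,)

    def test_averaging_reduces_spread(self, tiny_posterior):
        params = SimParams(alpha=0.85, Td=15, Ta=25, n_cells=100)
        m1, _ = posterior_predictive(tiny_posterior, n_reps=40, seed=2, params=params)
        m2, _ = posterior_predictive(tiny_posterior, n_reps=40, seed=3, params=params)
        singles = [
            posterior_predictive(tiny_posterior, n_reps=1, seed=s, params=params)[0].counts
            for s in (4, 5)
        ]
        mean_diff = np.abs(m1.counts - m2.counts).sum()
        single_diff = np.abs(singles[0] - singles[1]).sum()
        assert mean_diff <= single_diff
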