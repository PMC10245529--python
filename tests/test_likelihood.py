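"""Exact chain likelihood, aggregation and predicted leaf distributions."""

import math

import numpy as np
import pytest
from scipy.stats import norm

from phyllochron.data_model import GenotypeKey, LeafRangeWindow
from phyllochron.likelihood import (PhyllochronParams, aggregate_cumulated,
                                    chain_box_logprob, dataset_loglik,
                                    predict_leaf_distribution,
                                    validation_tables)
from phyllochron.simulate import SimulationDesign, simulate_plants

from conftest import make_intervals


class TestAggregateCumulated:
    def test_identity_at_f_min(self, params, window):
        assert aggregate_cumulated(params, window.f_min) == \
            (params.mu_C, params.sigma_C)

    def test_three_four_five_arithmetic(self, key):
        w = LeafRangeWindow(8, 10)
        p = PhyllochronParams(key=key, window=w, mu_C=100, sigma_C=3.0,
                              mu=[20.0, 20.0], sigma=[4.0, 1e-12])
        m, s = aggregate_cumulated(p, 10)
        assert m == pytest.approx(140.0)
        assert s == pytest.approx(5.0)

    def test_simulated_variance_matches(self, key, params, window):
        d = SimulationDesign(params={key: params}, n_rows=100,
                             plants_per_row=100,
                             schedule=np.arange(100.0, 360.0, 20.0),
                             neg_policy="allow", seed=8)
        _, latent = simulate_plants(d)
        for f0 in (window.f_min, window.f_max):
            m, s = aggregate_cumulated(params, f0)
            h = latent[f"H_{f0}"].to_numpy()
            n = len(h)
            assert abs(h.mean() - m) < 3 * s / math.sqrt(n)
            # SE of the sample SD of a Gaussian ~ s / sqrt(2 n)
            assert abs(h.std() - s) < 3 * s / math.sqrt(2 * n)

    def test_outside_window_errors(self, params, window):
        with pytest.raises(ValueError, match="outside"):
            aggregate_cumulated(params, window.f_max + 1)


def single_rank_problem(key, mu_C=150.0, sigma_C=10.0):
    w = LeafRangeWindow(8, 8)
    p = PhyllochronParams(key=key, window=w, mu_C=mu_C, sigma_C=sigma_C,
                          mu=[], sigma=[])
    return w, p


class TestChainBoxLogprob:
    def test_total_probability_is_one(self, key):
        _, p = single_rank_problem(key)
        ci = make_intervals(key, [8], [0.0], [np.inf])
        # the (0, inf) interval is effectively unconstrained for a Gaussian
        # far from 0: log-probability ~ 0
        assert chain_box_logprob(p, ci) == pytest.approx(0.0, abs=1e-12)

    def test_symmetry_half_probability(self, key):
        _, p = single_rank_problem(key)
        ci = make_intervals(key, [8], [0.0], [150.0])
        assert chain_box_logprob(p, ci) == pytest.approx(math.log(0.5),
                                                         abs=1e-6)

    def test_closed_form_single_rank(self, key):
        _, p = single_rank_problem(key)
        for lo, hi in [(140, 160), (130, 145), (155, 190), (100, 120)]:
            ci = make_intervals(key, [8], [lo], [hi])
            exact = math.log(norm.cdf(hi, 150, 10) - norm.cdf(lo, 150, 10))
            assert chain_box_logprob(p, ci, 128) == pytest.approx(exact,
                                                                  abs=1e-9)

    def test_three_rank_monte_carlo_oracle(self, key):
        w = LeafRangeWindow(8, 10)
        p = PhyllochronParams(key=key, window=w, mu_C=150, sigma_C=10,
                              mu=[20, 25], sigma=[5, 5])
        ci = make_intervals(key, [8, 9, 10], [140, 150, 170], [160, 180, 200])
        lp = chain_box_logprob(p, ci, 128)
        rng = np.random.default_rng(0)
        n = 2_000_000
        h0 = rng.normal(150, 10, n)
        h1 = h0 + rng.normal(20, 5, n)
        h2 = h1 + rng.normal(25, 5, n)
        inbox = ((h0 > 140) & (h0 <= 160) & (h1 > 150) & (h1 <= 180)
                 & (h2 > 170) & (h2 <= 200))
        phat = inbox.mean()
        se = math.sqrt(phat * (1 - phat) / n)
        assert abs(math.exp(lp) - phat) < 3 * se

    def test_grid_doubling_converged(self, key):
        w = LeafRangeWindow(8, 10)
        p = PhyllochronParams(key=key, window=w, mu_C=150, sigma_C=10,
                              mu=[20, 25], sigma=[5, 5])
        ci = make_intervals(key, [8, 9, 10], [140, 150, 170], [160, 180, 200])
        assert abs(chain_box_logprob(p, ci, 128)
                   - chain_box_logprob(p, ci, 256)) < 1e-6

    def test_infeasible_box_returns_neg_inf(self, key):
        _, p = single_rank_problem(key)
        ci = make_intervals(key, [8], [400.0], [420.0])
        with pytest.warns(UserWarning, match="negligible"):
            assert chain_box_logprob(p, ci) == -np.inf


class TestDatasetLoglik:
    def test_single_plant_equals_chain_logprob(self, key, params):
        ci = make_intervals(key, [8, 9, 10, 11, 12],
                            [150, 170, 190, 210, 230],
                            [170, 190, 210, 230, 250])
        single = chain_box_logprob(params, ci)
        assert dataset_loglik({key: params}, [ci]) == pytest.approx(single)

    def test_duplicated_plant_doubles(self, key, params):
        ci1 = make_intervals(key, [8, 9], [150, 170], [170, 190], plant_id="a")
        ci2 = make_intervals(key, [8, 9], [150, 170], [170, 190], plant_id="b")
        w = LeafRangeWindow(8, 9)
        p = PhyllochronParams(key=key, window=w, mu_C=160, sigma_C=10,
                              mu=[20.0], sigma=[4.0])
        assert dataset_loglik({key: p}, [ci1, ci2]) == pytest.approx(
            2 * dataset_loglik({key: p}, [ci1]))

    def test_true_params_beat_perturbed(self, key, params, window):
        wins = 0
        reps = 30
        for rep in range(reps):
            d = SimulationDesign(params={key: params}, n_rows=5,
                                 plants_per_row=10,
                                 schedule=np.arange(100.0, 360.0, 20.0),
                                 seed=500 + rep)
            from phyllochron.data_model import extract_intervals
            series, _ = simulate_plants(d)
            ivs = [extract_intervals(s) for s in series]
            shifted = PhyllochronParams(
                key=key, window=window, mu_C=params.mu_C + 10,
                sigma_C=params.sigma_C, mu=params.mu + 10, sigma=params.sigma)
            if dataset_loglik({key: params}, ivs) >= \
                    dataset_loglik({key: shifted}, ivs):
                wins += 1
        assert wins >= int(0.95 * reps)

    def test_unresolvable_group_errors(self, key, params):
        ci = make_intervals(key, [8], [150], [170])
        with pytest.raises(KeyError):
            dataset_loglik({"other": params}, [ci])


class TestPredictLeafDistribution:
    def test_sums_to_one_and_limits(self, params, window):
        for t in (0.0, 50.0, 150.0, 250.0, 1e5):
            v = predict_leaf_distribution(params, t)
            assert v.shape == (window.n_ranks + 1,)
            assert v.sum() == pytest.approx(1.0)
        assert predict_leaf_distribution(params, 0.0)[0] == pytest.approx(1.0)
        assert predict_leaf_distribution(params, 1e5)[-1] == pytest.approx(1.0)

    def test_matches_simulation_total_variation(self, key, params, window):
        d = SimulationDesign(params={key: params}, n_rows=100,
                             plants_per_row=100,
                             schedule=np.arange(100.0, 360.0, 20.0),
                             neg_policy="allow", seed=21)
        _, latent = simulate_plants(d)
        h = latent[[f"H_{f}" for f in range(window.f_min, window.f_max + 1)]].to_numpy()
        for t in (140.0, 180.0, 210.0, 240.0, 280.0):
            counts = (h <= t).sum(axis=1)  # 0 .. n_ranks
            emp = np.bincount(counts, minlength=window.n_ranks + 1) / len(h)
            pred = predict_leaf_distribution(params, t)
            assert 0.5 * np.abs(emp - pred).sum() < 0.01


class TestValidationTables:
    def test_perfect_model_on_own_simulation(self, key, params):
        d = SimulationDesign(params={key: params}, n_rows=40, plants_per_row=25,
                             schedule=np.arange(100.0, 360.0, 20.0), seed=33)
        series, _ = simulate_plants(d)
        breaks = np.arange(100.0, 380.0, 40.0)
        tab, _ = validation_tables({key: params}, series, breaks)
        assert np.max(np.abs(tab.p_obs - tab.p_pred)) < 0.02

    def test_overestimated_mu_shifts_prediction(self, key, params, window):
        """Inflating mu_f makes the model predict leaf f appears later, so
        the predicted share of class f-1 rises above the observed one."""
        d = SimulationDesign(params={key: params}, n_rows=40, plants_per_row=25,
                             schedule=np.arange(100.0, 360.0, 20.0), seed=34)
        series, _ = simulate_plants(d)
        bad_mu = params.mu.copy()
        bad_mu[1] += 8.0  # rank f_min+2 appears later under the bad model
        bad = PhyllochronParams(key=key, window=window, mu_C=params.mu_C,
                                sigma_C=params.sigma_C, mu=bad_mu,
                                sigma=params.sigma)
        breaks = np.arange(100.0, 380.0, 40.0)
        tab, _ = validation_tables({key: bad}, series, breaks)
        f_shift = window.f_min + 1  # class just below the inflated rank
        sub = tab[tab.leaf_rank == f_shift]
        assert (sub.p_pred - sub.p_obs).sum() > 0

    def test_single_plant_proportions_are_binary(self, key, params):
        d = SimulationDesign(params={key: params}, n_rows=1, plants_per_row=1,
                             schedule=np.arange(100.0, 360.0, 20.0), seed=35)
        series, _ = simulate_plants(d)
        # one observation per ATT bin -> proportions are indicator values
        tab, _ = validation_tables({key: params}, series,
                                   np.arange(95.0, 360.0, 20.0))
        assert set(np.round(tab.p_obs, 12)) <= {0.0, 1.0}
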