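"""Climate weights, windowed features, lasso and the false-climate test."""

import numpy as np
import pandas as pd
import pytest

from phyllochron.climate import (ClimateCandidate, ClimateSeries,
                                 build_features, compute_weights,
                                 cv_predict_mse, false_climate_test,
                                 fit_climate_lasso)
from phyllochron.data_model import GenotypeKey, LeafRangeWindow
from phyllochron.likelihood import PhyllochronParams
from phyllochron.simulate import SimulationDesign, simulate_plants
from phyllochron.data_model import extract_intervals

from conftest import make_intervals


W = LeafRangeWindow(8, 13)


def flat_params(n_groups=6, n_years=2, mu_step=0.0):
    """n_groups genotype-year parameter sets with constant 20 dd instant
    phyllochron (2 calendar days at 10 dd/day)."""
    out = {}
    per_year = n_groups // n_years
    for yi in range(n_years):
        for gi in range(per_year):
            k = GenotypeKey(line="F252", selection="Early",
                            genotype=f"G{gi}", year=f"Y{yi}")
            out[k] = PhyllochronParams(
                key=k, window=W, mu_C=170.0 + 10 * gi, sigma_C=8.0,
                mu=20.0 + mu_step * np.arange(W.n_instant),
                sigma=[3.0] * W.n_instant)
    return out


def att_by_year(params):
    att = pd.Series(10.0 * np.arange(101.0), index=pd.RangeIndex(101))
    return {k.year: att for k in params}


def climate_for(params, fill=1.0, lookback=30, n_days=100, variables=("T",)):
    series = []
    for year in {k.year for k in params}:
        for v in variables:
            idx = np.arange(-lookback, n_days)
            if callable(fill):
                vals = fill(idx)
            else:
                vals = np.full(len(idx), float(fill))
            series.append(ClimateSeries(year=year, variable=v,
                                        values=pd.Series(vals, index=idx)))
    return series


class TestComputeWeights:
    def test_fully_observed_plants_count_everywhere(self, key):
        plants = [make_intervals(key, np.arange(1, 15),
                                 np.linspace(20, 280, 14),
                                 np.linspace(40, 300, 14),
                                 plant_id=f"p{i}") for i in range(7)]
        wts = compute_weights(plants, W)
        assert set(wts.weight) == {7}

    def test_dissection_halves_weights_above_rank(self, key):
        full = [make_intervals(key, np.arange(1, 15),
                               np.linspace(20, 280, 14),
                               np.linspace(40, 300, 14),
                               plant_id=f"f{i}") for i in range(4)]
        # dissected at rank 10: ranks 11+ right-censored
        cut = [make_intervals(key, np.arange(1, 11),
                              np.linspace(20, 200, 10),
                              np.linspace(40, 220, 10),
                              plant_id=f"c{i}", last_time=220.0,
                              complete=False) for i in range(4)]
        wts = compute_weights(full + cut, W).set_index("leaf_rank")
        assert wts.loc[9, "weight"] == 8
        assert wts.loc[10, "weight"] == 8
        assert wts.loc[11, "weight"] == 4
        assert wts.loc[13, "weight"] == 4

    def test_weights_non_increasing_under_dissection(self, key, params):
        d = SimulationDesign(params={key: params}, n_rows=10,
                             plants_per_row=10,
                             schedule=np.arange(100.0, 360.0, 20.0),
                             dissect_fraction=0.5, dissect_rank=10, seed=11)
        series, _ = simulate_plants(d)
        ivs = [extract_intervals(s) for s in series]
        wts = compute_weights(ivs, params.window)
        w_sorted = wts.sort_values("leaf_rank")["weight"].to_numpy()
        assert np.all(np.diff(w_sorted) <= 0)


class TestBuildFeatures:
    def test_constant_climate_gives_window_lengths(self):
        params = flat_params()
        tab = build_features(params, att_by_year(params),
                             climate_for(params, fill=1.0))
        for w in tab.W0:
            assert np.allclose(tab.df[f"T_w{w}"], float(w))

    def test_backward_day_indexing(self):
        # X(day) = -day: at anchor a the w=3 feature is (a-1)+(a-2)+(a-3)
        params = flat_params(n_groups=6)
        tab = build_features(params, att_by_year(params),
                             climate_for(params, fill=lambda idx: -idx.astype(float)))
        df = tab.df
        # mu_C = 170 dd -> cal 17; mu = 20 dd -> 2 days per leaf
        first = df.iloc[0]
        anchor = int(np.floor(first["cal_prev"] + first["mu_cal"]))
        assert first["T_w3"] == pytest.approx(-(3 * anchor - 6))

    def test_cumulative_window_nesting(self):
        rng = np.random.default_rng(0)
        params = flat_params()
        tab = build_features(params, att_by_year(params),
                             climate_for(params,
                                         fill=lambda idx: rng.normal(size=len(idx))))
        df = tab.df
        w0 = list(tab.W0)
        for wa, wb in zip(w0[:-1], w0[1:]):
            diff = df[f"T_w{wb}"] - df[f"T_w{wa}"]
            # the wider window adds older days: increments need not be
            # positive but the nesting is exact for constant climate
            assert np.all(np.isfinite(diff))

    def test_insufficient_lookback_errors(self):
        params = flat_params()
        with pytest.raises(ValueError, match="cover"):
            build_features(params, att_by_year(params),
                           climate_for(params, lookback=0))

    def test_response_is_calendar_increment(self):
        params = flat_params()
        tab = build_features(params, att_by_year(params),
                             climate_for(params))
        # 20 dd at 10 dd/day = 2.0 calendar days for every rank
        assert np.allclose(tab.df["mu_cal"], 2.0)
        assert np.allclose(tab.df["mu_dd"], 20.0)


def _signal_table(seed=0, gamma=2.0, noise=0.01, n_groups=9):
    """Feature table whose response is driven by the T_w5 feature only."""
    rng = np.random.default_rng(seed)
    params = flat_params(n_groups=n_groups, n_years=3)
    clim = climate_for(params, fill=lambda idx: rng.normal(size=len(idx)),
                       variables=("T", "PAR", "RF"))
    tab = build_features(params, att_by_year(params), clim)
    df = tab.df
    x = df["T_w5"].to_numpy()
    x = (x - x.mean()) / x.std()
    df["mu_cal"] = 2.0 + gamma * x + rng.normal(0, noise, len(df))
    return tab


class TestLasso:
    def test_single_active_feature_recovered(self):
        hits = 0
        for seed in range(10):
            tab = _signal_table(seed=seed, gamma=1.0, noise=0.05)
            fit = fit_climate_lasso(tab, weighted=False,
                                    gamma_per_year_line=False)
            g = fit.gamma
            top = g.abs().idxmax()
            hits += (top == "T_w5" and g[top] > 0)
        assert hits >= 9

    def test_huge_penalty_zeroes_gamma(self):
        tab = _signal_table(seed=1)
        fit = fit_climate_lasso(tab, weighted=False, lambda_=1e9,
                                gamma_per_year_line=False)
        assert np.allclose(fit.gamma.to_numpy(), 0.0)

    def test_zero_noise_single_feature_r2(self):
        tab = _signal_table(seed=2, gamma=1.0, noise=1e-9)
        fit = fit_climate_lasso(tab, weighted=False,
                                gamma_per_year_line=False)
        df = tab.df
        from phyllochron.climate import (_penalized_design,
                                         _unpenalized_design)
        Z, _, _ = _unpenalized_design(df)
        X, names = _penalized_design(tab, False)
        pred = Z @ fit.unpenalized + X @ (fit.gamma.to_numpy())
        y = df["mu_cal"].to_numpy()
        ss_res = np.sum((y - pred) ** 2)
        ss_tot = np.sum((y - y.mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.999

    def test_too_few_groups_errors(self):
        params = flat_params(n_groups=2, n_years=1)
        tab = build_features(params, att_by_year(params),
                             climate_for(params))
        with pytest.raises(ValueError, match="cross-validation"):
            fit_climate_lasso(tab)


class TestCvPredictMse:
    def test_perfect_predictions_give_zero_mse(self):
        # constant response identical across groups: leave-one-out predicts
        # it exactly (alpha/beta structure) -> MSE ~ 0
        params = flat_params(n_groups=6, n_years=2)
        tab = build_features(params, att_by_year(params),
                             climate_for(params))
        preds, mse = cv_predict_mse(tab, weighted=False, lambda_=1e9)
        assert mse == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(preds["pred_dd"], preds["mu_dd"])

    def test_hand_computed_weighted_mse(self):
        params = flat_params(n_groups=6, n_years=2)
        tab = build_features(params, att_by_year(params),
                             climate_for(params))
        preds, mse0 = cv_predict_mse(tab, weighted=False, lambda_=1e9)
        # doubling all weights doubles the weighted MSE contributions
        tab.df["weight"] = 2.0
        _, mse2 = cv_predict_mse(tab, weighted=True, lambda_=1e9)
        tab.df["weight"] = 1.0
        _, mse1 = cv_predict_mse(tab, weighted=True, lambda_=1e9)
        assert mse2 == pytest.approx(2 * mse1, abs=1e-9)
        assert mse1 == pytest.approx(mse0, abs=1e-12)

    def test_row_order_invariance(self):
        tab = _signal_table(seed=3, gamma=0.5, noise=0.05)
        _, mse = cv_predict_mse(tab, weighted=False, lambda_=0.01)
        shuffled = tab
        shuffled.df = tab.df.sample(frac=1.0, random_state=0).reset_index(
            drop=True)
        _, mse_shuf = cv_predict_mse(shuffled, weighted=False, lambda_=0.01)
        assert mse_shuf == pytest.approx(mse, rel=1e-9)


class TestFalseClimateTest:
    def _pool(self, seed, n=7):
        rng = np.random.default_rng(seed)
        idx = np.arange(-30, 100)
        return [ClimateCandidate(
            label=f"f{i}",
            series={"T": pd.Series(rng.normal(size=len(idx)), index=idx)})
            for i in range(n)]

    def test_small_pool_errors(self):
        params = flat_params(n_groups=6, n_years=2)
        clim = climate_for(params)
        with pytest.raises(ValueError, match="pool"):
            false_climate_test(params, att_by_year(params), clim,
                               self._pool(0, n=2), n_false=10,
                               rng=np.random.default_rng(0))

    def test_tie_counts_as_not_smaller(self):
        # constant response and constant-feature pool: every false climate
        # ties with the truth -> p = 0 strictly-smaller convention
        params = flat_params(n_groups=6, n_years=2)
        clim = climate_for(params)
        idx = np.arange(-30, 100)
        pool = [ClimateCandidate(label=f"c{i}",
                                 series={"T": pd.Series(np.full(len(idx), 1.0),
                                                        index=idx)})
                for i in range(6)]
        res = false_climate_test(params, att_by_year(params), clim, pool,
                                 n_false=30, rng=np.random.default_rng(1),
                                 n_lambda=5)
        assert res.p_value == 0.0
        assert np.allclose(res.mse_false, res.mse_true)
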