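"""Sharing models, LRT arithmetic and row-permutation tests."""

import numpy as np
import pytest

from phyllochron.data_model import (GenotypeKey, LeafRangeWindow,
                                    extract_intervals)
from phyllochron.group_tests import (PermutationResult, SharingSpec,
                                     chi2_pvalue, fit_shared, lrt,
                                     permutation_test)
from phyllochron.likelihood import PhyllochronParams
from phyllochron.mcem import McemSettings
from phyllochron.simulate import SimulationDesign, simulate_plants

WINDOW = LeafRangeWindow(6, 9)


def two_line_dataset(seed=0, delta_muC=0.0, n_rows=4, plants_per_row=5,
                     selections=("Early",), genotypes_per_cell=1):
    params = {}
    for li, line in enumerate(("F252", "MBS")):
        for si, sel in enumerate(selections):
            for gi in range(genotypes_per_cell):
                k = GenotypeKey(line=line, selection=sel,
                                genotype=f"{line[0]}{sel[0]}{gi}", year="2015")
                params[k] = PhyllochronParams(
                    key=k, window=WINDOW, mu_C=150.0 + delta_muC * li,
                    sigma_C=10.0, mu=[20.0, 22.0, 21.0], sigma=[4.0, 4.0, 4.0])
    d = SimulationDesign(params=params, n_rows=n_rows,
                         plants_per_row=plants_per_row,
                         schedule=np.arange(80.0, 320.0, 20.0), seed=seed)
    series, _ = simulate_plants(d)
    return [extract_intervals(s) for s in series]


FAST = McemSettings(n_mc_start=25, n_mc_max=80, burn_in=30, reburn=5,
                    thinning=1, max_iter=6, rel_tol=5e-3, n_avg_final=2,
                    seed=0)


class TestSharingSpec:
    def test_only_the_seven_models_are_valid(self):
        valid = [(0, 0), (1, 0), (1, 1), (2, 1), (2, 2), (3, 2), (3, 3)]
        for i, j in valid:
            assert SharingSpec(i, j).name == f"M{i}{j}"
        for i, j in [(0, 1), (2, 0), (3, 1), (1, 2)]:
            with pytest.raises(ValueError):
                SharingSpec(i, j)

    def test_nesting_follows_the_lattice(self):
        chain = [SharingSpec(*ij) for ij in
                 [(0, 0), (1, 0), (1, 1), (2, 1), (2, 2), (3, 2), (3, 3)]]
        for lo, hi in zip(chain[:-1], chain[1:]):
            assert hi.nests(lo)
            assert not lo.nests(hi)
        assert not SharingSpec(1, 0).nests(SharingSpec(1, 1))


class TestFitShared:
    def test_m00_pools_everything(self):
        data = two_line_dataset(seed=1)
        fit = fit_shared(data, SharingSpec(0, 0), WINDOW, FAST,
                         rng=np.random.default_rng(0))
        assert len(fit.cum_cells) == 1 and len(fit.inst_cells) == 1
        assert fit.n_params == 2 + 2 * WINDOW.n_instant
        # equivalent to manually pooling under one label
        relabeled = []
        for ci in data:
            k = ci.key
            relabeled.append(type(ci)(
                plant_id=ci.plant_id, row_id=ci.row_id,
                key=GenotypeKey("L", "S", "G", k.year),
                ranks=ci.ranks, lower=ci.lower, upper=ci.upper,
                last_time=ci.last_time, complete=ci.complete))
        manual = fit_shared(relabeled, SharingSpec(0, 0), WINDOW, FAST,
                            rng=np.random.default_rng(0))
        assert manual.loglik == pytest.approx(fit.loglik, abs=1e-9)
        assert np.allclose(manual.params.mu, fit.params.mu)

    def test_m33_equals_independent_genotype_fits(self):
        data = two_line_dataset(seed=2, n_rows=3)
        fit = fit_shared(data, SharingSpec(3, 3), WINDOW, FAST,
                         rng=np.random.default_rng(1))
        assert len(fit.cum_cells) == 2
        total = 0.0
        for key in {ci.key for ci in data}:
            sub = [ci for ci in data if ci.key == key]
            f = fit_shared(sub, SharingSpec(3, 3), WINDOW, FAST,
                           rng=np.random.default_rng(2))
            total += f.loglik
        # independent fits reach the same optimum up to MCEM noise
        assert total == pytest.approx(fit.loglik, abs=2.0)

    def test_line_effect_grows_loglik_gap(self):
        gaps = {}
        for n_rows in (2, 6):
            data = two_line_dataset(seed=3, delta_muC=25.0, n_rows=n_rows)
            full = fit_shared(data, SharingSpec(1, 0), WINDOW, FAST,
                              rng=np.random.default_rng(3))
            red = fit_shared(data, SharingSpec(0, 0), WINDOW, FAST,
                             rng=np.random.default_rng(3))
            gaps[n_rows] = full.loglik - red.loglik
        assert gaps[6] > gaps[2] > 0

    def test_params_for_resolves_hierarchy(self):
        data = two_line_dataset(seed=4)
        fit = fit_shared(data, SharingSpec(1, 0), WINDOW, FAST,
                         rng=np.random.default_rng(4))
        k = data[0].key
        p = fit.params_for(k)
        assert p.window == WINDOW
        # instant parameters are shared across lines in M10
        other = [ci.key for ci in data if ci.key.line != k.line][0]
        assert np.allclose(fit.params_for(other).mu, p.mu)


class TestLrtChi2:
    def test_hand_built_lls(self):
        data = two_line_dataset(seed=5, n_rows=2, plants_per_row=3)
        full = fit_shared(data, SharingSpec(1, 0), WINDOW, FAST,
                          rng=np.random.default_rng(5))
        red = fit_shared(data, SharingSpec(0, 0), WINDOW, FAST,
                         rng=np.random.default_rng(5))
        full.loglik, red.loglik = -97.0, -100.0
        assert lrt(full, red) == pytest.approx(6.0)
        full.loglik = red.loglik
        assert lrt(full, red) == pytest.approx(0.0)

    def test_non_nested_pair_errors(self):
        data = two_line_dataset(seed=5, n_rows=2, plants_per_row=3)
        full = fit_shared(data, SharingSpec(1, 0), WINDOW, FAST,
                          rng=np.random.default_rng(5))
        red = fit_shared(data, SharingSpec(0, 0), WINDOW, FAST,
                         rng=np.random.default_rng(5))
        with pytest.raises(ValueError, match="nest"):
            lrt(red, full)

    def test_chi2_pvalue_values(self):
        assert chi2_pvalue(0.0, 1) == pytest.approx(1.0)
        assert chi2_pvalue(3.841, 1) == pytest.approx(0.05, abs=1e-3)
        for s in (0.7, 3.2, 9.0):
            assert chi2_pvalue(s, 2) == pytest.approx(np.exp(-s / 2), abs=1e-12)
        with pytest.raises(ValueError):
            chi2_pvalue(1.0, 0)


class TestPermutationTest:
    def test_too_few_assignments_error(self):
        # 2 rows per line -> C(4,2) = 6 <= 20 distinct assignments
        data = two_line_dataset(seed=6, n_rows=2)
        with pytest.raises(ValueError, match="distinct row assignments"):
            permutation_test(data, SharingSpec(1, 0), SharingSpec(0, 0),
                             WINDOW, settings=FAST,
                             rng=np.random.default_rng(0))

    def test_exhaustive_counting_convention(self):
        # 4 rows per line -> C(8,4) = 70 distinct assignments, enumerated
        data = two_line_dataset(seed=7, delta_muC=60.0, n_rows=4)
        res = permutation_test(data, SharingSpec(1, 0), SharingSpec(0, 0),
                               WINDOW, max_perms=100, settings=FAST,
                               rng=np.random.default_rng(1))
        assert res.exhaustive and res.n_permutations == 70
        # a 60-dd shift dwarfs the null: observed is the unique maximum
        assert res.p_value == pytest.approx(1 / 70)

    def test_sampled_mode_add_one_convention(self):
        data = two_line_dataset(seed=8, delta_muC=60.0, n_rows=4)
        res = permutation_test(data, SharingSpec(1, 0), SharingSpec(0, 0),
                               WINDOW, max_perms=25, settings=FAST,
                               rng=np.random.default_rng(2))
        assert not res.exhaustive and res.n_permutations == 25
        assert res.p_value == pytest.approx(1 / 26)
        assert 0.0 < res.p_value <= 1.0

    def test_invariant_to_group_relabeling(self):
        data = two_line_dataset(seed=9, delta_muC=30.0, n_rows=4)
        swapped = []
        rename = {"F252": "MBS", "MBS": "F252"}
        for ci in data:
            k = ci.key
            swapped.append(type(ci)(
                plant_id=ci.plant_id, row_id=ci.row_id,
                key=GenotypeKey(rename[k.line], k.selection, k.genotype,
                                k.year),
                ranks=ci.ranks, lower=ci.lower, upper=ci.upper,
                last_time=ci.last_time, complete=ci.complete))
        r1 = permutation_test(data, SharingSpec(1, 0), SharingSpec(0, 0),
                              WINDOW, max_perms=100, settings=FAST,
                              rng=np.random.default_rng(3))
        r2 = permutation_test(swapped, SharingSpec(1, 0), SharingSpec(0, 0),
                              WINDOW, max_perms=100, settings=FAST,
                              rng=np.random.default_rng(3))
        assert r1.exhaustive and r2.exhaustive
        assert r1.p_value == pytest.approx(r2.p_value, abs=0.05)

    def test_selection_permuted_within_line_strata(self):
        # full M21 distinguishes selection: permute Early/Late within lines
        data = two_line_dataset(seed=10, n_rows=3,
                                selections=("Early", "Late"))
        res = permutation_test(data, SharingSpec(2, 1), SharingSpec(1, 1),
                               WINDOW, max_perms=30, settings=FAST,
                               rng=np.random.default_rng(4))
        # C(6,3)^2 = 400 assignments available; sampled mode here
        assert res.n_permutations == 30
        assert 0.0 < res.p_value <= 1.0
        # one extra cumulated cell per line, each carrying (mu_C, sigma_C)
        assert res.df == 4
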