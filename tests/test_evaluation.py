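"""Metrics, stratified reports and the random baseline."""

import math

import numpy as np
import pytest

from tangle.evaluation import (BaselineResult, RandomBaselineConfig,
                               circular_cc, compute_metrics, evaluate_dataset,
                               expected_baseline, expected_random_mae, mae,
                               pearson_cc, random_baseline_mae, rmse,
                               wilcoxon_paired)
from tangle.geometry import AngleNormalizer, angular_difference
from tangle.profiles import AngleRecord


def _rec(aa, phi, phi_pred, ss="C", sa="E", chain="c1", pos="1"):
    return AngleRecord(residue_name=aa, chain_name=chain, position=pos,
                       phi=phi, phi_pred=phi_pred, ss=ss, sa=sa)


class TestPearson:
    def test_perfect_correlation(self):
        assert pearson_cc([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)

    def test_sign_flip(self):
        assert pearson_cc([1, 2, 3], [-1, -2, -3]) == pytest.approx(-1.0)

    def test_hand_computed_triple(self):
        # x=(0,1,2), y=(0,2,1): cov=0.5*sum((x-1)(y-1))/..., r = 0.5
        assert pearson_cc([0, 1, 2], [0, 2, 1]) == pytest.approx(0.5)

    def test_zero_variance_gives_nan_with_warning(self, caplog):
        assert math.isnan(pearson_cc([1, 1, 1], [0, 2, 1]))
        assert any("variance" in m for m in caplog.messages)

    def test_circular_variant_agrees_on_narrow_data(self, rng):
        x = rng.normal(0, 5, 200)
        y = x + rng.normal(0, 1, 200)
        assert circular_cc(x, y) == pytest.approx(pearson_cc(x, y), abs=0.05)


class TestMaeRmse:
    def test_identical_vectors(self):
        assert mae([10, 20], [10, 20]) == 0.0
        assert rmse([10, 20], [10, 20]) == 0.0

    def test_constant_offset(self):
        assert mae([0, 50, 100], [10, 60, 110]) == pytest.approx(10.0)

    def test_wrap_case_circular_vs_linear(self):
        assert mae([-175], [175], "circular") == pytest.approx(10.0)
        assert mae([-175], [175], "linear") == pytest.approx(350.0)

    def test_rmse_arithmetic(self):
        # errors (3, 4): sqrt((9+16)/2) = sqrt(12.5)
        assert rmse([0, 0], [3, 4]) == pytest.approx(math.sqrt(12.5))

    def test_rmse_dominates_mae(self, rng):
        x = rng.uniform(-180, 180, 300)
        y = rng.uniform(-180, 180, 300)
        assert rmse(x, y) >= mae(x, y)

    def test_norm_scale_requires_normalizer(self):
        with pytest.raises(ValueError):
            rmse([0], [1], scale="norm")

    def test_norm_scale_value(self):
        norm = AngleNormalizer(mu_phi=0, sigma_phi=30, mu_psi=0, sigma_psi=30)
        # 18 deg error = 18/180 = 0.1 on the normalized scale
        assert rmse([0.0], [18.0], scale="norm", normalizer=norm,
                    which="phi") == pytest.approx(0.1)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            mae([], [])


class TestEvaluateDataset:
    def test_perfect_prediction(self):
        recs = [_rec("ALA", a, a, pos=str(i))
                for i, a in enumerate([-60.0, -70.0, -80.0, 100.0])]
        rep = evaluate_dataset({"c1": recs}, "phi")
        assert rep.overall.cc == pytest.approx(1.0)
        assert rep.overall.mae == 0.0
        assert rep.chain_summary["frac_cc_ge_0.5"] == 1.0

    def test_stratum_counts_conserved(self):
        recs = ([_rec("ALA", -60, -50, ss="H") for _ in range(4)] +
                [_rec("GLY", 80, 100, ss="C") for _ in range(3)])
        rep = evaluate_dataset({"c1": recs}, "phi")
        for strata in (rep.by_aa, rep.by_ss, rep.by_sa):
            assert sum(m.n for m in strata.values()) == rep.overall.n == 7

    def test_twenty_degree_bins_span_the_circle(self):
        angles = np.arange(-180.0, 180.0, 5.0)
        recs = [_rec("ALA", a, a) for a in angles]
        rep = evaluate_dataset({"c1": recs}, "phi")
        assert len(rep.by_bin) == 18
        assert sum(m.n for m in rep.by_bin.values()) == angles.size

    def test_undefined_pairs_excluded(self):
        recs = [_rec("ALA", -60, -55), _rec("ALA", math.nan, -70),
                _rec("ALA", -65, math.nan), _rec("ALA", -80, -75)]
        rep = evaluate_dataset({"c1": recs}, "phi")
        assert rep.overall.n == 2

    def test_short_chain_skipped_from_chain_level(self, caplog):
        recs = [_rec("ALA", -60, -55)]
        rep = evaluate_dataset({"tiny": recs}, "phi")
        assert "tiny" not in rep.per_chain
        assert any("skipped" in m for m in caplog.messages)


class TestExpectedRandomMae:
    def test_symmetric_pool(self):
        assert expected_random_mae([0.0, 180.0], [90.0]) == pytest.approx(90.0)

    def test_single_element_pool(self):
        assert expected_random_mae([10.0], [0.0]) == pytest.approx(10.0)

    def test_matches_exhaustive_enumeration(self):
        pool = [-170.0, 10.0, 100.0, 175.0]
        obs = [-60.0, 0.0, 160.0]
        manual = np.mean([
            np.mean([angular_difference(o, p) for p in pool]) for o in obs])
        assert expected_random_mae(pool, obs) == pytest.approx(manual)


class TestRandomBaseline:
    def _records(self):
        rng = np.random.default_rng(3)
        train = [_rec("ALA", a, math.nan)
                 for a in rng.uniform(-90, -50, 40)]
        train += [_rec("GLY", a, math.nan)
                  for a in rng.uniform(-180, 180, 40)]
        test = [_rec("ALA", a, math.nan, pos=str(i))
                for i, a in enumerate(rng.uniform(-90, -50, 15))]
        test += [_rec("GLY", a, math.nan, pos=str(i))
                 for i, a in enumerate(rng.uniform(-180, 180, 10))]
        return train, test

    def test_single_element_pool_exact(self):
        train = [_rec("ALA", -70.0, math.nan)]
        test = [_rec("ALA", -60.0, math.nan)]
        res = random_baseline_mae(train, test, "phi",
                                  RandomBaselineConfig(repeats=7, seed=1))
        assert res.mean_mae == pytest.approx(10.0)

    def test_converges_to_exact_expectation(self):
        train, test = self._records()
        exact = expected_baseline(train, test, "phi")
        res = random_baseline_mae(train, test, "phi",
                                  RandomBaselineConfig(repeats=4000, seed=2))
        assert abs(res.mean_mae - exact) <= 3 * res.se_mae + 1e-9

    def test_monte_carlo_error_shrinks_with_repeats(self):
        train, test = self._records()
        ses = [random_baseline_mae(
            train, test, "phi",
            RandomBaselineConfig(repeats=r, seed=4)).se_mae
            for r in (100, 1000, 10000)]
        assert ses[0] > ses[1] > ses[2]

    def test_per_aa_beats_global_when_angles_depend_on_aa(self):
        train, test = self._records()
        per_aa = expected_baseline(train, test, "phi", granularity="per_aa")
        global_ = expected_baseline(train, test, "phi", granularity="global")
        assert per_aa <= global_

    def test_reproducible_under_seed(self):
        train, test = self._records()
        cfg = RandomBaselineConfig(repeats=200, seed=11)
        a = random_baseline_mae(train, test, "phi", cfg)
        b = random_baseline_mae(train, test, "phi", cfg)
        assert a.mean_mae == b.mean_mae

    def test_unseen_amino_acid_falls_back_to_global_pool(self, caplog):
        train = [_rec("ALA", a, math.nan) for a in (-60.0, -80.0)]
        test = [_rec("TRP", -70.0, math.nan)]
        res = random_baseline_mae(train, test, "phi",
                                  RandomBaselineConfig(repeats=50, seed=0))
        assert math.isfinite(res.mean_mae)
        assert any("global pool" in m for m in caplog.messages)

    def test_empty_pool_is_an_error(self):
        with pytest.raises(ValueError):
            random_baseline_mae([], [_rec("ALA", 0.0, math.nan)], "phi")


def test_wilcoxon_detects_consistent_improvement(rng):
    a = rng.uniform(20, 30, 30)
    b = a + rng.uniform(1, 5, 30)  # b consistently worse
    stat, p = wilcoxon_paired(a, b)
    assert p < 1e-4
    _, p_same = wilcoxon_paired(a, a + rng.normal(0, 0.5, 30))
    assert p_same > 0.01
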