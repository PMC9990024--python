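import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from sitqc import (
    CompetitivenessModel,
    SimulationConfig,
    bootstrap_fried,
    compare_arms,
    fit_beta_binomial,
    fried_index,
    induced_sterility,
    mixture_mean_hatch,
    pooled_hatch_rate,
)
from sitqc.competitiveness import (
    FriedDomainWarning,
    FriedInputs,
    FriedResult,
    FriedUndefinedError,
    per_cage_hatch_rate,
)
from sitqc.simulate import simulate_competition_experiment


class TestHatchRates:
    def test_pooled_is_egg_weighted(self):
        assert pooled_hatch_rate([100, 50], [40, 10]) == pytest.approx(50 / 150)
        assert pooled_hatch_rate([200], [75]) == 0.375
        assert pooled_hatch_rate([10, 10], [10, 10]) == 1.0

    def test_per_cage_is_unweighted(self):
        assert per_cage_hatch_rate([100, 50], [40, 10]) == pytest.approx(
            (0.4 + 0.2) / 2
        )

    def test_zero_eggs_rejected(self):
        with pytest.raises(ValueError):
            pooled_hatch_rate([0, 0], [0, 0])


class TestFriedIndex:
    def test_zero_numerator(self):
        assert fried_index(0.40, 0.40, 0.10) == 0.0

    def test_midpoint_gives_unity(self):
        assert fried_index(0.40, 0.25, 0.10) == pytest.approx(1.0)

    def test_mixture_built_ho_recovers_c(self):
        # Ho from the mixture identity at C = 2 -> index exactly 2
        ho = mixture_mean_hatch(2.0, 0.3766, 0.08)
        assert ho == pytest.approx(0.17887, abs=5e-6)
        assert fried_index(0.3766, ho, 0.08) == pytest.approx(2.0)

    def test_accepts_fried_inputs_container(self):
        inputs = FriedInputs(hn=0.40, ho=0.25, hs=0.10)
        assert fried_index(inputs) == pytest.approx(1.0)

    def test_undefined_when_ho_equals_hs(self):
        with pytest.raises(FriedUndefinedError):
            fried_index(0.4, 0.1, 0.1)

    def test_out_of_domain_warns(self):
        with pytest.warns(FriedDomainWarning):
            fried_index(0.4, 0.05, 0.10)

    def test_negative_when_competition_cage_outhatches_control(self):
        assert fried_index(0.30, 0.35, 0.10) < 0

    @settings(derandomize=True, max_examples=80)
    @given(
        c=st.floats(0.001, 20),
        hn=st.floats(0.05, 0.99),
        frac=st.floats(0.0, 0.9),
        k=st.floats(0.1, 10),
    )
    def test_round_trip_and_scale_invariance(self, c, hn, frac, k):
        """fried_index inverts the mixture mean exactly, for any N/S rescaling."""
        hs = hn * frac
        n, s = 50, 50
        ho = mixture_mean_hatch(c, hn, hs, n, s)
        assert fried_index(hn, ho, hs, n, s) == pytest.approx(c, rel=1e-9)
        # (N, S) -> (kN, kS) leaves the index unchanged
        n2, s2 = max(1, int(k * 40)), max(1, int(k * 40))
        ho2 = mixture_mean_hatch(c, hn, hs, n2, s2)
        assert fried_index(hn, ho2, hs, n2, s2) == pytest.approx(c, rel=1e-9)

    def test_strictly_decreasing_in_ho(self):
        hn, hs = 0.4, 0.05
        values = [fried_index(hn, ho, hs) for ho in np.linspace(0.06, 1.0, 50)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestInducedSterility:
    @pytest.mark.parametrize(
        "hn,ho,expected",
        [(0.3766, 0.3766, 0.0), (0.3766, 0.0, 100.0), (0.3766, 0.2209, 41.3436)],
    )
    def test_arithmetic(self, hn, ho, expected):
        assert induced_sterility(hn, ho) == pytest.approx(expected, abs=1e-3)

    def test_zero_hn_rejected(self):
        with pytest.raises(ValueError):
            induced_sterility(0.0, 0.1)

    @pytest.mark.parametrize("c", [0.0, 0.32, 1.16])
    def test_is_c_consistency_identity(self, c):
        """Under the mixture model IS = 100 * (C S / (N + C S)) * (1 - Hs/Hn)."""
        hn, hs, n, s = 0.3766, 0.0023, 50, 50
        ho = mixture_mean_hatch(c, hn, hs, n, s)
        expected = 100 * (c * s / (n + c * s)) * (1 - hs / hn)
        assert induced_sterility(hn, ho) == pytest.approx(expected, rel=1e-12)


class TestBootstrapFried:
    def test_single_cage_per_arm_degenerates_to_point(self, small_cages):
        one = small_cages.drop_duplicates("arm")
        res = bootstrap_fried(one, B=200, seed=1)["Ho"]
        assert res.C_mean == pytest.approx(res.C_point)
        assert res.C_se == 0.0
        assert res.n_undefined == 0

    def test_point_estimates_on_hand_table(self, small_cages):
        res = bootstrap_fried(small_cages, B=100, seed=1)["Ho"]
        # Hn = 0.4, Hs = 0.1, Ho = 0.25, N = S = 50 -> C = 1, IS = 37.5%
        assert res.C_point == pytest.approx(1.0)
        assert res.IS_point == pytest.approx(37.5)

    def test_seed_reproducibility_bitwise(self, small_cages):
        a = bootstrap_fried(small_cages, B=500, seed=42)["Ho"]
        b = bootstrap_fried(small_cages, B=500, seed=42)["Ho"]
        np.testing.assert_array_equal(a.C_resamples, b.C_resamples)
        np.testing.assert_array_equal(a.IS_resamples, b.IS_resamples)

    def test_missing_control_arm_rejected(self, small_cages):
        with pytest.raises(ValueError, match="Hs"):
            bootstrap_fried(small_cages[small_cages["arm"] != "Hs"], B=10, seed=1)

    def test_undefined_resamples_counted_not_dropped(self):
        # one Ho cage hatches below Hs: some resamples fall out of domain
        cages = pd.DataFrame(
            {
                "arm": ["Hn", "Hn", "Hs", "Hs", "Ho", "Ho"],
                "replicate": [1, 2, 1, 2, 1, 2],
                "n_fertile_males": [50, 50, 0, 0, 50, 50],
                "n_sterile_males": [0, 0, 50, 50, 50, 50],
                "n_females": [50] * 6,
                "eggs_total": [100, 100, 100, 100, 100, 100],
                "eggs_hatched": [40, 40, 20, 20, 5, 60],
            }
        )
        with pytest.warns(FriedDomainWarning):
            res = bootstrap_fried(cages, B=2000, seed=3)["Ho"]
        assert res.n_undefined > 0
        assert np.isfinite(res.C_mean)
        assert np.count_nonzero(np.isfinite(res.C_resamples)) == 2000 - res.n_undefined

    def test_parameter_recovery_at_study_scale(self):
        """4 cages x 50 females x Poisson(50) eggs recovers C = 1.16 within
        3 Monte-Carlo standard errors of the estimator's mean."""
        cfg = SimulationConfig(seed=101, c_true_by_arm={"Ho": 1.16},
                               hatch_sterile=0.0023)
        rng = np.random.default_rng(202)
        points = []
        for _ in range(50):
            cages = simulate_competition_experiment(cfg, rng)
            points.append(bootstrap_fried(cages, B=1, rng=rng)["Ho"].C_point)
        points = np.asarray(points)
        mc_se = points.std(ddof=1) / np.sqrt(len(points))
        assert abs(points.mean() - 1.16) < 3 * mc_se

    def test_per_cage_pooling_option(self, small_cages):
        res = bootstrap_fried(small_cages, B=100, seed=1, pooling="per_cage")["Ho"]
        assert res.C_point == pytest.approx(1.0)  # balanced cages: same answer
        with pytest.raises(ValueError, match="pooling"):
            bootstrap_fried(small_cages, B=10, seed=1, pooling="bogus")


class TestBetaBinomial:
    def test_single_cage_rejected(self):
        with pytest.raises(ValueError, match="2 cages"):
            fit_beta_binomial([100], [40])

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_binomial([100, 100], [0, 0])

    def test_rho_zero_likelihood_is_binomial(self):
        from scipy import stats

        n = np.array([120, 80, 100])
        k = np.array([50, 30, 41])
        from sitqc.competitiveness import _beta_binom_nll

        mu = k.sum() / n.sum()
        assert _beta_binom_nll(np.array([mu, 0.0]), k, n) == pytest.approx(
            -stats.binom.logpmf(k, n, mu).sum()
        )
        # and the beta-binomial converges to it as rho -> 0
        assert _beta_binom_nll(np.array([mu, 1e-8]), k, n) == pytest.approx(
            -stats.binom.logpmf(k, n, mu).sum(), rel=1e-4
        )

    def test_near_binomial_data_gives_small_rho(self):
        rng = np.random.default_rng(7)
        n = np.full(100, 500)
        k = rng.binomial(n, 0.38)
        fit = fit_beta_binomial(n, k)
        assert fit.converged
        assert fit.overdispersion < 0.02
        assert fit.mean_hatch == pytest.approx(0.38, abs=0.02)

    def test_parameter_recovery_with_overdispersion(self):
        """200 cages simulated at (mu, rho) = (0.38, 0.1): 3-SE recovery."""
        rng = np.random.default_rng(13)
        mu, rho = 0.38, 0.10
        a, b = mu * (1 - rho) / rho, (1 - mu) * (1 - rho) / rho
        n = rng.poisson(2500, size=200)
        k = rng.binomial(n, rng.beta(a, b, size=200))
        fit = fit_beta_binomial(n, k)
        assert fit.converged
        assert abs(fit.mean_hatch - mu) < 3 * fit.se_mean
        assert abs(fit.overdispersion - rho) < 3 * fit.se_overdispersion

    def test_oracle_against_r_style_grid(self):
        """Coarse 2-d likelihood grid never beats the optimiser."""
        from sitqc.competitiveness import _beta_binom_nll

        rng = np.random.default_rng(3)
        n = np.full(30, 400)
        k = rng.binomial(n, rng.beta(15, 25, size=30))
        fit = fit_beta_binomial(n, k)
        best_grid = min(
            _beta_binom_nll(np.array([m, r]), k, n)
            for m in np.linspace(0.2, 0.6, 41)
            for r in np.linspace(0.0, 0.3, 31)
        )
        assert -fit.log_likelihood <= best_grid + 1e-6


class TestCompareArms:
    def _fake_result(self, arm, values, B=None):
        values = np.asarray(values, dtype=float)
        B = B or len(values)
        return FriedResult(
            arm=arm, C_point=float(np.mean(values)), IS_point=0.0,
            C_resamples=values, IS_resamples=np.zeros_like(values),
            C_mean=float(np.mean(values)), C_se=float(np.std(values)),
            C_ci95=(0, 1), IS_mean=0.0, IS_se=0.0, IS_ci95=(0, 0),
            n_undefined=0, B=B,
        )

    def test_identical_resamples_share_letter(self):
        v = np.random.default_rng(1).normal(1.0, 0.1, 400)
        res = {"Ho": self._fake_result("Ho", v),
               "Ho_1_25": self._fake_result("Ho_1_25", v.copy())}
        out = compare_arms(res, metrics=("C",))
        _, letters = out["C"]
        assert letters["Ho"] == letters["Ho_1_25"]

    def test_separated_arms_distinct_letters(self):
        rng = np.random.default_rng(2)
        res = {
            "Ho": self._fake_result("Ho", rng.normal(1.2, 0.05, 400)),
            "Ho_1_25": self._fake_result("Ho_1_25", rng.normal(0.0, 0.05, 400)),
        }
        _, letters = compare_arms(res, metrics=("C",))["C"]
        assert not (set(letters["Ho"]) & set(letters["Ho_1_25"]))

    def test_overlapping_middle_gets_both_letters(self):
        rng = np.random.default_rng(3)
        res = {
            "Ho": self._fake_result("Ho", rng.normal(1.2, 0.08, 500)),
            "Ho_1_25": self._fake_result("Ho_1_25", rng.normal(1.05, 0.08, 500)),
            "Ho_2_25": self._fake_result("Ho_2_25", rng.normal(0.9, 0.08, 500)),
        }
        _, letters = compare_arms(res, metrics=("C",))["C"]
        assert letters["Ho"] == "a"
        assert letters["Ho_1_25"] == "ab"
        assert letters["Ho_2_25"] == "b"

    def test_all_undefined_rejected(self):
        bad = self._fake_result("Ho", np.full(100, np.nan))
        bad.n_undefined = 100
        good = self._fake_result("Ho_1_25", np.ones(100))
        with pytest.raises(ValueError, match="undefined"):
            compare_arms({"Ho": bad, "Ho_1_25": good})


def test_model_end_to_end_recovers_simulation_truth(config):
    cages = simulate_competition_experiment(config)
    results = CompetitivenessModel(cages).fit(B=3000, seed=7)
    assert set(results.fried) == {"Ho", "Ho_1_25", "Ho_2_25"}
    # unchilled sterile males out-compete chilled ones in the letters
    c_ho = results.fried["Ho"].C_point
    c_2 = results.fried["Ho_2_25"].C_point
    assert c_ho > c_2
    assert not (set(results.letters_C["Ho"]) & set(results.letters_C["Ho_2_25"]))
    hn = results.hatch_table.set_index("arm").loc["Hn", "hatch_pooled"]
    assert hn == pytest.approx(0.3766, abs=0.03)
    assert "Fried competitiveness" in results.summary()
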