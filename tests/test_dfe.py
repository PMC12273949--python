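"""Tests for the colony-sampling model, DFE construction, and comparisons."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from mabias.dfe import (
    DFEConfig,
    bias_fb_regression,
    build_dfe,
    class_fitness_tests,
    colony_sampling_weight,
    compare_dfe_batch,
    compare_dfe_fractions,
    subsample_dfe,
)


class TestColonySamplingWeight:
    def test_neutral_is_unity(self):
        for G in (1, 12, 27):
            assert colony_sampling_weight(0.0, G) == pytest.approx(1.0)

    def test_monotone_in_s(self):
        s = np.linspace(-0.5, 0.5, 41)
        r = colony_sampling_weight(s, 27)
        assert np.all(np.diff(r) > 0)
        assert np.all(r[s > 0] > 1) and np.all(r[s < 0] < 1)

    def test_lethal_s_rejected(self):
        with pytest.raises(ValueError):
            colony_sampling_weight(-1.0, 27)

    def test_matches_stochastic_colony_simulation(self):
        """Plug-in expectation vs. a fully stochastic Yule colony at G = 12.

        The population founded by one cell after T doubling times of a pure
        birth process is geometric with success probability 2^-(rate*T), so
        the colony can be simulated exactly without event-driven loops.  The
        deterministic expectation model tracks the stochastic mean to within
        a few percent (the Jensen gap of the ratio) at moderate |s|.
        """
        G, n_trials = 12, 400_000
        rng = np.random.default_rng(202)
        t = rng.choice(G, size=n_trials, p=2.0 ** np.arange(G) / (2.0**G - 1))
        T = G - t
        founders = (2**t - 1).astype(np.int64)
        n_w = np.where(
            founders > 0,
            rng.negative_binomial(np.maximum(founders, 1), 2.0 ** (-T)) + founders,
            0,
        )
        n_m0 = rng.geometric(2.0 ** (-T))
        f0 = (n_m0 / (n_m0 + n_w)).mean()
        for s in (-0.1, 0.1, 0.3):
            n_m = rng.geometric(2.0 ** (-(1 + s) * T))
            r_sim = (n_m / (n_m + n_w)).mean() / f0
            assert colony_sampling_weight(s, G) == pytest.approx(r_sim, rel=0.10)


class TestBuildDFE:
    def test_all_neutral(self):
        d = build_dfe([0.0] * 20, DFEConfig())
        assert (d.f_b, d.f_n, d.f_d) == (0.0, 1.0, 0.0)
        assert d.median_s == 0.0

    def test_fraction_partition(self, rng):
        s = rng.normal(-0.02, 0.1, 200)
        d = build_dfe(s, DFEConfig())
        assert d.f_b + d.f_n + d.f_d == pytest.approx(1.0, abs=1e-9)
        assert d.corrected_weights.sum() == pytest.approx(1.0)
        assert d.raw_counts.sum() == d.n_mutations == 200

    def test_correction_never_increases_fb(self, rng):
        # r(s) >= 1 exactly when s >= 0, so down-weighting beneficial
        # mutations can only lower the beneficial fraction
        for seed in range(5):
            s = np.random.default_rng(seed).normal(0.0, 0.1, 150)
            cfg = DFEConfig(apply_correction=True)
            raw = build_dfe(s, DFEConfig(apply_correction=False))
            corrected = build_dfe(s, cfg)
            assert corrected.f_b <= raw.f_b + 1e-12

    def test_uncorrected_fb_is_empirical_fraction(self, rng):
        s = rng.normal(0.0, 0.05, 300)
        d = build_dfe(s, DFEConfig(apply_correction=False, neutral_half_width=0.0, bin_width=0.05))
        assert d.f_b == pytest.approx((s > 0).mean())

    def test_correction_changes_weights_not_support(self, rng):
        s = rng.normal(-0.05, 0.1, 100)
        raw = build_dfe(s, DFEConfig(apply_correction=False))
        cor = build_dfe(s, DFEConfig(apply_correction=True))
        np.testing.assert_array_equal(raw.bin_edges, cor.bin_edges)
        np.testing.assert_array_equal(raw.raw_counts, cor.raw_counts)

    def test_neutral_zone_must_align_with_bins(self):
        with pytest.raises(ValueError):
            DFEConfig(bin_width=0.04, neutral_half_width=0.05)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_dfe([], DFEConfig())

    def test_lethal_assigned_to_most_deleterious_bin(self):
        d = build_dfe([-1.0, 0.0, 0.0], DFEConfig())
        assert d.raw_counts[0] == 1  # s = -1 sits in the lowest bin
        assert d.f_d > 0

    def test_environment_defaults(self):
        lb = DFEConfig.for_environment("LB")
        glu = DFEConfig.for_environment("glucose")
        assert lb.neutral_half_width == 0.05
        assert glu.neutral_half_width == 0.025


class TestCompareDFE:
    def test_identical_dfes(self, rng):
        s = rng.normal(0, 0.1, 100)
        a = build_dfe(s, DFEConfig(), strain_id="a")
        b = build_dfe(s, DFEConfig(), strain_id="b")
        comp = compare_dfe_fractions(a, b)
        assert comp.chisq_stat == pytest.approx(0.0, abs=1e-9)
        assert comp.p_raw == pytest.approx(1.0)

    def test_strongly_different_compositions(self):
        # (50, 25, 25) vs (10, 45, 45) out of 100: chi-squared p < 0.001
        cfg = DFEConfig(apply_correction=False)
        a = build_dfe(np.repeat([0.2, 0.0, -0.2], [50, 25, 25]), cfg, strain_id="a")
        b = build_dfe(np.repeat([0.2, 0.0, -0.2], [10, 45, 45]), cfg, strain_id="b")
        comp = compare_dfe_fractions(a, b)
        assert comp.p_raw < 0.001

    def test_benjamini_hochberg_adjustment(self):
        adjusted = multipletests([0.01, 0.02, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adjusted, [0.03, 0.03, 0.04])

    def test_batch_adjusted_p_not_below_raw(self, rng):
        dfes = [
            build_dfe(np.random.default_rng(k).normal(-0.02 * k, 0.08, 80), DFEConfig(), strain_id=f"s{k}")
            for k in range(4)
        ]
        table = compare_dfe_batch(dfes)
        assert len(table) == 6
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-12).all()


class TestSubsample:
    def test_full_sample_gives_zero_width_interval(self, rng):
        s = rng.normal(0, 0.1, 60)
        cfg = DFEConfig()
        res = subsample_dfe(s, 60, cfg, iterations=50, seed=3)
        full_fb = build_dfe(np.sort(s), cfg).f_b
        assert res["ci_low"] == res["ci_high"] == pytest.approx(full_fb)

    def test_interval_narrows_with_sample_size(self, rng):
        s = rng.normal(0, 0.1, 400)
        cfg = DFEConfig()
        widths = []
        for n in (50, 200, 390):
            res = subsample_dfe(s, n, cfg, iterations=100, seed=5)
            widths.append(res["ci_high"] - res["ci_low"])
        assert widths[0] > widths[1] > widths[2]

    def test_deterministic_under_fixed_seed(self, rng):
        s = rng.normal(0, 0.1, 100)
        a = subsample_dfe(s, 40, DFEConfig(), seed=11)
        b = subsample_dfe(s, 40, DFEConfig(), seed=11)
        np.testing.assert_array_equal(a["f_b_values"], b["f_b_values"])

    def test_oversampling_rejected(self):
        with pytest.raises(ValueError):
            subsample_dfe([0.0, 0.1], 3, DFEConfig())


class TestClassFitnessTests:
    def test_identical_groups_not_separated(self):
        vals = list(np.linspace(-0.1, 0.1, 20))
        df = pd.DataFrame({"group": ["x"] * 20 + ["y"] * 20, "s": vals + vals})
        out = class_fitness_tests(df)
        assert out["tests"]["p_raw"].iloc[0] == pytest.approx(1.0)
        assert out["letters"]["x"] == out["letters"]["y"]

    def test_transversions_right_shifted_power(self):
        # Ts ~ N(-0.05, 0.02) vs Tv ~ N(+0.02, 0.02), n = 100: the rank-sum
        # test should reject at alpha = 0.001 in essentially every replicate
        rejections = 0
        for seed in range(30):
            rng = np.random.default_rng(seed)
            df = pd.DataFrame(
                {
                    "group": ["Ts"] * 100 + ["Tv"] * 100,
                    "s": np.concatenate([rng.normal(-0.05, 0.02, 100), rng.normal(0.02, 0.02, 100)]),
                }
            )
            out = class_fitness_tests(df)
            rejections += out["tests"]["p_adjusted"].iloc[0] < 0.001
        assert rejections >= 30 * 0.99

    def test_three_group_letter_assignment(self):
        # A ~ B, A != C, B != C  ->  letters {a, a, b}
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "group": ["A"] * 50 + ["B"] * 50 + ["C"] * 50,
                "s": np.concatenate(
                    [rng.normal(0.0, 0.02, 50), rng.normal(0.0, 0.02, 50), rng.normal(0.3, 0.02, 50)]
                ),
            }
        )
        letters = class_fitness_tests(df)["letters"]
        assert letters["A"] == letters["B"]
        assert letters["C"] != letters["A"]

    def test_tiny_group_excluded_with_warning(self):
        df = pd.DataFrame({"group": ["a"] * 10 + ["b"] * 10 + ["tiny"], "s": np.arange(21) / 21})
        with pytest.warns(UserWarning):
            out = class_fitness_tests(df)
        assert "tiny" not in out["letters"]


class TestBiasFbRegression:
    def test_collinear_points(self):
        pts = [(0.1, 0.05), (0.5, 0.25), (0.9, 0.45)]
        res = bias_fb_regression(pts)
        assert res["r_squared"] == pytest.approx(1.0)
        assert res["slope"] == pytest.approx(0.5)

    def test_null_slope_p_uniform_under_permutation(self, rng):
        # with no relationship, the regression p-value is uniform: check via
        # a small permutation oracle
        x = np.linspace(0, 1, 7)
        pvals = [
            bias_fb_regression(list(zip(x, np.random.default_rng(k).normal(0.2, 0.05, 7))))["p_value"]
            for k in range(200)
        ]
        assert 0.02 < np.mean(np.asarray(pvals) < 0.05) < 0.10

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            bias_fb_regression([(0, 0), (1, 1)])


@given(st.lists(st.floats(-0.9, 0.9), min_size=1, max_size=60))
@settings(max_examples=40, deadline=None)
def test_dfe_fractions_always_partition(s_values):
    d = build_dfe(s_values, DFEConfig())
    assert 0 <= d.f_b <= 1 and 0 <= d.f_n <= 1 and 0 <= d.f_d <= 1
    assert d.f_b + d.f_n + d.f_d == pytest.approx(1.0, abs=1e-9)
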