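"""Calibration, rate conversion, normalization and gated group statistics."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from mnox.assay import (
    CalibrationCurve,
    absorbance_to_mnox,
    compact_letter_display,
    compare_groups,
    fit_standard_curve,
    gated_omnibus,
    normalize_to_control,
    oxidation_rate,
    two_group_test,
    _dunn_bonferroni,
)


class TestStandardCurve:
    def test_noiseless_points_fit_exactly(self):
        conc = np.array([0.0, 10.0, 25.0, 50.0, 100.0])
        absb = 0.002 * conc + 0.01
        curve = fit_standard_curve(conc, absb)
        assert curve.slope == pytest.approx(0.002, abs=1e-12)
        assert curve.intercept == pytest.approx(0.01, abs=1e-12)
        assert curve.r_squared == pytest.approx(1.0)
        assert curve.n_standards == 5

    def test_two_points_have_unit_r_squared(self):
        curve = fit_standard_curve([0.0, 50.0], [0.01, 0.11])
        assert curve.r_squared == pytest.approx(1.0)

    def test_identical_concentrations_rejected(self):
        with pytest.raises(ValueError, match="distinct"):
            fit_standard_curve([10.0, 10.0, 10.0], [0.1, 0.2, 0.3])

    def test_low_r_squared_warns_not_fails(self):
        with pytest.warns(UserWarning, match="below floor"):
            curve = fit_standard_curve([0, 10, 20, 30], [0.0, 0.5, 0.1, 0.6])
        assert curve.n_standards == 4

    def test_noisy_estimate_within_three_standard_errors(self, rng):
        from scipy import stats

        import warnings

        conc = np.tile(np.array([0.0, 5, 10, 25, 50, 100]), 30)
        absb = 0.01 + 0.002 * conc + rng.normal(0, 0.01, conc.size)
        fit = stats.linregress(conc, absb)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)  # r^2 floor is advisory
            curve = fit_standard_curve(conc, absb)
        assert abs(curve.slope - 0.002) < 3 * fit.stderr


class TestAbsorbanceInversion:
    curve = CalibrationCurve(slope=0.002, intercept=0.01, r_squared=1.0, n_standards=5)

    def test_intercept_maps_to_zero(self):
        conc, clamped = absorbance_to_mnox(0.01, self.curve)
        assert conc == 0.0 and not clamped

    def test_algebraic_inverse(self, rng):
        for _ in range(50):
            true = float(rng.uniform(0, 500))
            dil = float(rng.uniform(1, 20))
            absb = self.curve.intercept + self.curve.slope * (true / dil)
            conc, clamped = absorbance_to_mnox(absb, self.curve, dilution_factor=dil)
            assert conc == pytest.approx(true, rel=1e-9)
            assert not clamped

    def test_negative_clamped_and_flagged(self):
        conc, clamped = absorbance_to_mnox(0.0, self.curve)
        assert conc == 0.0 and clamped

    def test_non_positive_slope_rejected(self):
        bad = CalibrationCurve(slope=-0.002, intercept=0.0, r_squared=1.0, n_standards=2)
        with pytest.raises(ValueError, match="slope"):
            absorbance_to_mnox(0.5, bad)


class TestOxidationRate:
    def test_unit_case(self):
        assert oxidation_rate(100.0, 1.0, 1.0) == 100.0

    def test_zero_concentration(self):
        assert oxidation_rate(0.0, 5.0, 2.0) == 0.0

    def test_linearity_in_concentration(self, rng):
        conc = rng.uniform(1, 500, size=20)
        assert np.allclose(
            oxidation_rate(2 * conc, 3.0, 4.0), 2 * oxidation_rate(conc, 3.0, 4.0)
        )

    def test_invalid_mass_or_time_rejected(self):
        with pytest.raises(ValueError):
            oxidation_rate(10.0, 0.0, 1.0)
        with pytest.raises(ValueError):
            oxidation_rate(10.0, 1.0, -1.0)


class TestNormalizeToControl:
    def test_control_normalizes_to_mean_100(self):
        control = [90.0, 100.0, 110.0]
        assert np.mean(normalize_to_control(control, control)) == pytest.approx(100.0)

    def test_zero_treated_gives_zero_percent(self):
        assert normalize_to_control(0.0, [50.0, 60.0]) == 0.0

    def test_matches_direct_formula(self, rng):
        treated = rng.uniform(0, 100, size=12)
        control = rng.uniform(50, 150, size=4)
        assert np.allclose(
            normalize_to_control(treated, control), 100 * treated / control.mean()
        )

    def test_non_positive_control_rejected(self):
        with pytest.raises(ValueError, match="control mean"):
            normalize_to_control([1.0], [0.0, 0.0])


class TestTwoGroupTest:
    def test_identical_groups_p_one(self):
        stat, p = two_group_test([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert (stat, p) == (0.0, 1.0)

    def test_matches_pooled_variance_formula(self):
        a = np.array([4.0, 5.0, 6.0, 7.0])
        b = np.array([6.0, 7.0, 8.0, 11.0])
        stat, p = two_group_test(a, b, equal_var=True)
        sp2 = (a.var(ddof=1) * 3 + b.var(ddof=1) * 3) / 6
        expected_t = (a.mean() - b.mean()) / math.sqrt(sp2 * (1 / 4 + 1 / 4))
        assert stat == pytest.approx(expected_t, rel=1e-12)

    def test_large_shift_significant(self, rng):
        a = rng.normal(0, 1, 4)
        stat, p = two_group_test(a, a + 100.0)
        assert p < 0.05

    def test_small_groups_rejected(self):
        with pytest.raises(ValueError):
            two_group_test([1.0], [2.0, 3.0])


class TestCompactLetterDisplay:
    @staticmethod
    def pmat(labels, sig_pairs, alpha=0.05):
        labels = list(labels)
        p = pd.DataFrame(1.0, index=labels, columns=labels)
        for a, b in sig_pairs:
            p.loc[a, b] = p.loc[b, a] = alpha / 10
        return p

    def test_no_significant_pairs_single_letter(self):
        letters = compact_letter_display(self.pmat("abc", []))
        assert set(letters.values()) == {"a"}

    def test_all_pairs_significant_distinct_letters(self):
        labels = list("wxyz")
        letters = compact_letter_display(
            self.pmat(labels, itertools.combinations(labels, 2))
        )
        assert len(set(letters.values())) == 4
        assert all(len(v) == 1 for v in letters.values())

    def test_asymmetric_matrix_rejected(self):
        p = self.pmat("ab", [])
        p.iloc[0, 1] = 0.01
        with pytest.raises(ValueError, match="symmetric"):
            compact_letter_display(p)

    def test_sharing_relation_equals_nonsignificance(self, rng):
        """Verification oracle: for random p matrices, two groups share a
        letter iff their adjusted p >= alpha."""
        for trial in range(200):
            k = int(rng.integers(2, 7))
            labels = [f"g{i}" for i in range(k)]
            vals = rng.uniform(0, 1, size=(k, k))
            p = pd.DataFrame((vals + vals.T) / 2, index=labels, columns=labels)
            np.fill_diagonal(p.values, 1.0)
            letters = compact_letter_display(p, alpha=0.3)
            for a, b in itertools.combinations(labels, 2):
                shares = bool(set(letters[a]) & set(letters[b]))
                assert shares == (p.loc[a, b] >= 0.3), (trial, a, b, p)


class TestDunnBonferroni:
    def test_matches_hand_computed_rank_arithmetic(self):
        """Frozen oracle: mean ranks 3.25 / 5.75 / 10.5 on pooled ranks of
        12 untied values, z = Δr̄ / sqrt((N(N+1)/12)(1/4+1/4)), two-sided
        normal p × 3 comparisons."""
        groups = {
            "a": np.array([1.0, 2.0, 3.0, 4.0]),
            "b": np.array([2.5, 3.5, 4.5, 5.5]),
            "c": np.array([10.0, 11.0, 12.0, 13.0]),
        }
        p = _dunn_bonferroni(groups)
        assert p.loc["a", "b"] == pytest.approx(0.980399, abs=1e-6)
        assert p.loc["a", "c"] == pytest.approx(0.013379, abs=1e-6)
        assert p.loc["b", "c"] == pytest.approx(0.187343, abs=1e-6)
        assert np.allclose(p.values, p.values.T)

    def test_tie_correction_reduces_variance(self):
        tied = {
            "a": np.array([1.0, 1.0, 2.0, 2.0]),
            "b": np.array([1.0, 2.0, 2.0, 3.0]),
            "c": np.array([5.0, 6.0, 7.0, 8.0]),
        }
        p = _dunn_bonferroni(tied)
        assert (p.values <= 1).all() and (p.values >= 0).all()


class TestCompareGroups:
    def test_identical_groups_share_one_letter(self):
        g = {"a": [1.0, 1.0, 1.0], "b": [1.0, 1.0, 1.0], "c": [1.0, 1.0, 1.0]}
        res = compare_groups(g)
        assert res.omnibus_p == pytest.approx(1.0)
        assert set(res.letters.values()) == {"a"}

    def test_separated_group_gets_distinct_letter(self):
        g = {
            "t7": [1.0, 2.0, 3.0],
            "t14": [1.0, 2.0, 3.0],
            "t21": [100.0, 101.0, 102.0],
        }
        res = compare_groups(g)
        assert res.gate == "homogeneous"
        assert res.omnibus == "anova"
        # textbook one-way ANOVA F for this instance
        data = [np.array(v) for v in g.values()]
        grand = np.concatenate(data).mean()
        ss_between = sum(len(d) * (d.mean() - grand) ** 2 for d in data)
        ss_within = sum(((d - d.mean()) ** 2).sum() for d in data)
        f_expected = (ss_between / 2) / (ss_within / 6)
        assert res.omnibus_statistic == pytest.approx(f_expected, rel=1e-10)
        assert not (set(res.letters["t21"]) & set(res.letters["t7"]))
        assert set(res.letters["t7"]) & set(res.letters["t14"])

    def test_gate_selects_anova_iff_homogeneous(self, rng):
        for _ in range(50):
            if rng.random() < 0.5:
                g = {f"g{i}": rng.normal(0, 1, 5) for i in range(3)}
            else:
                g = {
                    "g0": rng.normal(0, 0.01, 5),
                    "g1": rng.normal(0, 10, 5),
                    "g2": rng.normal(0, 0.01, 5),
                }
            res = compare_groups(g)
            assert (res.omnibus == "anova") == (res.gate_p >= res.alpha)
            assert (res.posthoc_test == "tukey-kramer") == (res.omnibus == "anova")

    def test_gated_omnibus_consistent_with_compare_groups(self, rng):
        g = {f"g{i}": rng.normal(0, 1, 4) for i in range(4)}
        gate, gstat, gp, omnibus, stat, p = gated_omnibus(g)
        res = compare_groups(g)
        assert (gate, omnibus) == (res.gate, res.omnibus)
        assert p == pytest.approx(res.omnibus_p)

    def test_bartlett_gate_option(self, rng):
        g = {f"g{i}": rng.normal(0, 1, 5) for i in range(3)}
        res = compare_groups(g, gate_test="bartlett")
        assert res.gate_test == "bartlett"

    def test_small_group_rejected(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            compare_groups({"a": [1.0], "b": [1.0, 2.0]})

    def test_posthoc_matrix_symmetric_with_unit_diagonal(self, rng):
        g = {f"g{i}": rng.normal(i, 1, 4) for i in range(4)}
        res = compare_groups(g)
        p = res.posthoc_p
        assert np.allclose(p.values, p.values.T)
        assert np.allclose(np.diag(p.values), 1.0)
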