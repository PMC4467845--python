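import math

import numpy as np
import pytest
from scipy import stats as sps

from seadose import ValidationError, oneway_anova, studentized_range_q, tukey_hsd


def brute_force_anova(groups):
    """Direct evaluation of the defining sums of squares."""
    all_vals = [v for vals in groups.values() for v in vals]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(v) * (sum(v) / len(v) - grand) ** 2 for v in groups.values())
    ssw = sum(
        sum((x - sum(v) / len(v)) ** 2 for x in v) for v in groups.values()
    )
    dfb, dfw = len(groups) - 1, len(all_vals) - len(groups)
    return (ssb / dfb) / (ssw / dfw), dfb, dfw


class TestAnova:
    def test_hand_computed_example(self):
        groups = {"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]}
        res = oneway_anova(groups)
        assert res.f_statistic == pytest.approx(3.0)
        assert (res.df_between, res.df_within) == (2, 6)

    def test_equal_means_give_zero_f(self):
        res = oneway_anova({"a": [1, 2, 3], "b": [0, 2, 4]})
        assert res.f_statistic == pytest.approx(0.0)

    def test_matches_brute_force_oracle_on_random_data(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            k = rng.integers(2, 5)
            groups = {
                f"g{i}": list(rng.normal(rng.uniform(-2, 2), 1.0, rng.integers(2, 8)))
                for i in range(k)
            }
            res = oneway_anova(groups)
            f_ref, dfb, dfw = brute_force_anova(groups)
            assert res.f_statistic == pytest.approx(f_ref, rel=1e-9)
            assert (res.df_between, res.df_within) == (dfb, dfw)

    def test_matches_scipy_f_oneway(self):
        rng = np.random.default_rng(3)
        groups = {f"g{i}": rng.normal(i, 1.0, 6) for i in range(3)}
        res = oneway_anova(groups)
        ref = sps.f_oneway(*groups.values())
        assert res.f_statistic == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, rel=1e-9)

    def test_shift_and_scale_invariance_of_f(self):
        rng = np.random.default_rng(5)
        groups = {f"g{i}": rng.normal(i, 1.0, 5) for i in range(3)}
        f0 = oneway_anova(groups).f_statistic
        shifted = {k: [x + 17.3 for x in v] for k, v in groups.items()}
        scaled = {k: [4.2 * x for x in v] for k, v in groups.items()}
        assert oneway_anova(shifted).f_statistic == pytest.approx(f0, rel=1e-9)
        assert oneway_anova(scaled).f_statistic == pytest.approx(f0, rel=1e-9)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValidationError):
            oneway_anova({"a": [1, 2, 3]})
        with pytest.raises(ValidationError):
            oneway_anova({"a": [1, 2], "b": [3]})
        with pytest.raises(ValidationError):
            oneway_anova({"a": [1.0, 1.0], "b": [1.0, 1.0]})


class TestStudentizedRange:
    @pytest.mark.parametrize("alpha", [0.05, 0.01])
    @pytest.mark.parametrize("k", [2, 3, 5, 10])
    @pytest.mark.parametrize("df", [2, 6, 13, 22, 35, 90, 500])
    def test_table_with_interpolation_matches_distribution(self, alpha, k, df):
        q = studentized_range_q(alpha, k, df)
        ref = sps.studentized_range.ppf(1 - alpha, k, df)
        assert q == pytest.approx(ref, rel=5e-3)

    def test_unsupported_alpha_rejected(self):
        with pytest.raises(ValidationError):
            studentized_range_q(0.10, 3, 6)


class TestTukey:
    def test_identical_groups_not_significant(self):
        res = tukey_hsd({"a": [2.0, 2.1, 1.9], "b": [2.0, 2.1, 1.9], "c": [2.0, 2.1, 1.9]})
        assert not any(c.significant for c in res.pairwise)

    def test_well_separated_groups_all_significant(self):
        groups = {
            "a": [0.0, 0.1, -0.1],
            "b": [10.0, 10.1, 9.9],
            "c": [20.0, 20.1, 19.9],
        }
        res = tukey_hsd(groups, alpha=0.05)
        # MS_within = 0.01, n = 3: critical = q(0.05;3,6) * sqrt(0.01/3) ~ 0.25
        assert res.ms_within == pytest.approx(0.01)
        assert res.pairwise[0].critical_difference == pytest.approx(
            4.3392 * math.sqrt(0.01 / 3), rel=1e-3
        )
        assert all(c.significant for c in res.pairwise)

    def test_flags_agree_with_scipy_tukey(self):
        rng = np.random.default_rng(19)
        for _ in range(20):
            groups = {
                f"g{i}": rng.normal(rng.uniform(0, 2.5), 1.0, 6) for i in range(3)
            }
            ours = tukey_hsd(groups, alpha=0.05)
            ref = sps.tukey_hsd(*groups.values())
            for comp in ours.pairwise:
                i = int(comp.group_a[1]), int(comp.group_b[1])
                assert comp.significant == (ref.pvalue[i[0], i[1]] < 0.05)


class TestSurveySignificance:
    def test_ra226_varies_significantly_across_locations(self, survey_activity):
        groups = {}
        for rec in survey_activity:
            if rec.matrix == "fish":
                groups.setdefault(rec.location, []).append(rec.activities["Ra-226"].value)
        assert oneway_anova(groups).p_value < 0.05

    def test_th232_varies_significantly_across_locations(self, survey_activity):
        groups = {}
        for rec in survey_activity:
            if rec.matrix == "fish":
                groups.setdefault(rec.location, []).append(rec.activities["Th-232"].value)
        assert oneway_anova(groups).p_value < 0.05

    def test_k40_exceeds_other_nuclides_strongly(self, survey_activity):
        # K-40 activity dwarfs Ra-226 in fish: nuclide effect stronger than
        # the Ra-226 location effect (smaller p-value).
        by_loc_ra, k_vs_ra = {}, {"Ra-226": [], "K-40": []}
        for rec in survey_activity:
            if rec.matrix != "fish":
                continue
            by_loc_ra.setdefault(rec.location, []).append(rec.activities["Ra-226"].value)
            for chain in ("Ra-226", "K-40"):
                k_vs_ra[chain].append(rec.activities[chain].value)
        p_nuclide = oneway_anova(k_vs_ra).p_value
        p_location = oneway_anova(by_loc_ra).p_value
        assert p_nuclide < 0.001
        assert p_nuclide < p_location
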