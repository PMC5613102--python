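"""Step-wise conversion statistic, SFA percentages and group statistics."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

from vlcfa.conversion_stats import (
    EmptyProfileError,
    PeakTable,
    anova_tukey_cld,
    compact_letter_display,
    compare_groups,
    sfa_percentages,
    stepwise_conversions,
)
from vlcfa.fa_model import build_cascade, parse_fa


def make_table(substrate, areas, treatment="transgenic", sample_id="s1"):
    cascade = build_cascade(
        parse_fa(substrate), parse_fa(substrate).carbons + 2 * (len(areas) - 1)
    )
    return PeakTable(sample_id, treatment, dict(zip(cascade.members, areas))), cascade


class TestStepwiseConversions:
    @pytest.mark.parametrize(
        "areas, expected",
        [
            ([100, 0, 0], [0.0, None]),          # no products at all
            ([0, 50, 0], [100.0, 0.0]),          # substrate fully consumed
            ([60, 30, 10], [40.0, 25.0]),        # hand-evaluated formula
        ],
    )
    def test_reference_values(self, areas, expected):
        table, cascade = make_table("18:4n-3", areas)
        res = stepwise_conversions(table, cascade)
        got = [None if r.not_detected else r.conversion for r in res]
        for g, e in zip(got, expected):
            if e is None:
                assert g is None
            else:
                assert g == pytest.approx(e, abs=1e-12)

    def test_undetected_tail_is_nd(self):
        table, cascade = make_table("18:4n-3", [100, 50, 0, 0])
        res = stepwise_conversions(table, cascade)
        assert res[1].conversion == 0.0
        assert res[2].not_detected and res[2].conversion is None

    def test_zero_substrate_with_product_is_100(self):
        table, cascade = make_table("18:4n-3", [100, 0, 10])
        res = stepwise_conversions(table, cascade)
        # step 2: substrate (first product) absent, downstream present
        assert res[1].conversion == pytest.approx(100.0)

    def test_missing_members_warn_and_count_as_zero(self):
        cascade = build_cascade(parse_fa("18:4n-3"), 22)
        table = PeakTable("s1", "t", {cascade.members[0]: 80.0, cascade.members[1]: 20.0})
        with pytest.warns(UserWarning, match="22:4n-3"):
            res = stepwise_conversions(table, cascade)
        assert res[0].conversion == pytest.approx(20.0)
        assert res[1].conversion == pytest.approx(0.0)

    def test_lod_zeroes_small_areas(self):
        table, cascade = make_table("18:4n-3", [100, 0.5, 0.2])
        res = stepwise_conversions(table, cascade, lod=1.0)
        assert res[0].conversion == pytest.approx(0.0)
        assert res[1].not_detected

    def test_negative_area_rejected(self):
        cascade = build_cascade(parse_fa("18:4n-3"), 20)
        with pytest.raises(ValueError, match="negative"):
            PeakTable("s1", "t", {cascade.members[0]: -1.0})

    def test_single_member_cascade_rejected(self):
        table, _ = make_table("18:4n-3", [100])
        with pytest.raises(ValueError):
            stepwise_conversions(table, build_cascade(parse_fa("18:4n-3"), 18))

    @given(
        st.lists(st.floats(0, 1e6), min_size=3, max_size=9),
        st.floats(1e-3, 1e3),
    )
    def test_bounded_and_scale_invariant(self, areas, scale):
        table, cascade = make_table("18:4n-3", areas)
        scaled, _ = make_table("18:4n-3", [a * scale for a in areas])
        res = stepwise_conversions(table, cascade)
        res_scaled = stepwise_conversions(scaled, cascade)
        for r, rs in zip(res, res_scaled):
            if r.conversion is not None:
                assert 0.0 <= r.conversion <= 100.0
                assert rs.conversion == pytest.approx(r.conversion, rel=1e-9, abs=1e-9)
            else:
                assert rs.not_detected


class TestSfaPercentages:
    def test_single_qualifying_fa_is_100(self):
        t = PeakTable("s", "c", {parse_fa("26:0"): 5.0, parse_fa("16:0"): 99.0})
        prof = sfa_percentages(t)
        assert prof.percents == {parse_fa("26:0"): 100.0}

    def test_direct_normalization(self):
        t = PeakTable(
            "s", "c",
            {parse_fa("24:0"): 2.0, parse_fa("26:0"): 46.0, parse_fa("28:0"): 2.0},
        )
        prof = sfa_percentages(t)
        assert prof.percents[parse_fa("24:0")] == pytest.approx(4.0)
        assert prof.percents[parse_fa("26:0")] == pytest.approx(92.0)
        assert prof.percents[parse_fa("28:0")] == pytest.approx(4.0)

    def test_unsaturated_and_short_chains_excluded(self):
        t = PeakTable(
            "s", "c",
            {parse_fa("24:0"): 10.0, parse_fa("22:0"): 50.0, parse_fa("24:5n-3"): 50.0},
        )
        prof = sfa_percentages(t)
        assert list(prof.percents) == [parse_fa("24:0")]

    @given(st.lists(st.floats(0.01, 1e4), min_size=1, max_size=6))
    def test_percent_conservation(self, areas):
        fas = [parse_fa(f"{c}:0") for c in range(24, 24 + 2 * len(areas), 2)]
        prof = sfa_percentages(PeakTable("s", "c", dict(zip(fas, areas))))
        assert sum(prof.percents.values()) == pytest.approx(100.0, abs=1e-9)

    def test_empty_profile_signal(self):
        t = PeakTable("s", "c", {parse_fa("16:0"): 10.0})
        with pytest.raises(EmptyProfileError):
            sfa_percentages(t)
        t0 = PeakTable("s", "c", {parse_fa("26:0"): 0.0})
        with pytest.raises(EmptyProfileError):
            sfa_percentages(t0)


def random_group_data(rng, n_groups=3, n=4, spread=1.0):
    means = rng.uniform(0, 10, size=n_groups)
    return {
        f"g{i}": means[i] + rng.normal(0, spread, size=n) for i in range(n_groups)
    }


class TestGroupComparison:
    def test_identical_groups_share_letter(self, rng):
        base = np.array([5.0, 5.1, 4.9, 5.0])
        vc = anova_tukey_cld({"control": base, "transgenic": base + 1e-3})
        assert vc.letters["control"] == vc.letters["transgenic"]

    def test_separated_groups_distinct_letters(self):
        vc = anova_tukey_cld(
            {
                "lo": np.array([1.0, 0.9, 1.1]),
                "hi": np.array([100.0, 100.1, 99.9]),
            }
        )
        assert set(vc.letters["lo"]) & set(vc.letters["hi"]) == set()
        assert vc.anova_p < 1e-6

    def test_tukey_matches_independent_scipy_route(self, rng):
        for _ in range(20):
            data = random_group_data(rng, n_groups=4, n=5, spread=1.5)
            vc = anova_tukey_cld(data, alpha=0.05)
            groups = list(data)
            ref = sps.tukey_hsd(*[data[g] for g in groups])
            for i, g1 in enumerate(groups):
                for j, g2 in enumerate(groups):
                    if i < j:
                        ours = vc.tukey_p[tuple(sorted((g1, g2)))]
                        assert ours == pytest.approx(ref.pvalue[i, j], abs=2e-3)

    def test_letters_agree_with_pairwise_decisions(self, rng):
        for _ in range(30):
            spread = rng.uniform(0.2, 4.0)
            data = random_group_data(rng, n_groups=rng.integers(2, 6), n=4, spread=spread)
            vc = anova_tukey_cld(data, alpha=0.05)
            for g1 in data:
                for g2 in data:
                    if g1 >= g2:
                        continue
                    shares = bool(set(vc.letters[g1]) & set(vc.letters[g2]))
                    p = vc.tukey_p[tuple(sorted((g1, g2)))]
                    assert shares == (p > 0.05)

    def test_singleton_group_rejected_by_name(self):
        with pytest.raises(ValueError, match="lonely"):
            anova_tukey_cld({"ok": np.array([1.0, 2.0]), "lonely": np.array([1.0])})

    def test_compare_groups_over_profiles(self, rng):
        from vlcfa.conversion_stats import SFAProfile

        fa = parse_fa("28:0")
        fb = parse_fa("26:0")
        profiles = []
        for t, boost in [("control", 1.0), ("elovl4a", 4.0)]:
            for i in range(4):
                a, b = 10.0 * boost + rng.normal(0, 0.2), 90.0 + rng.normal(0, 0.2)
                total = a + b
                profiles.append(
                    SFAProfile(f"{t}_{i}", t, {fa: 100 * a / total, fb: 100 * b / total})
                )
        cmp = compare_groups(profiles, alpha=0.05)
        letters = cmp.variables[fa].letters
        assert letters["control"] != letters["elovl4a"]
        df = cmp.to_frame()
        assert set(df.columns) >= {"fatty_acid", "group", "mean", "se", "letter"}


class TestCompactLetterDisplay:
    def test_no_differences_single_letter(self):
        letters = compact_letter_display(["a", "b", "c"], set())
        assert len(set(letters.values())) == 1

    def test_chain_pattern(self):
        # lo differs from hi; mid differs from neither
        letters = compact_letter_display(
            ["hi", "mid", "lo"],
            {("hi", "lo")},
            means={"hi": 10.0, "mid": 5.0, "lo": 1.0},
        )
        assert set(letters["hi"]) & set(letters["lo"]) == set()
        assert set(letters["mid"]) & set(letters["hi"])
        assert set(letters["mid"]) & set(letters["lo"])

    def test_all_pairwise_different(self):
        sig = {("a", "b"), ("a", "c"), ("b", "c")}
        letters = compact_letter_display(["a", "b", "c"], sig, means={"a": 3, "b": 2, "c": 1})
        assert len({frozenset(v) for v in letters.values()}) == 3
        for g1 in "abc":
            for g2 in "abc":
                if g1 < g2:
                    assert not set(letters[g1]) & set(letters[g2])
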