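import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from gelheterosis.differential import (
    max_fold_change,
    one_way_anova,
    same_trend,
    select_inbred_differential,
    select_triad_differential,
)
from gelheterosis.errors import DegenerateVarianceError, DomainError
from gelheterosis.heterosis import TriadDesign
from gelheterosis.normalize import normalize_total_ppm
from gelheterosis.simulate import SyntheticSpec, generate_stage_course, generate_triads


def anova_by_hand(groups):
    """Independent brute-force sums-of-squares oracle."""
    allv = np.concatenate([np.asarray(g, float) for g in groups])
    grand = allv.mean()
    ssb = sum(len(g) * (np.mean(g) - grand) ** 2 for g in groups)
    ssw = sum(np.sum((np.asarray(g) - np.mean(g)) ** 2) for g in groups)
    dfb, dfw = len(groups) - 1, len(allv) - len(groups)
    f = (ssb / dfb) / (ssw / dfw)
    return f, stats.f.sf(f, dfb, dfw)


class TestOneWayAnova:
    def test_identical_groups_give_f_zero_p_one(self):
        r = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert r.f_stat == 0.0 and r.p_value == 1.0

    def test_known_instance_matches_sums_of_squares_oracle(self):
        groups = [[1, 2, 3], [2, 3, 4], [6, 7, 8]]
        r = one_way_anova(groups)
        assert r.f_stat == pytest.approx(21.0)
        assert (r.df_between, r.df_within) == (2, 6)
        f, p = anova_by_hand(groups)
        assert r.f_stat == pytest.approx(f) and r.p_value == pytest.approx(p)

    @given(
        st.lists(st.floats(1, 100), min_size=3, max_size=6),
        st.lists(st.floats(1, 100), min_size=3, max_size=6),
    )
    @settings(max_examples=50, deadline=None)
    def test_two_group_f_equals_pooled_t_squared(self, a, b):
        if np.std(a) == 0 and np.std(b) == 0:
            return
        r = one_way_anova([a, b])
        t = stats.ttest_ind(a, b, equal_var=True)
        assert r.f_stat == pytest.approx(t.statistic**2, rel=1e-9)
        assert r.p_value == pytest.approx(t.pvalue, rel=1e-9)

    def test_degenerate_variance_with_different_means_raises(self):
        with pytest.raises(DegenerateVarianceError):
            one_way_anova([[1, 1, 1], [2, 2, 2]])

    def test_fully_constant_data_is_no_evidence(self):
        r = one_way_anova([[5, 5], [5, 5], [5, 5]])
        assert r.f_stat == 0.0 and r.p_value == 1.0

    def test_requires_two_groups_of_two(self):
        with pytest.raises(DomainError):
            one_way_anova([[1, 2, 3]])
        with pytest.raises(DomainError):
            one_way_anova([[1, 2], [3]])


class TestMaxFoldChange:
    @pytest.mark.parametrize(
        "means,expected", [([10, 10, 10], 1.0), ([5, 20], 4.0), ([2, 3, 12], 6.0)]
    )
    def test_examples(self, means, expected):
        assert max_fold_change(means) == pytest.approx(expected)

    @given(st.lists(st.floats(0.01, 1e4), min_size=2, max_size=8),
           st.floats(0.1, 10))
    @settings(max_examples=100, deadline=None)
    def test_at_least_one_and_scale_and_permutation_invariant(self, means, c):
        f = max_fold_change(means)
        assert f >= 1.0
        assert max_fold_change([c * m for m in means]) == pytest.approx(f, rel=1e-9)
        assert max_fold_change(sorted(means)) == pytest.approx(f, rel=1e-9)

    def test_nonpositive_mean_rejected(self):
        with pytest.raises(DomainError):
            max_fold_change([1.0, 0.0])


class TestSameTrend:
    def test_all_increasing_replicates_agree(self):
        assert same_trend([[1, 2, 3, 4], [2, 3, 4, 5], [1.5, 2, 2.5, 3]], 0.02)

    def test_one_reversing_replicate_breaks_agreement(self):
        assert not same_trend([[1, 2, 3, 4], [2, 3, 4, 5], [1.5, 1.4, 2.5, 3]], 0.02)

    def test_near_constant_profiles_are_flat_hence_agree(self):
        base = np.array([100.0, 100.5, 99.8, 100.2])  # within 2% of constant
        assert same_trend([base, base * 1.001, base[::-1]], 0.02)

    def test_flat_sign_matches_enumeration_oracle(self):
        # every up/flat/down combination over 3 stage transitions, 2 replicates
        eps = 0.05
        steps = {1: 1.5, 0: 1.0, -1: 1 / 1.5}
        for sa in itertools.product([-1, 0, 1], repeat=3):
            for sb in itertools.product([-1, 0, 1], repeat=3):
                prof = lambda s: np.cumprod([100.0] + [steps[x] for x in s])
                expected = sa == sb
                assert same_trend([prof(sa), prof(sb)], eps) == expected

    def test_single_stage_rejected(self):
        with pytest.raises(DomainError):
            same_trend([[1.0], [1.0]], 0.02)


class TestInbredScreen:
    def test_recovers_planted_spots_at_low_noise(self):
        spec = SyntheticSpec(
            n_spots_per_class={"changing": 10, "null": 90},
            cv=0.05, seed=42, stages=("D6", "D8", "D10", "D12"),
        )
        table, labels = generate_stage_course(spec)
        norm = normalize_total_ppm(table)
        calls = select_inbred_differential(norm, "L1", list(spec.stages))
        passed = {c.spot_id for c in calls if c.passed}
        planted = set(labels[labels.planted_class == "changing"].spot_id)
        assert passed == planted

    def test_constant_spots_never_pass(self):
        spec = SyntheticSpec(
            n_spots_per_class={"null": 20}, cv=0.0, stages=("D6", "D8"), seed=1
        )
        table, _ = generate_stage_course(spec)
        calls = select_inbred_differential(table, "L1", ["D6", "D8"])
        assert not any(c.passed for c in calls)

    def test_exact_threshold_fold_fails_strict_inequality(self):
        # noiseless monotone spot at exactly 1.5-fold, plus within-stage jitter
        # so the ANOVA itself is defined
        import pandas as pd

        rows = []
        for s, stage in enumerate(["D6", "D8", "D10"]):
            mean = 100.0 * 1.5 ** (s / 2)
            for rep, d in zip((1, 2, 3), (-1.0, 0.0, 1.0)):
                rows.append(("s1", "L1", stage, rep, mean + d))
        table = pd.DataFrame(
            rows, columns=["spot_id", "genotype", "stage", "replicate", "intensity"]
        )
        calls = select_inbred_differential(table, "L1", ["D6", "D8", "D10"])
        (call,) = calls
        assert call.max_fold == pytest.approx(1.5, rel=1e-6)
        assert call.p_value < 0.05 and call.trend_ok
        assert not call.passed


class TestTriadScreen:
    TRIAD = TriadDesign("F1", "P_low", "P_high", ("D10",))

    def test_null_triad_passes_nothing_beyond_type_one_noise(self):
        spec = SyntheticSpec(
            n_spots_per_class={"null": 200}, cv=0.05, stages=("D10",), seed=9
        )
        table, _ = generate_triads(spec)
        calls = select_triad_differential(table, self.TRIAD, "D10")
        # alpha=0.05 ANOVA alone admits ~5%; the 2-fold filter then removes
        # essentially everything at cv 5%
        assert sum(c.passed for c in calls) / len(calls) <= 0.05

    def test_planted_elevation_recovered(self):
        spec = SyntheticSpec(
            n_spots_per_class={"null": 5}, cv=0.05, stages=("D10",), seed=3,
        )
        table, _ = generate_triads(spec)
        # raise F1 of one spot 2.5-fold above the common level
        sel = (table.spot_id == "spot00001") & (table.genotype == "F1")
        table.loc[sel, "intensity"] *= 2.5
        calls = {c.spot_id: c for c in select_triad_differential(table, self.TRIAD, "D10")}
        assert calls["spot00001"].passed

    def test_exact_two_fold_fails_strict_inequality(self):
        import pandas as pd

        rows = []
        for geno, mean in [("P_low", 100.0), ("P_high", 100.0), ("F1", 200.0)]:
            for rep, d in zip((1, 2, 3), (-1.0, 0.0, 1.0)):
                rows.append(("s1", geno, "D10", rep, mean + d))
        table = pd.DataFrame(
            rows, columns=["spot_id", "genotype", "stage", "replicate", "intensity"]
        )
        (call,) = select_triad_differential(table, self.TRIAD, "D10")
        assert call.max_fold == pytest.approx(2.0, rel=1e-6)
        assert call.p_value < 0.05
        assert not call.passed


def test_screen_is_invariant_to_row_order_and_gel_rescaling():
    spec = SyntheticSpec(
        n_spots_per_class={"+": 5, "null": 5}, cv=0.05, stages=("D10",), seed=12
    )
    table, _ = generate_triads(spec)
    triad = TriadDesign("F1", "P_low", "P_high", ("D10",))

    def outcome(t):
        norm = normalize_total_ppm(t)
        return {c.spot_id: c.passed for c in select_triad_differential(norm, triad, "D10")}

    base = outcome(table)
    shuffled = table.sample(frac=1.0, random_state=1)
    assert outcome(shuffled) == base
    rescaled = table.copy()
    one_gel = (rescaled.genotype == "F1") & (rescaled.replicate == 2)
    rescaled.loc[one_gel, "intensity"] *= 7.0
    assert outcome(rescaled) == base
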