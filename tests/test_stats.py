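"""Statistics tests: descriptives, Levene, ANOVA forms, post-hoc layer."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from edemaquant import (
    GroupSample,
    anova_from_summary,
    bonferroni_pairwise,
    describe,
    levene_mean_centered,
    oneway_anova,
    posthoc_dispatch,
    tamhane_t2,
)
from edemaquant.stats import format_p


def sample(label, values):
    return GroupSample(label, tuple(values))


class TestDescribe:
    def test_sem_identity_published_scale(self):
        """A group with SD 11.58 and n=16 has SEM 2.90 at 2 dp."""
        rng = np.random.default_rng(0)
        v = rng.normal(90.0, 1.0, 16)
        v = (v - v.mean()) / v.std(ddof=1) * 11.58 + 90.67  # exact sd/mean
        n, mean, sd, sem = describe(sample("g", v))
        assert (n, round(mean, 2), round(sd, 2)) == (16, 90.67, 11.58)
        assert round(sem, 2) == 2.90

    def test_constant_sample(self):
        n, mean, sd, sem = describe(sample("g", [4.0] * 5))
        assert sd == 0.0 and sem == 0.0

    def test_hand_computed(self):
        n, mean, sd, sem = describe(sample("g", [1.0, 2.0, 3.0]))
        assert mean == 2.0
        assert sd == pytest.approx(1.0, abs=1e-15)
        assert sem == pytest.approx(1 / math.sqrt(3), abs=1e-15)

    def test_n_below_two_rejected(self):
        with pytest.raises(ValueError):
            sample("g", [1.0])


def brute_levene(groups):
    """Independent oracle: one-way ANOVA on |x - group mean| by the sums."""
    devs = [np.abs(np.asarray(g) - np.mean(g)) for g in groups]
    k = len(devs)
    n = sum(len(d) for d in devs)
    grand = np.concatenate(devs).mean()
    ssb = sum(len(d) * (d.mean() - grand) ** 2 for d in devs)
    ssw = sum(((d - d.mean()) ** 2).sum() for d in devs)
    f = (ssb / (k - 1)) / (ssw / (n - k))
    return f, sps.f.sf(f, k - 1, n - k)


class TestLevene:
    def test_identical_groups(self):
        g = [sample("a", [1, 2, 3, 4.0]), sample("b", [4, 3, 2, 1.0])]
        stat, p = levene_mean_centered(g)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0, abs=1e-12)

    def test_all_constant_groups(self):
        g = [sample("a", [2.0, 2.0]), sample("b", [5.0, 5.0])]
        assert levene_mean_centered(g) == (0.0, 1.0)

    def test_matches_brute_force_oracle(self):
        raw = [[0.0, 2.0, 0.0, 2.0], [-10.0, 10.0, -9.0, 9.0], [1.0, 1.5, 2.0, 2.5]]
        groups = [sample(str(i), v) for i, v in enumerate(raw)]
        stat, p = levene_mean_centered(groups)
        f_ref, p_ref = brute_levene(raw)
        assert stat == pytest.approx(f_ref, rel=1e-12)
        assert p == pytest.approx(p_ref, rel=1e-12)

    def test_requires_two_groups(self):
        with pytest.raises(ValueError):
            levene_mean_centered([sample("a", [1.0, 2.0])])


class TestAnova:
    def test_identical_groups_f_zero(self):
        g = [sample("a", [1, 2, 3.0]), sample("b", [1, 2, 3.0])]
        f, df_b, df_w, p = oneway_anova(g)
        assert f == 0.0 and (df_b, df_w) == (1, 4)

    def test_zero_within_variance_separated(self):
        f, _, _, p = oneway_anova([sample("a", [0.0, 0.0]), sample("b", [1.0, 1.0])])
        assert math.isinf(f) and p == 0.0

    def test_matches_scipy(self):
        rng = np.random.default_rng(5)
        raw = [rng.normal(m, 1.0, 10) for m in (0.0, 0.5, 1.0)]
        f, _, _, p = oneway_anova([sample(str(i), v) for i, v in enumerate(raw)])
        ref = sps.f_oneway(*raw)
        assert f == pytest.approx(ref.statistic, rel=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-12)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_summary_identity(self, seed):
        """Summary-statistics ANOVA is algebraically the raw-data ANOVA."""
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 5))
        raw = [rng.normal(rng.uniform(-2, 2), rng.uniform(0.5, 3), int(rng.integers(3, 12)))
               for _ in range(k)]
        groups = [sample(str(i), v) for i, v in enumerate(raw)]
        f1, db1, dw1, p1 = oneway_anova(groups)
        stats_ = [describe(g) for g in groups]
        f2, db2, dw2, p2 = anova_from_summary(
            [s[1] for s in stats_], [s[2] for s in stats_], [s[0] for s in stats_]
        )
        assert (db1, dw1) == (db2, dw2)
        assert f1 == pytest.approx(f2, rel=1e-10)
        assert p1 == pytest.approx(p2, rel=1e-8)

    def test_summary_equal_means(self):
        f, *_ = anova_from_summary([3.0, 3.0], [1.0, 2.0], [8, 8])
        assert f == 0.0

    def test_summary_single_group_rejected(self):
        with pytest.raises(ValueError):
            anova_from_summary([1.0], [0.5], [10])


class TestPosthoc:
    def test_tamhane_identical_groups(self):
        g = [sample("a", [1, 2, 3, 4.0]), sample("b", [1, 2, 3, 4.0])]
        (pc,) = tamhane_t2(g)
        assert pc.statistic == 0.0
        assert pc.p_adjusted == 1.0

    def test_tamhane_adjustment_is_monotone(self):
        rng = np.random.default_rng(6)
        g = [sample(str(i), rng.normal(i * 0.1, 1 + i, 8)) for i in range(3)]
        for pc in tamhane_t2(g):
            assert pc.p_adjusted >= pc.p_raw
            assert pc.p_adjusted <= 1.0

    def test_welch_satterthwaite_against_formula(self):
        """Hand evaluation of the Welch t and Satterthwaite df."""
        a = np.array([0.0, 0.0, 0.0, 0.0])
        b = np.array([10.0, 10.0, 10.0, 10.0001])
        g = [sample("a", a), sample("b", b)]
        (pc,) = tamhane_t2(g)
        va, vb = a.var(ddof=1), b.var(ddof=1)
        se2 = va / 4 + vb / 4
        t_ref = (a.mean() - b.mean()) / math.sqrt(se2)
        df_ref = se2**2 / ((va / 4) ** 2 / 3 + (vb / 4) ** 2 / 3)
        assert pc.statistic == pytest.approx(t_ref, rel=1e-12)
        assert pc.df == pytest.approx(df_ref, rel=1e-12)

    def test_bonferroni_monotone_and_capped(self):
        rng = np.random.default_rng(7)
        g = [sample(str(i), rng.normal(0, 1, 6)) for i in range(3)]
        for pc in bonferroni_pairwise(g):
            assert pc.p_adjusted >= pc.p_raw
            assert pc.p_adjusted <= 1.0
            assert pc.p_adjusted == pytest.approx(min(1.0, 3 * pc.p_raw), rel=1e-12)

    def test_dispatch_unequal_variances_selects_tamhane(self):
        rng = np.random.default_rng(8)
        g = [
            sample("tight", rng.normal(0, 0.01, 16)),
            sample("wide", rng.normal(0.5, 5.0, 16)),
            sample("mid", rng.normal(1.0, 0.02, 16)),
        ]
        rep = posthoc_dispatch(g)
        assert rep.levene_p < 0.05
        assert rep.posthoc_method == "Tamhane"

    def test_dispatch_report_invariants(self):
        rng = np.random.default_rng(9)
        g = [sample(str(i), rng.normal(i, 1.0, 10)) for i in range(3)]
        rep = posthoc_dispatch(g)
        assert rep.df_between == 2
        assert rep.df_within == 27
        for d in rep.descriptives:
            assert d["sem"] == pytest.approx(d["sd"] / math.sqrt(d["n"]), rel=1e-12)
        assert len(rep.pairwise) == 3
        assert rep.posthoc_method == ("Tamhane" if rep.levene_p < 0.05 else "Bonferroni")


class TestFormatP:
    def test_underflow_floor(self):
        assert format_p(0.0) == "< 1e-300"
        assert format_p(1e-310) == "< 1e-300"
        assert format_p(5.75e-25) == "5.75e-25"
        assert format_p(0.163) == "0.163"
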