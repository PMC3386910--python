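"""Normalized hits, RPKM, regulation factors, profiles, chi-squared offset test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from snipmap.mapper import CountTable
from snipmap.quantify import (
    build_profile_set,
    build_regulation_table,
    group_average_profile,
    normalized_hits,
    profile_offset_test,
    regulation_factor,
    rpkm,
    rpkm_table,
    unit_sum_profile,
)


def make_counts(counts, lengths=None, sample_id="s"):
    counts = np.asarray(counts, dtype=np.int64)
    lengths = np.asarray(lengths if lengths is not None else [1000] * len(counts))
    return CountTable(
        sample_id=sample_id,
        names=[f"g{i}" for i in range(len(counts))],
        lengths=lengths,
        counts=counts,
        profiles=[np.zeros(1, dtype=np.int64)] * len(counts),
        total_reads=int(counts.sum()),
        total_mapped=int(counts.sum()),
    )


class TestNormalizedHits:
    def test_fractions(self):
        nh = normalized_hits(make_counts([10, 30]))
        assert np.allclose(nh, [0.25, 0.75])

    def test_single_gene_is_one(self):
        assert normalized_hits(make_counts([7]))[0] == 1.0

    def test_sums_to_one_on_random_counts(self, rng):
        ct = make_counts(rng.integers(0, 1000, size=200) + 1)
        assert abs(normalized_hits(ct).sum() - 1.0) < 1e-12

    def test_zero_mapped_rejected(self):
        with pytest.raises(ValueError):
            normalized_hits(make_counts([0, 0]))


class TestRpkm:
    @pytest.mark.parametrize(
        "count,length,total,expected",
        [(10, 1000, 1_000_000, 10.0), (0, 500, 1_000_000, 0.0),
         (85, 500, 2_000_000, 85.0)],
    )
    def test_values(self, count, length, total, expected):
        assert rpkm(count, length, total) == pytest.approx(expected)

    @pytest.mark.parametrize("length,total", [(0, 1000), (1000, 0)])
    def test_degenerate_inputs_rejected(self, length, total):
        with pytest.raises(ValueError):
            rpkm(10, length, total)

    def test_rpkm_is_normalized_hits_times_1e9_over_length(self, rng):
        lengths = rng.integers(200, 5000, size=50)
        ct = make_counts(rng.integers(1, 500, size=50), lengths)
        nh = normalized_hits(ct)
        rp = rpkm_table(ct)
        assert np.allclose(rp, nh * 1e9 / lengths)


class TestRegulationFactor:
    def test_ratio_of_means(self):
        assert regulation_factor([4e-5], [1e-5]) == pytest.approx(4.0)

    def test_equal_means_give_unity(self):
        assert regulation_factor([2e-5, 4e-5], [3e-5, 3e-5]) == pytest.approx(1.0)

    def test_swapping_sides_inverts_exactly(self, rng):
        m = rng.random(3) * 1e-4 + 1e-6
        w = rng.random(3) * 1e-4 + 1e-6
        f = regulation_factor(m, w)
        assert regulation_factor(w, m) == pytest.approx(1.0 / f)

    def test_pseudocount_applied_only_when_a_side_is_zero(self):
        # wt side zero: 0.5 reads added to every count on both sides
        f = regulation_factor([8, 12], [0, 0],
                              mutant_totals=[1000, 1000], wt_totals=[1000, 1000])
        expected = np.mean([8.5 / 1000, 12.5 / 1000]) / np.mean([0.5 / 1000, 0.5 / 1000])
        assert f == pytest.approx(expected)
        # no zero side: raw counts used untouched
        f2 = regulation_factor([8, 12], [4, 6],
                               mutant_totals=[1000, 1000], wt_totals=[1000, 1000])
        assert f2 == pytest.approx(2.0)

    def test_both_sides_zero_without_pseudocount_is_undefined(self):
        f = regulation_factor([0], [0], mutant_totals=[100], wt_totals=[100],
                              pseudocount_reads=0.0)
        assert np.isnan(f)

    def test_programmed_induction_recovered(self):
        """Two-condition fixture with a programmed 8x induction, 2 replicates a
        side: the recovered factor lands within sampling error of 8."""
        rng = np.random.default_rng(42)
        n_genes, depth = 500, 60  # many genes: composition effect on totals is tiny
        base = np.full(n_genes, depth, dtype=float)
        mut_exp = base.copy()
        mut_exp[0] *= 8.0
        mut = [rng.poisson(mut_exp) for _ in range(2)]
        wt = [rng.poisson(base) for _ in range(2)]
        mt = [m.sum() for m in mut]
        wtot = [w.sum() for w in wt]
        f = regulation_factor([m[0] for m in mut], [w[0] for w in wt],
                              mutant_totals=mt, wt_totals=wtot)
        km, kw = sum(m[0] for m in mut), sum(w[0] for w in wt)
        se_log = np.sqrt(1 / km + 1 / kw)
        assert abs(np.log(f / 8.0)) < 3 * se_log


class TestRegulationTable:
    def test_factors_and_logs(self):
        samples = {
            "m1": make_counts([20, 10], sample_id="m1"),
            "m2": make_counts([20, 10], sample_id="m2"),
            "w1": make_counts([5, 25], sample_id="w1"),
            "w2": make_counts([5, 25], sample_id="w2"),
        }
        reg = build_regulation_table(samples, {"growth": (["m1", "m2"], ["w1", "w2"])})
        f0 = (20 / 30) / (5 / 30)
        assert reg["factor_growth"][0] == pytest.approx(f0)
        assert reg["log2_growth"][0] == pytest.approx(np.log2(f0))
        assert reg["nh_m1"].sum() == pytest.approx(1.0)


class TestProfiles:
    def test_unit_sum_example(self):
        assert np.allclose(unit_sum_profile([1, 2, 3, 4]), [0.1, 0.2, 0.3, 0.4])

    def test_constant_series(self):
        assert np.allclose(unit_sum_profile([5] * 12), np.full(12, 1 / 12))

    @settings(derandomize=True, max_examples=40)
    @given(
        series=st.lists(st.integers(min_value=0, max_value=10**6), min_size=2,
                        max_size=24).filter(lambda s: sum(s) > 0),
        k=st.floats(min_value=1e-3, max_value=1e3, allow_nan=False),
    )
    def test_scale_invariance(self, series, k):
        a = unit_sum_profile(series)
        b = unit_sum_profile(np.asarray(series, dtype=float) * k)
        assert np.allclose(a, b)

    def test_all_zero_series_rejected(self):
        with pytest.raises(ValueError):
            unit_sum_profile([0, 0, 0])

    def test_group_average_identity_and_mixing(self):
        p = unit_sum_profile([1, 3])
        assert np.allclose(group_average_profile([p, p]), p)
        assert np.allclose(
            group_average_profile([np.array([1.0, 0.0]), np.array([0.0, 1.0])]),
            [0.5, 0.5],
        )

    def test_group_of_random_profiles_sums_to_one(self, rng):
        profiles = [unit_sum_profile(rng.integers(1, 100, size=12)) for _ in range(41)]
        assert abs(group_average_profile(profiles).sum() - 1.0) < 1e-9

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_average_profile([])

    def test_build_profile_set_excludes_zero_genes(self):
        series = pd.DataFrame(
            {"t0": [1, 0, 5], "t1": [3, 0, 5]}, index=["a", "zero", "c"]
        )
        ps = build_profile_set(series, groups={"grp": ["a", "c", "zero"]})
        assert ps.excluded == ["zero"]
        assert np.allclose(ps.profiles.sum(axis=1), 1.0)
        assert abs(ps.group_profiles.loc["grp"].sum() - 1.0) < 1e-9


class TestProfileOffsetTest:
    def test_proportional_series_homogeneous(self):
        a = np.array([5, 10, 20, 10, 5])
        stat, p, df = profile_offset_test(a, 3 * a)
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)
        assert df == 4

    def test_closed_form_2x2(self):
        stat, p, df = profile_offset_test([10, 0], [0, 10])
        assert stat == pytest.approx(20.0)
        assert df == 1
        assert p == pytest.approx(stats.chi2.sf(20.0, 1))

    def test_double_zero_timepoint_dropped(self):
        stat, p, df = profile_offset_test([10, 0, 5], [8, 0, 9])
        assert df == 1  # one column dropped

    def test_significance_grows_with_depth_for_shifted_peaks(self):
        shape_a = np.array([1, 4, 16, 4, 1], dtype=float)
        shape_b = np.roll(shape_a, 1)
        stats_seen, ps = [], []
        for depth in (2, 20, 200):
            a = np.round(shape_a * depth).astype(int)
            b = np.round(shape_b * depth).astype(int)
            stat, p, _ = profile_offset_test(a, b)
            stats_seen.append(stat)
            ps.append(p)
        assert stats_seen[0] < stats_seen[1] < stats_seen[2]
        assert ps[0] > ps[1] >= ps[2]
        assert ps[2] < 1e-10
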