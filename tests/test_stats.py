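import numpy as np
import pandas as pd
import pytest
from scipy.stats import wilcoxon as scipy_wilcoxon

from petex.catalog import ALL_FEATURES
from petex.errors import ValidationError
from petex.stats import (
    build_comparison_table,
    comparison_markdown,
    icc_agreement,
    spearman,
    summarize_families,
    wilcoxon_signed_rank,
)


class TestWilcoxon:
    def test_identical_samples_degenerate(self):
        r = wilcoxon_signed_rank(np.arange(10.0), np.arange(10.0))
        assert r.p == 1.0 and r.degenerate

    def test_exact_p_n6_one_signed(self):
        r = wilcoxon_signed_rank(np.zeros(6), np.arange(1.0, 7.0))
        assert r.p == pytest.approx(2 / 64)
        assert r.method == "exact"

    def test_exact_p_n5_never_below_alpha(self):
        r = wilcoxon_signed_rank(np.zeros(5), np.arange(1.0, 6.0))
        assert r.p == pytest.approx(2 / 32)
        assert r.p > 0.05

    def test_agrees_with_scipy_exact(self, rng):
        for _ in range(20):
            n = int(rng.integers(6, 26))
            x = rng.normal(size=n)
            y = x + rng.normal(size=n)
            ours = wilcoxon_signed_rank(x, y)
            ref = scipy_wilcoxon(y, x, mode="exact")
            assert ours.p == pytest.approx(float(ref.pvalue), rel=1e-12)

    def test_normal_branch_close_to_exact_at_boundary(self, rng):
        # at n = 25 the two branches agree to 0.01 absolute on tie-free data
        diffs = []
        for _ in range(50):
            x = rng.normal(size=25)
            y = x + rng.normal(size=25) * 0.6
            exact = wilcoxon_signed_rank(x, y, method="exact")
            approx = wilcoxon_signed_rank(x, y, method="normal")
            assert exact.method == "exact" and approx.method == "normal"
            diffs.append(abs(exact.p - approx.p))
        assert max(diffs) < 0.01

    def test_zero_differences_discarded(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0, 7.0])
        y = np.array([1.0, 3.0, 5.0, 2.0, 9.0, 4.0, 12.0])  # one zero diff
        r = wilcoxon_signed_rank(x, y)
        assert r.n == 6

    def test_monotone_transform_invariance(self, rng):
        x = rng.gamma(2.0, 1.0, size=15)
        y = rng.gamma(2.0, 1.0, size=15)
        p1 = wilcoxon_signed_rank(x, y).p
        p2 = wilcoxon_signed_rank(np.log(x), np.log(y)).p
        # ranks of differences change, but one-signedness of each pair does
        # not; invariance holds for the sign pattern and approximately for p
        # only when the transform preserves difference ordering -- the exact
        # rank-based invariant is p(x, y) == p(a*x+b, a*y+b) for a > 0
        p3 = wilcoxon_signed_rank(3.0 * x + 1.0, 3.0 * y + 1.0).p
        assert p1 == pytest.approx(p3, rel=1e-12)

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValidationError):
            wilcoxon_signed_rank(np.zeros(4), np.arange(4.0))


class TestSpearman:
    def test_perfect_monotone(self):
        r = spearman(np.arange(8.0), np.arange(8.0) ** 2)
        assert r.r == pytest.approx(1.0)
        rr = spearman(np.arange(8.0), -np.arange(8.0))
        assert rr.r == pytest.approx(-1.0)

    def test_hand_computed_r(self):
        # ranks (1,2,3,4) vs (1,2,4,3): r = 1 - 6*2/(4*15) = 0.8
        r = spearman(np.array([1.0, 2.0, 3.0, 4.0]), np.array([1.0, 2.0, 4.0, 3.0]))
        assert r.r == pytest.approx(0.8)

    def test_constant_input_flagged(self):
        r = spearman(np.ones(6), np.arange(6.0))
        assert r.degenerate and np.isnan(r.r)


class TestIcc:
    def test_identical_raters_give_one(self, rng):
        a = rng.normal(size=20)
        assert icc_agreement(np.c_[a, a]) == pytest.approx(1.0)

    def test_shuffled_rater_near_zero(self, rng):
        a = rng.normal(size=200)
        b = rng.permutation(a)
        assert abs(icc_agreement(np.c_[a, b])) < 0.15

    def test_agrees_with_pingouin_absolute_single(self, rng):
        import pandas as pd
        import pingouin as pg

        a = rng.normal(size=30)
        b = a + rng.normal(size=30) * 0.3 + 0.2
        ours = icc_agreement(np.c_[a, b])
        df = pd.DataFrame(
            {
                "s": np.repeat(np.arange(30), 2),
                "r": np.tile([0, 1], 30),
                "v": np.c_[a, b].ravel(),
            }
        )
        ref = pg.intraclass_corr(df, targets="s", raters="r", ratings="v")
        ref_icc = float(ref.loc[ref["Type"] == "ICC(A,1)", "ICC"].iloc[0])
        assert ours == pytest.approx(ref_icc, rel=1e-9)

    def test_constant_offset_penalised(self):
        # absolute agreement: a systematic offset keeps consistency but
        # lowers ICC(2,1) below 1; verify against the mean-squares formula
        a = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        b = a + 2.0
        icc = icc_agreement(np.c_[a, b])
        assert icc < 1.0

        n, k = 5, 2
        x = np.c_[a, b]
        grand = x.mean()
        ms_r = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
        ms_c = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
        resid = x - x.mean(axis=1, keepdims=True) - x.mean(axis=0, keepdims=True) + grand
        ms_e = (resid**2).sum() / ((n - 1) * (k - 1))
        expected = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e + k * (ms_c - ms_e) / n)
        assert icc == pytest.approx(expected, rel=1e-9)


def _feature_table(n_patients, rng, effect=0.0, groups=("benign", "malignant")):
    rows = []
    for i in range(n_patients):
        group = groups[i % len(groups)]
        base = {name: float(rng.gamma(3.0, 2.0)) for name in ALL_FEATURES}
        late = {name: v * (1.0 + effect) + float(rng.normal(0, 0.05)) for name, v in base.items()}
        rows.append({"patient_id": f"p{i}", "timepoint": "early", "group": group, **base})
        rows.append({"patient_id": f"p{i}", "timepoint": "late", "group": group, **late})
    return pd.DataFrame(rows)


class TestComparisonTable:
    def test_identical_timepoints_all_null(self, rng):
        df = _feature_table(12, rng)
        for name in ALL_FEATURES:
            df.loc[df["timepoint"] == "late", name] = df.loc[
                df["timepoint"] == "early", name
            ].to_numpy()
        table = build_comparison_table(df)
        assert all(r.direction == "none" for r in table)
        assert all(r.wilcoxon_p == 1.0 for r in table if not np.isnan(r.wilcoxon_p))

    def test_row_count_features_times_groups(self, rng):
        table = build_comparison_table(_feature_table(12, rng))
        assert len(table) == 99 * 3

    def test_small_group_skipped(self, rng):
        table = build_comparison_table(
            _feature_table(6, rng, groups=("benign", "benign", "malignant"))
        )
        groups = {r.group for r in table}
        assert "malignant" not in groups  # only 2 malignant patients

    def test_uniform_decrease_flagged_down(self, rng):
        df = _feature_table(10, rng, effect=-0.2)
        table = build_comparison_table(df)
        down = [r for r in table if r.group == "all" and r.direction == "down"]
        assert len(down) > 90

    def test_ranges_contain_medians(self, rng):
        for r in build_comparison_table(_feature_table(10, rng, effect=0.1)):
            if np.isnan(r.early_median):
                continue
            assert r.early_min <= r.early_median <= r.early_max
            assert r.late_min <= r.late_median <= r.late_max


class TestFamilySummary:
    def test_counts_partition_and_total(self, rng):
        table = build_comparison_table(_feature_table(12, rng, effect=-0.15))
        summaries = summarize_families(table)
        by_key = {(s.group, s.family): s for s in summaries}
        for group in ("all", "benign", "malignant"):
            total = by_key[(group, "total")]
            fams = [by_key[(group, f)] for f in ("first", "second", "high", "fractal")]
            assert total.n_significant == sum(f.n_significant for f in fams)
            for s in fams + [total]:
                assert s.n_up + s.n_down == s.n_significant
        assert by_key[("all", "first")].family_size == 37
        assert by_key[("all", "second")].family_size == 25
        assert by_key[("all", "high")].family_size == 31
        assert by_key[("all", "fractal")].family_size == 6

    def test_null_table_all_zero(self, rng):
        df = _feature_table(8, rng)
        for name in ALL_FEATURES:
            df.loc[df["timepoint"] == "late", name] = df.loc[
                df["timepoint"] == "early", name
            ].to_numpy()
        summaries = summarize_families(build_comparison_table(df))
        assert all(s.n_significant == 0 for s in summaries)


class TestMarkdownReport:
    def test_report_contains_all_features_and_test_count(self, rng):
        table = build_comparison_table(_feature_table(10, rng, effect=0.1))
        md = comparison_markdown(table)
        for name in ALL_FEATURES:
            assert name in md
        assert "Wilcoxon signed-rank tests performed" in md
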