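"""Grouping, mean/SEM, t-tests, fold change, and cohort reports."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from dabquant import (
    PositivityFractions,
    SampleRecord,
    THICKNESS_RULE,
    assign_groups,
    cohort_report,
    compare_groups,
    fold_change,
    mean_sem,
    rule_from_stage_map,
    unpaired_t_test,
)


def make_record(sample_id, t_stage, h, tissue_type="melanoma"):
    return SampleRecord(
        sample_id=sample_id,
        tissue_type=tissue_type,
        t_stage=t_stage,
        n_stage="N0",
        m_stage="M0",
        n_analyzed=1000,
        fractions=PositivityFractions(1 - h / 3, 0.0, 0.0, h / 3),
        h_score=h,
    )


def make_cohort(thin_h, thick_h):
    records = [make_record(f"a{i}", "T1" if i % 2 else "T2", h)
               for i, h in enumerate(thin_h)]
    records += [make_record(f"b{i}", "T3" if i % 2 else "T4", h)
                for i, h in enumerate(thick_h)]
    return records


class TestAssignGroups:
    def test_thickness_rule_partition(self):
        records = make_cohort([0.9, 1.0], [0.5, 0.6])
        partition = assign_groups(records, THICKNESS_RULE)
        assert {r.t_stage for r in partition["thin"]} <= {"T1", "T2"}
        assert {r.t_stage for r in partition["thick"]} <= {"T3", "T4"}

    def test_normal_skin_unassigned(self):
        records = make_cohort([0.9, 1.0], [0.5, 0.6])
        records.append(make_record("n1", "NA", 0.8, tissue_type="normal"))
        partition = assign_groups(records, THICKNESS_RULE)
        assert sum(len(v) for v in partition.values()) == 4

    def test_empty_records_refused(self):
        with pytest.raises(ValueError):
            assign_groups([], THICKNESS_RULE)

    def test_undersized_group_refused(self):
        records = make_cohort([0.9], [0.5, 0.6])
        with pytest.raises(ValueError, match="n=1"):
            assign_groups(records, THICKNESS_RULE)

    def test_stage_mapped_twice_rejected(self):
        with pytest.raises(ValueError):
            rule_from_stage_map("bad", {"a": ["T1"], "b": ["T1", "T2"]})


class TestMeanSem:
    def test_hand_checked_values(self):
        mean, sem = mean_sem([1.0, 2.0, 3.0])
        assert mean == pytest.approx(2.0)
        assert sem == pytest.approx(1.0 / np.sqrt(3.0))

    def test_constant_values_have_zero_sem(self):
        assert mean_sem([5, 5, 5, 5]) == (5.0, 0.0)

    def test_single_value_refused(self):
        with pytest.raises(ValueError):
            mean_sem([0.95])

    def test_sem_shrinks_as_inverse_sqrt_of_replication(self, rng):
        n = 12
        base = rng.normal(1.0, 0.3, size=n)
        _, sem1 = mean_sem(base)
        for k in (4, 9):
            _, semk = mean_sem(np.tile(base, k))
            # 1/sqrt(k) scaling, exact once the n-1 denominators of the two
            # sample standard deviations are accounted for
            bessel = np.sqrt((n * k / (n * k - 1)) * ((n - 1) / n))
            assert semk == pytest.approx(sem1 / np.sqrt(k) * bessel, rel=1e-9)
            assert semk < sem1 / np.sqrt(k) * 1.01


class TestUnpairedTTest:
    def test_identical_groups(self):
        t, df, p = unpaired_t_test([1, 2, 3], [1, 2, 3])
        assert t == 0.0
        assert p == pytest.approx(1.0)

    def test_hand_checked_student_example(self):
        t, df, p = unpaired_t_test([1, 2, 3], [4, 5, 6], variant="student")
        assert t == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0))
        assert df == 4.0
        assert p == pytest.approx(0.0213, abs=2e-4)

    def test_swap_symmetry(self):
        t1, _, p1 = unpaired_t_test([1, 2, 4], [5, 6, 9])
        t2, _, p2 = unpaired_t_test([5, 6, 9], [1, 2, 4])
        assert t1 == pytest.approx(-t2)
        assert p1 == pytest.approx(p2)

    def test_degenerate_conventions(self):
        with pytest.warns(UserWarning):
            _, _, p_eq = unpaired_t_test([2, 2], [2, 2])
        assert p_eq == 1.0
        with pytest.warns(UserWarning):
            _, _, p_ne = unpaired_t_test([2, 2], [3, 3])
        assert p_ne == 0.0

    def test_too_small_group_refused(self):
        with pytest.raises(ValueError):
            unpaired_t_test([1.0], [1, 2, 3])

    @settings(max_examples=60, deadline=None)
    @given(
        seed=st.integers(0, 10_000),
        na=st.integers(2, 30),
        nb=st.integers(2, 30),
        variant=st.sampled_from(["student", "welch"]),
    )
    def test_agrees_with_reference_implementation(self, seed, na, nb, variant):
        r = np.random.default_rng(seed)
        a = r.normal(0.0, 1.0, size=na)
        b = r.normal(0.3, 1.4, size=nb)
        t, df, p = unpaired_t_test(a, b, variant=variant)
        ref = stats.ttest_ind(a, b, equal_var=(variant == "student"))
        assert t == pytest.approx(ref.statistic, abs=1e-9)
        assert p == pytest.approx(ref.pvalue, abs=1e-9)
        assert df == pytest.approx(ref.df, abs=1e-9)


class TestFoldChange:
    def test_equal_means(self):
        assert fold_change(2.0, 2.0) == 1.0

    def test_reported_group_means(self):
        assert fold_change(0.95, 0.57) == pytest.approx(5 / 3)

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            fold_change(1.0, 0.0)


class TestCompareGroups:
    def test_identical_groups_not_significant(self):
        records = make_cohort([0.7, 0.8, 0.9], [0.7, 0.8, 0.9])
        cmp = compare_groups(records)
        assert cmp.fold_change == pytest.approx(1.0)
        assert not cmp.significant
        assert cmp.direction == "no change"

    def test_study_sized_separation_is_significant(self, rng):
        thin = rng.normal(0.95, 0.2, size=8)
        thick = rng.normal(0.57, 0.2, size=75)
        cmp = compare_groups(make_cohort(thin, thick))
        assert cmp.significant
        assert cmp.direction == "decrease in thick"
        assert cmp.group_a.n == 8 and cmp.group_b.n == 75

    def test_single_sample_group_refused(self):
        with pytest.raises(ValueError):
            compare_groups(make_cohort([0.9], [0.5, 0.6, 0.7]))

    def test_welch_variant_propagates(self):
        records = make_cohort([0.9, 1.0, 1.1], [0.5, 0.6, 0.7])
        cmp = compare_groups(records, variant="welch")
        assert cmp.variant == "welch"
        assert cmp.df != 4.0  # Satterthwaite df is non-integer in general


class TestCohortReport:
    def _comparison(self, rng):
        thin = rng.normal(0.95, 0.2, size=8)
        thick = rng.normal(0.57, 0.2, size=20)
        return compare_groups(make_cohort(thin, thick))

    def test_csv_and_chart_written(self, tmp_path, rng):
        csv_path, chart_path = cohort_report([self._comparison(rng)], tmp_path)
        lines = csv_path.read_text().strip().splitlines()
        assert len(lines) == 2  # header + one data row
        png = chart_path.read_bytes()
        assert len(png) > 0 and png[:8] == b"\x89PNG\r\n\x1a\n"

    def test_report_is_deterministic(self, tmp_path, rng):
        cmp = self._comparison(rng)
        p1, _ = cohort_report([cmp], tmp_path / "a")
        p2, _ = cohort_report([cmp], tmp_path / "b")
        assert p1.read_bytes() == p2.read_bytes()

    def test_empty_report_refused(self, tmp_path):
        with pytest.raises(ValueError):
            cohort_report([], tmp_path)
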