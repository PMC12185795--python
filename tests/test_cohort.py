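"""Cohort I/O, filtering rules, 2x2 aggregation and descriptive statistics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import bayesrr as br
from bayesrr.cohort import SCHEMA, cohort_from_frame
from bayesrr.errors import (
    CohortValidationError,
    DegenerateCohortError,
    SchemaError,
    UndefinedTestError,
)

from conftest import SEED, full_row, make_csv, random_cohort


class TestReadCohortCsv:
    def test_well_formed_identity(self, tmp_path):
        path = make_csv(tmp_path, [full_row(), full_row(age=91), full_row(age=83, died=0)])
        cohort = br.read_cohort_csv(path)
        assert cohort.n == 3
        assert cohort.n_dropped_missing == 0
        assert cohort.n_dropped_elective == 0

    def test_missing_mortality_dropped_and_counted(self, tmp_path):
        rows = [full_row(), full_row(age=91), full_row(died=0)]
        rows.append(full_row().rsplit(",", 1)[0] + ",")  # empty mortality cell
        cohort = br.read_cohort_csv(make_csv(tmp_path, rows))
        assert cohort.n == 3
        assert cohort.n_dropped_missing == 1

    def test_elective_rows_dropped_when_flagged(self, tmp_path):
        rows = [full_row(), full_row(elective=1), full_row(age=92, elective=1)]
        cohort = br.read_cohort_csv(make_csv(tmp_path, rows), drop_elective=True)
        assert cohort.n == 1
        assert cohort.n_dropped_elective == 2
        kept = br.read_cohort_csv(make_csv(tmp_path, rows), drop_elective=False)
        assert kept.n == 3

    def test_malformed_header_names_missing_columns(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("age_years,sex\n85,male\n")
        with pytest.raises(SchemaError, match="sofa"):
            br.read_cohort_csv(path)

    @pytest.mark.parametrize(
        "row", [full_row(sofa=25), full_row(cfs=0), full_row(age=79)]
    )
    def test_out_of_range_scores_rejected_with_row_index(self, tmp_path, row):
        with pytest.raises(CohortValidationError, match="row 0"):
            br.read_cohort_csv(make_csv(tmp_path, [row]))

    def test_round_trip_is_field_identical(self, tmp_path, rng):
        cohort = random_cohort(rng)
        # knock out some covariate cells to exercise missing-value round-trip
        df = cohort.df.copy()
        df.loc[3, "sofa"] = None
        df.loc[5, "sex"] = None
        cohort = cohort_from_frame(df[list(SCHEMA)])
        out = tmp_path / "rt.csv"
        cohort.write_csv(out)
        back = br.read_cohort_csv(out)
        for col in SCHEMA:
            a, b = cohort.df[col], back.df[col]
            assert (a.isna() == b.isna()).all(), col
            assert (a.dropna() == b.dropna()).all(), col


class TestAggregation:
    def test_fixture_counts(self, fixture_table):
        cohort = br.expand_two_by_two(fixture_table)
        agg = br.aggregate_two_by_two(cohort)
        assert (agg.d1, agg.n1, agg.d0, agg.n0) == (365, 807, 3219, 7601)

    def test_four_record_direct_count(self):
        from bayesrr.cohort import TwoByTwoTable

        cohort = br.expand_two_by_two(TwoByTwoTable(1, 2, 1, 2))
        agg = br.aggregate_two_by_two(cohort)
        assert (agg.d1, agg.n1, agg.d0, agg.n0) == (1, 2, 1, 2)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_tally(self, seed):
        cohort = random_cohort(np.random.default_rng(seed))
        agg = br.aggregate_two_by_two(cohort)
        d1 = n1 = d0 = n0 = 0
        for _, row in cohort.df.iterrows():
            if row["age_years"] >= 90:
                n1 += 1
                d1 += bool(row["mortality_30d"])
            else:
                n0 += 1
                d0 += bool(row["mortality_30d"])
        assert (agg.d1, agg.n1, agg.d0, agg.n0) == (d1, n1, d0, n0)

    def test_absent_group_raises(self, rng):
        cohort = random_cohort(rng)
        octo_only = cohort.df[cohort.df["age_group"] == "octogenarian"]
        sub = cohort_from_frame(octo_only[list(SCHEMA)])
        with pytest.raises(DegenerateCohortError):
            br.aggregate_two_by_two(sub)


class TestMortalityPercents:
    def test_published_rounding(self, fixture_table):
        assert br.mortality_percents(fixture_table, rounded=True) == (45.0, 42.0)

    def test_boundaries_and_arithmetic(self):
        from bayesrr.cohort import TwoByTwoTable

        assert br.mortality_percents(TwoByTwoTable(0, 10, 10, 10)) == (0.0, 100.0)
        p1, p0 = br.mortality_percents(TwoByTwoTable(1, 3, 1, 4))
        assert p1 == pytest.approx(100 / 3)
        assert p0 == pytest.approx(25.0)


class TestChiSquare:
    def test_uncorrected_on_published_counts(self, fixture_table):
        stat, p = br.chi_square_2x2(fixture_table)
        assert stat == pytest.approx(2.4735, abs=2e-4)
        assert p == pytest.approx(0.1158, abs=2e-4)

    def test_proportional_table_is_null(self):
        from bayesrr.cohort import TwoByTwoTable

        stat, p = br.chi_square_2x2(TwoByTwoTable(10, 100, 100, 1000))
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_invariance_under_group_and_outcome_swap(self, fixture_table):
        t = fixture_table
        from bayesrr.cohort import TwoByTwoTable

        stat, _ = br.chi_square_2x2(t)
        swapped_groups = TwoByTwoTable(t.d0, t.n0, t.d1, t.n1)
        swapped_outcome = TwoByTwoTable(t.n1 - t.d1, t.n1, t.n0 - t.d0, t.n0)
        assert br.chi_square_2x2(swapped_groups)[0] == pytest.approx(stat)
        assert br.chi_square_2x2(swapped_outcome)[0] == pytest.approx(stat)

    def test_zero_margin_raises(self):
        from bayesrr.cohort import TwoByTwoTable

        with pytest.raises(UndefinedTestError):
            br.chi_square_2x2(TwoByTwoTable(0, 10, 0, 10))


class TestMannWhitney:
    def test_identical_samples_symmetric(self):
        u, p = br.mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert u == pytest.approx(4.5)
        assert p == pytest.approx(1.0, abs=0.01)

    def test_complete_separation_convention(self):
        u, _ = br.mann_whitney_u([1, 2], [10, 11])
        assert u == 0.0  # U counts wins of the first sample

    def test_matches_pairwise_enumeration(self):
        a, b = [1, 2, 3, 4], [2, 3, 4, 5]
        brute = sum(
            1.0 if x > y else 0.5 if x == y else 0.0 for x in a for y in b
        )
        u, _ = br.mann_whitney_u(a, b)
        assert u == pytest.approx(brute)

    def test_empty_sample_raises(self):
        with pytest.raises(UndefinedTestError):
            br.mann_whitney_u([], [1.0])


class TestDescriptiveSummary:
    def test_three_point_quartiles_linear_convention(self, rng):
        # numpy linear interpolation: median = middle order statistic,
        # quartiles interpolate between order statistics
        cohort = random_cohort(rng, n=40)
        df = cohort.df.copy()
        nona = df.index[df["age_group"] == "nonagenarian"][:3]
        df = df.loc[list(nona) + list(df.index[df["age_group"] == "octogenarian"])]
        df.loc[nona, "sofa"] = [4, 6, 9]
        cohort = cohort_from_frame(df[list(SCHEMA)].reset_index(drop=True))
        summary = br.descriptive_summary(cohort)
        med, q1, q3 = summary.continuous["sofa"]["nonagenarian"]
        assert med == 6.0
        assert (q1, q3) == (5.0, 7.5)

    def test_synthetic_default_group_sizes(self):
        cohort, _ = br.generate_cohort(br.default_config_from_fixture(), seed=SEED)
        summary = br.descriptive_summary(cohort)
        assert summary.group_sizes == {"octogenarian": 7601, "nonagenarian": 807}

    def test_all_male_cohort_is_100_percent_male(self, rng):
        cohort = random_cohort(rng)
        df = cohort.df.copy()
        df["sex"] = "male"
        cohort = cohort_from_frame(df[list(SCHEMA)])
        summary = br.descriptive_summary(cohort)
        for group in ("octogenarian", "nonagenarian"):
            count, pct = summary.categorical["sex"][group]["male"]
            assert pct == 100.0

    def test_categorical_percents_sum_to_100(self, rng):
        cohort = random_cohort(rng, n=80)
        summary = br.descriptive_summary(cohort)
        for group in ("octogenarian", "nonagenarian"):
            pcts = [v[1] for v in summary.categorical["sex"][group].values()]
            assert sum(pcts) == pytest.approx(100.0)
            dx = [v[1] for v in summary.categorical["admission_dx"][group].values()]
            assert sum(dx) == pytest.approx(100.0)
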