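"""Cohort ingestion, inclusion threshold, profile matching, tables."""

import numpy as np
import pandas as pd
import pytest

import symptomnet as sn
from symptomnet.cohort import NO_PROFILE, ColumnConfig
from symptomnet.exceptions import (
    EmptyInputError,
    FormatError,
    InvalidArgumentError,
)

ITEMS = [f"phq{i}" for i in range(1, 10)]


def write_cohort(tmp_path, rows, name="cohort.csv", sep=",", header=None):
    header = header or (["respondent_id"] + ITEMS)
    lines = [sep.join(header)]
    for i, row in enumerate(rows):
        lines.append(sep.join([f"r{i + 1}"] + [str(v) for v in row]))
    path = tmp_path / name
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadResponses:
    def test_valid_rows_ingested(self, tmp_path):
        path = write_cohort(
            tmp_path,
            [[1] * 9, [0] * 9, [3, 2, 1, 0, 0, 0, 0, 0, 0]],
        )
        rm = sn.load_responses(path)
        assert rm.n_respondents == 3
        assert rm.respondent_ids == ("r1", "r2", "r3")
        assert list(rm.totals) == [9, 0, 6]

    def test_tsv_dialect_sniffed(self, tmp_path):
        path = write_cohort(tmp_path, [[2] * 9], name="cohort.tsv", sep="\t")
        assert sn.load_responses(path).n_respondents == 1

    def test_out_of_range_row_dropped_with_warning(self, tmp_path):
        path = write_cohort(tmp_path, [[1] * 9, [4] + [1] * 8])
        with pytest.warns(UserWarning, match="excluded 1"):
            rm = sn.load_responses(path)
        assert rm.n_respondents == 1
        assert rm.n_dropped_invalid == 1

    def test_missing_cell_row_dropped(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "respondent_id," + ",".join(ITEMS) + "\n"
            "r1,1,1,1,1,1,1,1,1,1\n"
            "r2,1,,1,1,1,1,1,1,1\n"
        )
        with pytest.warns(UserWarning):
            rm = sn.load_responses(path)
        assert rm.respondent_ids == ("r1",)

    def test_header_only_is_empty_input(self, tmp_path):
        path = write_cohort(tmp_path, [])
        with pytest.raises(EmptyInputError):
            sn.load_responses(path)

    def test_non_numeric_cell_is_format_error_naming_cell(self, tmp_path):
        path = write_cohort(tmp_path, [[1] * 9, ["x"] + [1] * 8])
        with pytest.raises(FormatError, match="row 2.*phq1"):
            sn.load_responses(path)

    def test_fractional_cell_is_format_error(self, tmp_path):
        path = write_cohort(tmp_path, [[1.5] + [1] * 8])
        with pytest.raises(FormatError, match="non-integer"):
            sn.load_responses(path)

    def test_unmapped_columns_error(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text("a,b\n1,2\n")
        with pytest.raises(FormatError, match="unmapped"):
            sn.load_responses(path)

    def test_covariates_carried_through(self, tmp_path):
        path = tmp_path / "c.csv"
        path.write_text(
            "respondent_id," + ",".join(ITEMS) + ",age\n"
            "r1,2,2,2,2,2,2,2,2,2,41\n"
        )
        rm = sn.load_responses(
            path, ColumnConfig(covariate_columns=("age",))
        )
        assert list(rm.covariates["age"]) == [41]


@pytest.mark.parametrize(
    "scores, pattern",
    [
        ((1, 1, 1, 1, 1, 1, 1, 1, 2), "111111111"),
        ((0,) * 9, "000000000"),
        ((3, 2, 1, 3, 0, 0, 0, 0, 0), "111100000"),
    ],
)
def test_dichotomize_presence_at_score_one(scores, pattern):
    assert sn.dichotomize(scores).pattern == pattern


class TestMatchProfiles:
    def make_rm(self, rows):
        return sn.ResponseMatrix(
            scores=np.array(rows),
            respondent_ids=tuple(f"r{i}" for i in range(len(rows))),
        )

    def test_included_respondents_get_catalog_ids(self, phq_catalog):
        rm = self.make_rm([[1, 1, 1, 1, 1, 1, 1, 1, 2]])  # total 10
        matched = sn.match_profiles(rm, phq_catalog)
        assert matched.profile_ids[0] == 1

    def test_below_threshold_stays_unmatched(self, phq_catalog):
        rm = self.make_rm([[1] * 9])  # total 9
        matched = sn.match_profiles(rm, phq_catalog)
        assert matched.profile_ids[0] == NO_PROFILE
        assert matched.n_included == 0

    def test_four_symptom_profile_lookup(self, phq_catalog):
        rm = self.make_rm([[3, 3, 3, 1, 0, 0, 0, 0, 0]])  # total 10
        matched = sn.match_profiles(rm, phq_catalog)
        expected = phq_catalog.id_for(sn.SymptomProfile.from_pattern("111100000"))
        assert matched.profile_ids[0] == expected

    def test_catalog_threshold_mismatch_rejected(self):
        rm = self.make_rm([[2] * 9])
        other = sn.enumerate_catalog(sn.ProfileRule(threshold=12))
        with pytest.raises(InvalidArgumentError, match="does not match"):
            sn.match_profiles(rm, other)

    def test_random_cohort_matching_invariants(self, phq_catalog):
        """Everyone at/above the cutoff gets exactly one valid ID (>= 4
        present symptoms guarantees catalog membership); nobody below it
        is assigned one."""
        rng = np.random.default_rng(3)
        scores = rng.integers(0, 4, size=(300, 9))
        rm = sn.ResponseMatrix(
            scores=scores,
            respondent_ids=tuple(f"r{i}" for i in range(300)),
        )
        matched = sn.match_profiles(rm, phq_catalog)
        inc = matched.included
        assert np.array_equal(inc, matched.totals >= 10)
        assert np.all(matched.profile_ids[inc] >= 1)
        assert np.all(matched.profile_ids[~inc] == NO_PROFILE)
        assert np.all((scores[inc] >= 1).sum(axis=1) >= 4)


class TestFrequencyTable:
    def test_single_pattern_cohort_is_one_row_at_100(self, phq_catalog):
        rm = sn.ResponseMatrix(
            scores=np.tile([2] * 9, (5, 1)),
            respondent_ids=tuple(f"r{i}" for i in range(5)),
        )
        table = sn.frequency_table(sn.match_profiles(rm, phq_catalog), phq_catalog)
        assert len(table.table) == 1
        assert table.table["percent"].iloc[0] == 100.0
        assert table.coverage(1) == 100.0

    def test_planted_mixture_percents_near_weights(
        self, three_profile_cohort, phq_catalog
    ):
        """Weights 0.5/0.3/0.2 planted on catalog IDs 1, 2, 11."""
        table = sn.frequency_table(three_profile_cohort, phq_catalog)
        top = table.table.set_index("profile_id")
        assert list(table.table["profile_id"].head(3)) == [1, 2, 11]
        for pid, w in ((1, 50), (2, 30), (11, 20)):
            assert abs(top.loc[pid, "percent"] - w) < 3
        assert abs(table.coverage(2) - 80) < 3
        assert table.coverage(table.n_profiles_observed) == pytest.approx(100.0)

    def test_equal_counts_ranked_by_catalog_id(self, phq_catalog):
        rows = [[2] * 9] * 3 + [[2] * 8 + [0]] * 3
        rm = sn.ResponseMatrix(
            scores=np.array(rows),
            respondent_ids=tuple(f"r{i}" for i in range(6)),
        )
        table = sn.frequency_table(sn.match_profiles(rm, phq_catalog), phq_catalog)
        assert list(table.table["profile_id"]) == [1, 2]
        assert list(table.table["rank"]) == [1, 2]

    def test_percents_invariant_to_row_order(self, three_profile_cohort, phq_catalog):
        rng = np.random.default_rng(0)
        perm = rng.permutation(three_profile_cohort.n_respondents)
        shuffled = sn.ResponseMatrix(
            scores=three_profile_cohort.scores[perm],
            respondent_ids=tuple(
                three_profile_cohort.respondent_ids[i] for i in perm
            ),
        )
        t1 = sn.frequency_table(three_profile_cohort, phq_catalog).table
        t2 = sn.frequency_table(
            sn.match_profiles(shuffled, phq_catalog), phq_catalog
        ).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_descriptives_present(self, three_profile_cohort, phq_catalog):
        table = sn.frequency_table(three_profile_cohort, phq_catalog).table
        assert (table["mean_total"] >= 10).all()
        assert (table["sd_total"] >= 0).all()
        assert table["percent"].sum() == pytest.approx(100.0)

    def test_empty_cohort_warns_not_errors(self, phq_catalog):
        rm = sn.ResponseMatrix(
            scores=np.zeros((3, 9), dtype=int),
            respondent_ids=("a", "b", "c"),
        )
        matched = sn.match_profiles(rm, phq_catalog)
        with pytest.warns(UserWarning, match="no respondents"):
            table = sn.frequency_table(matched, phq_catalog)
        assert table.n_included == 0
        with pytest.warns(UserWarning, match="exceeds"):
            assert table.coverage(1) == 0.0

    def test_coverage_top_m_above_row_count_warns_total(
        self, three_profile_cohort, phq_catalog
    ):
        table = sn.frequency_table(three_profile_cohort, phq_catalog)
        with pytest.warns(UserWarning, match="exceeds"):
            assert table.coverage(999) == pytest.approx(100.0)
        with pytest.raises(InvalidArgumentError):
            table.coverage(0)


@pytest.mark.parametrize(
    "total, band",
    [(10, "moderate"), (14, "moderate"), (15, "moderately severe"),
     (19, "moderately severe"), (20, "severe"), (27, "severe")],
)
def test_severity_bands(total, band):
    assert sn.severity_band(total) == band


def test_response_matrix_round_trip(tmp_path, three_profile_cohort):
    """Export then re-import preserves scores, inclusion and matched IDs."""
    path = tmp_path / "matched.csv"
    three_profile_cohort.to_csv(path)
    back = sn.ResponseMatrix.from_csv(path)
    assert np.array_equal(back.scores, three_profile_cohort.scores)
    assert np.array_equal(back.included, three_profile_cohort.included)
    assert np.array_equal(back.profile_ids, three_profile_cohort.profile_ids)
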