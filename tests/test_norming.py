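"""The rank-based inverse-normal scaling core and its norm tables."""

import json

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import ndtri

from cognorm import norming
from cognorm.battery import DIRECTIONS, SUBTESTS
from cognorm.norming import (
    AgeBin,
    BinUnderflowError,
    CoverageError,
    IncompleteBatteryError,
    NormModel,
    build_norm_tables,
    default_age_bins,
    rank_inverse_normal,
    scale_without_age,
    score_subjects,
    single_age_bin,
)

from conftest import toy_cohort


def oracle_scale(values, direction="higher_better"):
    """Independent mid-rank enumeration oracle (no rankdata)."""
    x = np.asarray(values, dtype=float)
    perf = x if direction == "higher_better" else -x
    n = x.size
    out = np.empty(n)
    for i in range(n):
        less = np.sum(perf < perf[i])
        equal = np.sum(perf == perf[i])
        midrank = less + (equal + 1) / 2.0
        out[i] = 100.0 + 15.0 * ndtri((midrank - 0.5) / n)
    return out


class TestRankInverseNormal:
    def test_median_of_three_scores_exactly_100(self):
        out = rank_inverse_normal([1, 2, 3])
        assert out[1] == pytest.approx(100.0, abs=1e-12)

    def test_five_point_frozen_values(self):
        # high-precision inverse-erf oracle values for positions (i-0.5)/5
        expected = [80.7767, 92.1340, 100.0, 107.8660, 119.2233]
        out = rank_inverse_normal([10, 20, 30, 40, 50])
        assert out == pytest.approx(expected, abs=5e-4)

    def test_mean_exactly_100_and_sd_near_15(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(20_000)
        out = rank_inverse_normal(x)
        assert out.mean() == pytest.approx(100.0, abs=1e-9)
        assert out.std(ddof=1) == pytest.approx(15.0, abs=0.05)

    def test_lower_better_reverses_orientation(self):
        out = rank_inverse_normal([10.0, 20.0, 30.0], direction="lower_better")
        assert out[0] > 100.0 > out[2]

    def test_rankit_position_is_monotone_and_distinct(self):
        out = rank_inverse_normal([5, 1, 9, 3], position="rankit")
        assert np.all(np.diff(out[np.argsort([5, 1, 9, 3])]) > 0)

    @pytest.mark.parametrize(
        "bad", [[1.0], [], [1.0, np.nan, 2.0], [np.inf, 0.0]]
    )
    def test_invalid_input_rejected(self, bad):
        with pytest.raises(ValueError):
            rank_inverse_normal(bad)

    @given(
        st.lists(
            st.floats(-1e6, 1e6, allow_nan=False, allow_infinity=False),
            min_size=2,
            max_size=40,
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_properties_monotone_ties_and_symmetry(self, values):
        x = np.asarray(values)
        hi = rank_inverse_normal(x, "higher_better")
        lo = rank_inverse_normal(x, "lower_better")
        order = np.argsort(x, kind="stable")
        # monotone in performance, ties identical
        assert np.all(np.diff(hi[order]) >= -1e-9)
        for i in range(len(x)):
            same = x == x[i]
            assert np.allclose(hi[same], hi[i])
        # direction reversal mirrors around 100
        assert np.allclose(hi + lo, 200.0, atol=1e-9)

    def test_matches_enumeration_oracle_with_ties(self):
        x = [3.0, 1.0, 3.0, 7.0, 2.0, 2.0]
        for d in ("higher_better", "lower_better"):
            assert rank_inverse_normal(x, d) == pytest.approx(
                oracle_scale(x, d), abs=1e-10
            )


class TestAgeBins:
    def test_default_scheme_is_14_bins_partitioning_13_to_90(self):
        bins = default_age_bins()
        assert len(bins) == 14
        assert (bins[0].lower, bins[0].upper) == (13, 20)
        assert (bins[-1].lower, bins[-1].upper) == (80, 90)
        for a, b in zip(bins, bins[1:]):
            assert a.upper == b.lower
        assert all(b.upper - b.lower == 5 for b in bins[1:-1])


class TestBuildNormTables:
    def test_full_age_range_uses_all_14_bins(self):
        rng = np.random.default_rng(1)
        n = 700
        ages = rng.uniform(13, 89.9, n)
        cohort = toy_cohort(
            {s: list(rng.normal(20, 5, n)) for s in SUBTESTS}, ages=list(ages)
        )
        tables = build_norm_tables(cohort)
        for t in tables.values():
            assert len(t.bins) == 14

    def test_tied_raw_scores_share_scaled_score(self):
        cohort = toy_cohort({s: [10, 10, 12, 15, 9] for s in SUBTESTS})
        tables = build_norm_tables(cohort, single_age_bin())
        for s in SUBTESTS:
            t = tables[s]
            assert t.score(30, 10) == t.score(30, 10)
            scored = score_subjects(cohort, {s: t})
            col = scored[f"scaled_{s}"].to_numpy()
            assert col[0] == col[1]

    def test_toy_bin_equals_direct_transform(self):
        vals = [7.0, 3.0, 11.0, 5.0, 9.0]
        cohort = toy_cohort({s: vals for s in SUBTESTS})
        tables = build_norm_tables(cohort, single_age_bin())
        direct = rank_inverse_normal(vals, DIRECTIONS["matrices"])
        scored = score_subjects(cohort, tables)
        assert scored["scaled_matrices"].to_numpy() == pytest.approx(direct)

    def test_small_bins_match_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        for size in range(2, 9):
            vals = np.round(rng.normal(20, 4, size), 1)
            cohort = toy_cohort({s: list(vals) for s in SUBTESTS})
            tables = build_norm_tables(cohort, single_age_bin())
            for s in ("trail_a_s", "matrices"):
                scored = score_subjects(cohort, {s: tables[s]})
                assert scored[f"scaled_{s}"].to_numpy() == pytest.approx(
                    oracle_scale(vals, DIRECTIONS[s]), abs=1e-10
                )

    def test_underfilled_bin_raises_naming_it(self):
        cohort = toy_cohort(
            {s: [10, 11, 12] for s in SUBTESTS}, ages=[30, 31, 50]
        )
        scheme = [AgeBin(25, 45), AgeBin(45, 55)]
        with pytest.raises(BinUnderflowError, match="45-54"):
            build_norm_tables(cohort, scheme)

    def test_age_outside_bins_raises(self):
        cohort = toy_cohort({s: [10, 11] for s in SUBTESTS}, ages=[30, 95])
        with pytest.raises(CoverageError):
            build_norm_tables(cohort)


class TestScoreSubjects:
    def test_median_subject_scores_100_everywhere(self):
        # subject 2 sits at the median of every subtest and of the sum
        raws = {s: [10.0, 12.0, 14.0, 16.0, 18.0] for s in SUBTESTS}
        cohort = toy_cohort(raws)
        model = NormModel.fit(cohort, single_age_bin())
        scored = model.score(cohort)
        # trails are lower_better: median is still the middle value
        for s in SUBTESTS:
            assert scored[f"scaled_{s}"].iloc[2] == pytest.approx(100.0)
        assert scored["grand_index"].iloc[2] == pytest.approx(100.0)

    def test_grand_index_matches_bruteforce_two_subtest_battery(self):
        rng = np.random.default_rng(11)
        pair = ("matrices", "arithmetic")
        vals = {s: rng.normal(15, 4, 5) for s in pair}
        cohort = toy_cohort({s: list(v) for s, v in vals.items()})
        tables = build_norm_tables(cohort, single_age_bin(), subtests=pair)
        scored = score_subjects(cohort, tables)
        # oracle: scale each subtest, sum, re-rank, re-transform
        sums = oracle_scale(vals[pair[0]]) + oracle_scale(vals[pair[1]])
        gi = oracle_scale(sums)
        assert scored["grand_index"].to_numpy() == pytest.approx(gi, abs=1e-10)

    def test_rescoring_norming_cohort_is_bit_identical(self, small_cohort):
        model = NormModel.fit(small_cohort)
        first = model.score(small_cohort)
        second = model.score(small_cohort)
        pd.testing.assert_frame_equal(first, second)
        # and the Grand Index has the advertised location
        assert first["grand_index"].mean() == pytest.approx(100.0, abs=0.2)

    def test_unseen_values_clamp_monotonically(self):
        vals = [10.0, 20.0, 30.0, 40.0, 50.0]
        cohort = toy_cohort({s: vals for s in SUBTESTS})
        tables = build_norm_tables(cohort, single_age_bin())
        t = tables["matrices"]  # higher_better
        assert t.score(30, 5.0) == t.score(30, 10.0)  # below range clamps
        assert t.score(30, 99.0) == t.score(30, 50.0)  # above range clamps
        assert t.score(30, 25.0) == t.score(30, 20.0)  # floors to worse side
        tt = tables["trail_a_s"]  # lower_better: worse side is slower
        assert tt.score(30, 25.0) == tt.score(30, 30.0)

    def test_missing_subtest_raises(self, small_cohort):
        model = NormModel.fit(small_cohort)
        broken = small_cohort.copy()
        broken.loc[3, "matrices"] = np.nan
        with pytest.raises(IncompleteBatteryError):
            model.score(broken)

    def test_age_not_covered_raises(self, small_cohort):
        model = NormModel.fit(small_cohort)
        broken = small_cohort.copy()
        broken.loc[0, "age"] = 95.0
        with pytest.raises(CoverageError):
            model.score(broken)


class TestScaleWithoutAge:
    def test_equals_single_bin_norm_tables(self, small_cohort):
        direct = scale_without_age(small_cohort)
        tables = build_norm_tables(small_cohort, single_age_bin())
        scored = score_subjects(small_cohort, tables)
        for s in SUBTESTS:
            assert direct[f"scaled_{s}"].to_numpy() == pytest.approx(
                scored[f"scaled_{s}"].to_numpy()
            )

    def test_median_subject_sums_to_800(self):
        raws = {s: [10.0, 12.0, 14.0, 16.0, 18.0] for s in SUBTESTS}
        out = scale_without_age(toy_cohort(raws))
        assert out["sum_score"].iloc[2] == pytest.approx(800.0)

    def test_age_gradient_visible_only_without_age_norming(self, small_cohort):
        plain = scale_without_age(small_cohort)
        model = NormModel.fit(small_cohort)
        scored = model.score(small_cohort)
        age = small_cohort["age"]
        r_plain = np.corrcoef(plain["sum_score"], age)[0, 1]
        r_normed = np.corrcoef(scored["grand_index"], age)[0, 1]
        assert r_plain < -0.1  # built-in ageing gradient
        assert abs(r_normed) < 0.05  # age-norming removes it


class TestNormModelSerialization:
    def test_json_round_trip_is_lossless(self, small_cohort, tmp_path):
        from cognorm.io import read_norm_tables, write_norm_tables

        model = NormModel.fit(small_cohort)
        path = tmp_path / "norms.json"
        write_norm_tables(model, path)
        loaded = read_norm_tables(path)
        for s in SUBTESTS:
            for b1, b2 in zip(model.tables[s].bins, loaded.tables[s].bins):
                assert np.array_equal(b1.raw, b2.raw)
                assert np.array_equal(b1.scaled, b2.scaled)
        assert np.array_equal(model.aggregate.raw, loaded.aggregate.raw)
        pd.testing.assert_frame_equal(
            model.score(small_cohort), loaded.score(small_cohort)
        )

    def test_truncated_file_rejected(self, small_cohort, tmp_path):
        from cognorm.io import read_norm_tables, write_norm_tables

        model = NormModel.fit(small_cohort)
        path = tmp_path / "norms.json"
        write_norm_tables(model, path)
        path.write_text(path.read_text()[:100])
        with pytest.raises(ValueError):
            read_norm_tables(path)

    def test_version_mismatch_rejected(self, small_cohort, tmp_path):
        from cognorm.io import read_norm_tables, write_norm_tables

        model = NormModel.fit(small_cohort)
        path = tmp_path / "norms.json"
        write_norm_tables(model, path)
        payload = json.loads(path.read_text())
        payload["format_version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(ValueError, match="version"):
            read_norm_tables(path)
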