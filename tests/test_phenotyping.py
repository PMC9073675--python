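"""Mrt classification rules, timing summaries, and the two-sample comparison."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_line, table_from_lines
from mrtline.phenotyping import (
    MRT_SEVERITY,
    LineAssay,
    MrtClass,
    ReplicateOutcome,
    classify_line,
    classify_table,
    compare_time_to_failure,
    mean_time_to_sterility,
)
from mrtline.synthetic_data import AssayDesign, SyntheticConfig, generate_assay_table


class TestMeanTimeToSterility:
    @pytest.mark.parametrize(
        "gens, n_cens, expected_mean, expected_sterile, expected_cens",
        [
            ([6, 6, 6], 0, 6.0, 3, 0),
            ([12, 15], 1, 13.5, 2, 1),
            ([], 3, None, 0, 3),
        ],
    )
    def test_examples(self, gens, n_cens, expected_mean, expected_sterile, expected_cens):
        res = mean_time_to_sterility(make_line(gens, n_cens))
        assert res.mean == expected_mean
        assert res.n_sterile == expected_sterile
        assert res.n_censored == expected_cens

    def test_non_mrt_failures_excluded(self):
        # two low-fitness deaths at generation 2 must not drag the mean down
        res = mean_time_to_sterility(make_line([2, 2, 12, 16], non_mrt=2))
        assert res.mean == 14.0
        assert res.n_sterile == 2

    def test_empty_line_rejected(self):
        with pytest.raises(ValueError):
            LineAssay(line_id="L1", outcomes=[], horizon=21)


class TestClassifyLine:
    @pytest.mark.parametrize(
        "gens, n_cens, horizon, non_mrt, expected",
        [
            # heat-sensitive sterile: all 10 replicates sterile at generation 1
            ([1] * 10, 0, 21, 0, MrtClass.TS_STERILE),
            # strong Mrt: mean 6.4 < 10, max 10 < 15, all sterile
            ([4, 5, 5, 6, 6, 6, 7, 7, 8, 10], 0, 21, 0, MrtClass.STRONG),
            # moderate: all sterile by 21, mean 13 < 16, max 17 kills strong
            ([9, 11, 12, 13, 13, 14, 14, 15, 16, 17], 0, 21, 0, MrtClass.MODERATE),
            # weak: mean 13.5 < 16 but one replicate fertile at 21; 2/3 sterile
            ([12, 15], 1, 21, 0, MrtClass.WEAK),
            # wild type: 1 of 3 sterile (EG4349-style pattern)
            ([5], 2, 21, 0, MrtClass.WILD_TYPE),
            # all censored
            ([], 10, 21, 0, MrtClass.WILD_TYPE),
            # majority of replicates are non-Mrt failures: excluded
            ([3, 4, 4, 5, 5, 6], 4, 21, 6, MrtClass.EXCLUDED_LOW_FITNESS),
            # strong is still scorable at horizon 14
            ([4, 5, 5, 6, 6, 6, 7, 7, 8, 10], 0, 14, 0, MrtClass.STRONG),
            # but a moderate-looking pattern at horizon 14 cannot be scored
            ([10, 11, 11, 12, 12, 13, 13, 13, 14, 14], 0, 14, 0, MrtClass.WILD_TYPE),
            # nor can a weak-looking one
            ([10, 11, 12, 12, 13, 13, 13], 3, 14, 0, MrtClass.WILD_TYPE),
        ],
    )
    def test_rules(self, gens, n_cens, horizon, non_mrt, expected):
        line = make_line(gens, n_cens, horizon=horizon, non_mrt=non_mrt)
        assert classify_line(line) is expected

    def test_strict_thresholds(self):
        # mean exactly 10 is not "less than 10"
        assert classify_line(make_line([10] * 10)) is MrtClass.MODERATE
        # max exactly 15 is not "less than 15"
        assert classify_line(make_line([5] * 9 + [15])) is MrtClass.MODERATE

    def test_sterile_generation_beyond_horizon_rejected(self):
        with pytest.raises(ValueError, match="horizon"):
            make_line([16], horizon=14)


# -- property tests ---------------------------------------------------------

@settings(max_examples=200, derandomize=True)
@given(
    gens=st.lists(st.integers(min_value=1, max_value=21), max_size=10),
    n_censored=st.integers(min_value=0, max_value=10),
    non_mrt=st.integers(min_value=0, max_value=3),
)
def test_partition_exactly_one_class(gens, n_censored, non_mrt):
    """Every line receives exactly one class from the enumeration."""
    if not gens and n_censored == 0:
        n_censored = 1
    line = make_line(gens, n_censored, non_mrt=non_mrt)
    assert classify_line(line) in MrtClass


@settings(max_examples=200, derandomize=True)
@given(
    gens=st.lists(st.integers(min_value=2, max_value=21), min_size=1, max_size=10),
    n_censored=st.integers(min_value=0, max_value=5),
    data=st.data(),
)
def test_monotonicity_stronger_data_never_weakens_class(gens, n_censored, data):
    """Earlier sterility / fewer survivors can only strengthen the class."""
    before = classify_line(make_line(gens, n_censored))
    # decrease every sterile generation by up to gen-1, convert one censored
    # replicate (if any) to sterile at the horizon
    new_gens = [data.draw(st.integers(min_value=1, max_value=g)) for g in gens]
    new_cens = n_censored - 1 if n_censored else 0
    if n_censored:
        new_gens = new_gens + [21]
    after = classify_line(make_line(new_gens, new_cens))
    assert MRT_SEVERITY[after] >= MRT_SEVERITY[before]


class TestClassifyTable:
    def test_empty_table(self):
        per_line, counts = classify_table(table_from_lines({}))
        assert len(per_line) == 0
        assert sum(counts.values()) == 0

    def test_counts_sum_and_diagnostics(self):
        table = table_from_lines(
            {"A": ([1] * 10, 0), "B": ([4, 5, 6], 0), "C": ([5], 2), "D": ([12, 15], 1)}
        )
        per_line, counts = classify_table(table)
        assert sum(counts.values()) == 4
        by_line = per_line.set_index("line_id")["mrt_class"]
        assert by_line["A"] == "ts_sterile"
        assert by_line["B"] == "strong"
        assert by_line["C"] == "wild_type"
        assert by_line["D"] == "weak"
        assert per_line.set_index("line_id").loc["D", "mean_time_to_sterility"] == 13.5

    def test_duplicate_keys_rejected(self):
        table = table_from_lines({"A": ([4, 5], 0)})
        table.loc[1, "replicate_id"] = "r01"
        with pytest.raises(ValueError, match="duplicate"):
            classify_table(table)

    def test_mixture_recovery_on_synthetic_table(self):
        """Classifying a generated table recovers the generating mixture."""
        mixture = {"strong": 0.25, "moderate": 0.25, "weak": 0.2, "wild_type": 0.3}
        n_lines = 10_000
        config = SyntheticConfig(AssayDesign(n_lines, 10, 21), mixture, seed=11)
        table = generate_assay_table(config)
        _, counts = classify_table(table)
        for cls, p in mixture.items():
            se = np.sqrt(n_lines * p * (1 - p))
            assert abs(counts[cls] - n_lines * p) < 3 * se, cls


class TestCompareTimeToFailure:
    def test_identical_tables(self):
        table = table_from_lines({"A": ([4, 9, 13], 1), "B": ([2, 18], 2)})
        res = compare_time_to_failure(table, table.copy(), n_permutations=99, seed=0)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_shifted_distributions_detected(self, rng):
        """An 8-generation shift with 100 replicates per arm is near-certain to reject."""
        rejections = 0
        for trial in range(20):
            a = rng.integers(3, 9, size=100)
            b = a + 8
            ta = pd.DataFrame(
                {
                    "line_id": "A",
                    "replicate_id": [f"r{i}" for i in range(100)],
                    "sterile_generation": a,
                    "censored": 0,
                    "failure_mode": "mrt_sterile",
                }
            )
            tb = ta.assign(sterile_generation=b)
            res = compare_time_to_failure(ta, tb, n_permutations=199, seed=trial)
            rejections += res.p_value <= 0.05
        assert rejections >= 19

    def test_invalid_permutation_count(self):
        table = table_from_lines({"A": ([4], 0)})
        with pytest.raises(ValueError):
            compare_time_to_failure(table, table, n_permutations=0)
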