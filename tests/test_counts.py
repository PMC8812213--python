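import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st

from tpdscan import (
    BinGrid,
    DayWindow,
    brute_force_counts,
    compute_counts,
    derive_index_exposures,
    load_counts,
    save_counts,
    validate_cohort,
)
from tpdscan.counts import cohort_fingerprint, is_observed
from tpdscan.errors import StaleCacheError, TpdError

from conftest import small_random_cohort

W_SURV = DayWindow(1, 30)
W_CTRL = DayWindow(-180, -1)


class TestDayWindow:
    def test_rejects_empty_interval(self):
        with pytest.raises(ValueError):
            DayWindow(5, 1)

    @pytest.mark.parametrize("start,end", [(-5, 5), (0, 10), (-10, 0), (0, 0)])
    def test_rejects_intervals_containing_day_zero(self, start, end):
        with pytest.raises(ValueError):
            DayWindow(start, end)

    def test_day_count(self):
        assert DayWindow(1, 30).n_days == 30
        assert DayWindow(-180, -1).n_days == 180


class TestBinGrid:
    def test_positive_and_negative_bin_edges(self):
        grid = BinGrid(bin_width_days=30, min_bin=-2, max_bin=2)
        assert grid.window(1) == DayWindow(1, 30)
        assert grid.window(2) == DayWindow(31, 60)
        assert grid.window(-1) == DayWindow(-30, -1)
        assert grid.window(-2) == DayWindow(-60, -31)

    def test_no_bin_zero_and_full_day_coverage(self):
        grid = BinGrid(bin_width_days=7, min_bin=-3, max_bin=3)
        assert 0 not in grid.bins
        days = sorted(
            d for w in grid.windows().values() for d in range(w.start_day, w.end_day + 1)
        )
        assert days == [d for d in range(-21, 22) if d != 0]

    def test_rejects_degenerate_grids(self):
        with pytest.raises(ValueError):
            BinGrid(bin_width_days=0)
        with pytest.raises(ValueError):
            BinGrid(min_bin=1, max_bin=3)


class TestIndexExposures:
    def test_earliest_exposure_wins(self):
        cohort = validate_cohort(
            pd.DataFrame(
                {"person_id": [1, 1], "drug_id": ["A", "A"], "day": [50, 10]}
            ),
            pd.DataFrame(columns=["person_id", "condition_id", "day"]),
            pd.DataFrame({"person_id": [1], "start_day": [0], "end_day": [100]}),
        )
        idx = derive_index_exposures(cohort)
        assert len(idx) == 1
        assert int(idx.index_day.iloc[0]) == 10

    def test_one_index_per_drug(self):
        cohort = validate_cohort(
            pd.DataFrame(
                {"person_id": [1, 1], "drug_id": ["A", "B"], "day": [10, 20]}
            ),
            pd.DataFrame(columns=["person_id", "condition_id", "day"]),
            pd.DataFrame({"person_id": [1], "start_day": [0], "end_day": [100]}),
        )
        assert len(derive_index_exposures(cohort)) == 2

    def test_same_date_duplicates_collapse(self):
        cohort = validate_cohort(
            pd.DataFrame(
                {
                    "person_id": [1, 1, 2, 2, 3],
                    "drug_id": ["A", "A", "A", "B", "A"],
                    "day": [10, 10, 20, 20, 30],
                }
            ),
            pd.DataFrame(columns=["person_id", "condition_id", "day"]),
            pd.DataFrame(
                {"person_id": [1, 2, 3], "start_day": [0] * 3, "end_day": [100] * 3}
            ),
        )
        idx = derive_index_exposures(cohort)
        assert len(idx) == 4  # (1,A), (2,A), (2,B), (3,A)


class TestIsObserved:
    def test_window_inside_period(self):
        assert is_observed(100, W_SURV, 0, 400)

    def test_window_after_period_end(self):
        assert not is_observed(390, DayWindow(20, 40), 0, 400)

    def test_single_day_overlap_counts(self):
        # window [index+1, index+30] with period ending exactly at index+1
        assert is_observed(100, W_SURV, 0, 101)
        assert not is_observed(100, W_SURV, 0, 100)
        # and at the other edge: period starting at index+30
        assert is_observed(100, W_SURV, 130, 400)
        assert not is_observed(100, W_SURV, 131, 400)


class TestWorkedFixtureCounts:
    def test_surveillance_window(self, worked_store):
        assert worked_store.c(W_SURV) == 3
        assert worked_store.cx("A", W_SURV) == 2
        assert worked_store.cx("B", W_SURV) == 1
        assert worked_store.cy("Y", W_SURV) == 1
        assert worked_store.cxy("A", "Y", W_SURV) == 1
        assert worked_store.cxy("B", "Y", W_SURV) == 0

    def test_control_window(self, worked_store):
        assert worked_store.cy("Y", W_CTRL) == 1  # P3's pre-index event
        assert worked_store.cxy("A", "Y", W_CTRL) == 0
        assert worked_store.cxy("B", "Y", W_CTRL) == 1

    def test_empty_cohort_all_zero(self, empty_cohort):
        store = compute_counts(empty_cohort, [W_SURV])
        assert store.c(W_SURV) == 0
        assert not store.CX and not store.CY and not store.CXY


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["distinct", "all"])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_on_random_cohorts(self, seed, mode):
        cohort = small_random_cohort(seed)
        windows = [W_SURV, W_CTRL, DayWindow(-30, -1)]
        fast = compute_counts(cohort, windows, mode=mode)
        slow = brute_force_counts(cohort, windows, mode=mode)
        assert fast.equals(slow)

    def test_all_mode_dominates_distinct_on_repeat_exposures(self):
        cohort = validate_cohort(
            pd.DataFrame(
                {"person_id": [1, 1], "drug_id": ["A", "A"], "day": [100, 200]}
            ),
            pd.DataFrame({"person_id": [1], "condition_id": ["Y"], "day": [210]}),
            pd.DataFrame({"person_id": [1], "start_day": [0], "end_day": [400]}),
        )
        w = W_SURV
        distinct = compute_counts(cohort, [w], mode="distinct")
        both = compute_counts(cohort, [w], mode="all")
        assert both.c(w) == 2 and distinct.c(w) == 1
        # distinct anchors at day 100: Y@210 is outside [101,130]
        assert distinct.cxy("A", "Y", w) == 0
        # all mode's second occurrence (day 200) catches Y@210
        assert both.cxy("A", "Y", w) == 1
        assert all(both.C[win] >= distinct.C[win] for win in distinct.C)


class TestStoreInvariants:
    @pytest.mark.parametrize("mode", ["distinct", "all"])
    def test_dominance_chain_on_random_cohort(self, mode):
        cohort = small_random_cohort(7)
        store = compute_counts(cohort, [W_SURV, W_CTRL], mode=mode)
        for (x, y, w), v in store.CXY.items():
            assert 0 <= v <= min(store.cx(x, w), store.cy(y, w)) <= store.c(w)

    def test_cx_sums_to_c(self):
        cohort = small_random_cohort(8)
        store = compute_counts(cohort, [W_SURV, W_CTRL])
        for w in store.windows:
            assert sum(v for (x, wx), v in store.CX.items() if wx == w) == store.c(w)

    @given(st.integers(min_value=0, max_value=10_000))
    @hyp_settings(max_examples=8, deadline=None, derandomize=True)
    def test_window_monotonicity(self, seed):
        """Enlarging a window never decreases any count."""
        cohort = small_random_cohort(seed % 50, n_persons=60)
        small, big = DayWindow(1, 15), DayWindow(1, 30)
        store = compute_counts(cohort, [small, big])
        assert store.c(big) >= store.c(small)
        for (x, w), v in store.CX.items():
            if w == small:
                assert store.cx(x, big) >= v
        for (y, w), v in store.CY.items():
            if w == small:
                assert store.cy(y, big) >= v
        for (x, y, w), v in store.CXY.items():
            if w == small:
                assert store.cxy(x, y, big) >= v


class TestCache:
    def test_skip_baseline_matches_fresh_computation(self):
        cohort = small_random_cohort(9)
        windows = [W_SURV, W_CTRL]
        fresh = compute_counts(cohort, windows)
        cached = compute_counts(
            cohort, windows, baseline_cache=fresh, skip_baseline=True
        )
        assert cached.equals(fresh)

    def test_tampered_fingerprint_raises(self):
        cohort = small_random_cohort(9)
        windows = [W_SURV]
        cache = compute_counts(cohort, windows)
        cache.fingerprint = "0:0:0:deadbeefdeadbeef"
        with pytest.raises(StaleCacheError, match="fingerprint"):
            compute_counts(cohort, windows, baseline_cache=cache, skip_baseline=True)

    def test_different_cohort_invalidates_cache(self):
        cache = compute_counts(small_random_cohort(9), [W_SURV])
        other = small_random_cohort(10)
        with pytest.raises(StaleCacheError):
            compute_counts(other, [W_SURV], baseline_cache=cache, skip_baseline=True)

    def test_mode_and_window_mismatches_raise(self):
        cohort = small_random_cohort(9)
        cache = compute_counts(cohort, [W_SURV], mode="distinct")
        with pytest.raises(StaleCacheError, match="mode"):
            compute_counts(cohort, [W_SURV], mode="all", baseline_cache=cache, skip_baseline=True)
        with pytest.raises(StaleCacheError, match="window"):
            compute_counts(cohort, [W_SURV, W_CTRL], baseline_cache=cache, skip_baseline=True)

    def test_skip_without_cache_raises(self):
        with pytest.raises(StaleCacheError):
            compute_counts(small_random_cohort(9), [W_SURV], skip_baseline=True)


class TestPersistence:
    def test_round_trip(self, worked_store, tmp_path):
        path = str(tmp_path / "store.csv")
        save_counts(worked_store, path)
        assert load_counts(path).equals(worked_store)

    def test_empty_store_round_trip(self, empty_cohort, tmp_path):
        store = compute_counts(empty_cohort, [W_SURV])
        path = str(tmp_path / "store.csv")
        save_counts(store, path)
        assert load_counts(path).equals(store)

    def test_loaded_store_usable_as_cache(self, tmp_path):
        cohort = small_random_cohort(11)
        store = compute_counts(cohort, [W_SURV])
        path = str(tmp_path / "store.csv")
        save_counts(store, path)
        again = compute_counts(
            cohort, [W_SURV], baseline_cache=load_counts(path), skip_baseline=True
        )
        assert again.equals(store)

    def test_corrupt_file_raises_format_error(self, tmp_path):
        path = tmp_path / "store.csv"
        path.write_text("not,a,store\n1,2,3\n")
        (tmp_path / "store.csv.meta.json").write_text("{}")
        with pytest.raises((TpdError, KeyError)):
            load_counts(str(path))


def test_fingerprint_is_order_insensitive(worked_cohort):
    shuffled = validate_cohort(
        worked_cohort.exposures.sample(frac=1, random_state=5),
        worked_cohort.conditions.sample(frac=1, random_state=6),
        worked_cohort.observation,
    )
    assert cohort_fingerprint(shuffled) == cohort_fingerprint(worked_cohort)


def test_fingerprint_changes_with_content(worked_cohort):
    altered = validate_cohort(
        worked_cohort.exposures.assign(day=worked_cohort.exposures.day + 1),
        worked_cohort.conditions,
        worked_cohort.observation,
    )
    assert cohort_fingerprint(altered) != cohort_fingerprint(worked_cohort)
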