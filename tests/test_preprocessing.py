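import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ventrl.preprocessing import (
    VentilationEvent,
    define_ventilation_events,
    estimate_hold_limits,
    hold_event,
    ideal_body_weight,
    impute,
    missingness_diagnostic,
    sample_and_hold,
    svd_complete,
    tukey_outlier_filter,
)
from ventrl.trajectory_io import DEFAULT_MANIFEST, TrajectoryTable
from conftest import tiny_cohort_frame

NAMES = DEFAULT_MANIFEST.names


def _stay_frame(stay_id, vt, peep, fio2, flags=None, n_bins=None, outcome="survived"):
    """Build a single-stay frame from per-bin setting lists (None = missing)."""
    n_bins = n_bins or len(vt)
    flags = flags or {}
    rng = np.random.default_rng(0)
    rows = []
    for b in range(n_bins):
        row = {
            "stay_id": stay_id, "time_bin": b,
            "height_cm": 170.0, "sex": "male", "age_years": 55.0,
            "outcome": outcome,
            "extubation": b in flags.get("extubation", ()),
            "niv_start": b in flags.get("niv_start", ()),
            "suppl_o2": b in flags.get("suppl_o2", ()),
            "withdrawal": b in flags.get("withdrawal", ()),
            "vt_set_ml": vt[b] if b < len(vt) and vt[b] is not None else np.nan,
            "peep_cmh2o": peep[b] if b < len(peep) and peep[b] is not None else np.nan,
            "fio2_pct": fio2[b] if b < len(fio2) and fio2[b] is not None else np.nan,
        }
        row.update({nm: float(rng.normal()) for nm in NAMES})
        rows.append(row)
    return pd.DataFrame(rows)


def _table(*frames):
    return TrajectoryTable(df=pd.concat(frames, ignore_index=True), manifest=DEFAULT_MANIFEST)


class TestEventDefinition:
    def test_vt_onset_peep_continuation_extubation_end(self):
        """Vt at bin 1, PEEP through bin 8, extubation at 9: one event of 8
        post-onset bins."""
        n = 12
        vt = [None, 450.0] + [None] * (n - 2)
        peep = [None, None] + [6.0] * 7 + [None] * 3
        fio2 = [None] * n
        table = _table(_stay_frame("a", vt, peep, fio2, flags={"extubation": (9,)}))
        events = define_ventilation_events(table)
        assert len(events) == 1
        ev = events[0]
        assert ev.onset_bin == 1
        assert ev.n_post_onset_bins == 8

    def test_short_event_excluded(self):
        """An event of 20 h (5 bins) fails the 24-h minimum-duration filter."""
        vt = [None, 450.0, 450.0, 450.0, 450.0, 450.0] + [None] * 6
        table = _table(_stay_frame("a", vt, [None] * 12, [None] * 12))
        assert define_ventilation_events(table) == []

    def test_only_first_of_two_events_kept(self):
        """Settings at bins 1-7, an 8-h+ gap, then settings again: only the
        first event is returned."""
        vt = [None] + [450.0] * 7 + [None, None, None] + [500.0] * 6
        table = _table(_stay_frame("a", vt, [None] * 17, [None] * 17, n_bins=17))
        events = define_ventilation_events(table)
        assert len(events) == 1
        assert events[0].onset_bin == 1
        assert not np.any(np.nan_to_num(events[0].vt_set_ml) == 500.0)

    def test_gap_terminates_event(self):
        """No setting documented for more than two sample periods ends the event."""
        vt = [None] + [450.0] * 7 + [None] * 10
        table = _table(_stay_frame("a", vt, [None] * 18, [None] * 18))
        ev = define_ventilation_events(table)[0]
        assert ev.bins.max() <= 9  # held at most CONTINUATION_BINS past bin 7

    def test_age_filter(self):
        vt = [None] + [450.0] * 8
        frame = _stay_frame("a", vt, [None] * 9, [None] * 9)
        frame["age_years"] = 17.0
        assert define_ventilation_events(_table(frame)) == []

    def test_withdrawal_filter(self):
        vt = [None] + [450.0] * 8
        table = _table(_stay_frame("a", vt, [None] * 9, [None] * 9,
                                   flags={"withdrawal": (4,)}))
        assert define_ventilation_events(table) == []

    def test_idempotent_on_clean_stay(self):
        vt = [None] + [450.0] * 8
        table = _table(_stay_frame("a", vt, [None] * 9, [None] * 9))
        ev1 = define_ventilation_events(table)
        ev2 = define_ventilation_events(table)
        assert len(ev1) == len(ev2) == 1
        np.testing.assert_array_equal(ev1[0].bins, ev2[0].bins)


class TestHoldLimits:
    def _table_with_gaps(self, gap):
        df = tiny_cohort_frame(n_stays=2, n_bins=10)
        feat = NAMES[0]
        df[feat] = np.nan
        df.loc[df["time_bin"] % gap == 0, feat] = 1.0
        return TrajectoryTable(df=df, manifest=DEFAULT_MANIFEST)

    def test_every_bin_gives_limit_one(self):
        limits = estimate_hold_limits(self._table_with_gaps(1))
        assert limits[NAMES[0]] == 1

    def test_every_third_bin_gives_limit_three(self):
        limits = estimate_hold_limits(self._table_with_gaps(3))
        assert limits[NAMES[0]] == 3

    def test_median_of_mixed_gaps(self):
        """Observations at bins 0,1,2,7 give gaps {1,1,5}: median 1."""
        df = tiny_cohort_frame(n_stays=1, n_bins=10)
        feat = NAMES[1]
        df[feat] = np.nan
        df.loc[df["time_bin"].isin([0, 1, 2, 7]), feat] = 2.0
        limits = estimate_hold_limits(TrajectoryTable(df=df, manifest=DEFAULT_MANIFEST))
        assert limits[feat] == 1

    def test_sparse_feature_gets_fallback(self):
        df = tiny_cohort_frame(n_stays=1, n_bins=10)
        feat = NAMES[2]
        df[feat] = np.nan
        df.loc[df["time_bin"] == 0, feat] = 5.0
        limits = estimate_hold_limits(
            TrajectoryTable(df=df, manifest=DEFAULT_MANIFEST), fallback=4
        )
        assert limits[feat] == 4

    def test_empty_table_raises(self):
        df = tiny_cohort_frame().iloc[0:0]
        with pytest.raises(ValueError):
            estimate_hold_limits(TrajectoryTable(df=df, manifest=DEFAULT_MANIFEST))


class TestSampleAndHold:
    @pytest.mark.parametrize(
        "series,limit,expected",
        [
            ([7, np.nan, np.nan, np.nan], 2, [7, 7, 7, np.nan]),
            ([1, 2, 3], 1, [1, 2, 3]),
            ([np.nan, 3, np.nan], 1, [np.nan, 3, 3]),
        ],
    )
    def test_examples(self, series, limit, expected):
        np.testing.assert_array_equal(sample_and_hold(np.array(series, float), limit),
                                      np.array(expected, float))

    @given(
        data=st.lists(st.one_of(st.none(), st.floats(-50, 50)), min_size=1, max_size=30),
        limit=st.integers(1, 5),
    )
    @settings(max_examples=200, deadline=None)
    def test_never_fills_beyond_limit(self, data, limit):
        """Every filled cell has an observation within ``limit`` bins before
        it, and observed cells are untouched."""
        series = np.array([np.nan if v is None else v for v in data])
        out = sample_and_hold(series, limit)
        for i in range(len(series)):
            if np.isnan(series[i]) and not np.isnan(out[i]):
                window = series[max(0, i - limit): i]
                assert np.any(~np.isnan(window))
                src = np.where(~np.isnan(series[: i]))[0][-1]
                assert out[i] == series[src]
            elif not np.isnan(series[i]):
                assert out[i] == series[i]


class TestTukey:
    def test_hand_computed_fence_flags_extreme(self):
        """For {1..9, 100}: Q1=3, Q3=8 (linear interpolation), fences
        [-4.5, 15.5], so only 100 is flagged."""
        vals = np.array([1, 2, 3, 4, 5, 6, 7, 8, 9, 100], float)
        mask = tukey_outlier_filter(vals)
        assert mask.sum() == 1 and mask[-1]

    def test_constant_series_unflagged(self):
        assert not tukey_outlier_filter(np.full(20, 3.0)).any()

    def test_one_to_nine_unflagged(self):
        assert not tukey_outlier_filter(np.arange(1.0, 10.0)).any()

    def test_missing_cells_never_flagged(self):
        vals = np.array([1, 2, 3, 4, 5, np.nan, 100], float)
        mask = tukey_outlier_filter(vals)
        assert not mask[5]

    def test_frequency_interval_mode_tightens(self):
        vals = np.concatenate([np.linspace(0, 1, 100), [1.4]])
        loose = tukey_outlier_filter(vals, frequency_interval=False)
        tight = tukey_outlier_filter(vals, frequency_interval=True)
        assert tight.sum() >= loose.sum()


def _event_from_features(features, stay_id="e", outcome="survived"):
    n = features.shape[0]
    return VentilationEvent(
        stay_id=stay_id, onset_bin=1, bins=np.arange(1, n + 1),
        features=features, vt_set_ml=np.full(n, 400.0),
        peep_cmh2o=np.full(n, 6.0), fio2_pct=np.full(n, 40.0),
        outcome=outcome, ibw_kg=60.0,
    )


class TestImpute:
    def test_over_half_missing_event_discarded(self):
        rng = np.random.default_rng(0)
        feats = rng.normal(size=(8, 44))
        mask = rng.random(feats.shape) < 0.6
        feats[mask] = np.nan
        assert mask.mean() > 0.5
        good = _event_from_features(rng.normal(size=(8, 44)), "good")
        bad = _event_from_features(feats, "bad")
        kept, diag = impute([good, bad], DEFAULT_MANIFEST)
        assert [e.stay_id for e in kept] == ["good"]
        assert diag.n_events_discarded == 1

    def test_discard_rule_exact_boundary(self):
        """An event at exactly 50% missing survives; just above is dropped."""
        feats = np.ones((2, 44))
        feats[0, :] = np.nan  # exactly half missing
        ev = _event_from_features(feats)
        kept, diag = impute([ev], DEFAULT_MANIFEST)
        assert len(kept) == 1 and diag.n_events_discarded == 0

    def test_knn_twin_row_recovery(self):
        """With one row the exact twin of another up to a deleted cell,
        1-nearest-neighbor imputation restores the twin's value."""
        rng = np.random.default_rng(1)
        base = rng.normal(size=44)
        feats = np.vstack([base, base, rng.normal(size=44) + 10])
        feats = feats.copy()
        feats[1, 7] = np.nan
        ev = _event_from_features(feats)
        kept, _ = impute([ev], DEFAULT_MANIFEST, method="knn", knn_k=1)
        assert kept[0].features[1, 7] == pytest.approx(base[7], rel=1e-9)

    def test_svd_rank1_completion(self):
        """A rank-1 outer product with one deleted entry is recovered to
        1e-6 relative error by rank-1 iterative completion."""
        u = np.linspace(1, 2, 12)
        v = np.linspace(3, 4, 44)
        m = np.outer(u, v)
        m_missing = m.copy()
        m_missing[5, 20] = np.nan
        out = svd_complete(m_missing, rank=1, max_iter=500, tol=1e-12)
        assert abs(out[5, 20] - m[5, 20]) / abs(m[5, 20]) < 1e-6

    @pytest.mark.parametrize("method", ["knn", "svd", "mean"])
    def test_output_complete_and_observed_untouched(self, method):
        rng = np.random.default_rng(2)
        feats = rng.normal(size=(10, 44))
        mask = rng.random(feats.shape) < 0.2
        orig = feats.copy()
        feats[mask] = np.nan
        ev = _event_from_features(feats)
        kept, diag = impute([ev], DEFAULT_MANIFEST, method=method)
        out = kept[0].features
        assert not np.isnan(out).any()
        np.testing.assert_allclose(out[~mask], orig[~mask])
        assert diag.imputed_fraction_per_feature[NAMES[0]] == pytest.approx(
            mask[:, 0].mean()
        )


class TestIdealBodyWeight:
    @pytest.mark.parametrize(
        "sex,height,expected",
        [("male", 152.4, 50.0), ("female", 152.4, 45.5), ("male", 172.4, 68.2)],
    )
    def test_formula(self, sex, height, expected):
        assert ideal_body_weight(sex, height) == pytest.approx(expected)

    def test_non_positive_height_rejected(self):
        with pytest.raises(ValueError):
            ideal_body_weight("male", 0.0)


class TestMissingnessDiagnostic:
    def test_mcar_pvalues_not_systematically_small(self):
        """Under MCAR missingness, few features show significant association."""
        rng = np.random.default_rng(3)
        df = tiny_cohort_frame(n_stays=40, n_bins=15, seed=3)
        vals = rng.normal(size=(len(df), 44))
        miss = rng.random(vals.shape) < 0.2
        vals[miss] = np.nan
        df[NAMES] = vals
        res = missingness_diagnostic(TrajectoryTable(df=df, manifest=DEFAULT_MANIFEST))
        applicable = res[res["applicable"]]
        assert (applicable["p_value"] < 0.05).mean() < 0.10

    def test_mar_mechanism_detected(self):
        """Missingness deterministically triggered by another feature's value
        yields a tiny p-value for the affected feature."""
        rng = np.random.default_rng(4)
        df = tiny_cohort_frame(n_stays=40, n_bins=15, seed=4)
        vals = rng.normal(size=(len(df), 44))
        df[NAMES] = vals
        driver = df[NAMES[0]]
        target = NAMES[1]
        df.loc[driver > driver.median(), target] = np.nan
        res = missingness_diagnostic(TrajectoryTable(df=df, manifest=DEFAULT_MANIFEST))
        row = res[res["feature"] == target].iloc[0]
        assert row["applicable"]
        assert row["p_value"] < 1e-3
        assert row["most_associated"] == NAMES[0]

    def test_fully_observed_feature_marked_na(self, tiny_table):
        res = missingness_diagnostic(tiny_table)
        assert not res["applicable"].any()
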