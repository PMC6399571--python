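import collections

import pytest

from fallnet.synthetic import AdmissionRecord, FallEvent
from fallnet.windowing import (
    BalancingError,
    DailyWindow,
    DataIntegrityError,
    SplitError,
    SplitPlan,
    build_all_windows,
    build_windows,
    fold_seed,
    monte_carlo_folds,
    oversample_positives,
    read_windows,
    split_by_patient,
    write_windows,
)


def _admission(los, daily_observations, patient_id=1, admission_id=10):
    return AdmissionRecord(
        patient_id=patient_id,
        admission_id=admission_id,
        admit_day=0,
        length_of_stay=los,
        static_fields={},
        daily_observations=daily_observations,
    )


def _event(day, hour, admission_id=10):
    return FallEvent(
        admission_id=admission_id, day_index=day, hour=hour, injury_level="none"
    )


def test_nonfaller_contributes_one_negative_window_per_day():
    adm = _admission(4, {0: {"a": "x"}, 2: {"a": "y"}})
    windows = build_windows(adm)
    assert len(windows) == 4
    assert [w.label for w in windows] == [0, 0, 0, 0]
    assert [w.start_day for w in windows] == [0.0, 1.0, 2.0, 3.0]
    # locf: day-0 state carries until the day-2 update
    assert [w.evidence["a"] for w in windows] == ["x", "x", "y", "y"]


def test_faller_contributes_only_the_prefall_window():
    adm = _admission(5, {0: {"a": "x"}, 1: {"a": "y"}, 3: {"a": "z"}})
    windows = build_windows(adm, [_event(day=2, hour=6)])
    assert len(windows) == 1
    (w,) = windows
    assert w.label == 1
    # the positive window is the 24 h ending at the fall: [1.25, 2.25)
    assert w.start_day == pytest.approx(2 + 6 / 24 - 1.0)
    assert w.end_day == pytest.approx(2 + 6 / 24)
    # observations through day 2 are usable; the day-3 update is in the future
    assert w.evidence["a"] == "y"


def test_two_falls_give_two_positive_windows():
    adm = _admission(8, {0: {"a": "x"}})
    windows = build_windows(adm, [_event(1, 12.0), _event(5, 3.0)])
    assert [w.label for w in windows] == [1, 1]
    assert windows[0].end_day == pytest.approx(1.5)
    assert windows[1].end_day == pytest.approx(5.125)


def test_keep_post_fall_restores_negative_days():
    adm = _admission(5, {0: {"a": "x"}})
    windows = build_windows(adm, [_event(1, 12.0)], keep_post_fall=True)
    labels = [w.label for w in windows]
    assert labels.count(1) == 1
    assert labels.count(0) >= 1  # days after the fall come back as negatives
    assert sum(labels) == 1


def test_event_outside_stay_is_rejected():
    adm = _admission(3, {})
    with pytest.raises(DataIntegrityError):
        build_windows(adm, [_event(3, 1.0)])
    with pytest.raises(DataIntegrityError):
        build_windows(adm, [_event(1, 24.0)])


def test_event_for_other_admission_is_rejected():
    adm = _admission(3, {})
    with pytest.raises(DataIntegrityError):
        build_windows(adm, [_event(1, 1.0, admission_id=99)])


def test_carry_horizon_limits_locf():
    adm = _admission(5, {0: {"a": "x"}})
    windows = build_windows(adm, carry_horizon=2)
    assert windows[0].evidence == {"a": "x"}
    assert windows[1].evidence == {"a": "x"}
    assert windows[2].evidence == {}  # day-0 state expired


def test_build_all_windows_equals_per_admission_path(small_cohort):
    fast = build_all_windows(small_cohort)
    slow = []
    events = {
        adm: [e for e in small_cohort.fall_events() if e.admission_id == adm]
        for adm in small_cohort.static["admission_id"]
    }
    for adm in small_cohort.iter_admissions():
        slow.extend(build_windows(adm, events[adm.admission_id]))
    key = lambda w: (w.admission_id, w.window_index)
    fast, slow = sorted(fast, key=key), sorted(slow, key=key)
    assert len(fast) == len(slow)
    for a, b in zip(fast, slow):
        assert a == b


def test_split_by_patient_partitions_patients():
    windows = [
        DailyWindow(p, p, d, float(d), 0, {}) for p in range(20) for d in range(3)
    ]
    plan = split_by_patient(windows, 0.1, seed=4)
    assert len(plan.test_patients) == 2
    assert plan.train_patients | plan.test_patients == set(range(20))
    assert not plan.train_patients & plan.test_patients
    # every window follows its patient
    for w in plan.test_windows(windows):
        assert w.patient_id in plan.test_patients


def test_split_requires_two_patients():
    windows = [DailyWindow(1, 1, d, float(d), 0, {}) for d in range(5)]
    with pytest.raises(SplitError):
        split_by_patient(windows, 0.5, seed=0)


def test_split_plan_rejects_overlap():
    with pytest.raises(SplitError):
        SplitPlan(frozenset({1, 2}), frozenset({2, 3}), seed=0)


def _label_windows(n_pos, n_neg):
    out = [DailyWindow(i, i, 0, 0.0, 1, {}) for i in range(n_pos)]
    out += [DailyWindow(100 + i, 100 + i, 0, 0.0, 0, {}) for i in range(n_neg)]
    return out


def test_oversampling_balances_exactly_when_divisible():
    out = oversample_positives(_label_windows(2, 10), seed=0)
    counts = collections.Counter(w.label for w in out)
    assert counts == {0: 10, 1: 10}
    per_pos = collections.Counter(
        w.patient_id for w in out if w.label == 1
    )
    assert sorted(per_pos.values()) == [5, 5]


def test_oversampling_distributes_the_remainder():
    out = oversample_positives(_label_windows(3, 10), seed=0)
    per_pos = collections.Counter(w.patient_id for w in out if w.label == 1)
    assert sorted(per_pos.values()) == [3, 3, 4]
    assert sum(w.label == 0 for w in out) == 10


def test_oversampling_requires_both_classes():
    with pytest.raises(BalancingError):
        oversample_positives(_label_windows(0, 5), seed=0)
    with pytest.raises(BalancingError):
        oversample_positives(_label_windows(5, 0), seed=0)
    with pytest.raises(BalancingError):
        oversample_positives(_label_windows(6, 5), seed=0)


def test_fold_seed_is_deterministic_and_bounded():
    seeds = [fold_seed(123456789, i) for i in range(1000)]
    assert seeds == [fold_seed(123456789, i) for i in range(1000)]
    assert all(0 <= s < 2**31 for s in seeds)
    assert len(set(seeds)) == len(seeds)


def test_monte_carlo_folds_resample_independently():
    windows = [
        DailyWindow(p, p, d, float(d), 0, {}) for p in range(30) for d in range(2)
    ]
    plans = monte_carlo_folds(windows, k=5, seed=3)
    assert len(plans) == 5
    test_sets = [p.test_patients for p in plans]
    assert len(set(test_sets)) > 1  # folds differ (subsampling, not a partition)


def test_windows_round_trip_through_csv(tmp_path, small_windows):
    path = tmp_path / "w.csv"
    write_windows(small_windows, path)
    back = read_windows(path)
    assert len(back) == len(small_windows)
    key = lambda w: (w.admission_id, w.window_index)
    for a, b in zip(sorted(back, key=key), sorted(small_windows, key=key)):
        assert a == b
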