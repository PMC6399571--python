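import math

import numpy as np
import pytest

from fallnet.evaluation import (
    auc_concordance,
    calibration_deciles,
    cross_validate,
    error_rate,
    evaluate_predictions,
    log_loss,
    plot_calibration,
    plot_roc,
    roc_auc,
    spherical_payoff,
)
from fallnet.learning import DirichletPrior


def test_error_rate_counts_threshold_mistakes():
    p = [0.9, 0.2, 0.6, 0.4]
    y = [1, 0, 0, 1]
    # 0.6 -> predicted 1 but y=0; 0.4 -> predicted 0 but y=1
    assert error_rate(p, y) == pytest.approx(0.5)
    assert error_rate(p, y, threshold=0.95) == pytest.approx(0.5)


def test_log_loss_of_uniform_predictor_is_ln_two():
    y = [0, 1] * 50
    assert log_loss([0.5] * 100, y) == pytest.approx(math.log(2), abs=1e-12)


def test_log_loss_hand_value():
    # -(ln 0.8 + ln 0.9) / 2 for p=(0.8 on y=1, 0.1 on y=0)
    expected = -(math.log(0.8) + math.log(0.9)) / 2
    assert log_loss([0.8, 0.1], [1, 0]) == pytest.approx(expected, abs=1e-12)


def test_spherical_payoff_of_uniform_predictor_is_inverse_sqrt_two():
    y = [0, 1] * 50
    assert spherical_payoff([0.5] * 100, y) == pytest.approx(
        1 / math.sqrt(2), abs=1e-12
    )


def test_spherical_payoff_of_perfect_predictor_is_one():
    assert spherical_payoff([1.0, 0.0, 1.0], [1, 0, 1]) == pytest.approx(1.0)


def test_scoring_rules_reward_the_truth():
    # proper scores: the true probabilities beat miscalibrated competitors
    rng = np.random.default_rng(8)
    truth = rng.uniform(0.05, 0.95, size=60_000)
    y = (rng.random(truth.size) < truth).astype(int)
    competitors = [
        np.clip(truth + 0.15, 0, 1),
        np.clip(truth * 0.5, 0, 1),
        np.full_like(truth, y.mean()),
    ]
    for alt in competitors:
        assert log_loss(truth, y) < log_loss(alt, y)
        assert spherical_payoff(truth, y) > spherical_payoff(alt, y)


def test_auc_matches_pairwise_oracle_with_ties():
    rng = np.random.default_rng(12)
    p = np.round(rng.random(300), 2)  # rounding forces ties
    y = (rng.random(300) < 0.3).astype(int)

    def oracle(p, y):
        pos, neg = p[y == 1], p[y == 0]
        wins = (pos[:, None] > neg[None, :]).sum()
        ties = (pos[:, None] == neg[None, :]).sum()
        return (wins + 0.5 * ties) / (len(pos) * len(neg))

    assert auc_concordance(p, y) == pytest.approx(oracle(p, y), abs=1e-9)
    auc, curve = roc_auc(p, y)
    assert auc == pytest.approx(oracle(p, y), abs=1e-9)
    # area under the returned polyline equals the concordance value
    fpr, tpr = curve[:, 0], curve[:, 1]
    assert np.trapezoid(tpr, fpr) == pytest.approx(auc, abs=1e-9)


def test_auc_of_random_predictions_is_near_half():
    rng = np.random.default_rng(19)
    p = rng.random(20_000)
    y = (rng.random(20_000) < 0.5).astype(int)
    assert auc_concordance(p, y) == pytest.approx(0.5, abs=0.02)


def test_auc_requires_both_classes():
    with pytest.raises(ValueError):
        roc_auc([0.1, 0.9], [1, 1])


def test_calibration_bins_have_equal_counts_without_ties():
    rng = np.random.default_rng(2)
    p = rng.random(1000)
    y = (rng.random(1000) < p).astype(int)
    bins = calibration_deciles(p, y)
    assert [b.count for b in bins] == [100] * 10
    assert sum(b.count for b in bins) == 1000


def test_calibration_keeps_tied_predictions_together():
    p = [0.3] * 55 + [0.8] * 45
    y = [0] * 55 + [1] * 45
    bins = calibration_deciles(p, y)
    occupied = [b for b in bins if b.count]
    assert len(occupied) == 2
    assert occupied[0].count == 55 and occupied[1].count == 45
    assert occupied[0].observed_rate == 0.0
    assert occupied[1].observed_rate == 1.0


def test_wilson_interval_brackets_the_observed_rate():
    rng = np.random.default_rng(3)
    p = rng.random(5000)
    y = (rng.random(5000) < p).astype(int)
    for b in calibration_deciles(p, y):
        assert b.ci_low <= b.observed_rate <= b.ci_high
        assert 0.0 <= b.ci_low and b.ci_high <= 1.0


def test_wilson_coverage_is_near_nominal():
    # 500 replicates of n=200 Bernoulli(0.3): the 95% interval should cover
    rng = np.random.default_rng(44)
    from fallnet.evaluation import _wilson

    hits = 0
    for _ in range(500):
        k = rng.binomial(200, 0.3)
        lo, hi = _wilson(int(k), 200)
        hits += lo <= 0.3 <= hi
    assert 0.90 <= hits / 500 <= 0.99


def test_evaluate_predictions_handles_single_class_folds():
    report = evaluate_predictions([0.1, 0.2, 0.3], [0, 0, 0], with_curves=False)
    assert math.isnan(report.auc)
    assert report.no_information_rate == pytest.approx(1.0)
    assert report.error_rate == pytest.approx(0.0)


def test_no_information_rate_is_majority_class_share():
    report = evaluate_predictions(
        [0.1] * 7 + [0.9] * 3, [0] * 7 + [1] * 3, with_curves=False
    )
    assert report.no_information_rate == pytest.approx(0.7)


def test_cross_validate_is_deterministic(small_windows):
    import fallnet as fn

    skeleton = fn.load_schema(fn.bundled_schema_path("development"))
    kwargs = dict(k=3, seed=9)
    a = cross_validate(skeleton, small_windows, DirichletPrior(), **kwargs)
    b = cross_validate(skeleton, small_windows, DirichletPrior(), **kwargs)
    # string compare: json keeps NaN folds (no-positive test sets) comparable
    import json

    assert json.dumps(a.to_dict(), sort_keys=True) == json.dumps(
        b.to_dict(), sort_keys=True
    )
    assert len(a.folds) == 3
    assert a.n_windows == sum(f.n_windows for f in a.folds)


def test_kfold_mode_partitions_every_patient(small_windows):
    import fallnet as fn

    skeleton = fn.load_schema(fn.bundled_schema_path("development"))
    report = cross_validate(
        skeleton, small_windows, DirichletPrior(), k=3, seed=9, mode="kfold"
    )
    # a true partition scores every window exactly once
    assert report.n_windows == len(small_windows)


def test_plots_write_vector_files(tmp_path):
    rng = np.random.default_rng(6)
    p = rng.random(500)
    y = (rng.random(500) < p).astype(int)
    report = evaluate_predictions(p, y)
    plot_roc(report, tmp_path / "roc.svg")
    plot_calibration(report, tmp_path / "cal.svg")
    assert (tmp_path / "roc.svg").stat().st_size > 0
    assert (tmp_path / "cal.svg").stat().st_size > 0
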