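import numpy as np
import pandas as pd
import pytest

from fallnet import synthetic
from fallnet.inference import joint_distribution
from fallnet.synthetic import (
    ConfigurationError,
    development_config,
    ground_truth_network,
    mask_missing,
    read_cohort,
    sample_cohort,
    validation_config,
    write_cohort,
)


def test_generation_is_deterministic_in_the_seed():
    a = sample_cohort(development_config(n_admissions=200, seed=5))
    b = sample_cohort(development_config(n_admissions=200, seed=5))
    pd.testing.assert_frame_equal(a.static, b.static)
    pd.testing.assert_frame_equal(a.observations, b.observations)
    pd.testing.assert_frame_equal(a.events, b.events)


def test_different_seeds_differ():
    a = sample_cohort(development_config(n_admissions=200, seed=5))
    b = sample_cohort(development_config(n_admissions=200, seed=6))
    assert not a.static.equals(b.static)


def test_empty_cohort_is_valid():
    cohort = sample_cohort(development_config(n_admissions=0, seed=0))
    assert cohort.n_admissions == 0
    assert cohort.total_hospital_days == 0
    assert cohort.n_falls == 0


def test_planted_fall_marginal_equals_target_rate():
    for cfg in (development_config(n_admissions=1), validation_config(n_admissions=1)):
        truth = ground_truth_network(cfg)
        p = joint_distribution(truth, ["fall"], max_size=2**24)
        assert p[1] == pytest.approx(cfg.target_fall_rate / 1000.0, abs=1e-10)


def test_static_marginals_match_configuration():
    cfg = development_config(n_admissions=20_000, seed=21)
    cohort = sample_cohort(cfg)
    sex = cohort.static["sex"].value_counts(normalize=True)
    assert sex["female"] == pytest.approx(
        cfg.demographic_marginals["sex"]["female"], abs=0.01
    )
    age = cohort.static["age_bin"].value_counts(normalize=True)
    for state, target in cfg.demographic_marginals["age_bin"].items():
        assert age.get(state, 0.0) == pytest.approx(target, abs=0.01)
    kpcs = cohort.static["kpcs_group"].value_counts(normalize=True)
    for state, target in cfg.kpcs_marginals.items():
        assert kpcs.get(state, 0.0) == pytest.approx(target, abs=0.01)


def test_realized_fall_rate_within_binomial_noise():
    cfg = development_config(n_admissions=5000, seed=33)
    cohort = sample_cohort(cfg)
    days = cohort.total_hospital_days
    p = cfg.target_fall_rate / 1000.0
    sigma = np.sqrt(p * (1 - p) / days) * 1000.0
    assert abs(cohort.fall_rate_per_1000() - cfg.target_fall_rate) < 3 * sigma


def test_fall_events_lie_within_the_stay(small_cohort):
    los = small_cohort.static.set_index("admission_id")["length_of_stay"]
    ev = small_cohort.events
    assert (ev["day"] >= 0).all()
    assert (ev["day"] < los.loc[ev["admission_id"]].to_numpy()).all()
    assert ev["hour"].between(0, 24, inclusive="left").all()


def test_injury_levels_are_none_minor_or_moderate(small_cohort):
    assert set(small_cohort.events["injury_level"]) <= {"none", "minor", "moderate"}


def test_length_of_stay_bounds():
    cfg = development_config(n_admissions=3000, seed=9)
    cohort = sample_cohort(cfg)
    los = cohort.static["length_of_stay"]
    assert (los >= 1).all()
    assert (los <= cfg.length_of_stay_distribution["max_days"]).all()


def test_daily_factors_depend_on_their_planted_parents():
    # elimination problems must be more frequent in care-intensive KPCS groups
    cfg = development_config(n_admissions=8000, seed=41)
    cohort = sample_cohort(cfg)
    obs = cohort.observations
    elim = obs[obs["variable"] == "elimination_problem"]
    merged = elim.merge(
        cohort.static[["admission_id", "kpcs_group"]], on="admission_id"
    )
    rate = merged.groupby("kpcs_group")["value"].apply(
        lambda s: (s == "yes").mean()
    )
    assert rate["g5_6"] > rate["g1"]


def test_validate_names_the_offending_field():
    cfg = development_config(n_admissions=10)
    cfg.target_fall_rate = -1.0
    with pytest.raises(ConfigurationError, match="target_fall_rate"):
        cfg.validate()
    cfg = development_config(n_admissions=10)
    cfg.missingness_rates = {"mobility_impairment": 1.5}
    with pytest.raises(ConfigurationError, match="mobility_impairment"):
        cfg.validate()


def test_masking_with_zero_rate_is_identity(small_cohort):
    cfg = development_config(n_admissions=600, seed=11)
    cfg.missingness_rates = {"mobility_impairment": 0.0}
    masked = mask_missing(small_cohort, cfg)
    pd.testing.assert_frame_equal(masked.observations, small_cohort.observations)


def test_masking_with_unit_rate_removes_the_variable(small_cohort):
    cfg = development_config(n_admissions=600, seed=11)
    cfg.missingness_rates = {"mobility_impairment": 1.0}
    masked = mask_missing(small_cohort, cfg)
    assert "mobility_impairment" not in set(masked.observations["variable"])


def test_masking_hits_the_configured_fraction_and_spares_others(small_cohort):
    cfg = development_config(n_admissions=600, seed=11)
    cfg.missingness_rates = {"hendrich_score": 0.4}
    masked = mask_missing(small_cohort, cfg, seed=77)
    before = (small_cohort.observations["variable"] == "hendrich_score").sum()
    after = (masked.observations["variable"] == "hendrich_score").sum()
    assert 1 - after / before == pytest.approx(0.4, abs=0.03)
    for var in ("mobility_impairment", "sedative_use"):
        assert (
            (masked.observations["variable"] == var).sum()
            == (small_cohort.observations["variable"] == var).sum()
        )


def test_masking_never_touches_events(small_cohort):
    cfg = development_config(n_admissions=600, seed=11)
    cfg.missingness_rates = {"hendrich_score": 0.9}
    masked = mask_missing(small_cohort, cfg)
    pd.testing.assert_frame_equal(masked.events, small_cohort.events)


def test_cohort_round_trip_through_csv(tmp_path, small_cohort):
    write_cohort(small_cohort, tmp_path)
    back = read_cohort(tmp_path)
    pd.testing.assert_frame_equal(back.static, small_cohort.static)
    pd.testing.assert_frame_equal(back.observations, small_cohort.observations)
    pd.testing.assert_frame_equal(back.events, small_cohort.events)
    assert back.config.seed == small_cohort.config.seed


def test_iter_admissions_covers_every_admission(small_cohort):
    ids = [adm.admission_id for adm in small_cohort.iter_admissions()]
    assert sorted(ids) == sorted(small_cohort.static["admission_id"])


def test_validation_style_uses_stratify_tool():
    cfg = validation_config(n_admissions=50, seed=2)
    cohort = sample_cohort(cfg)
    variables = set(cohort.observations["variable"])
    assert "stratify_score" in variables
    assert "hendrich_score" not in variables
    assert synthetic.risk_tool_node("validation") == "stratify_score"
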