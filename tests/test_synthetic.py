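import dataclasses
import math

import numpy as np
import pytest
from scipy.special import expit, logit
from scipy.stats import chisquare

from bomarisk.descriptive import pair_distances, species_event_counts
from bomarisk.study_io import PREDATORS
from bomarisk.synthetic import (
    SimConfig,
    calibrate_attempt_coefficients,
    default_config,
    generate_bomas,
    marginal_attempt_rate,
    simulate_retaliation,
    simulate_study,
    simulate_visits,
    published_attempt_coefficients,
)


def test_default_config_invariants():
    cfg = default_config()
    assert abs(sum(cfg.species_mixture.values()) - 1.0) < 1e-12
    assert sum(cfg.visits_per_arm) == 1152
    assert cfg.n_pairs == 45
    assert cfg.attempt_coefficients["season"] == pytest.approx(1.1009)
    assert set(cfg.wet_months) == {11, 12, 1, 2, 3, 4, 5}


def test_calibration_hits_target_marginal_rates():
    """The calibrated intercept/boma-type coefficients reproduce the target
    per-arm monthly rates under the quadrature expectation."""
    coefs = calibrate_attempt_coefficients()
    sig = math.hypot(0.5, 0.5)
    assert marginal_attempt_rate(coefs["intercept"], coefs["season"], 0.0,
                                 sig, 7 / 12) == pytest.approx(0.102, abs=1e-9)
    assert marginal_attempt_rate(coefs["intercept"], coefs["season"], coefs["boma_type"],
                                 sig, 7 / 12) == pytest.approx(0.081, abs=1e-9)


def test_bad_configs_rejected():
    cfg = default_config()
    with pytest.raises(ValueError, match="sum to 1"):
        dataclasses.replace(cfg, species_mixture={"spotted_hyena": 0.5, "lion": 0.4})
    with pytest.raises(ValueError, match=">= 0"):
        dataclasses.replace(cfg, sigma_village=-0.1)
    with pytest.raises(ValueError, match="partition"):
        dataclasses.replace(cfg, wet_months=frozenset({13}))
    with pytest.raises(ValueError, match="unknown coefficient"):
        dataclasses.replace(cfg, attempt_coefficients={"intercept": 0.0, "slope_x": 1.0})
    with pytest.raises(ValueError, match="non-empty"):
        dataclasses.replace(cfg, villages=())


def test_same_seed_identical_study():
    a = simulate_study(default_config(seed=11))
    b = simulate_study(default_config(seed=11))
    assert a.bomas == b.bomas
    assert a.visits == b.visits
    assert a.retaliation == b.retaliation


def test_registry_structure():
    """45 pairs -> 45 experimental + 45 control bomas, pair members share a
    village and sit 15-972 m apart."""
    cfg = default_config(seed=5)
    bomas, covariates = generate_bomas(cfg)
    arms = [b.arm for b in bomas]
    assert arms.count("experimental") == 45 and arms.count("control") == 45
    by_pair = {}
    for b in bomas:
        by_pair.setdefault(b.pair_id, []).append(b)
    assert all(len(v) == 2 and v[0].village == v[1].village for v in by_pair.values())
    d = pair_distances(bomas)
    assert len(d) == 45
    assert all(15.0 <= x <= 972.0 for x in d.values())
    for cov in covariates.values():
        cov.validate()


def test_single_pair_distance_envelope():
    bomas, _ = generate_bomas(default_config(seed=9, n_pairs=1))
    d = list(pair_distances(bomas).values())
    assert len(d) == 1 and 15.0 <= d[0] <= 972.0


def test_per_arm_visit_totals_match_config(default_study):
    by_arm = {b.boma_id: b.arm for b in default_study.bomas}
    counts = {"experimental": 0, "control": 0}
    for v in default_study.visits:
        counts[by_arm[v.boma_id]] += 1
    assert counts == {"experimental": 631, "control": 521}


def test_successes_never_exceed_attempts(default_study):
    for v in default_study.visits:
        for s in PREDATORS:
            assert v.successes.get(s, 0) <= v.attempts.get(s, 0)


def test_rate_recovery_at_sigma_zero():
    """With no random effects the empirical attempt frequency converges to the
    closed-form seasonal mixture of logistic probabilities."""
    intercept = float(logit(0.102))
    cfg = default_config(
        seed=101, n_pairs=450, visits_per_arm=(6310, 5210),
        sigma_village=0.0, sigma_year=0.0,
        attempt_coefficients={"intercept": intercept})
    study = simulate_study(cfg)
    n = len(study.visits)
    events = sum(sum(v.attempts.values()) for v in study.visits)
    rate = events / n
    se = math.sqrt(0.102 * 0.898 / n)
    assert abs(rate - 0.102) < 3 * se


def test_degenerate_intercept_yields_no_attempts():
    cfg = default_config(seed=2, attempt_coefficients={"intercept": -50.0})
    study = simulate_study(cfg)
    assert sum(sum(v.attempts.values()) for v in study.visits) == 0


def test_season_odds_ratio_recovered_empirically():
    """With only a season effect of 1.1009 the empirical wet:dry odds ratio
    approaches exp(1.1009) = 3.01."""
    cfg = default_config(
        seed=303, n_pairs=500, visits_per_arm=(25000, 25000),
        sigma_village=0.0, sigma_year=0.0,
        attempt_coefficients={"intercept": -2.0, "season": 1.1009})
    study = simulate_study(cfg)
    wet = {True: [0, 0], False: [0, 0]}
    for v in study.visits:
        w = v.visit_date.month in cfg.wet_months
        wet[w][0] += int(any(v.attempts.values()))
        wet[w][1] += 1
    p_wet = wet[True][0] / wet[True][1]
    p_dry = wet[False][0] / wet[False][1]
    odds_ratio = (p_wet / (1 - p_wet)) / (p_dry / (1 - p_dry))
    assert odds_ratio == pytest.approx(math.exp(1.1009), rel=0.08)


def test_species_mixture_chi_square(replicate_studies):
    """Pooled species shares are consistent with the configured mixture
    (goodness-of-fit not rejected at alpha = 0.01)."""
    counts = {s: 0 for s in PREDATORS}
    for study in replicate_studies:
        for s, c in species_event_counts(study.visits).items():
            counts[s] += c
    mix = default_config().species_mixture
    total = sum(counts.values())
    observed = np.array([counts[s] for s in PREDATORS], float)
    expected = np.array([mix[s] * total for s in PREDATORS])
    assert chisquare(observed, expected).pvalue > 0.01


def test_retaliation_rates_and_determinism():
    cfg = default_config(seed=17)
    a = simulate_retaliation(cfg)
    b = simulate_retaliation(cfg)
    assert a == b
    # cheetah and jackal rates are zero -> all counts zero
    assert all(r.killed == 0 for r in a if r.species in ("cheetah", "jackal"))


def test_retaliation_yearly_mean_converges():
    """Landscape lion kills are Poisson(20)/year: the mean over many simulated
    years converges to 20."""
    cfg = default_config(seed=23, years=tuple(range(1900, 2100)))
    records = simulate_retaliation(cfg)
    lion_by_year = {}
    for r in records:
        if r.species == "lion":
            lion_by_year[r.year] = lion_by_year.get(r.year, 0) + r.killed
    yearly = np.array(list(lion_by_year.values()), float)
    assert yearly.mean() == pytest.approx(20.0, abs=3 * math.sqrt(20.0 / len(yearly)))


def test_count_mode_allows_multiple_attempts_per_month():
    cfg = default_config(seed=31, count_attempts=True,
                         attempt_coefficients={"intercept": 1.5})
    study = simulate_study(cfg)
    per_window = [sum(v.attempts.values()) for v in study.visits]
    assert max(per_window) > 1
    for v in study.visits:
        for s in PREDATORS:
            assert v.successes.get(s, 0) <= v.attempts.get(s, 0)


def test_oversized_schedule_rejected():
    cfg = default_config()
    with pytest.raises(ValueError, match="month"):
        simulate_visits(*generate_bomas(cfg)[:2],
                        dataclasses.replace(cfg, visits_per_arm=(20000, 521)))
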