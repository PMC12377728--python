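"""Loss, initial sampling, multi-start optimization, and ensemble prediction."""

import numpy as np
import pytest

from ifnb_logic import (
    ConditionPanel,
    FitConfig,
    FitResult,
    ParameterSet,
    fit_model,
    get_model,
    loss,
    predict_panel,
    sample_initial,
    worst_fit_point,
)
from ifnb_logic.data_io import Condition
from ifnb_logic.state_ensemble import TFActivity
from ifnb_logic.synthetic_data import GroundTruth, simulate_panel


def _exact_panel(spec, params):
    truth = GroundTruth(spec, params, [
        (c.genotype, c.stimulus, c.activity)
        for c in __import__("ifnb_logic").canonical_fixture()
    ])
    return simulate_panel(truth)


def test_loss_zero_for_exact_reproduction(p50_spec, derived_params):
    panel = _exact_panel(p50_spec, derived_params)
    assert loss(p50_spec, derived_params, panel) == pytest.approx(0.0, abs=1e-24)


def test_loss_single_condition_square():
    spec = get_model("two_site_h1")
    params = ParameterSet(binding={"kI": 10.0, "kN": 10.0},
                          transcription={"tI": 0.0, "tN": 0.0})
    # all activities zero -> f = 0, so the residual is the observation itself
    panel = ConditionPanel([Condition("WT", "CpG", TFActivity(0, 0, 0), 0.1)])
    assert loss(spec, params, panel) == pytest.approx(0.01)


def test_loss_on_canonical_fixture(p50_spec, derived_params, panel):
    value = loss(p50_spec, derived_params, panel)
    # independent per-condition evaluation
    from ifnb_logic import promoter_activity

    expected = sum(
        (promoter_activity(p50_spec, derived_params, c.activity) - c.ifnb_obs) ** 2
        for c in panel
    )
    assert value == pytest.approx(expected, abs=1e-12)
    assert value < 0.1


def test_sample_initial_deterministic_and_bounded(p50_spec):
    cfg = FitConfig(n_starts=1, top_k=1, seed=5)
    a = sample_initial(p50_spec, cfg, np.random.default_rng(42))
    b = sample_initial(p50_spec, cfg, np.random.default_rng(42))
    assert a.to_flat_dict() == b.to_flat_dict()

    rng = np.random.default_rng(0)
    for _ in range(200):
        p = sample_initial(p50_spec, cfg, rng)
        for v in p.binding.values():
            assert 1e-2 <= v <= 1e4
        for v in p.transcription.values():
            assert 0 <= v <= 1


def test_sample_initial_log_uniform(p50_spec):
    """log10 kI1 should be approximately uniform over its six decades."""
    cfg = FitConfig(n_starts=1, top_k=1)
    rng = np.random.default_rng(1)
    draws = np.array([
        np.log10(sample_initial(p50_spec, cfg, rng).binding["kI1"])
        for _ in range(10_000)
    ])
    hist, _ = np.histogram(draws, bins=6, range=(-2, 4))
    assert np.all(np.abs(hist / 10_000 - 1 / 6) < 0.02)


def test_fit_is_deterministic(panel):
    spec = get_model("two_site_h1")
    cfg = FitConfig(n_starts=8, top_k=3, seed=9)
    r1 = fit_model(spec, panel, cfg)
    r2 = fit_model(spec, panel, cfg)
    assert r1.to_json() == r2.to_json()


def test_fit_losses_nondecreasing(canonical_fit):
    losses = canonical_fit.losses
    assert np.all(np.diff(losses) >= 0)
    assert len(losses) == 20


def test_more_starts_never_worsen_best_loss(panel):
    spec = get_model("two_site_h1")
    best = [
        fit_model(spec, panel, FitConfig(n_starts=n, top_k=2, seed=3)).best_loss
        for n in (4, 10, 20)
    ]
    assert best[1] <= best[0] + 1e-15
    assert best[2] <= best[1] + 1e-15


def test_noise_free_self_consistency(p50_spec, derived_params):
    """Fitting data generated by the model itself recovers a near-perfect fit."""
    panel = _exact_panel(p50_spec, derived_params)
    result = fit_model(p50_spec, panel, FitConfig(n_starts=80, n_restarts=4, seed=6))
    assert result.best_loss < 1e-6


def test_canonical_fit_silences_single_tf_states(canonical_fit):
    """tI and tN come out near zero across the fitted ensemble."""
    ok = sum(
        1 for p, _ in canonical_fit.ranked
        if p.transcription["tI"] < 0.1 and p.transcription["tN"] < 0.1
    )
    assert ok >= 18


def test_predict_panel_single_member(p50_spec, derived_params, panel):
    single = FitResult(p50_spec.name, [(derived_params, 0.0)],
                       FitConfig(n_starts=1, top_k=1), 0)
    pred = predict_panel(p50_spec, single, panel)
    assert np.allclose(pred.mean_f, pred.member_f[0])


def test_predicted_stimulus_ordering(p50_spec, canonical_fit, panel):
    pred = predict_panel(p50_spec, canonical_fit, panel)
    assert pred.mean_for("WT-PolyIC") >= pred.mean_for("WT-LPS") >= pred.mean_for("WT-CpG")


def test_nfkb_independence_under_polyic(p50_spec, canonical_fit, panel):
    pred = predict_panel(p50_spec, canonical_fit, panel)
    ratio = pred.mean_for("NFkBko-PolyIC") / pred.mean_for("WT-PolyIC")
    assert 0.9 <= ratio <= 1.1


def test_worst_fit_point_perfect_fit_ties_to_first(p50_spec, derived_params):
    panel = _exact_panel(p50_spec, derived_params)
    single = FitResult(p50_spec.name, [(derived_params, 0.0)],
                       FitConfig(n_starts=1, top_k=1), 0)
    cond, resid = worst_fit_point(p50_spec, single, panel)
    assert resid == pytest.approx(0.0, abs=1e-12)
    assert cond.key == panel.keys[0]


def test_fit_rejects_empty_panel(p50_spec):
    with pytest.raises(ValueError):
        fit_model(p50_spec, ConditionPanel([]), FitConfig(n_starts=2, top_k=1))


def test_fit_config_validation():
    with pytest.raises(ValueError):
        FitConfig(n_starts=5, top_k=10)
    with pytest.raises(ValueError):
        FitConfig(k_bounds=(0.0, 10.0))
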