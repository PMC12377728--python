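"""State enumeration, weights, probabilities, and promoter activity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ifnb_logic import (
    ParameterSet,
    TFActivity,
    build_three_site,
    build_three_site_p50,
    build_two_site,
    enumerate_states,
    promoter_activity,
    state_probabilities,
    state_weight,
    transcription_decomposition,
)
from ifnb_logic.state_ensemble import CompiledEnsemble

from conftest import naive_ensemble

# hand-enumerated weights for the derived case (nfkb=0, irf=0.25, p50=1):
# {unbound 1, I1 75, I2 0.46875, p50 25, I1&I2 35.15625, p50&I2 11.71875}
_DERIVED_Z = 1 + 75 + 0.46875 + 25 + 35.15625 + 11.71875


def _state(spec, label):
    for s in enumerate_states(spec):
        if s.label == label:
            return s
    raise KeyError(label)


@pytest.mark.parametrize(
    "spec,expected",
    [
        (build_two_site(1, 1), 4),
        (build_three_site(1, 3, 1), 8),
        (build_three_site_p50(1, 3), 12),
    ],
    ids=["two_site", "three_site", "three_site_p50"],
)
def test_state_counts(spec, expected):
    states = enumerate_states(spec)
    assert len(states) == expected
    assert states[0].label == "unbound"
    assert len({s.label for s in states}) == expected


def test_p50_model_state_labels():
    labels = [s.label for s in enumerate_states(build_three_site_p50(1, 3))]
    assert labels == [
        "unbound", "p50", "N", "I1", "I2",
        "p50&N", "p50&I2", "N&I1", "N&I2", "I1&I2",
        "p50&N&I2", "N&I1&I2",
    ]


@pytest.mark.parametrize(
    "label,irf,expected",
    [
        ("unbound", 0.25, 1.0),              # empty product
        ("I1", 0.25, 75.0),                  # 300 * 0.25
        ("I2", 0.25, 30 * 0.25**3),          # Hill exponent 3 at the distal IRE
    ],
)
def test_state_weight_examples(p50_spec, derived_params, label, irf, expected):
    act = TFActivity(nfkb=0.0, irf=irf, p50=0.0)
    w = state_weight(_state(p50_spec, label), derived_params, act, p50_spec)
    assert w == pytest.approx(expected, rel=1e-12)


def test_negative_activity_rejected():
    with pytest.raises(ValueError):
        TFActivity(nfkb=-0.1, irf=0.0, p50=0.0)


def test_all_zero_activity_is_unbound(p50_spec, derived_params):
    act = TFActivity(0.0, 0.0, 0.0)
    dist = state_probabilities(p50_spec, derived_params, act)
    assert dist["unbound"] == pytest.approx(1.0)
    assert promoter_activity(p50_spec, derived_params, act) == 0.0


def test_probabilities_derived_case(p50_spec, derived_params):
    """Six nonzero weights at (nfkb=0, irf=0.25, p50=1); hand-computed shares."""
    dist = state_probabilities(p50_spec, derived_params, TFActivity(0, 0.25, 1))
    assert dist["I1"] == pytest.approx(75 / _DERIVED_Z, abs=1e-12)
    assert dist["I1&I2"] == pytest.approx(35.15625 / _DERIVED_Z, abs=1e-12)
    assert dist["N"] == 0.0


def test_promoter_activity_derived_case(p50_spec, derived_params):
    f = promoter_activity(p50_spec, derived_params, TFActivity(0, 0.25, 1))
    # only I1&I2 has nonzero capability among the occupied states here
    assert f == pytest.approx(35.15625 / _DERIVED_Z, abs=1e-12)


def test_decomposition_derived_case(p50_spec, derived_params):
    dec = transcription_decomposition(p50_spec, derived_params, TFActivity(0, 0.25, 1))
    assert dec["I1&I2"] == pytest.approx(35.15625 / _DERIVED_Z, abs=1e-12)
    assert dec["unbound"] == 0.0
    assert dec["p50"] == 0.0
    others = [v for k, v in dec.tu.items() if k != "I1&I2"]
    assert all(v <= 1e-12 for v in others)
    assert dec.total_f == pytest.approx(sum(dec.tu.values()), abs=1e-12)


def test_zero_activity_decomposition(p50_spec, derived_params):
    dec = transcription_decomposition(p50_spec, derived_params, TFActivity(0, 0, 0))
    assert all(v == 0 for v in dec.tu.values())
    assert dec.total_f == 0


def test_distribution_and_decomposition_exports(p50_spec, derived_params):
    import json

    act = TFActivity(1, 0.25, 1)
    dist = state_probabilities(p50_spec, derived_params, act)
    df = dist.to_frame()
    assert list(df.columns) == ["state", "index", "probability"]
    assert len(df) == 12
    assert json.loads(dist.to_json())["N&I1"] == pytest.approx(dist["N&I1"])

    dec = transcription_decomposition(p50_spec, derived_params, act)
    ddf = dec.to_frame()
    assert list(ddf.columns) == ["state", "index", "tu"]
    assert json.loads(dec.to_json())["total_f"] == pytest.approx(dec.total_f)


def test_p50_zero_reduces_to_three_site(derived_params):
    """With p50=0, the 12-state model restricted to p50-free states matches
    the 8-state model with the same shared parameters."""
    p50_spec = build_three_site_p50(1, 3)
    three = build_three_site(1, 3, 1)
    params3 = ParameterSet(
        binding={k: v for k, v in derived_params.binding.items() if k != "KP"},
        transcription=dict(derived_params.transcription),
    )
    act = TFActivity(0.7, 0.3, 0.0)
    d12 = state_probabilities(p50_spec, derived_params, act)
    d8 = state_probabilities(three, params3, act)
    for label, p in d8.probabilities.items():
        assert d12[label] == pytest.approx(p, abs=1e-12)
    p50_states = [l for l in d12.labels if "p50" in l]
    assert all(d12[l] == 0 for l in p50_states)


def test_cooperativity_factor_one_is_neutral():
    base = build_three_site(1, 3, 1)
    coop = build_three_site(1, 3, 1, coop_flags=("N-I1", "N-I2", "I1-I2"))
    pb = ParameterSet(binding={"kI1": 50, "kI2": 20, "kN": 5},
                      transcription={"tI": 0.1, "tN": 0.2, "tI1N": 0.5,
                                     "tI2N": 0.9, "tI1I2": 1.0})
    pc = ParameterSet(binding=dict(pb.binding), transcription=dict(pb.transcription),
                      cooperativity={"cNI": 1.0, "cI1I2": 1.0})
    act = TFActivity(0.6, 0.4, 0.0)
    db = state_probabilities(base, pb, act)
    dc = state_probabilities(coop, pc, act)
    for label in db.labels:
        assert dc[label] == pytest.approx(db[label], abs=1e-12)
    assert promoter_activity(coop, pc, act) == pytest.approx(
        promoter_activity(base, pb, act), abs=1e-12)


# -- randomized properties ---------------------------------------------------

def _family_case(draw, family):
    """Draw (spec, params) for one model family."""
    logk = st.floats(min_value=-2, max_value=4)
    t = st.floats(min_value=0, max_value=1)
    logc = st.floats(min_value=-2, max_value=2)
    if family == "two_site":
        spec = build_two_site(draw(st.sampled_from([1, 3])),
                              draw(st.sampled_from([1, 3])),
                              cooperativity=draw(st.booleans()))
    elif family == "three_site":
        spec = build_three_site(draw(st.sampled_from([1, 3])),
                                draw(st.sampled_from([1, 3])), 1,
                                coop_flags=("I1-I2",) if draw(st.booleans()) else ())
    else:
        spec = build_three_site_p50(draw(st.sampled_from([1, 3])),
                                    draw(st.sampled_from([1, 3])),
                                    distal_synergy_allowed=draw(st.booleans()))
    params = ParameterSet(
        binding={n: 10.0 ** draw(logk) for n in spec.free_k},
        transcription={n: draw(t) for n in spec.free_t},
        cooperativity={n: 10.0 ** draw(logc) for n in spec.free_c},
    )
    act = TFActivity(draw(t), draw(t), draw(t))
    return spec, params, act


@settings(max_examples=60, derandomize=True, deadline=None)
@given(data=st.data(), family=st.sampled_from(["two_site", "three_site", "three_site_p50"]))
def test_matches_naive_enumeration_and_normalizes(data, family):
    """Production probabilities/f (scalar and compiled paths) equal a naive
    double-loop enumeration; probabilities sum to one; f respects bounds."""
    spec, params, act = _family_case(data.draw, family)
    dist = state_probabilities(spec, params, act)
    dec = transcription_decomposition(spec, params, act)
    table, f_naive = naive_ensemble(spec, params, act)

    assert sum(dist.probabilities.values()) == pytest.approx(1.0, abs=1e-12)
    for label, (p, tu) in table.items():
        assert dist[label] == pytest.approx(p, abs=1e-12)
        assert dec[label] == pytest.approx(tu, abs=1e-12)
    assert dec.total_f == pytest.approx(f_naive, abs=1e-12)

    ens = CompiledEnsemble(spec)
    k, c, t = ens.split_vector(ens.vector_from_params(params))
    basis = ens.activity_basis(act.as_array()[None, :])
    f_compiled = float(ens.f(basis, k, t, c if len(c) else None)[0])
    assert f_compiled == pytest.approx(f_naive, abs=1e-12)

    t_max = max(ens.t_vector(t))
    assert -1e-12 <= dec.total_f <= t_max + 1e-12


def test_f_monotone_in_irf_fitted_regime(p50_spec, derived_params):
    """In the fitted regime, f never decreases with IRF at fixed NFkB/p50."""
    irf_grid = np.linspace(0, 1, 50)
    for nfkb in (0.0, 0.5, 1.0):
        for p50 in (0.0, 0.5, 1.0):
            f = [promoter_activity(p50_spec, derived_params, TFActivity(nfkb, x, p50))
                 for x in irf_grid]
            assert np.all(np.diff(f) >= -1e-12)
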