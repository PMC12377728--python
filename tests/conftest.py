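"""Shared fixtures: canonical panel, paper-regime parameters, one shared fit.

Also hosts an intentionally naive enumeration oracle (double loop over the
occupancy product, scalar arithmetic only) used to cross-check the
production probability/activity computations.
"""

import itertools

import numpy as np
import pytest

from ifnb_logic import (
    FitConfig,
    ParameterSet,
    canonical_fixture,
    fit_model,
    get_model,
)

_TOKEN_RANK = {"p50": 0, "N": 1, "I": 2, "I1": 2, "I2": 3}


def naive_ensemble(spec, params, activity):
    """Brute-force reference: label -> (probability, tu), plus total f.

    Enumerates the full per-site occupancy product with plain Python loops
    and scalar arithmetic; independent of the package's enumeration,
    compiled evaluator, and label ordering.
    """
    act = {"NFKB": activity.nfkb, "IRF": activity.irf, "P50": activity.p50}
    sites = {}
    for u in spec.units:
        sites.setdefault(u.site, []).append(u)
    entries = []
    for combo in itertools.product(*[[None] + opts for opts in sites.values()]):
        chosen = [u for u in combo if u is not None]
        w = 1.0
        for u in chosen:
            w *= params.binding[u.k_param] * act[u.species] ** u.hill
        tokens = {u.token for u in chosen}
        for term in spec.coop:
            if set(term.tokens) <= tokens:
                w *= params.cooperativity.get(term.c_param, 1.0)
        const, coeffs = spec.t_expression(frozenset(tokens))
        t = const + sum(coef * params.transcription[p] for p, coef in coeffs)
        label = "&".join(sorted(tokens, key=_TOKEN_RANK.get)) if tokens else "unbound"
        entries.append((label, w, t))
    Z = sum(w for _, w, _ in entries)
    table = {label: (w / Z, w / Z * t) for label, w, t in entries}
    f = sum(tu for _, tu in table.values())
    return table, f


@pytest.fixture(scope="session")
def panel():
    return canonical_fixture()


@pytest.fixture(scope="session")
def p50_spec():
    return get_model("p50_1&3")


@pytest.fixture(scope="session")
def derived_params():
    """The published approximate best-fit regime of the 1&3 p50 model."""
    return ParameterSet(
        binding={"kI1": 300.0, "kI2": 30.0, "kN": 12.0, "KP": 25.0},
        transcription={"tI": 0.0, "tN": 0.0, "tI1N": 0.5, "tI2N": 1.0, "tI1I2": 1.0},
    )


@pytest.fixture(scope="session")
def canonical_fit(p50_spec, panel):
    """Top-20 ensemble from a 200-start fit of the 1&3 p50 model."""
    return fit_model(p50_spec, panel, FitConfig(n_starts=200, seed=1))
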