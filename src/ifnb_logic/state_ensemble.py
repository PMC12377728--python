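"""Equilibrium state ensemble of the IFN-beta enhancer.

The enhancer is modelled as a set of binding sites that are either empty or
occupied by one transcription-factor species. Each occupancy configuration
(state) gets a Boltzmann-style statistical weight

    w(state) = prod_occ  k_site,species * X_species**h_site,species
             * prod_pairs c_pair,

the product running over the state's occupancies (k the binding constant in
MNU^-1, X the factor's activity in max-normalized units, h the Hill
exponent) and over any declared cooperativity pairs present in the state.
The unbound state has weight 1, so the partition function is always >= 1.
State probabilities are weights normalized by their sum, and the promoter
activity is the capability-weighted mean

    f = sum_s P(s) * t_s,

with t fixed at 0 for the unbound state and 1 for the fully bound state.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .model_library import (
    TOKEN_ORDER,
    UNBOUND_LABEL,
    ModelConfigError,
    ModelSpec,
)

__all__ = [
    "Occupancy",
    "EnhancerState",
    "TFActivity",
    "ParameterSet",
    "StateDistribution",
    "TranscriptionDecomposition",
    "enumerate_states",
    "state_weight",
    "state_probabilities",
    "promoter_activity",
    "transcription_decomposition",
    "CompiledEnsemble",
]

_ADMISSIBLE = {
    "IRE1": {"IRF", "P50"},
    "IRE2": {"IRF"},
    "IRE": {"IRF"},
    "KB": {"NFKB"},
}

_SPECIES_INDEX = {"NFKB": 0, "IRF": 1, "P50": 2}


@dataclass(frozen=True)
class Occupancy:
    """A single site occupied by a single species."""

    site: str
    species: str

    def __post_init__(self) -> None:
        allowed = _ADMISSIBLE.get(self.site)
        if allowed is None:
            raise ModelConfigError(f"unknown site {self.site!r}")
        if self.species not in allowed:
            raise ModelConfigError(
                f"{self.species} is not admissible at {self.site}"
            )


def _label(tokens) -> str:
    toks = sorted(tokens, key=lambda t: TOKEN_ORDER[t])
    return "&".join(toks) if toks else UNBOUND_LABEL


@dataclass(frozen=True)
class EnhancerState:
    """One occupancy configuration, with its canonical '&'-joined label."""

    occupancies: frozenset
    tokens: frozenset
    label: str

    @property
    def n_bound(self) -> int:
        return len(self.occupancies)


@dataclass(frozen=True)
class TFActivity:
    """Transcription-factor activities in max-normalized units (MNU)."""

    nfkb: float
    irf: float
    p50: float = 0.0

    def __post_init__(self) -> None:
        for name, v in (("nfkb", self.nfkb), ("irf", self.irf), ("p50", self.p50)):
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} activity must be finite and >= 0, got {v}")

    def as_array(self) -> np.ndarray:
        return np.array([self.nfkb, self.irf, self.p50], float)

    def replace(self, **kw) -> "TFActivity":
        d = {"nfkb": self.nfkb, "irf": self.irf, "p50": self.p50}
        d.update(kw)
        return TFActivity(**d)


@dataclass
class ParameterSet:
    """Named parameter values for one enhancer model.

    binding
        Binding constants (kI1, kI2, kN, KP, ...), MNU^-1, strictly positive.
    transcription
        Free transcription capabilities in [0, 1]. t0 = 0 and t_full = 1 are
        implicit constants; a constrained tI2N (distal synergy disallowed)
        is computed, never stored here.
    cooperativity
        Pairwise binding-cooperativity factors, strictly positive (1 = none).
    """

    binding: dict
    transcription: dict
    cooperativity: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, v in {**self.binding, **self.cooperativity}.items():
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be finite and > 0, got {v}")
        for name, v in self.transcription.items():
            if not (np.isfinite(v) and -1e-12 <= v <= 1 + 1e-12):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")

    def capability(self, spec: ModelSpec, tokens) -> float:
        """Transcription capability of a state, resolving linear constraints."""
        const, coeffs = spec.t_expression(frozenset(tokens))
        return const + sum(c * self.transcription[p] for p, c in coeffs)

    def coop_factor(self, name: str) -> float:
        return self.cooperativity.get(name, 1.0)

    def to_flat_dict(self) -> dict:
        return {**self.binding, **self.cooperativity, **self.transcription}

    @classmethod
    def from_flat_dict(cls, spec: ModelSpec, d: dict) -> "ParameterSet":
        return cls(
            binding={k: d[k] for k in spec.free_k},
            transcription={k: d[k] for k in spec.free_t},
            cooperativity={k: d[k] for k in spec.free_c},
        )


@dataclass
class StateDistribution:
    """Probability of each enumerated enhancer state; sums to 1."""

    labels: list
    probabilities: dict

    def __getitem__(self, label: str) -> float:
        return self.probabilities[label]

    def as_array(self) -> np.ndarray:
        return np.array([self.probabilities[l] for l in self.labels])

    def to_frame(self):
        """Tidy frame with columns state, index, probability."""
        import pandas as pd

        return pd.DataFrame(
            {"state": self.labels,
             "index": range(len(self.labels)),
             "probability": [self.probabilities[l] for l in self.labels]}
        )

    def to_json(self) -> str:
        import json

        return json.dumps(self.probabilities)


@dataclass
class TranscriptionDecomposition:
    """Per-state transcription units tu(s) = P(s) * t_s; sums to f."""

    labels: list
    tu: dict
    total_f: float

    def __getitem__(self, label: str) -> float:
        return self.tu[label]

    def to_frame(self):
        """Tidy frame with columns state, index, tu."""
        import pandas as pd

        return pd.DataFrame(
            {"state": self.labels,
             "index": range(len(self.labels)),
             "tu": [self.tu[l] for l in self.labels]}
        )

    def to_json(self) -> str:
        import json

        return json.dumps({"tu": self.tu, "total_f": self.total_f})


def enumerate_states(spec: ModelSpec):
    """All sterically allowed occupancy combinations, canonically ordered.

    Order: unbound first, then by number of bound sites, then by token rank
    (p50 < N < I1 < I2). Deterministic for a given spec.
    """
    by_site: dict = {}
    for u in spec.units:
        Occupancy(u.site, u.species)  # validates admissibility
        by_site.setdefault(u.site, []).append(u)
    choices = [[None] + opts for opts in by_site.values()]
    states = []
    for combo in itertools.product(*choices):
        occs = frozenset(Occupancy(u.site, u.species) for u in combo if u is not None)
        tokens = frozenset(u.token for u in combo if u is not None)
        states.append(EnhancerState(occs, tokens, _label(tokens)))
    states.sort(key=lambda s: (s.n_bound,
                               tuple(sorted(TOKEN_ORDER[t] for t in s.tokens))))
    return states


def _unit_for(spec: ModelSpec, occ: Occupancy):
    for u in spec.units:
        if u.site == occ.site and u.species == occ.species:
            return u
    raise ModelConfigError(f"occupancy {occ} not declared in model {spec.name}")


def state_weight(state: EnhancerState, params: ParameterSet,
                 activity: TFActivity, spec: ModelSpec) -> float:
    """Statistical weight of one state; the unbound state has weight 1."""
    act = activity.as_array()
    w = 1.0
    for occ in state.occupancies:
        u = _unit_for(spec, occ)
        x = act[_SPECIES_INDEX[occ.species]]
        w *= params.binding[u.k_param] * x ** u.hill
    for term in spec.coop:
        if term.tokens <= state.tokens:
            w *= params.coop_factor(term.c_param)
    return w


def state_probabilities(spec: ModelSpec, params: ParameterSet,
                        activity: TFActivity) -> StateDistribution:
    """Normalized state probabilities P(s) = w(s) / sum_s' w(s')."""
    states = enumerate_states(spec)
    w = np.array([state_weight(s, params, activity, spec) for s in states])
    p = w / w.sum()
    labels = [s.label for s in states]
    return StateDistribution(labels, dict(zip(labels, p)))


def promoter_activity(spec: ModelSpec, params: ParameterSet,
                      activity: TFActivity) -> float:
    """Promoter activity f = sum_s P(s) * t_s, in max-normalized units."""
    return transcription_decomposition(spec, params, activity).total_f


def transcription_decomposition(spec: ModelSpec, params: ParameterSet,
                                activity: TFActivity) -> TranscriptionDecomposition:
    """Transcription units contributed by each state; totals to f."""
    states = enumerate_states(spec)
    dist = state_probabilities(spec, params, activity)
    tu = {}
    for s in states:
        t = params.capability(spec, s.tokens)
        tu[s.label] = dist[s.label] * t
    return TranscriptionDecomposition(dist.labels, tu, float(sum(tu.values())))


class CompiledEnsemble:
    """Vectorized evaluator of the ensemble over many activity rows at once.

    Precomputes, per state: the incidence of each free k parameter, of each
    cooperativity parameter, the summed Hill exponent of each TF species,
    and the transcription-capability linear map. Given an (C, 3) activity
    matrix (columns nfkb, irf, p50), evaluating weights / probabilities / f
    for a parameter vector is a handful of dense numpy operations — this is
    the hot path of the fitting and prediction machinery.
    """

    def __init__(self, spec: ModelSpec):
        self.spec = spec
        self.states = enumerate_states(spec)
        self.labels = [s.label for s in self.states]
        S = len(self.states)
        nk, nc, nt = len(spec.free_k), len(spec.free_c), len(spec.free_t)
        self.k_names = list(spec.free_k)
        self.c_names = list(spec.free_c)
        self.t_names = list(spec.free_t)
        self.K = np.zeros((S, nk))           # k-parameter incidence
        self.C = np.zeros((S, nc))           # cooperativity incidence
        self.A = np.zeros((S, 3))            # summed Hill exponent per species
        self.Tconst = np.zeros(S)
        self.Tmap = np.zeros((S, nt))
        k_index = {n: j for j, n in enumerate(self.k_names)}
        c_index = {n: j for j, n in enumerate(self.c_names)}
        t_index = {n: j for j, n in enumerate(self.t_names)}
        for i, s in enumerate(self.states):
            for occ in s.occupancies:
                u = _unit_for(spec, occ)
                self.K[i, k_index[u.k_param]] += 1
                self.A[i, _SPECIES_INDEX[occ.species]] += u.hill
            for term in spec.coop:
                if term.tokens <= s.tokens:
                    self.C[i, c_index[term.c_param]] += 1
            const, coeffs = spec.t_expression(s.tokens)
            self.Tconst[i] = const
            for p, coef in coeffs:
                self.Tmap[i, t_index[p]] += coef

    def activity_basis(self, act: np.ndarray) -> np.ndarray:
        """(C, S) matrix of prod_species activity**hill, with 0**0 == 1."""
        act = np.atleast_2d(np.asarray(act, float))
        # broadcast (C, 1, 3) ** (S, 3); mask exponent-0 entries to 1
        powed = np.where(self.A[None, :, :] > 0,
                         act[:, None, :] ** self.A[None, :, :], 1.0)
        return powed.prod(axis=2)

    def weights(self, basis: np.ndarray, k: np.ndarray,
                c: np.ndarray | None = None) -> np.ndarray:
        scale = np.exp(self.K @ np.log(k))
        if self.C.shape[1]:
            scale = scale * np.exp(self.C @ np.log(c))
        return basis * scale[None, :]

    def t_vector(self, t: np.ndarray) -> np.ndarray:
        return self.Tconst + self.Tmap @ t

    def probabilities(self, basis, k, c=None) -> np.ndarray:
        w = self.weights(basis, k, c)
        return w / w.sum(axis=1, keepdims=True)

    def f(self, basis, k, t, c=None) -> np.ndarray:
        """Promoter activity per activity row."""
        return self.probabilities(basis, k, c) @ self.t_vector(t)

    def split_vector(self, x: np.ndarray):
        """Split a packed parameter vector into (k, c, t) in natural units."""
        nk, nc = len(self.k_names), len(self.c_names)
        return x[:nk], x[nk:nk + nc], x[nk + nc:]

    def params_from_vector(self, x: np.ndarray) -> ParameterSet:
        k, c, t = self.split_vector(np.asarray(x, float))
        return ParameterSet(
            binding=dict(zip(self.k_names, map(float, k))),
            transcription=dict(zip(self.t_names, map(float, np.clip(t, 0, 1)))),
            cooperativity=dict(zip(self.c_names, map(float, c))),
        )

    def vector_from_params(self, params: ParameterSet) -> np.ndarray:
        return np.array(
            [params.binding[n] for n in self.k_names]
            + [params.coop_factor(n) for n in self.c_names]
            + [params.transcription[n] for n in self.t_names]
        )
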