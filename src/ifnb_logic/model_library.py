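"""Catalogue of IFN-beta enhancer model variants.

Each variant is a :class:`ModelSpec`: a declarative description of the
enhancer's binding sites, which transcription-factor species may occupy
them, the Hill exponent of each binding reaction, optional pairwise
binding-cooperativity terms, and the per-state transcription capability.

Three families are covered:

``two_site``
    One kappaB site (NFkB) and one IRE site (IRF); 4 states.
``three_site``
    One kappaB site, a proximal IRE (IRE1) and a distal IRE (IRE2); 8 states.
``three_site_p50``
    The three-site model extended with competitive occupancy of IRE1 by the
    transcriptionally inert p50:p50 homodimer; 12 states.

State labels use '&'-joined tokens in the fixed order p50, N, I1, I2
(``"p50&N&I2"``); the empty occupancy set is labelled ``"unbound"``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import yaml

__all__ = [
    "BindingUnit",
    "CoopTerm",
    "ModelSpec",
    "ModelConfigError",
    "build_two_site",
    "build_three_site",
    "build_three_site_p50",
    "canonical_model_grid",
    "get_model",
]

# sites and admissible species
SITES = ("IRE1", "IRE2", "KB", "IRE")
SPECIES = ("IRF", "NFKB", "P50")
TOKEN_ORDER = {"p50": 0, "N": 1, "I": 2, "I1": 2, "I2": 3}
UNBOUND_LABEL = "unbound"

#: transcription capabilities that are fixed, never free parameters
T_UNBOUND = 0.0
T_FULL = 1.0


class ModelConfigError(ValueError):
    """Raised for malformed model configuration (unknown site/species/exponent)."""


@dataclass(frozen=True)
class BindingUnit:
    """One admissible site-species binding reaction.

    ``weight = k * activity**hill`` is the contribution of this occupancy to
    a state weight (the Hill-nonlinear binding equilibrium ``k*X**(h-1)``
    times one factor of ligand activity ``X``).
    """

    site: str
    species: str
    token: str
    k_param: str
    hill: int

    def __post_init__(self) -> None:
        if self.site not in SITES:
            raise ModelConfigError(f"unknown site {self.site!r}")
        if self.species not in SPECIES:
            raise ModelConfigError(f"unknown species {self.species!r}")
        if not (isinstance(self.hill, int) and 1 <= self.hill <= 6):
            raise ModelConfigError(
                f"Hill exponent must be an integer in [1, 6], got {self.hill!r}"
            )


@dataclass(frozen=True)
class CoopTerm:
    """Pairwise binding-cooperativity factor applied once per co-occupied pair."""

    tokens: frozenset
    c_param: str


@dataclass(frozen=True)
class ModelSpec:
    """Declarative enhancer model: structure + free-parameter declaration.

    ``capabilities`` maps a frozenset of non-p50 tokens to a linear
    expression ``(const, ((param, coef), ...))`` giving that state's
    transcription capability; p50-containing states inherit the capability
    of their non-p50 occupants.
    """

    family: str
    name: str
    units: tuple
    coop: tuple = ()
    distal_synergy_allowed: bool = True
    capabilities: dict = field(default_factory=dict, hash=False, compare=False)
    free_k: tuple = ()
    free_c: tuple = ()
    free_t: tuple = ()

    @property
    def free_params(self):
        """Ordered free parameter names: binding k's, cooperativity c's, t's."""
        return list(self.free_k) + list(self.free_c) + list(self.free_t)

    @property
    def hill(self):
        return {u.site: u.hill for u in self.units if u.species != "P50"}

    def t_expression(self, tokens: frozenset):
        """Linear expression for the transcription capability of a state."""
        key = frozenset(t for t in tokens if t != "p50")
        try:
            return self.capabilities[key]
        except KeyError:
            raise ModelConfigError(f"no capability declared for state {sorted(key)}")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "name": self.name,
            "units": [
                {
                    "site": u.site,
                    "species": u.species,
                    "token": u.token,
                    "k_param": u.k_param,
                    "hill": u.hill,
                }
                for u in self.units
            ],
            "coop": [
                {"tokens": sorted(c.tokens), "c_param": c.c_param} for c in self.coop
            ],
            "distal_synergy_allowed": self.distal_synergy_allowed,
            "capabilities": [
                {
                    "tokens": sorted(k),
                    "const": expr[0],
                    "coeffs": {p: c for p, c in expr[1]},
                }
                for k, expr in self.capabilities.items()
            ],
            "free_k": list(self.free_k),
            "free_c": list(self.free_c),
            "free_t": list(self.free_t),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelSpec":
        return cls(
            family=d["family"],
            name=d["name"],
            units=tuple(BindingUnit(**u) for u in d["units"]),
            coop=tuple(
                CoopTerm(frozenset(c["tokens"]), c["c_param"]) for c in d["coop"]
            ),
            distal_synergy_allowed=d["distal_synergy_allowed"],
            capabilities={
                frozenset(c["tokens"]): (
                    float(c["const"]),
                    tuple(sorted(c["coeffs"].items())),
                )
                for c in d["capabilities"]
            },
            free_k=tuple(d["free_k"]),
            free_c=tuple(d["free_c"]),
            free_t=tuple(d["free_t"]),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)

    @classmethod
    def from_json(cls, s: str) -> "ModelSpec":
        return cls.from_dict(json.loads(s))

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_yaml(cls, s: str) -> "ModelSpec":
        return cls.from_dict(yaml.safe_load(s))


def _check_exponent(name: str, h: int) -> None:
    if not (isinstance(h, int) and 1 <= h <= 6):
        raise ModelConfigError(f"{name} must be an integer Hill exponent in [1, 6], got {h!r}")


def _expr(param: str):
    return (0.0, ((param, 1.0),))


def build_two_site(hI: int = 1, hN: int = 1, cooperativity: bool = False,
                   name: str | None = None) -> ModelSpec:
    """Two-site model: one IRE (IRF, Hill hI) and one kappaB site (NFkB, Hill hN).

    Four states: unbound, N, I, N&I. tI and tN are free; the doubly bound
    state has maximal capability t=1 and the unbound state t=0.
    """
    _check_exponent("hI", hI)
    _check_exponent("hN", hN)
    units = (
        BindingUnit("IRE", "IRF", "I", "kI", hI),
        BindingUnit("KB", "NFKB", "N", "kN", hN),
    )
    coop = (CoopTerm(frozenset({"N", "I"}), "cNI"),) if cooperativity else ()
    capabilities = {
        frozenset(): (T_UNBOUND, ()),
        frozenset({"I"}): _expr("tI"),
        frozenset({"N"}): _expr("tN"),
        frozenset({"N", "I"}): (T_FULL, ()),
    }
    return ModelSpec(
        family="two_site",
        name=name or f"two_site_h{hI}" + ("_hN3" if hN == 3 else "") + ("_coop" if cooperativity else ""),
        units=units,
        coop=coop,
        capabilities=capabilities,
        free_k=("kI", "kN"),
        free_c=tuple(c.c_param for c in coop),
        free_t=("tI", "tN"),
    )


def _three_site_capabilities(distal_synergy_allowed: bool) -> dict:
    """Per-state capability map shared by the three-site families.

    Singly bound IRF states share one tI (proximal and distal alike); when
    distal synergy is disallowed the N&I2 state's capability is the additive
    tI + tN instead of a free tI2N.
    """
    tI2N = _expr("tI2N") if distal_synergy_allowed else (0.0, (("tI", 1.0), ("tN", 1.0)))
    return {
        frozenset(): (T_UNBOUND, ()),
        frozenset({"N"}): _expr("tN"),
        frozenset({"I1"}): _expr("tI"),
        frozenset({"I2"}): _expr("tI"),
        frozenset({"N", "I1"}): _expr("tI1N"),
        frozenset({"N", "I2"}): tI2N,
        frozenset({"I1", "I2"}): _expr("tI1I2"),
        frozenset({"N", "I1", "I2"}): (T_FULL, ()),
    }


def _irf_nfkb_coop(coop_flags, separate_nfkb_coop: bool):
    terms = []
    if "I1-I2" in coop_flags:
        terms.append(CoopTerm(frozenset({"I1", "I2"}), "cI1I2"))
    if "N-I1" in coop_flags:
        terms.append(
            CoopTerm(frozenset({"N", "I1"}), "cNI1" if separate_nfkb_coop else "cNI")
        )
    if "N-I2" in coop_flags:
        terms.append(
            CoopTerm(frozenset({"N", "I2"}), "cNI2" if separate_nfkb_coop else "cNI")
        )
    unknown = set(coop_flags) - {"I1-I2", "N-I1", "N-I2"}
    if unknown:
        raise ModelConfigError(f"unknown cooperativity flags {sorted(unknown)}")
    return tuple(terms)


def _coop_param_names(terms) -> tuple:
    seen: list = []
    for t in terms:
        if t.c_param not in seen:
            seen.append(t.c_param)
    return tuple(seen)


def build_three_site(hI1: int = 1, hI2: int = 1, hN: int = 1,
                     coop_flags=(), separate_nfkb_coop: bool = False,
                     name: str | None = None) -> ModelSpec:
    """Three-site model: proximal IRE1, distal IRE2 (both IRF) and a kappaB site.

    Eight states; free parameters kI1, kI2, kN and the five t's (tI shared by
    the singly bound IRF states, tN, tI1N, tI2N, tI1I2), plus any declared
    cooperativity factors.
    """
    for nm, h in (("hI1", hI1), ("hI2", hI2), ("hN", hN)):
        _check_exponent(nm, h)
    units = (
        BindingUnit("IRE1", "IRF", "I1", "kI1", hI1),
        BindingUnit("IRE2", "IRF", "I2", "kI2", hI2),
        BindingUnit("KB", "NFKB", "N", "kN", hN),
    )
    coop = _irf_nfkb_coop(coop_flags, separate_nfkb_coop)
    return ModelSpec(
        family="three_site",
        name=name or f"three_site_{hI1}&{hI2}",
        units=units,
        coop=coop,
        capabilities=_three_site_capabilities(True),
        free_k=("kI1", "kI2", "kN"),
        free_c=_coop_param_names(coop),
        free_t=("tI", "tN", "tI1N", "tI2N", "tI1I2"),
    )


def build_three_site_p50(hI1: int = 1, hI2: int = 3,
                         coop_flags=(), distal_synergy_allowed: bool = True,
                         separate_nfkb_coop: bool = False,
                         name: str | None = None) -> ModelSpec:
    """Three-site model with p50:p50 competing against IRF for the proximal IRE1.

    p50:p50 may co-occur with NFkB and/or IRF at IRE2 but excludes IRF from
    IRE1, adding four states (12 total). It contributes no transcription:
    each p50-containing state inherits the capability of its other occupants.
    NFkB binding is linear (KN); the p50 affinity KP is free.
    """
    _check_exponent("hI1", hI1)
    _check_exponent("hI2", hI2)
    units = (
        BindingUnit("IRE1", "IRF", "I1", "kI1", hI1),
        BindingUnit("IRE1", "P50", "p50", "KP", 1),
        BindingUnit("IRE2", "IRF", "I2", "kI2", hI2),
        BindingUnit("KB", "NFKB", "N", "kN", 1),
    )
    coop = _irf_nfkb_coop(coop_flags, separate_nfkb_coop)
    free_t = ("tI", "tN", "tI1N", "tI2N", "tI1I2") if distal_synergy_allowed \
        else ("tI", "tN", "tI1N", "tI1I2")
    return ModelSpec(
        family="three_site_p50",
        name=name or f"p50_{hI1}&{hI2}",
        units=units,
        coop=coop,
        distal_synergy_allowed=distal_synergy_allowed,
        capabilities=_three_site_capabilities(distal_synergy_allowed),
        free_k=("kI1", "kI2", "kN", "KP"),
        free_c=_coop_param_names(coop),
        free_t=free_t,
    )


def canonical_model_grid():
    """All named model variants evaluated in the analysis, as (name, spec) pairs.

    Two-site: hI x hN in {1,3}^2, each with and without NFkB-IRF binding
    cooperativity. Three-site: the 1&1/1&3/3&1/3&3 Hill combinations, each
    with and without NFkB-IRF cooperativity. p50 family: the four Hill
    combinations, each plain, with IRF-IRF cooperativity, with NFkB-IRF
    cooperativity, and with distal synergy disallowed (tI2N = tI + tN).
    """
    grid = []
    for hI in (1, 3):
        for hN in (1, 3):
            for coop in (False, True):
                spec = build_two_site(hI, hN, coop)
                grid.append((spec.name, spec))
    for hI1 in (1, 3):
        for hI2 in (1, 3):
            base = build_three_site(hI1, hI2, 1)
            grid.append((base.name, base))
            withc = build_three_site(hI1, hI2, 1, coop_flags=("N-I1", "N-I2"),
                                     name=f"three_site_{hI1}&{hI2}_coopNI")
            grid.append((withc.name, withc))
    for hI1 in (1, 3):
        for hI2 in (1, 3):
            base = build_three_site_p50(hI1, hI2)
            grid.append((base.name, base))
            coop_ii = build_three_site_p50(hI1, hI2, coop_flags=("I1-I2",),
                                           name=f"p50_{hI1}&{hI2}_coopII")
            grid.append((coop_ii.name, coop_ii))
            coop_ni = build_three_site_p50(hI1, hI2, coop_flags=("N-I1", "N-I2"),
                                           name=f"p50_{hI1}&{hI2}_coopNI")
            grid.append((coop_ni.name, coop_ni))
            nodistal = build_three_site_p50(hI1, hI2, distal_synergy_allowed=False,
                                            name=f"p50_{hI1}&{hI2}_nodistal")
            grid.append((nodistal.name, nodistal))
    return grid


def get_model(name: str) -> ModelSpec:
    """Look up a model variant from the canonical grid by name."""
    for nm, spec in canonical_model_grid():
        if nm == name:
            return spec
    raise ModelConfigError(f"unknown model name {name!r}")
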