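"""Multi-start Nelder-Mead fitting of ensemble models to a condition panel.

The loss is the unweighted sum of squared residuals between the model's
promoter activity f and the observed IFN-beta per condition (all quantities
share the max-normalized scale). Nelder-Mead is unconstrained, so binding
constants and cooperativity factors are optimized in log space and
transcription capabilities are clamped to [0, 1] inside the objective.
Each fit draws ``n_starts`` random initial parameter sets, polishes each
with Nelder-Mead, and returns the ``top_k`` local optima ranked by loss
(ties broken by start index) — the "top 20" ensemble used for prediction.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.optimize import minimize

from .data_io import ConditionPanel
from .model_library import ModelSpec, get_model
from .state_ensemble import CompiledEnsemble, ParameterSet

__all__ = [
    "FitConfig",
    "FitResult",
    "PanelPrediction",
    "loss",
    "sample_initial",
    "fit_model",
    "predict_panel",
    "worst_fit_point",
]

logger = logging.getLogger(__name__)


@dataclass
class FitConfig:
    """Settings for a multi-start fit.

    k_bounds / c_bounds are log-uniform sampling (and clamping) ranges in
    MNU^-1; t parameters are sampled uniformly on t_bounds. max_fev caps the
    number of objective evaluations per Nelder-Mead start.
    """

    n_starts: int = 1000
    top_k: int = 20
    seed: int = 0
    k_bounds: tuple = (1e-2, 1e4)
    t_bounds: tuple = (0.0, 1.0)
    c_bounds: tuple = (1e-2, 1e2)
    max_iter: int = 2000
    max_fev: int = 3000
    n_restarts: int = 2
    xatol: float = 1e-5
    fatol: float = 1e-9

    def __post_init__(self) -> None:
        if self.top_k > self.n_starts:
            raise ValueError("top_k must not exceed n_starts")
        for name in ("k_bounds", "c_bounds"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ValueError(f"{name} must be a positive increasing range")

    def to_dict(self) -> dict:
        d = asdict(self)
        for name in ("k_bounds", "t_bounds", "c_bounds"):
            d[name] = list(d[name])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "FitConfig":
        d = dict(d)
        for name in ("k_bounds", "t_bounds", "c_bounds"):
            if name in d:
                d[name] = tuple(d[name])
        return cls(**d)


@dataclass
class FitResult:
    """Ranked ensemble of optimized parameter sets for one model."""

    model_name: str
    ranked: list  # [(ParameterSet, loss)] ascending by loss
    config: FitConfig
    seed: int

    @property
    def best(self) -> ParameterSet:
        return self.ranked[0][0]

    @property
    def best_loss(self) -> float:
        return self.ranked[0][1]

    @property
    def losses(self) -> np.ndarray:
        return np.array([l for _, l in self.ranked])

    def members(self):
        return [p for p, _ in self.ranked]

    def t_values(self, name: str) -> np.ndarray:
        """A transcription parameter's value across the ensemble members."""
        return np.array([p.transcription[name] for p, _ in self.ranked])

    def to_json(self) -> str:
        return json.dumps(
            {
                "model_name": self.model_name,
                "seed": self.seed,
                "config": self.config.to_dict(),
                "ranked": [
                    {"loss": l, "params": p.to_flat_dict()} for p, l in self.ranked
                ],
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, s: str, spec: ModelSpec | None = None) -> "FitResult":
        d = json.loads(s)
        spec = spec or get_model(d["model_name"])
        ranked = [
            (ParameterSet.from_flat_dict(spec, r["params"]), float(r["loss"]))
            for r in d["ranked"]
        ]
        return cls(d["model_name"], ranked, FitConfig.from_dict(d["config"]), d["seed"])


def loss(spec: ModelSpec, params: ParameterSet, panel: ConditionPanel) -> float:
    """Sum of squared residuals between predicted f and observed IFN-beta."""
    ens = CompiledEnsemble(spec)
    basis = ens.activity_basis(panel.activities())
    x = ens.vector_from_params(params)
    k, c, t = ens.split_vector(x)
    f = ens.f(basis, k, t, c if len(c) else None)
    return float(np.sum((f - panel.observations()) ** 2))


def sample_initial(spec: ModelSpec, config: FitConfig,
                   rng: np.random.Generator) -> ParameterSet:
    """Draw one random starting parameter set.

    Binding constants and cooperativity factors are log-uniform on their
    bounds; transcription capabilities are uniform on [0, 1]. The draw order
    (k's, then c's, then t's, each in the spec's declared order) is fixed so
    identical seeds give identical streams.
    """
    lo_k, hi_k = np.log(config.k_bounds)
    lo_c, hi_c = np.log(config.c_bounds)
    binding = {n: float(np.exp(rng.uniform(lo_k, hi_k))) for n in spec.free_k}
    coop = {n: float(np.exp(rng.uniform(lo_c, hi_c))) for n in spec.free_c}
    t = {n: float(rng.uniform(*config.t_bounds)) for n in spec.free_t}
    return ParameterSet(binding=binding, transcription=t, cooperativity=coop)


def _make_objective(ens: CompiledEnsemble, basis: np.ndarray, obs: np.ndarray,
                    config: FitConfig):
    nk, nc = len(ens.k_names), len(ens.c_names)
    log_k = np.log(config.k_bounds)
    log_c = np.log(config.c_bounds)

    def constrain(z: np.ndarray):
        k = np.exp(np.clip(z[:nk], *log_k))
        c = np.exp(np.clip(z[nk:nk + nc], *log_c)) if nc else None
        t = np.clip(z[nk + nc:], 0.0, 1.0)
        return k, c, t

    def objective(z: np.ndarray) -> float:
        k, c, t = constrain(z)
        f = ens.f(basis, k, t, c)
        return float(np.sum((f - obs) ** 2))

    return objective, constrain


def fit_model(spec: ModelSpec, panel: ConditionPanel,
              config: FitConfig | None = None) -> FitResult:
    """Multi-start Nelder-Mead fit; returns the top_k ranked local optima."""
    if len(panel) == 0:
        raise ValueError("panel must be nonempty")
    config = config or FitConfig()
    ens = CompiledEnsemble(spec)
    basis = ens.activity_basis(panel.activities())
    obs = panel.observations()
    objective, constrain = _make_objective(ens, basis, obs, config)
    rng = np.random.default_rng(config.seed)
    nk, nc = len(ens.k_names), len(ens.c_names)

    results = []
    for i in range(config.n_starts):
        p0 = sample_initial(spec, config, rng)
        x0 = ens.vector_from_params(p0)
        z0 = np.concatenate([np.log(x0[:nk + nc]), x0[nk + nc:]])
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                # Nelder-Mead can stall with a collapsed simplex; restarting
                # from the incumbent until no further improvement polishes
                # each start to a genuine local optimum.
                res = None
                for _ in range(1 + config.n_restarts):
                    prev = res.fun if res is not None else np.inf
                    res = minimize(
                        objective, z0, method="Nelder-Mead",
                        options={
                            "maxiter": config.max_iter,
                            "maxfev": config.max_fev,
                            "xatol": config.xatol,
                            "fatol": config.fatol,
                        },
                    )
                    z0 = res.x
                    if prev - res.fun <= config.fatol:
                        break
        except Exception as exc:  # a failed start is discarded, never fatal
            logger.warning("start %d failed: %s", i, exc)
            continue
        k, c, t = constrain(res.x)
        vec = np.concatenate([k, c if c is not None else [], t])
        results.append((float(res.fun), i, ens.params_from_vector(vec)))

    results.sort(key=lambda r: (r[0], r[1]))
    ranked = [(p, l) for l, _, p in results[:config.top_k]]
    return FitResult(spec.name, ranked, config, config.seed)


@dataclass
class PanelPrediction:
    """Per-condition predictions of an ensemble: member f values and mean."""

    keys: list
    member_f: np.ndarray  # (n_members, n_conditions)
    mean_f: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.mean_f = self.member_f.mean(axis=0)

    def mean_for(self, key: str) -> float:
        return float(self.mean_f[self.keys.index(key)])


def predict_panel(spec: ModelSpec, fitresult: FitResult,
                  panel: ConditionPanel) -> PanelPrediction:
    """Evaluate each ensemble member's f on the panel and average."""
    ens = CompiledEnsemble(spec)
    basis = ens.activity_basis(panel.activities())
    rows = []
    for p in fitresult.members():
        k, c, t = ens.split_vector(ens.vector_from_params(p))
        rows.append(ens.f(basis, k, t, c if len(c) else None))
    return PanelPrediction(panel.keys, np.array(rows))


def worst_fit_point(spec: ModelSpec, fitresult: FitResult, panel: ConditionPanel):
    """Condition with the largest |ensemble-mean f - observation|.

    Ties are broken by panel order. Used to compare model variants: a model
    is rejected when even its best ensemble leaves one condition poorly fit.
    """
    pred = predict_panel(spec, fitresult, panel)
    resid = np.abs(pred.mean_f - panel.observations())
    idx = int(np.argmax(resid))  # argmax returns the first maximal index
    return panel.conditions[idx], float(resid[idx])
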