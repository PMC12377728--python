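"""Forward predictions from a fitted enhancer-state ensemble.

Given the top-K fitted parameter sets, these routines tabulate per-condition
state probabilities and transcription-unit (TU) decompositions, evaluate the
promoter on an NFkB x IRF dose-response grid at fixed p50, and titrate
p50:p50 under fixed stimulus inputs to expose the competitive tuning of the
N&IRF1 synergy mode.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_io import ConditionPanel
from .fitting import FitResult
from .model_library import ModelSpec
from .state_ensemble import CompiledEnsemble, TFActivity

__all__ = [
    "DoseGrid",
    "condition_state_table",
    "dose_response_grid",
    "p50_titration",
]


def _member_arrays(ens: CompiledEnsemble, fitresult: FitResult, act: np.ndarray):
    """Per-member state probabilities and TUs on an activity matrix.

    Returns (probs, tus), each of shape (n_members, n_rows, n_states).
    """
    basis = ens.activity_basis(act)
    probs, tus = [], []
    for p in fitresult.members():
        k, c, t = ens.split_vector(ens.vector_from_params(p))
        P = ens.probabilities(basis, k, c if len(c) else None)
        probs.append(P)
        tus.append(P * ens.t_vector(t)[None, :])
    return np.array(probs), np.array(tus)


def condition_state_table(spec: ModelSpec, fitresult: FitResult,
                          panel: ConditionPanel):
    """Ensemble-mean state probabilities and TUs per panel condition.

    Returns two DataFrames (probabilities, TUs), one row per condition and
    one column per state label.
    """
    ens = CompiledEnsemble(spec)
    probs, tus = _member_arrays(ens, fitresult, panel.activities())
    prob_df = pd.DataFrame(probs.mean(axis=0), index=panel.keys, columns=ens.labels)
    tu_df = pd.DataFrame(tus.mean(axis=0), index=panel.keys, columns=ens.labels)
    return prob_df, tu_df


@dataclass
class DoseGrid:
    """TU decomposition of the promoter on an NFkB x IRF grid at fixed p50."""

    nfkb_axis: np.ndarray
    irf_axis: np.ndarray
    p50: float
    labels: list
    tu: dict        # label -> (n_nfkb, n_irf) array
    f: np.ndarray   # (n_nfkb, n_irf)

    def to_frame(self) -> pd.DataFrame:
        """Tidy frame: nfkb, irf, state, tu."""
        rows = []
        for label in self.labels:
            arr = self.tu[label]
            for i, n in enumerate(self.nfkb_axis):
                for j, x in enumerate(self.irf_axis):
                    rows.append({"nfkb": n, "irf": x, "state": label,
                                 "tu": arr[i, j]})
        return pd.DataFrame(rows)


def dose_response_grid(spec: ModelSpec, params, p50: float = 1.0,
                       n: int = 101) -> DoseGrid:
    """Evaluate the TU decomposition on an n x n [0,1]^2 NFkB x IRF grid."""
    if n < 2:
        raise ValueError("grid needs n >= 2 points per axis")
    ens = CompiledEnsemble(spec)
    axis = np.linspace(0.0, 1.0, n)
    nf, ir = np.meshgrid(axis, axis, indexing="ij")
    act = np.column_stack([nf.ravel(), ir.ravel(), np.full(nf.size, p50)])
    basis = ens.activity_basis(act)
    k, c, t = ens.split_vector(ens.vector_from_params(params))
    P = ens.probabilities(basis, k, c if len(c) else None)
    TU = P * ens.t_vector(t)[None, :]
    tu = {label: TU[:, s].reshape(n, n) for s, label in enumerate(ens.labels)}
    f = TU.sum(axis=1).reshape(n, n)
    return DoseGrid(axis, axis, p50, ens.labels, tu, f)


def p50_titration(spec: ModelSpec, fitresult: FitResult,
                  stimulus_inputs: TFActivity, p50_values,
                  prob_states=("p50&N", "N&I1"),
                  tu_states=("N&I1", "N&I1&I2")) -> pd.DataFrame:
    """Ensemble mean +- SD of state probabilities and TUs along a p50 series.

    ``stimulus_inputs`` fixes nfkb and irf (its p50 field is ignored); each
    entry of ``p50_values`` overrides the p50 activity. Returns a tidy frame
    with columns p50, quantity ('prob' or 'tu'), state, mean, sd.
    """
    p50_values = np.asarray(p50_values, float)
    if np.any(p50_values < 0) or np.any(np.diff(p50_values) < 0):
        raise ValueError("p50_values must be nonnegative and sorted")
    ens = CompiledEnsemble(spec)
    act = np.column_stack([
        np.full(p50_values.size, stimulus_inputs.nfkb),
        np.full(p50_values.size, stimulus_inputs.irf),
        p50_values,
    ])
    probs, tus = _member_arrays(ens, fitresult, act)
    idx = {label: s for s, label in enumerate(ens.labels)}
    rows = []
    for quantity, arr, states in (("prob", probs, prob_states),
                                  ("tu", tus, tu_states)):
        for label in states:
            vals = arr[:, :, idx[label]]  # (members, p50 points)
            for j, p in enumerate(p50_values):
                rows.append({
                    "p50": p, "quantity": quantity, "state": label,
                    "mean": float(vals[:, j].mean()),
                    "sd": float(vals[:, j].std()),
                })
    return pd.DataFrame(rows)
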