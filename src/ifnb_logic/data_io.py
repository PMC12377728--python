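"""The 10-condition stimulus x genotype data panel.

Each condition records the nuclear activities of NFkB, IRF and the p50:p50
homodimer (max-normalized units, MNU) together with the observed IFN-beta
mRNA induction (MNU) for one genotype under one stimulus. The canonical
panel covers wild type under CpG / LPS / PolyIC, IRF3/7 and IRF3/5/7
knockouts, NFkB (RelA/cRel) knockouts, and p50 knockouts.

The canonical fixture shipped here is a documented reconstruction of the
curated literature panel: its activity and IFN-beta values were chosen so
that the published approximate best-fit parameters reproduce the published
state-probability tables. ``read_panel`` accepts any user-supplied CSV with
the same columns, so a curated panel can replace the reconstruction.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass

import pandas as pd

from .state_ensemble import TFActivity

__all__ = [
    "GENOTYPES",
    "STIMULI",
    "Condition",
    "ConditionPanel",
    "PanelFormatError",
    "read_panel",
    "write_panel",
    "canonical_fixture",
    "basal_condition",
    "apply_genotype",
]

GENOTYPES = ("WT", "IRF37ko", "IRF357ko", "NFkBko", "p50ko")
STIMULI = ("basal", "CpG", "LPS", "PolyIC")

PANEL_COLUMNS = ["genotype", "stimulus", "nfkb", "irf", "p50", "ifnb"]


class PanelFormatError(ValueError):
    """Raised when a panel file violates the expected schema."""


@dataclass(frozen=True)
class Condition:
    """One genotype x stimulus condition with TF inputs and observed IFN-beta."""

    genotype: str
    stimulus: str
    activity: TFActivity
    ifnb_obs: float

    def __post_init__(self) -> None:
        if self.genotype not in GENOTYPES:
            raise PanelFormatError(f"unknown genotype {self.genotype!r}")
        if self.stimulus not in STIMULI:
            raise PanelFormatError(f"unknown stimulus {self.stimulus!r}")
        if not 0 <= self.ifnb_obs <= 1.5:
            raise PanelFormatError(
                f"ifnb for {self.key} must be within [0, 1.5], got {self.ifnb_obs}"
            )

    @property
    def key(self) -> str:
        return f"{self.genotype}-{self.stimulus}"


@dataclass
class ConditionPanel:
    """Ordered collection of conditions with unique (genotype, stimulus) keys."""

    conditions: list
    name: str = "panel"

    def __post_init__(self) -> None:
        keys = [c.key for c in self.conditions]
        if len(set(keys)) != len(keys):
            dup = sorted({k for k in keys if keys.count(k) > 1})
            raise PanelFormatError(f"duplicate conditions: {dup}")

    def __len__(self) -> int:
        return len(self.conditions)

    def __iter__(self):
        return iter(self.conditions)

    def __getitem__(self, key):
        if isinstance(key, int):
            return self.conditions[key]
        for c in self.conditions:
            if c.key == key:
                return c
        raise KeyError(key)

    @property
    def keys(self):
        return [c.key for c in self.conditions]

    def activities(self):
        """(n, 3) activity matrix with columns nfkb, irf, p50."""
        import numpy as np

        return np.array([c.activity.as_array() for c in self.conditions])

    def observations(self):
        import numpy as np

        return np.array([c.ifnb_obs for c in self.conditions])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "genotype": c.genotype,
                    "stimulus": c.stimulus,
                    "nfkb": c.activity.nfkb,
                    "irf": c.activity.irf,
                    "p50": c.activity.p50,
                    "ifnb": c.ifnb_obs,
                }
                for c in self.conditions
            ],
            columns=PANEL_COLUMNS,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, name: str = "panel") -> "ConditionPanel":
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise PanelFormatError(f"missing column(s): {', '.join(missing)}")
        conditions = []
        for i, row in enumerate(df.itertuples(index=False)):
            try:
                vals = {c: float(getattr(row, c)) for c in ("nfkb", "irf", "p50", "ifnb")}
            except (TypeError, ValueError) as exc:
                raise PanelFormatError(f"row {i}: non-numeric value ({exc})") from exc
            for col, v in vals.items():
                if not 0 <= v <= 1.5:
                    raise PanelFormatError(
                        f"row {i}: {col}={v} outside the admissible [0, 1.5] MNU range"
                    )
                if v > 1:
                    warnings.warn(
                        f"row {i}: {col}={v} exceeds 1 MNU (max-normalized scale)",
                        stacklevel=2,
                    )
            try:
                cond = Condition(
                    genotype=str(row.genotype),
                    stimulus=str(row.stimulus),
                    activity=TFActivity(vals["nfkb"], vals["irf"], vals["p50"]),
                    ifnb_obs=vals["ifnb"],
                )
            except PanelFormatError as exc:
                raise PanelFormatError(f"row {i}: {exc}") from exc
            conditions.append(cond)
        return cls(conditions, name=name)


def read_panel(path) -> ConditionPanel:
    """Read a condition panel from CSV (columns genotype,stimulus,nfkb,irf,p50,ifnb)
    or from the mirroring JSON layout (list of row objects) if the path ends
    in ``.json``."""
    if str(path).endswith(".json"):
        with open(path) as fh:
            df = pd.DataFrame(json.load(fh))
    else:
        df = pd.read_csv(path)
    return ConditionPanel.from_frame(df, name=str(path))


def write_panel(panel: ConditionPanel, path) -> None:
    """Write a panel to CSV (or JSON for ``.json`` paths) at 4-decimal MNU
    precision; round-trips losslessly at that precision."""
    df = panel.to_frame().round(4)
    if str(path).endswith(".json"):
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2)
    else:
        df.to_csv(path, index=False, float_format="%.4f")


# (genotype, stimulus, nfkb, irf, p50, ifnb) — reconstruction of the curated
# literature panel; see module docstring.
_CANONICAL_ROWS = [
    ("WT", "CpG", 0.5, 0.01, 1.0, 0.02),
    ("WT", "LPS", 1.0, 0.25, 1.0, 0.45),
    ("WT", "PolyIC", 0.8, 1.0, 1.0, 1.0),
    ("IRF37ko", "LPS", 1.0, 0.02, 1.0, 0.02),
    ("IRF37ko", "PolyIC", 0.8, 0.1, 1.0, 0.2),
    ("IRF357ko", "PolyIC", 0.8, 0.0, 1.0, 0.0),
    ("NFkBko", "LPS", 0.0, 0.25, 1.0, 0.25),
    ("NFkBko", "PolyIC", 0.0, 1.0, 1.0, 1.0),
    ("p50ko", "CpG", 0.5, 0.01, 0.0, 0.30),
    ("p50ko", "LPS", 1.0, 0.25, 0.0, 0.60),
]


def canonical_fixture() -> ConditionPanel:
    """The canonical 10-condition panel (documented reconstruction)."""
    conditions = [
        Condition(g, s, TFActivity(n, i, p), f)
        for g, s, n, i, p, f in _CANONICAL_ROWS
    ]
    return ConditionPanel(conditions, name="canonical")


def basal_condition() -> Condition:
    """Unstimulated WT inputs, for prediction only (not part of the fitted panel)."""
    return Condition("WT", "basal", TFActivity(0.05, 0.01, 1.0), 0.0)


def apply_genotype(activity: TFActivity, genotype: str) -> TFActivity:
    """Zero the TF activities ablated by a genotype.

    NFkBko removes RelA/cRel activators (nfkb -> 0); p50ko removes the
    p50:p50 homodimer; IRF357ko ablates all IRF activity. IRF37ko leaves the
    measured residual IRF untouched — the residual is a data value.
    """
    if genotype not in GENOTYPES:
        raise PanelFormatError(f"unknown genotype {genotype!r}")
    if genotype == "NFkBko":
        return activity.replace(nfkb=0.0)
    if genotype == "p50ko":
        return activity.replace(p50=0.0)
    if genotype == "IRF357ko":
        return activity.replace(irf=0.0)
    return activity
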