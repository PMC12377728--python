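"""Tabulate enhancer-state probabilities and transcription contributions.

Loads the fitted 1&3 ensemble (run 01_fit_models.py first) and writes the
per-condition state-probability and TU tables, i.e. which of the twelve
occupancy states the enhancer sits in under each stimulus x genotype
condition and how much transcription each state contributes.

Finding: CpG parks the enhancer in the inactive NFkB&p50 state; LPS splits
occupancy between the half-active NFkB&IRF1 and the fully active
NFkB&IRF1&IRF2 states; PolyIC drives the fully bound state, which collapses
onto the equally active IRF1&IRF2 state when NFkB is removed.
"""

import pathlib

from ifnb_logic import FitResult, canonical_fixture, condition_state_table, get_model
from ifnb_logic.data_io import ConditionPanel, basal_condition

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    spec = get_model("p50_1&3")
    fit_path = RESULTS / "fit_p50_1and3.json"
    if not fit_path.exists():
        raise SystemExit("run analysis/01_fit_models.py first")
    fit = FitResult.from_json(fit_path.read_text(), spec)
    panel = canonical_fixture()
    # prepend the unstimulated condition for prediction (not part of the fit)
    display = ConditionPanel([basal_condition(), *panel], name="display")
    prob, tu = condition_state_table(spec, fit, display)
    prob.round(4).to_csv(RESULTS / "state_probabilities.csv")
    tu.round(4).to_csv(RESULTS / "state_tu.csv")
    for key in ("WT-CpG", "WT-LPS", "WT-PolyIC", "NFkBko-PolyIC", "p50ko-CpG"):
        top = prob.loc[key].sort_values(ascending=False).head(2)
        print(f"{key}: " + ", ".join(f"{s} {p:.0%}" for s, p in top.items()))
    print(f"wrote {RESULTS / 'state_probabilities.csv'} and state_tu.csv")


if __name__ == "__main__":
    main()
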