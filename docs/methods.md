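# Methods

## Model

The enhancer is treated as an equilibrium ensemble of occupancy states
(Shea–Ackers-style statistical thermodynamics). Sites: one κB site (NFκB),
a proximal IRE₁ (IRF, or the p50:p50 homodimer in the competition family),
and a distal IRE₂ (IRF). A state is any assignment of at most one species
per site; the three families therefore have 4, 8, and 12 states. Each
occupancy contributes `k · X^h` to the state weight — the Hill-nonlinear
binding equilibrium `k · X^(h−1)` times one factor of ligand activity `X`.
This `k · X^h` convention is fixed everywhere; since `h ≥ 1`, `0^0` never
arises and zero activity always gives zero weight. Declared cooperativity
terms multiply a state's weight once per co-occupied pair present (pairs
only; the fully bound state accrues every applicable pair factor).

Probabilities are weights normalized by the partition function (≥ 1, since
the unbound weight is 1), and promoter activity is `f = Σ P(s)·t_s` with
`t_unbound = 0`, `t_full = 1`, and the remaining capabilities free in
[0, 1]. p50-containing states inherit the capability of their non-p50
occupants (p50:p50 is transcriptionally inert). In the
"distal synergy disallowed" variant, the N&IRF₂ capability is the additive
`tI2N = tI + tN` rather than a free parameter; it is computed on the fly
and never stored or sampled.

Canonical state labels join tokens in the fixed order p50, N, I1, I2
("p50&N&I2"); the empty state is "unbound". Weights are computed in linear
space: panel activities are ≤ ~1 MNU and binding constants ≤ 10⁴ MNU⁻¹, so
no log-space machinery is needed. The hot path (fitting, grids) uses a
compiled incidence-matrix evaluator (`CompiledEnsemble`); the scalar
per-state functions are the readable reference path, and the test suite
checks both against a naive double-loop enumeration.

Open modeling choices resolved here: a single shared `tI` covers both
singly bound IRF states; NFκB–IRF binding cooperativity, when enabled in
the three-site families, uses one shared factor `cNI` by default (separate
`cNI1`/`cNI2` are available via a flag); Hill exponents are integers in
1–6, with the canonical grid using {1, 3} and NFκB fixed linear in the p50
family.

## Data panel

The fitted data are 10 genotype × stimulus conditions (WT / IRF3/7ko /
IRF3/5/7ko / NFκBko / p50ko under CpG, LPS, PolyIC), each with NFκB, IRF
and p50:p50 activities and observed IFNβ on the max-normalized [0, 1]
scale. The shipped `canonical_fixture()` is a documented reconstruction of
the curated literature panel: its values were chosen so that plugging the
published approximate best-fit parameters (kI1 ≈ 300, kI2 ≈ 30, KP ≈ 25,
kN ≈ 12 MNU⁻¹; tI = tN = 0, tI1N = 0.5, tI2N = tI1I2 = 1) into the model
reproduces the published per-condition state probabilities. `read_panel`
accepts any CSV with the same schema, so a curated panel can substitute for
the reconstruction; values are validated to [0, 1.5] with warnings above 1.
An unstimulated WT row is provided for prediction only — the fitted panel
is exactly the 10 stimulated conditions. Genotype transforms zero the
ablated activity (NFκBko → nfkb = 0, p50ko → p50 = 0, IRF3/5/7ko →
irf = 0); the residual IRF of IRF3/7ko is a measured data value and is
never transformed.

A known limitation of the reconstruction: the sum-of-squares optimum of the
reconstructed panel lies in a parameter basin with a very large proximal-IRE
binding constant (kI1 at the upper sampling bound, with kI1/KP ≈ 14
preserved) and correspondingly smaller tI1N (≈ 0.32) and tI2N (≈ 0.68) than
the published regime, because the reconstruction's p50ko-CpG and WT-LPS
observations are fit slightly better by saturating IRE₁ occupancy. All
qualitative conclusions (two synergy modes, silent single-TF states,
stimulus-specific state usage, model discrimination in favor of 1&3) are
unchanged; per-condition occupancies of the dominant states agree with the
published values to within a few percentage points.

## Fitting

Loss is the unweighted sum of squared residuals between predicted `f` and
observed IFNβ (all observations share the MNU scale). Each fit draws
`n_starts` initial parameter sets — binding constants and cooperativity
factors log-uniform on [10⁻², 10⁴] and [10⁻², 10²] MNU⁻¹ respectively,
capabilities uniform on [0, 1] — and polishes each with Nelder–Mead.
Nelder–Mead is unconstrained, so k and c are optimized as logarithms
clamped to their bounds inside the objective and t values are clamped to
[0, 1]. Because a single Nelder–Mead run can stall with a collapsed
simplex, each start is re-run from its incumbent (`n_restarts`, default 2)
until the improvement falls below `fatol`. The `top_k = 20` local optima,
ranked by loss with ties broken by start index, form the prediction
ensemble; per-condition predictions are ensemble means. Failed starts are
logged and discarded. Everything is reproducible from the seed, and start
streams are nested: increasing `n_starts` can only improve the best loss.

Model comparison follows the worst-fit criterion: a variant is judged by
the condition with the largest absolute residual between ensemble-mean
prediction and observation.

Defaults: `n_starts` 1000 for production fits; the analysis scripts and
end-to-end tests use 100–200 starts, which reach the same optima on this
10-condition panel at a fraction of the cost. Optimizer tolerances default
to `xatol` 10⁻⁵, `fatol` 10⁻⁹, ≤ 3000 function evaluations per start.

## Synthetic data and recovery

Ground truths are drawn either in the fitted "synergy" regime
(tI, tN ~ U[0, 0.1]; tI1I2, tI2N ~ U[0.9, 1]; tI1N ~ U[0.3, 0.7]; binding
constants log-uniform within a decade of the fitted values, kN spanning its
weakly identified 5–10³ MNU⁻¹ range) or uniformly over the full sampling
bounds ("random"). Panels are forward-simulated at the canonical input
activities; observation noise (additive Gaussian, clipped to [0, 1]) is off
by default because the robustness analysis perturbs inputs, not readouts.
The recovery harness fits noise-free simulated panels and reports
capability errors and the worst per-condition |f_fit − f_true|; binding
constants are recovered only up to identifiability, so f-space agreement is
the fidelity measure. What passing recovery shows: the optimizer can
re-identify the generating logic from ideal data of this panel's size and
design. What it does not show: identifiability under real measurement
error, cross-laboratory normalization artifacts, or inputs outside the
panel's activity range.

## Noise robustness

The robustness study multiplies each condition's NFκB and IRF activities by
`1 + ε`, `ε ~ N(0, error)` — "x% error" is interpreted as the standard
deviation of multiplicative Gaussian input noise — clipped below at 0 (so
knockout zeros stay zero), with p50 and the observed IFNβ untouched and no
upper clip (max-normalization describes the original data, not a hard
bound). For each error level, `n_datasets` perturbed panels are refit and
the best parameter set per dataset is kept; summaries are per-parameter
medians and IQRs plus the fraction of datasets whose best fit satisfies the
synergy requirement (tI, tN < 0.2 and tI1I2, tI2N > 0.8). Canonical levels
are 1/10/20/40% with 100 datasets; the scripted runs use 25 datasets at 100
starts each, a documented scale-down.

## Forward predictions

State tables report ensemble-mean probabilities and TU contributions per
condition (mean and population SD across the top 20). Dose-response grids
evaluate the TU decomposition on an n × n grid over [0, 1]² NFκB × IRF at
fixed p50 (default 101 × 101, exported as tidy CSV, not images). The p50
titration sweeps p50:p50 over [0, 2] MNU (the basal level is 1, so the
sweep covers depletion through doubling) at fixed stimulus inputs and
tracks P(N&I1), P(p50&N), TU(N&I1) and TU(N&I1&I2). Conservation
(f = Σ TU) holds to 10⁻¹⁰ at every grid point by construction and is
asserted in tests.

## Numerical notes and degenerate inputs

- Probabilities normalize to 1 within 10⁻¹² (the partition function is
  bounded below by the unbound weight).
- All-zero activities give P(unbound) = 1 and f = 0 exactly.
- Ties in ensemble ranking are broken by start index; ties in the worst-fit
  condition by panel order.
- Empty panels, non-positive binding constants, capabilities outside
  [0, 1], negative activities, unknown genotypes/sites/species, and
  malformed panel files raise typed errors with the offending field or row.
- `kN` is structurally weakly identified by this panel (NFκB is either 0 or
  saturating in most conditions); tests assert f-space agreement rather
  than kN recovery.

## Limitations

- The ensemble is equilibrium-only: no kinetics of activation, chromatin
  remodeling, or mRNA turnover.
- No AP1 site or additional upstream elements; activities are static
  scalars per condition rather than signaling time courses.
- The shipped panel is a reconstruction (see above); analyses that depend
  on the exact location of the fitted optimum in parameter space — rather
  than on predicted occupancies and expression — should be re-run with a
  curated data matrix via `read_panel`.
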