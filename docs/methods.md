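# Methods

## Setting and estimand

The package evaluates a policy that, from a fixed onset year, covers a set
of healthcare quality indicators while comparable indicators from other
clinical areas remain uncovered. Data are annual national aggregates: for
indicator `i` and year `t`, a population size `n_it` (cases) and an
adverse-care-event count `e_it`. Because the policy applied simultaneously
to all hospitals, there is no regional or provider-level variation to
exploit; the treated unit is the indicator, and the DiD contrasts the
pre-to-post change of the *average program indicator* against the average
control indicator.

Two estimands are reported. The pooled logit-scale DiD `δ` (and `exp(δ)`,
an odds ratio) refers to the average indicator in an average year. The
marginal ATT risk ratio re-weights by patients: observed vs counterfactual
post-period event probability for the average treated patient, with each
program×post cell weighted by `n_it`. Absolute prevented events are
`Σ n_it (p*_it − p_it)`.

## Identification and estimation choices

**Parallel trends on the logit scale.** The identifying assumption is that
without the program the group-mean logits would have evolved in parallel.
The logit link accommodates proportions with baselines spanning orders of
magnitude (0.2%–10% in the study data); an additive effect on the logit
scale is a constant odds ratio.

**Equal indicator weights, equal year weights.** Group-year means weight
every indicator equally regardless of `n_it`, fixing the indicator mix over
time. The pooled δ is the difference of unweighted year-means of these
group-year means (two-stage equal weighting). Equal year weights are the
natural choice for the balanced 4+4 pre/post design; with an unbalanced
design the two-stage construction still defines the estimand but no longer
coincides with a single cell-level regression. `estimator.did_via_ols`
provides the cell-level fixed-effects (indicator + year + treated×post) OLS
equivalent as a cross-check; on balanced panels the two agree to machine
precision, and the test suite additionally checks δ against a pure-Python
two-way mean decomposition.

**Counterfactual construction.** The headline risk ratio applies the single
pooled δ uniformly to all program×post cells, `p*_it = expit(logit(p_it) −
δ)`, matching how a pooled estimate is usually transformed. A year-specific
variant (`delta_by_year`, e.g. the post-onset event-study path) is exposed
for sensitivity analysis; with a ramping effect it attributes less of the
first post year's gap to the program.

**Continuity correction.** `logit(p)` is undefined at `p ∈ {0, 1}`.
Observed national aggregates never reach the boundary, but bootstrap
replicates of small cells can. Boundary cells use `(e + 0.5) / (n + 1)`
(Haldane–Anscombe style) *inside the logit only*; raw proportions are kept
for the patient-weighted probability sums. Every correction is logged at
WARNING level and surfaces in the run log.

**Risk-ratio orientation.** `RR = p_obs / p_cf` (observed over
counterfactual), so a beneficial program gives `RR < 1` and "probability
reduced by `1 − RR`" reads off directly.

## Uncertainty

**Parametric binomial bootstrap (default).** Aggregated data leave no
patient-level resampling unit, so replicates redraw each cell count from
`Binomial(n_it, p̂_it)` holding the panel structure fixed, rerun the entire
chain, and collect δ, the odds ratio, the risk ratio, prevented counts and
the full event-study path per replicate — derived quantities are therefore
transformed *within* replicates, never by post-hoc transformation of the δ
interval. Percentile intervals are the default; a normal approximation (on
the log scale for ratio quantities) is available as a cross-check. The
generator is seeded; identical configuration gives bit-identical bounds.

Two variants are exposed and labeled because the published record does not
say which is intended: `risk_ratio` / `prevented_total` propagate each
replicate's own δ, while the `*_conditional` versions hold δ at its point
estimate and only resample the cells.

**Delta method.** δ is linear in the cell logits with weights ±1/(group
size × period length); with `Var(logit p̂_it) ≈ 1/(n_it p̂_it (1 − p̂_it))`
this gives a closed-form SE used as an independent check — bootstrap and
delta-method SEs agree within ~10% on simulated panels.

**Indicator resampling (option).** Drawing indicators with replacement
within groups targets a superpopulation-of-indicators estimand (uncertainty
from indicator heterogeneity rather than binomial noise). It is available
via `resample_unit="indicators"` but is not the default, since the study
indicators are a fixed, exhaustively enumerated set.

## Synthetic data generator

`generate_panel` draws, per panel: indicator intercepts
`α_i ~ Normal(−3.9, 1.0)` on the logit scale (once per panel — indicator
identity is stable across years, mirroring the comparability requirement of
the inclusion rules); a common linear trend (default −0.05/year, mild
secular quality improvement); a post-onset effect path added to program
indicators (default ramp-then-plateau `{2017: −0.35, 2018: −0.60,
2019: −0.60, 2020: −0.70}`, a free parameter shaped like typical
announcement-driven policy responses — tests never treat the default path
as ground truth); and `e_it ~ Binomial(n_it, expit(θ_it))`. Population
sizes take a per-indicator base drawn log-uniform between `10^3.5` and
`10^5.5` with ±10% annual jitter: case volumes differ enormously *between*
indicators but are stable *within* an indicator over years, and the
resulting marginal event proportions span roughly 0.2%–10%, matching the
observed study range. True logits are clamped to keep probabilities inside
`(10⁻⁶, 1 − 10⁻⁶)`, with a logged warning.

The defaults are calibrated to the aggregate features of the study data
(baseline spread, population spread, 9+10 indicators, 2013–2020, onset
2017). What the generator deliberately does **not** emulate: within-year
overdispersion beyond binomial sampling, provider-level clustering,
correlated shocks across indicators (e.g., a pandemic year hitting one
clinical area), or drifting population shares. Passing recovery and
coverage tests therefore demonstrates correctness of the estimation
machinery under the model's own assumptions — not robustness of the design
to their violation; that question is addressed separately by the violation
generator (`generate_violation_panel`), where an additive shift `s` on
control post-period logits provably moves `E[δ̂]` by `−s` and a pre-onset
slope divergence is picked up by the pre-trend diagnostic.

## Data layer conventions

Input files are UTF-8 CSV with a header; a column-name mapping adapts
externally exported tables without code changes. Reverse-coded sources
(favorable-event counts) are complemented at load time so stored counts
always measure adverse events. Panels must be balanced (every indicator ×
year exactly once); cells with `n_it = 0` are rejected as corrupt rather
than imputed, since every analyzed indicator has large annual populations.
Eligibility attributes (comparability ratings, reference-range presence,
validity assessments) are supplied as metadata columns and filtered by a
pure predicate; the three-level comparability vocabulary
(`not_comparable < moderately_comparable < fully_comparable`) is a minimal
ordinal encoding of the published rating language. Years are calendar data
years; the post-period is `year ≥ onset`.

The bundled study table carries only 8-year aggregates (the published
per-year series are not in the main record); `annualized_demo_panel`
splits them evenly across years — exact in the totals, synthetic in the
yearly split — to exercise the pipeline, not to estimate real trends.

## Numerical and reporting conventions

Rounding (two decimals for δ/OR/RR, nearest hundred for prevented events)
applies only in the human-readable summary; exported tables keep full
precision. Every table carries the config hash (analytic configuration
only, excluding the output path) and seed. Problem sizes used by the
Monte-Carlo checks — 200 panels with 500 bootstrap replicates for recovery
and coverage, 100 panels for null and violation checks, 2000 replicates for
a single-panel interval — give Monte-Carlo error comfortably below the
assertion tolerances (e.g., SE of mean δ̂ ≈ 0.002 at 200 panels against a
±0.02 recovery band).

## Known limitations

- The design cannot test parallel counterfactual trends; the pre-trend
  diagnostic flags violations only as far as pre-onset data reveal them.
- With aggregated data, bootstrap uncertainty reflects binomial sampling
  only; provider clustering would widen honest intervals.
- The pooled δ averages a possibly dynamic effect; the event-study path
  should always be inspected alongside it.
- Outcome indicators are excluded by design (risk-adjustment drift);
  conclusions are confined to process/indication quality.
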