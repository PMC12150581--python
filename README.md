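# qualdid

Difference-in-differences (DiD) impact evaluation for panels of healthcare
**quality indicators**, built for the setting where a national quality policy
covers some indicators but not others, so the treated and control units are
indicators rather than hospitals or regions. The motivating application is
Germany's 2017 quality-assurance directive for hospital capacity planning:
9 program and 10 control process/indication indicators, each observed as
annual national aggregates (population size `n_it`, adverse-care-event count
`e_it`) over 2013–2020.

It is intended for health-services researchers and quality-assurance
analysts evaluating policies with routinely collected, aggregated indicator
data.

## The model

Let `p_it = e_it / n_it` be the adverse-event proportion of indicator `i` in
year `t` and `ȳ_gt` the *unweighted* mean of `logit(p_it)` over the
indicators of group `g ∈ {program, control}` — equal indicator weights fix
the indicator mix over time, which blocks confounding through shifting
population shares between indicators whose baseline risks differ by orders
of magnitude. Under parallel counterfactual trends on the logit scale, the
pooled effect is

```
δ = (ȳ_P,post − ȳ_P,pre) − (ȳ_C,post − ȳ_C,pre)
```

with equal weight per year within each period; `exp(δ)` is the odds ratio
for the average program indicator in an average year. Year-wise estimates
`δ_t = (ȳ_P,t − ȳ_C,t) − (ȳ_P,2016 − ȳ_C,2016)` form the event-study path
(pre-onset years double as the parallel-trends diagnostic). The effect is
marginalized over treated patients via counterfactual cell probabilities
`p*_it = expit(logit(p_it) − δ)`: the marginal ATT risk ratio is
`RR = (Σ e_it / Σ n_it) / (Σ n_it p*_it / Σ n_it)` over program×post cells,
and `Σ n_it (p*_it − p_it)` counts the adverse events prevented by the
program. Intervals come from a parametric binomial bootstrap
(`e_it ~ Binomial(n_it, p̂_it)`, full re-estimation per replicate), with a
closed-form delta-method cross-check.

A synthetic-panel generator (`qualdid.simulate`) draws panels from exactly
this data-generating process — per-indicator baseline logits, a common
linear trend, a configurable post-onset effect path, binomial sampling with
realistic population sizes — plus controlled violations (pre-trend
divergence, control-group spillover) for bias studies.

## Worked example

```yaml
# demo.yaml
simulate:
  seed: 1
  effect_path: {2017: -0.61, 2018: -0.61, 2019: -0.61, 2020: -0.61}
bootstrap:
  n_replicates: 2000
  seed: 1
```

```
$ qualdid estimate --config demo.yaml --out demo_out
delta (logit DiD): -0.61
odds ratio:        0.54
risk ratio (ATT):  0.55
prevented events:  26,900
  95% CI delta: (-0.664, -0.574)
  95% CI risk_ratio: (0.52, 0.568)
  95% CI prevented_total: (2.46e+04, 2.99e+04)
```

The simulated panel was drawn with a true constant program effect of
δ = −0.61 on the logit scale; the estimate recovers it, the implied odds
ratio `exp(−0.61) ≈ 0.54` says the odds of an adverse event for the average
program indicator were roughly halved, and the risk ratio of 0.55 says the
average treated patient's event probability fell by about 45% relative to
the no-program counterfactual — about 26,900 adverse events avoided in this
synthetic population. `demo_out/` contains the full report bundle: tidy CSV
tables for the group-year mean trajectories, the event-study path with
intervals, observed/counterfactual group-period probabilities, per-indicator
prevented events, the bootstrap draws, and a `summary.json` + `run.log`
carrying the config hash and seeds.

The same pipeline runs on real data (`input: {panel: ..., metadata: ...}`
instead of a `simulate:` block); `qualdid.datasets` ships the 19 study
indicators with their published 2013–2020 national aggregates. The
library surface (`load_panel`, `select_control_candidates`,
`apply_final_inclusion`, `estimate`, `att_summary`, `parametric_bootstrap`,
`pretrend_diagnostic`, ...) exposes every stage individually.

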