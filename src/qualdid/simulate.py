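"""Synthetic indicator panels under the assumed data-generating process.

The generator mirrors the identification assumptions of the analysis: each
indicator carries a time-constant baseline logit (drawn once per panel, so
baseline adverse-event risks span orders of magnitude, roughly 0.2%-10%
under the defaults), both groups share a common linear year trend on the
logit scale (parallel trends), and program indicators additionally receive
a program effect from the onset year on, by default a ramp that plateaus
after two years.  Event counts are binomial draws with indicator-specific
annual population sizes spanning thousands to several hundred thousand
cases.

A violation generator injects controlled departures from the assumptions —
a diverging pre-trend for the program group, or a spillover shift on
control-group post-period logits — to quantify estimator bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.special

from .panel import Comparability, Group, IndicatorMeta, IndicatorType, PanelDataset

import pandas as pd

__all__ = [
    "DgpConfig",
    "constant_effect",
    "implied_pooled_delta",
    "generate_panel",
    "generate_violation_panel",
]

logger = logging.getLogger(__name__)

#: default program-effect path on the logit scale: rapid ramp over the first
#: two program years, then a plateau with a slight late increase
DEFAULT_EFFECT_PATH = {2017: -0.35, 2018: -0.60, 2019: -0.60, 2020: -0.70}

_THETA_BOUND = scipy.special.logit(1e-6)  # clamp |theta| so p stays in (1e-6, 1-1e-6)


@dataclass(frozen=True)
class DgpConfig:
    """Parameters of the synthetic data-generating process.

    ``baseline_logit_mean``/``sd`` parameterize the per-indicator intercept
    α_i ~ Normal(mean, sd²), shared across groups by default.
    ``common_slope`` is the yearly logit trend common to both groups
    (negative = quality improves).  ``effect_path`` maps each post-onset
    calendar year to the program effect δ_t added to program indicators.
    Annual population sizes are log-uniform between ``population_range``
    bounds per indicator, with a small uniform year-to-year jitter.
    """

    n_program: int = 9
    n_control: int = 10
    years: Sequence[int] = tuple(range(2013, 2021))
    onset_year: int = 2017
    reference_year: int = 2016
    baseline_logit_mean: float = -3.9
    baseline_logit_sd: float = 1.0
    common_slope: float = -0.05
    effect_path: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_PATH)
    )
    population_range: tuple[float, float] = (10**3.5, 10**5.5)
    population_jitter: float = 0.1
    seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "years", tuple(int(y) for y in self.years))
        post = [y for y in self.years if y >= self.onset_year]
        missing = [y for y in post if y not in self.effect_path]
        if missing:
            raise ValueError(f"effect_path lacks post-onset years {missing}")
        if self.n_program < 1 or self.n_control < 1:
            raise ValueError("need at least one indicator per group")


def constant_effect(delta: float, *, years=tuple(range(2013, 2021)),
                    onset_year: int = 2017) -> dict[int, float]:
    """Effect path with the same δ in every post-onset year."""
    return {int(y): float(delta) for y in years if y >= onset_year}


def implied_pooled_delta(config: DgpConfig) -> float:
    """The pooled DiD implied by the configured effect path.

    With equal year weights and no assumption violations, the estimand
    equals the unweighted mean of δ_t over the post-onset years.
    """
    post = [y for y in config.years if y >= config.onset_year]
    return float(np.mean([config.effect_path[y] for y in post]))


def _make_metas(config: DgpConfig) -> dict[str, IndicatorMeta]:
    comp = {y: Comparability.FULLY_COMPARABLE for y in config.years}
    metas = {}
    for k in range(config.n_program):
        iid = f"P{k + 1:02d}"
        metas[iid] = IndicatorMeta(
            indicator_id=iid, label=f"synthetic program indicator {k + 1}",
            clinical_area="synthetic program area", group=Group.PROGRAM,
            indicator_type=IndicatorType.PROCESS, comparability_by_year=comp,
            area_reviewed_for_program=True,
        )
    for k in range(config.n_control):
        iid = f"C{k + 1:02d}"
        metas[iid] = IndicatorMeta(
            indicator_id=iid, label=f"synthetic control indicator {k + 1}",
            clinical_area="synthetic control area", group=Group.CONTROL,
            indicator_type=IndicatorType.PROCESS, comparability_by_year=comp,
        )
    return metas


def _true_logits(config: DgpConfig, rng: np.random.Generator,
                 trend_divergence: float, spillover: float):
    """Per-indicator true logit matrix θ (indicators × years) plus metadata."""
    metas = _make_metas(config)
    ids = sorted(metas)  # C01..C10, P01..P09 — order fixed by id
    is_program = np.array([metas[i].group == Group.PROGRAM for i in ids])
    years = np.array(config.years)
    alpha = rng.normal(config.baseline_logit_mean, config.baseline_logit_sd,
                       size=len(ids))
    theta = alpha[:, None] + config.common_slope * (years - config.onset_year)[None, :]
    post = years >= config.onset_year
    effect = np.array([config.effect_path.get(int(y), 0.0) if p else 0.0
                       for y, p in zip(years, post)])
    theta[is_program] += effect[None, :]
    if trend_divergence:
        # extra pre-onset slope for program indicators, anchored to zero at
        # the last pre-onset year so the reference-year gap is unchanged
        pre_ramp = np.where(~post, years - (config.onset_year - 1), 0.0)
        theta[is_program] += trend_divergence * pre_ramp[None, :]
    if spillover:
        theta[~is_program] += spillover * post[None, :].astype(float)
    out_of_range = np.abs(theta) > np.abs(_THETA_BOUND)
    if out_of_range.any():
        logger.warning(
            "clamping %d true logit(s) outside (1e-6, 1-1e-6) probability range",
            int(out_of_range.sum()),
        )
        theta = np.clip(theta, _THETA_BOUND, -_THETA_BOUND)
    return metas, ids, years, theta


def _generate(config: DgpConfig, rng: np.random.Generator | None,
              trend_divergence: float = 0.0, spillover: float = 0.0) -> PanelDataset:
    if rng is None:
        rng = np.random.default_rng(config.seed)
    metas, ids, years, theta = _true_logits(config, rng, trend_divergence, spillover)
    lo, hi = config.population_range
    base = np.exp(rng.uniform(np.log(lo), np.log(hi), size=len(ids)))
    jitter = rng.uniform(1 - config.population_jitter, 1 + config.population_jitter,
                         size=(len(ids), len(years)))
    n = np.maximum(1, np.round(base[:, None] * jitter)).astype(np.int64)
    p = scipy.special.expit(theta)
    e = rng.binomial(n, p)
    cells = pd.DataFrame({
        "indicator_id": np.repeat(ids, len(years)),
        "year": np.tile(years, len(ids)),
        "population_size": n.ravel(),
        "event_count": e.ravel(),
    })
    return PanelDataset(
        metas=metas, cells=cells, years=config.years,
        program_onset_year=config.onset_year, reference_year=config.reference_year,
    )


def generate_panel(config: DgpConfig, rng: np.random.Generator | None = None
                   ) -> PanelDataset:
    """Draw one balanced synthetic panel from the configured process.

    For indicator i in year t the true logit is
    θ_it = α_i + slope·(t − onset) + δ_t·[i ∈ program][t ≥ onset], and the
    event count is Binomial(n_it, expit(θ_it)).  Pass an explicit ``rng``
    to draw replicate panels from one generator stream; otherwise
    ``config.seed`` initializes a fresh stream (same seed, same panel).
    """
    return _generate(config, rng)


def generate_violation_panel(
    config: DgpConfig,
    *,
    trend_divergence: float = 0.0,
    spillover: float = 0.0,
    rng: np.random.Generator | None = None,
) -> PanelDataset:
    """Panel with controlled violations of the identifying assumptions.

    ``trend_divergence`` adds an extra pre-onset slope (per year) to program
    indicators, anchored at the last pre-onset year — the event-study
    pre-period then deviates visibly from zero.  ``spillover`` shifts
    control-group post-period logits additively by the given amount; the
    DiD contrast then recovers δ_true − spillover, so a program that also
    *improves* control indicators (negative shift on the adverse-event
    logit) biases the estimated effect toward zero.  Both zero reduces to
    :func:`generate_panel`.
    """
    return _generate(config, rng, trend_divergence=trend_divergence,
                     spillover=spillover)
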