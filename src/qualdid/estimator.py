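"""Equal-indicator-weight difference-in-differences on the logit scale.

The identifying assumption is that, absent the 2017 program, the *average
indicator* logit of the adverse-event proportion in the program group would
have moved in parallel to the control-group average.  Estimation is a
two-stage mean construction: per group and year, the unweighted mean over
indicators of logit(p_it); the pooled effect δ is then the pre-to-post
change of that mean in the program group minus the same change in the
control group, with equal weight per year.  exp(δ) is the odds ratio for
the average program indicator in an average year.

The marginal ATT risk ratio re-weights by patients: the observed
post-period program-group event probability (patient-weighted) divided by
its counterfactual under no program, where each cell's counterfactual
probability removes δ on the logit scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.special

from .panel import Group, PanelDataset

__all__ = [
    "logit",
    "expit",
    "corrected_proportion",
    "cell_logits",
    "group_year_means",
    "pooled_did",
    "did_via_ols",
    "event_study",
    "counterfactual_cells",
    "att_summary",
    "estimate",
    "DidEstimate",
    "AttSummary",
]

logger = logging.getLogger(__name__)


def logit(p):
    """log(p / (1-p)); defined on the open unit interval only.

    Boundary proportions are handled upstream by the continuity correction
    (:func:`corrected_proportion`), never by this function.
    """
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("logit requires probabilities strictly inside (0, 1)")
    out = scipy.special.logit(p)
    return float(out) if out.ndim == 0 else out


def expit(x):
    """Inverse logit, 1 / (1 + exp(-x))."""
    out = scipy.special.expit(np.asarray(x, dtype=float))
    return float(out) if out.ndim == 0 else out


def corrected_proportion(event_count, population_size):
    """Proportion with a Haldane-Anscombe-style continuity correction.

    Returns e/n except at the boundary (e = 0 or e = n), where
    (e + 0.5)/(n + 1) keeps the logit finite.  Observed national aggregates
    never hit the boundary, but bootstrap replicates of small cells can.
    Corrections are counted and logged at WARNING level.
    """
    e = np.asarray(event_count, dtype=float)
    n = np.asarray(population_size, dtype=float)
    at_boundary = (e == 0) | (e == n)
    n_corr = int(np.count_nonzero(at_boundary))
    if n_corr:
        logger.warning("continuity correction applied to %d boundary cell(s)", n_corr)
    p = np.where(at_boundary, (e + 0.5) / (n + 1.0), e / np.where(n > 0, n, 1.0))
    return float(p) if p.ndim == 0 else p


def cell_logits(panel: PanelDataset) -> pd.DataFrame:
    """Tidy cell table with continuity-corrected proportions and logits."""
    df = panel.to_frame()
    df["p_corrected"] = corrected_proportion(
        df.event_count.to_numpy(), df.population_size.to_numpy()
    )
    df["logit_p"] = logit(df.p_corrected.to_numpy())
    return df


def group_year_means(panel: PanelDataset) -> pd.DataFrame:
    """Average indicator logit per group and year (Fig-1A-style trajectories).

    Every indicator receives the same weight regardless of its population
    size; this fixes the indicator mix over time and thereby blocks
    confounding through shifting population shares between indicators whose
    baseline risks differ by orders of magnitude.
    """
    df = cell_logits(panel)
    out = (
        df.groupby(["group", "year"], as_index=False)
        .agg(mean_logit=("logit_p", "mean"), n_indicators=("indicator_id", "nunique"))
        .sort_values(["group", "year"], kind="mergesort")
        .reset_index(drop=True)
    )
    return out


def _period_means(means: pd.DataFrame, onset_year: int) -> pd.DataFrame:
    m = means.copy()
    m["period"] = np.where(m.year >= onset_year, "post", "pre")
    return m.groupby(["group", "period"])["mean_logit"].mean()


def pooled_did(means: pd.DataFrame, onset_year: int) -> float:
    """Pooled DiD δ on the logit scale.

    δ = (post − pre change of the program-group year-mean trajectory)
    minus the same change for the control group, each period mean taken
    with equal weight per year.
    """
    pm = _period_means(means, onset_year)
    for g in ("program", "control"):
        for p in ("pre", "post"):
            if (g, p) not in pm.index:
                raise ValueError(f"no {p}-period years for group {g!r}")
    return float(
        (pm["program", "post"] - pm["program", "pre"])
        - (pm["control", "post"] - pm["control", "pre"])
    )


def did_via_ols(panel: PanelDataset) -> float:
    """Cross-check: δ as the group×period interaction of a cell-level OLS fit.

    Regresses cell logits on indicator and year fixed effects plus a
    program×post interaction (unweighted least squares, so each indicator
    counts equally).  On a balanced panel this reproduces the two-stage
    mean construction of :func:`pooled_did` exactly.
    """
    import statsmodels.formula.api as smf

    df = cell_logits(panel)
    df["treated_post"] = (
        (df.group == "program") & (df.year >= panel.program_onset_year)
    ).astype(float)
    fit = smf.ols("logit_p ~ C(indicator_id) + C(year) + treated_post", data=df).fit()
    return float(fit.params["treated_post"])


def event_study(means: pd.DataFrame, reference_year: int) -> pd.Series:
    """Year-wise DiD path δ_t relative to the reference year's group gap.

    δ_t = (ȳ_program,t − ȳ_control,t) − (ȳ_program,ref − ȳ_control,ref);
    δ at the reference year is zero by construction.  Pre-onset values are
    the parallel-trends diagnostic; post-onset values trace effect dynamics.
    """
    wide = means.pivot(index="year", columns="group", values="mean_logit")
    gap = wide["program"] - wide["control"]
    if reference_year not in gap.index:
        raise ValueError(f"reference year {reference_year} not in the panel years")
    path = gap - gap.loc[reference_year]
    path.loc[reference_year] = 0.0  # exact zero, no float residue
    path.name = "delta_t"
    return path


def counterfactual_cells(
    panel: PanelDataset,
    delta: float,
    *,
    delta_by_year: Mapping[int, float] | None = None,
) -> pd.DataFrame:
    """Counterfactual no-program probabilities for program-group post cells.

    p*_it = expit(logit(p_it) − δ): removing a negative δ raises the
    counterfactual risk above the observed one.  By default the single
    pooled δ applies uniformly; pass ``delta_by_year`` (e.g., the post-onset
    event-study path) for a year-specific variant.
    """
    df = cell_logits(panel)
    df = df[(df.group == "program") & (df.year >= panel.program_onset_year)].copy()
    if delta_by_year is not None:
        shift = df.year.map(dict(delta_by_year))
        if shift.isna().any():
            missing = sorted(df.year[shift.isna()].unique())
            raise ValueError(f"delta_by_year lacks post years {missing}")
        shift = shift.to_numpy(dtype=float)
    else:
        shift = float(delta)
    df["p_counterfactual"] = expit(df.logit_p.to_numpy() - shift)
    df["prevented"] = df.population_size * (df.p_counterfactual - df.proportion)
    return df[
        ["indicator_id", "year", "population_size", "event_count", "proportion",
         "p_counterfactual", "prevented"]
    ].reset_index(drop=True)


@dataclass
class AttSummary:
    """Marginal (patient-weighted) post-period program-group effect summary.

    ``p_obs`` is the observed probability of an adverse care event for the
    average treated patient in the post period, ``p_cf`` its counterfactual
    under no program; ``risk_ratio = p_obs / p_cf`` is the marginal causal
    risk ratio for the ATT.  ``prevented_total`` counts adverse events
    avoided because of the program, in patients.
    """

    p_obs: float
    p_cf: float
    risk_ratio: float
    prevented_total: float
    prevented_by_indicator: dict[str, float] = field(default_factory=dict)


def att_summary(
    panel: PanelDataset,
    delta: float,
    *,
    delta_by_year: Mapping[int, float] | None = None,
) -> AttSummary:
    """Marginalize the logit-scale effect over the treated patients.

    Both probabilities are patient-weighted across program×post cells:
    p_obs = Σ e_it / Σ n_it and p_cf = Σ n_it p*_it / Σ n_it, so years and
    indicators enter in proportion to their case volume.
    """
    cf = counterfactual_cells(panel, delta, delta_by_year=delta_by_year)
    n_total = float(cf.population_size.sum())
    p_obs = float(cf.event_count.sum()) / n_total
    p_cf = float((cf.population_size * cf.p_counterfactual).sum()) / n_total
    by_ind = cf.groupby("indicator_id")["prevented"].sum().to_dict()
    return AttSummary(
        p_obs=p_obs,
        p_cf=p_cf,
        risk_ratio=p_obs / p_cf,
        prevented_total=float(cf.prevented.sum()),
        prevented_by_indicator={k: float(v) for k, v in by_ind.items()},
    )


@dataclass
class DidEstimate:
    """Pooled DiD estimate with the event-study path.

    ``ci_delta``/``ci_or`` stay ``None`` until an uncertainty method fills
    them in.
    """

    delta: float
    event_study: dict[int, float]
    reference_year: int
    onset_year: int
    ci_delta: tuple[float, float] | None = None
    ci_or: tuple[float, float] | None = None

    @property
    def odds_ratio(self) -> float:
        return float(np.exp(self.delta))


def estimate(panel: PanelDataset) -> DidEstimate:
    """Run the full point-estimation chain on a validated panel."""
    means = group_year_means(panel)
    delta = pooled_did(means, panel.program_onset_year)
    path = event_study(means, panel.reference_year)
    return DidEstimate(
        delta=delta,
        event_study={int(y): float(v) for y, v in path.items()},
        reference_year=panel.reference_year,
        onset_year=panel.program_onset_year,
    )
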