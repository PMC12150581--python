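"""Interval estimation for the DiD analysis.

The published record offers no patient-level resampling unit — only annual
national aggregates — so the default uncertainty machinery is a parametric
binomial bootstrap: the 19-indicator panel structure is held fixed, each
replicate redraws every cell count e_it ~ Binomial(n_it, p̂_it) and reruns
the entire estimation chain.  All derived quantities (odds ratio, marginal
ATT risk ratio, prevented events, the event-study path) are recomputed
within each replicate, so their intervals propagate the uncertainty in δ
consistently rather than transforming the δ interval after the fact.
Conditional variants (holding δ at its point estimate when transforming to
risk ratio and prevented counts) are reported alongside.

A closed-form delta-method interval for δ serves as an independent
cross-check: Var(logit p̂) ≈ 1/(n p (1−p)) per cell, propagated through the
equal-weight mean structure of the estimator.

Indicator-level resampling (drawing indicators with replacement within each
group) is exposed as an option; it targets variability across indicators
and therefore changes the estimand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
import scipy.special
import scipy.stats

from .estimator import cell_logits, estimate
from .panel import PanelDataset

__all__ = [
    "BootstrapConfig",
    "BootstrapResult",
    "parametric_bootstrap",
    "delta_method_se",
    "delta_method_ci",
]


@dataclass(frozen=True)
class BootstrapConfig:
    """Bootstrap settings; identical seed and settings give identical bounds."""

    n_replicates: int = 2000
    seed: int | None = None
    interval_level: float = 0.95
    interval_method: str = "percentile"  # or "normal"
    resample_unit: str = "cells"  # or "indicators"

    def __post_init__(self) -> None:
        if self.n_replicates < 0:
            raise ValueError("n_replicates must be non-negative (0 = skip)")
        if not 0 < self.interval_level < 1:
            raise ValueError("interval_level must be in (0, 1)")
        if self.interval_method not in ("percentile", "normal"):
            raise ValueError(f"unknown interval_method {self.interval_method!r}")
        if self.resample_unit not in ("cells", "indicators"):
            raise ValueError(f"unknown resample_unit {self.resample_unit!r}")


#: quantities whose normal-approximation interval is built on the log scale
_LOG_SCALE = {"odds_ratio", "risk_ratio"}


@dataclass
class BootstrapResult:
    """Replicate draws plus point estimates, with interval accessors."""

    config: BootstrapConfig
    point: dict[str, float]
    draws: dict[str, np.ndarray]          # scalar quantities, each (R,)
    event_study_years: np.ndarray
    event_study_draws: np.ndarray         # (R, n_years)
    event_study_point: np.ndarray

    def interval(self, name: str, level: float | None = None
                 ) -> tuple[float, float]:
        return _interval(self.draws[name], self.point[name],
                         level or self.config.interval_level,
                         self.config.interval_method,
                         log_scale=name in _LOG_SCALE)

    def intervals(self, level: float | None = None) -> pd.DataFrame:
        """Point estimates with interval bounds for every scalar quantity."""
        rows = []
        for name in self.draws:
            lo, hi = self.interval(name, level)
            rows.append((name, self.point[name], lo, hi))
        return pd.DataFrame(rows, columns=["quantity", "estimate", "ci_low", "ci_high"])

    def event_study_intervals(self, level: float | None = None) -> pd.DataFrame:
        """Year-wise DiD path with interval bounds (the Fig-1B-style table)."""
        rows = []
        for j, y in enumerate(self.event_study_years):
            lo, hi = _interval(self.event_study_draws[:, j],
                               float(self.event_study_point[j]),
                               level or self.config.interval_level,
                               self.config.interval_method)
            rows.append((int(y), float(self.event_study_point[j]), lo, hi))
        return pd.DataFrame(rows, columns=["year", "delta_t", "ci_low", "ci_high"])

    def draws_frame(self) -> pd.DataFrame:
        """All replicate draws as a tidy table, for diagnostics export."""
        df = pd.DataFrame(self.draws)
        for j, y in enumerate(self.event_study_years):
            df[f"delta_t_{int(y)}"] = self.event_study_draws[:, j]
        df.insert(0, "replicate", np.arange(len(df)))
        return df


def _interval(draws: np.ndarray, point: float, level: float, method: str,
              log_scale: bool = False) -> tuple[float, float]:
    alpha = 1 - level
    if method == "percentile":
        lo, hi = np.quantile(draws, [alpha / 2, 1 - alpha / 2])
        return float(lo), float(hi)
    z = scipy.stats.norm.ppf(1 - alpha / 2)
    if log_scale and point > 0 and np.all(draws > 0):
        se = np.log(draws).std(ddof=1)
        return float(point * np.exp(-z * se)), float(point * np.exp(z * se))
    se = draws.std(ddof=1)
    return float(point - z * se), float(point + z * se)


# ---------------------------------------------------------------------------
# bootstrap engine
# ---------------------------------------------------------------------------

def _corrected_logit_matrix(e: np.ndarray, n: np.ndarray) -> np.ndarray:
    """logit(e/n) with boundary cells nudged to (e+0.5)/(n+1); vectorized."""
    boundary = (e == 0) | (e == n)
    p = np.where(boundary, (e + 0.5) / (n + 1.0), e / n)
    return scipy.special.logit(p)


def _panel_arrays(panel: PanelDataset):
    df = cell_logits(panel).sort_values(["indicator_id", "year"], kind="mergesort")
    n = df.population_size.to_numpy(dtype=float)
    e = df.event_count.to_numpy(dtype=float)
    years = np.array(panel.years)
    is_program = (df.group == "program").to_numpy()
    year_idx = df.year.map({int(y): j for j, y in enumerate(years)}).to_numpy()
    return df, n, e, years, is_program, year_idx


def _estimate_from_logits(
    logits: np.ndarray, is_program: np.ndarray, year_idx: np.ndarray,
    years: np.ndarray, onset_year: int, reference_year: int,
):
    """δ and the event-study path from an (R, cells) logit matrix."""
    R = logits.shape[0]
    T = len(years)
    gy = np.empty((R, 2, T))  # group (0=control, 1=program) × year means
    for g, mask_g in enumerate([~is_program, is_program]):
        for j in range(T):
            mask = mask_g & (year_idx == j)
            gy[:, g, j] = logits[:, mask].mean(axis=1)
    post = years >= onset_year
    delta = (gy[:, 1, post].mean(axis=1) - gy[:, 1, ~post].mean(axis=1)) \
        - (gy[:, 0, post].mean(axis=1) - gy[:, 0, ~post].mean(axis=1))
    gap = gy[:, 1, :] - gy[:, 0, :]
    ref_j = int(np.nonzero(years == reference_year)[0][0])
    path = gap - gap[:, [ref_j]]
    return delta, path


def parametric_bootstrap(panel: PanelDataset, config: BootstrapConfig
                         ) -> BootstrapResult:
    """Bootstrap distributions of δ, OR, RR, prevented counts and δ_t path.

    Default (``resample_unit='cells'``): each replicate redraws every cell
    count from Binomial(n_it, p̂_it) and reruns the estimator.  Degenerate
    replicates (cells at 0 or n) are absorbed by the continuity correction.
    ``prevented_total_conditional`` and ``risk_ratio_conditional`` transform
    each replicate's cells with the *point* estimate of δ instead of the
    replicate's own δ, i.e., they condition on δ̂.
    """
    if config.n_replicates < 1:
        raise ValueError("parametric_bootstrap needs at least one replicate")
    rng = np.random.default_rng(config.seed)
    point_est = estimate(panel)
    point_att = _att_from_point(panel, point_est.delta)
    df, n, e, years, is_program, year_idx = _panel_arrays(panel)
    onset, ref = panel.program_onset_year, panel.reference_year
    post_mask = years >= onset
    prog_post = is_program & post_mask[year_idx]
    ids_pp = df.indicator_id.to_numpy()[prog_post]

    R = config.n_replicates
    if config.resample_unit == "cells":
        p_hat = e / n
        e_rep = rng.binomial(n.astype(np.int64), p_hat, size=(R, len(n))).astype(float)
        n_rep = np.broadcast_to(n, (R, len(n)))
        logits = _corrected_logit_matrix(e_rep, n_rep)
        delta, path = _estimate_from_logits(
            logits, is_program, year_idx, years, onset, ref)
        rr, rr_c, prev, prev_c, p_obs, p_cf = _att_from_matrix(
            e_rep[:, prog_post], n[prog_post], logits[:, prog_post],
            delta, point_est.delta)
    else:
        delta, path, rr, rr_c, prev, prev_c, p_obs, p_cf = _indicator_bootstrap(
            panel, config, rng, point_est.delta)

    draws = {
        "delta": delta,
        "odds_ratio": np.exp(delta),
        "risk_ratio": rr,
        "risk_ratio_conditional": rr_c,
        "p_obs": p_obs,
        "p_cf": p_cf,
        "prevented_total": prev,
        "prevented_total_conditional": prev_c,
    }
    point = {
        "delta": point_est.delta,
        "odds_ratio": point_est.odds_ratio,
        "risk_ratio": point_att.risk_ratio,
        "risk_ratio_conditional": point_att.risk_ratio,
        "p_obs": point_att.p_obs,
        "p_cf": point_att.p_cf,
        "prevented_total": point_att.prevented_total,
        "prevented_total_conditional": point_att.prevented_total,
    }
    path_point = np.array([point_est.event_study[int(y)] for y in years])
    return BootstrapResult(
        config=config, point=point, draws=draws, event_study_years=years,
        event_study_draws=path, event_study_point=path_point,
    )


def _att_from_point(panel, delta):
    from .estimator import att_summary

    return att_summary(panel, delta)


def _att_from_matrix(e_pp, n_pp, logits_pp, delta, delta_point):
    """Patient-weighted RR and prevented counts per replicate.

    ``e_pp``/``logits_pp`` are (R, cells) over program×post cells; raw
    replicate proportions enter the probability sums, the corrected logits
    enter the counterfactual shift.
    """
    n_tot = n_pp.sum()
    p_obs = e_pp.sum(axis=1) / n_tot
    p_rep = e_pp / n_pp
    p_star = scipy.special.expit(logits_pp - delta[:, None])
    p_cf = (n_pp * p_star).sum(axis=1) / n_tot
    prevented = (n_pp * (p_star - p_rep)).sum(axis=1)
    p_star_c = scipy.special.expit(logits_pp - delta_point)
    p_cf_c = (n_pp * p_star_c).sum(axis=1) / n_tot
    prevented_c = (n_pp * (p_star_c - p_rep)).sum(axis=1)
    return p_obs / p_cf, p_obs / p_cf_c, prevented, prevented_c, p_obs, p_cf


def _indicator_bootstrap(panel, config, rng, delta_point):
    """Resample indicators with replacement within each group (option).

    Keeps observed cells fixed; uncertainty reflects indicator-to-indicator
    heterogeneity instead of binomial sampling noise, which targets a
    different (superpopulation-of-indicators) estimand.
    """
    df, n, e, years, is_program, year_idx = _panel_arrays(panel)
    onset, ref = panel.program_onset_year, panel.reference_year
    T = len(years)
    ids = sorted(panel.metas)
    prog_ids = [i for i in ids if panel.metas[i].group.value == "program"]
    ctrl_ids = [i for i in ids if panel.metas[i].group.value == "control"]
    # per-indicator (n_ind, T) matrices, row order = ids
    order = {i: k for k, i in enumerate(ids)}
    lg = np.empty((len(ids), T))
    nn = np.empty((len(ids), T))
    ee = np.empty((len(ids), T))
    logit_all = df.logit_p.to_numpy()
    for row, (iid, j) in enumerate(zip(df.indicator_id, year_idx)):
        lg[order[iid], j] = logit_all[row]
        nn[order[iid], j] = n[row]
        ee[order[iid], j] = e[row]
    post = years >= onset
    ref_j = int(np.nonzero(years == ref)[0][0])
    R = config.n_replicates
    out = {k: np.empty(R) for k in
           ("delta", "rr", "rr_c", "prev", "prev_c", "p_obs", "p_cf")}
    paths = np.empty((R, T))
    prog_rows = np.array([order[i] for i in prog_ids])
    ctrl_rows = np.array([order[i] for i in ctrl_ids])
    for r in range(R):
        pr = rng.choice(prog_rows, size=len(prog_rows), replace=True)
        cr = rng.choice(ctrl_rows, size=len(ctrl_rows), replace=True)
        yP, yC = lg[pr].mean(axis=0), lg[cr].mean(axis=0)
        d = (yP[post].mean() - yP[~post].mean()) - (yC[post].mean() - yC[~post].mean())
        gap = yP - yC
        paths[r] = gap - gap[ref_j]
        n_pp, e_pp, lg_pp = nn[pr][:, post], ee[pr][:, post], lg[pr][:, post]
        n_tot = n_pp.sum()
        p_obs = e_pp.sum() / n_tot
        p_star = scipy.special.expit(lg_pp - d)
        p_cf = (n_pp * p_star).sum() / n_tot
        p_star_c = scipy.special.expit(lg_pp - delta_point)
        p_cf_c = (n_pp * p_star_c).sum() / n_tot
        out["delta"][r] = d
        out["rr"][r] = p_obs / p_cf
        out["rr_c"][r] = p_obs / p_cf_c
        out["prev"][r] = (n_pp * (p_star - e_pp / n_pp)).sum()
        out["prev_c"][r] = (n_pp * (p_star_c - e_pp / n_pp)).sum()
        out["p_obs"][r] = p_obs
        out["p_cf"][r] = p_cf
    return (out["delta"], paths, out["rr"], out["rr_c"], out["prev"],
            out["prev_c"], out["p_obs"], out["p_cf"])


# ---------------------------------------------------------------------------
# delta method
# ---------------------------------------------------------------------------

def delta_method_se(panel: PanelDataset) -> float:
    """Closed-form standard error of δ from independent binomial cells.

    δ is linear in the cell logits with weight ±1/(group size × period
    length); Var(logit p̂_it) ≈ 1/(n_it p̂_it (1−p̂_it)) then sums to
    Var(δ) = Σ w_it² v_it.
    """
    df = cell_logits(panel)
    n_prog = len(panel.indicator_ids("program"))
    n_ctrl = len(panel.indicator_ids("control"))
    n_pre, n_post = len(panel.pre_years), len(panel.post_years)
    group_size = np.where(df.group == "program", n_prog, n_ctrl)
    period_len = np.where(df.year >= panel.program_onset_year, n_post, n_pre)
    w = 1.0 / (group_size * period_len)
    v = 1.0 / (df.population_size * df.p_corrected * (1 - df.p_corrected))
    return float(np.sqrt((w**2 * v).sum()))


def delta_method_ci(panel: PanelDataset, level: float = 0.95
                    ) -> tuple[float, float]:
    """Normal-approximation interval δ̂ ± z·SE from :func:`delta_method_se`."""
    from .estimator import group_year_means, pooled_did

    delta = pooled_did(group_year_means(panel), panel.program_onset_year)
    se = delta_method_se(panel)
    z = scipy.stats.norm.ppf(0.5 + level / 2)
    return delta - z * se, delta + z * se
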