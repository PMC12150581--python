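"""Estimator: logit machinery, DiD construction, counterfactuals, ATT."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from qualdid import (
    att_summary,
    counterfactual_cells,
    estimate,
    event_study,
    expit,
    group_year_means,
    logit,
    pooled_did,
)
from qualdid.estimator import cell_logits, corrected_proportion, did_via_ols
from qualdid.simulate import DgpConfig, generate_panel

from conftest import make_panel


# ---------------------------------------------------------------------------
# logit / expit
# ---------------------------------------------------------------------------

def test_logit_values():
    assert logit(0.5) == 0.0
    assert logit(0.0143) == pytest.approx(-4.2331, abs=5e-5)


@given(st.floats(1e-6, 1 - 1e-6))
def test_expit_inverts_logit(p):
    assert expit(logit(p)) == pytest.approx(p, rel=1e-9)


@pytest.mark.parametrize("p", [0.0, 1.0, -0.2, 1.5])
def test_logit_rejects_out_of_domain(p):
    with pytest.raises(ValueError):
        logit(p)


def test_continuity_correction_only_at_boundary(caplog):
    assert corrected_proportion(3, 100) == 0.03
    assert corrected_proportion(0, 100) == pytest.approx(0.5 / 101)
    assert corrected_proportion(100, 100) == pytest.approx(100.5 / 101)
    with caplog.at_level("WARNING", logger="qualdid.estimator"):
        corrected_proportion(np.array([0, 5]), np.array([10, 10]))
    assert "continuity correction" in caplog.text


# ---------------------------------------------------------------------------
# group-year means
# ---------------------------------------------------------------------------

def test_group_year_mean_hand_value():
    # two control indicators at 1% and 10%: mean logit = -3.39617
    p = {("C1", y): 0.01 for y in (2016, 2017)}
    p.update({("C2", y): 0.10 for y in (2016, 2017)})
    p.update({("P1", y): 0.05 for y in (2016, 2017)})
    means = group_year_means(make_panel(p, years=(2016, 2017)))
    row = means[(means.group == "control") & (means.year == 2016)].iloc[0]
    assert row.mean_logit == pytest.approx(-3.39617, abs=1e-5)
    assert row.n_indicators == 2


def test_single_indicator_group_mean_is_cell_logit(toy_panel):
    means = group_year_means(toy_panel)
    assert means[(means.group == "program") & (means.year == 2015)
                 ].mean_logit.iloc[0] == pytest.approx(logit(0.02))


def test_group_means_shift_equivariance(toy_panel):
    """Shifting every proportion by a common logit offset shifts the mean by it."""
    base = group_year_means(toy_panel)
    df = toy_panel.to_frame()
    shifted_p = {(r.indicator_id, r.year): expit(logit(r.proportion) + 0.3)
                 for r in df.itertuples()}
    n = {(r.indicator_id, r.year): 10**7 for r in df.itertuples()}
    shifted = group_year_means(make_panel(shifted_p, n, years=toy_panel.years))
    merged = base.merge(shifted, on=["group", "year"], suffixes=("", "_s"))
    # exact up to integer rounding of counts at n = 1e7
    assert np.allclose(merged.mean_logit_s - merged.mean_logit, 0.3, atol=1e-4)


# ---------------------------------------------------------------------------
# pooled DiD and event study
# ---------------------------------------------------------------------------

def _means_frame(values):
    """values: {(group, year): mean_logit}"""
    rows = [(g, y, v, 1) for (g, y), v in values.items()]
    return pd.DataFrame(rows, columns=["group", "year", "mean_logit",
                                       "n_indicators"])


def test_pooled_did_hand_arithmetic():
    means = _means_frame({
        ("program", 2016): -4.0, ("control", 2016): -3.0,
        ("program", 2017): -4.8, ("control", 2017): -3.2,
    })
    assert pooled_did(means, 2017) == pytest.approx(-0.6)


def test_pooled_did_cancels_identical_trajectories():
    traj = {2015: -3.0, 2016: -2.9, 2017: -2.5, 2018: -2.6}
    means = _means_frame({(g, y): v for g in ("program", "control")
                          for y, v in traj.items()})
    assert pooled_did(means, 2017) == pytest.approx(0.0)


def test_pooled_did_constructed_shift():
    means = _means_frame({
        **{("control", y): -3.0 for y in range(2013, 2021)},
        **{("program", y): -3.0 for y in range(2013, 2017)},
        **{("program", y): -3.61 for y in range(2017, 2021)},
    })
    assert pooled_did(means, 2017) == pytest.approx(-0.61)


def test_event_study_reference_and_toy_gaps():
    means = _means_frame({
        ("control", 2015): -3.0, ("control", 2016): -3.0, ("control", 2017): -3.0,
        ("program", 2015): -4.0, ("program", 2016): -4.1, ("program", 2017): -4.6,
    })
    path = event_study(means, reference_year=2016)
    assert path.loc[2016] == 0.0
    assert path.loc[2015] == pytest.approx(0.1)
    assert path.loc[2017] == pytest.approx(-0.5)


def test_event_study_zero_under_constant_gap():
    means = _means_frame({(g, y): (-3.0 if g == "control" else -4.2)
                          for g in ("program", "control")
                          for y in range(2013, 2017)})
    path = event_study(means, reference_year=2016)
    assert np.allclose(path, 0.0)


def _oracle_delta(panel):
    """Hand-loop two-way mean decomposition of the group-year means.

    Pure-Python reimplementation: per-cell logits with the boundary
    correction, unweighted indicator means per group-year, then the 2×2
    interaction of period means.  Independent of the pandas-based path.
    """
    by_gy = {}
    for row in panel.cells.itertuples():
        g = panel.metas[row.indicator_id].group.value
        e, n = row.event_count, row.population_size
        p = (e + 0.5) / (n + 1) if e in (0, n) else e / n
        by_gy.setdefault((g, row.year), []).append(math.log(p / (1 - p)))
    gy = {k: sum(v) / len(v) for k, v in by_gy.items()}
    out = {}
    for g in ("program", "control"):
        pre = [gy[g, y] for y in panel.pre_years]
        post = [gy[g, y] for y in panel.post_years]
        out[g] = sum(post) / len(post) - sum(pre) / len(pre)
    return out["program"] - out["control"]


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_pooled_did_matches_hand_decomposition_on_small_panels(seed):
    cfg = DgpConfig(n_program=2, n_control=3, years=(2015, 2016, 2017, 2018),
                    effect_path={2017: -0.4, 2018: -0.7}, seed=seed)
    panel = generate_panel(cfg)
    delta = pooled_did(group_year_means(panel), panel.program_onset_year)
    assert delta == pytest.approx(_oracle_delta(panel), abs=1e-12)


@pytest.mark.parametrize("seed", [10, 11])
def test_pooled_did_matches_fixed_effects_regression(seed):
    panel = generate_panel(DgpConfig(seed=seed))
    delta = pooled_did(group_year_means(panel), panel.program_onset_year)
    assert delta == pytest.approx(did_via_ols(panel), abs=1e-8)


# ---------------------------------------------------------------------------
# counterfactuals and ATT
# ---------------------------------------------------------------------------

def test_counterfactual_identity_at_zero_delta(toy_panel):
    cf = counterfactual_cells(toy_panel, 0.0)
    assert np.allclose(cf.p_counterfactual, cf.proportion)
    assert np.allclose(cf.prevented, 0.0)


def test_counterfactual_hand_value():
    p = {("P1", 2016): 0.0143, ("P1", 2017): 0.0143,
         ("C1", 2016): 0.03, ("C1", 2017): 0.03}
    panel = make_panel(p, years=(2016, 2017))
    cf = counterfactual_cells(panel, -0.61)
    assert cf.p_counterfactual.iloc[0] == pytest.approx(0.0260, abs=5e-5)


def test_counterfactual_monotone_in_delta(toy_panel):
    cfs = [counterfactual_cells(toy_panel, d).p_counterfactual.to_numpy()
           for d in (-0.8, -0.4, 0.0, 0.4)]
    for lo, hi in zip(cfs[1:], cfs[:-1]):
        assert np.all(lo < hi)


def test_att_uniform_cells_closed_form():
    p, d = 0.02, -0.5
    cells = {("P1", y): p for y in (2016, 2017, 2018)}
    cells.update({("C1", y): 0.04 for y in (2016, 2017, 2018)})
    panel = make_panel(cells, years=(2016, 2017, 2018))
    att = att_summary(panel, d)
    assert att.risk_ratio == pytest.approx(p / expit(logit(p) - d), rel=1e-9)


def test_att_prevented_matches_brute_force_cell_loop():
    p = {("P1", 2017): 0.01, ("P2", 2017): 0.04,
         ("C1", 2017): 0.02,
         ("P1", 2016): 0.01, ("P2", 2016): 0.04, ("C1", 2016): 0.02}
    n = {("P1", 2017): 100, ("P2", 2017): 300,
         ("C1", 2017): 1000,
         ("P1", 2016): 100, ("P2", 2016): 300, ("C1", 2016): 1000}
    panel = make_panel(p, n, years=(2016, 2017))
    delta = -0.61
    att = att_summary(panel, delta)
    expected = 100 * (expit(logit(0.01) + 0.61) - 0.01) \
        + 300 * (expit(logit(0.04) + 0.61) - 0.04)
    assert att.prevented_total == pytest.approx(expected, rel=1e-9)
    assert sum(att.prevented_by_indicator.values()) == pytest.approx(
        att.prevented_total)


def test_att_reconstruction_and_sign_consistency():
    panel = generate_panel(DgpConfig(seed=42))
    est = estimate(panel)
    att = att_summary(panel, est.delta)
    df = panel.to_frame()
    pp = df[(df.group == "program") & (df.period == "post")]
    # patient-weighted observed probability reconstructs raw counts exactly
    assert att.p_obs * pp.population_size.sum() == pytest.approx(
        pp.event_count.sum(), rel=1e-12)
    assert est.delta < 0
    assert est.odds_ratio < 1
    assert att.risk_ratio < 1
    assert att.prevented_total > 0


def test_population_scale_equivariance():
    base_p = {(i, y): v for i, v in (("P1", 0.02), ("P2", 0.05), ("C1", 0.03))
              for y, v in [(2016, v), (2017, v * 0.8)]}
    n1 = {k: 5000 for k in base_p}
    n10 = {k: 50000 for k in base_p}
    panel1 = make_panel(base_p, n1, years=(2016, 2017))
    panel10 = make_panel(base_p, n10, years=(2016, 2017))
    e1, e10 = estimate(panel1), estimate(panel10)
    assert e1.delta == pytest.approx(e10.delta, rel=1e-9)
    a1 = att_summary(panel1, e1.delta)
    a10 = att_summary(panel10, e10.delta)
    assert a1.risk_ratio == pytest.approx(a10.risk_ratio, rel=1e-9)
    assert a10.prevented_total == pytest.approx(10 * a1.prevented_total, rel=1e-9)


def test_event_study_is_exactly_zero_at_reference(default_effect_config):
    panel = generate_panel(default_effect_config)
    est = estimate(panel)
    assert est.event_study[panel.reference_year] == 0.0
    assert est.odds_ratio == pytest.approx(np.exp(est.delta), rel=1e-15)
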