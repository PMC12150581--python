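"""Bundled reference data.

The package ships the study population of the German 2017 quality-assurance
directive evaluation: 9 program and 10 control quality indicators with
their 2013-2020 national aggregate population sizes and adverse-care-event
counts.  The published record only aggregates over the eight data years;
annual per-indicator series must be requested from the reporting institute.
:func:`annualized_demo_panel` therefore spreads the aggregates evenly over
the years to obtain a structurally faithful (but synthetic in its yearly
split) demonstration panel that exercises the full pipeline.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .panel import Group, IndicatorMeta, IndicatorType, PanelDataset

__all__ = ["load_national_aggregates", "annualized_demo_panel"]

_DATA_FILE = "national_aggregates_2013_2020.csv"


def load_national_aggregates() -> pd.DataFrame:
    """The 19 analysis indicators with 2013-2020 national aggregates.

    ``adverse_events`` counts adverse care events (reverse coding already
    resolved); ``reverse_coded`` records whether the source indicator
    originally counted favorable events.  A ``proportion`` column is added.
    """
    with resources.files("qualdid.data").joinpath(_DATA_FILE).open("rb") as fh:
        df = pd.read_csv(fh, dtype={"indicator_id": str})
    df["proportion"] = df.adverse_events / df.population_size
    return df


def _split_evenly(total: int, parts: int) -> np.ndarray:
    """Integer split of ``total`` into ``parts`` summing exactly to total."""
    base, rem = divmod(int(total), parts)
    out = np.full(parts, base, dtype=np.int64)
    out[:rem] += 1
    return out


def annualized_demo_panel(years=tuple(range(2013, 2021))) -> PanelDataset:
    """Balanced demonstration panel from the bundled national aggregates.

    Each indicator's 8-year population and event totals are split evenly
    across years (remainders to the earliest years), so per-indicator sums
    reproduce the published aggregates exactly while the yearly split is a
    synthetic convention.  Suitable for exercising the pipeline end to end;
    carries no information about time trends.
    """
    agg = load_national_aggregates()
    years = tuple(int(y) for y in years)
    rows = []
    metas: dict[str, IndicatorMeta] = {}
    for _, r in agg.iterrows():
        n_by_year = _split_evenly(r.population_size, len(years))
        e_by_year = _split_evenly(r.adverse_events, len(years))
        for y, n, e in zip(years, n_by_year, e_by_year):
            rows.append((r.indicator_id, y, n, e))
        metas[r.indicator_id] = IndicatorMeta(
            indicator_id=r.indicator_id,
            label=r.label,
            clinical_area=r.clinical_area,
            group=Group.parse(r.group),
            indicator_type=IndicatorType.parse(r.indicator_type),
            reverse_coded=bool(r.reverse_coded),
            comparability_by_year={y: "fully_comparable" for y in years},
        )
    cells = pd.DataFrame(
        rows, columns=["indicator_id", "year", "population_size", "event_count"]
    )
    return PanelDataset(metas=metas, cells=cells, years=years)
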