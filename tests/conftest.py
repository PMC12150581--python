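import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from qualdid import DgpConfig, IndicatorMeta, PanelDataset, constant_effect

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_panel(p_by_cell, n_by_cell=None, years=None, onset=2017, reference=2016):
    """Build a small exact panel from per-(indicator, year) proportions.

    ``p_by_cell`` maps (indicator_id, year) -> proportion; indicator ids
    starting with 'P' are program, 'C' control.  Event counts are rounded
    so that e/n reproduces the requested proportion as closely as integers
    allow (choose n so that n*p is integral for exactness).
    """
    if n_by_cell is None:
        n_by_cell = {k: 10000 for k in p_by_cell}
    years = years or sorted({y for _, y in p_by_cell})
    rows = []
    ids = sorted({i for i, _ in p_by_cell})
    for (i, y), p in p_by_cell.items():
        n = n_by_cell[(i, y)]
        rows.append((i, y, n, int(round(n * p))))
    metas = {
        i: IndicatorMeta(
            indicator_id=i,
            group="program" if i.startswith("P") else "control",
            comparability_by_year={y: "fully_comparable" for y in years},
        )
        for i in ids
    }
    cells = pd.DataFrame(
        rows, columns=["indicator_id", "year", "population_size", "event_count"]
    )
    return PanelDataset(metas=metas, cells=cells, years=years,
                        program_onset_year=onset, reference_year=reference)


@pytest.fixture
def toy_panel():
    """1 program + 1 control indicator over 4 years, exact proportions."""
    p = {}
    for y, v in zip((2015, 2016, 2017, 2018), (0.02, 0.02, 0.01, 0.01)):
        p[("P1", y)] = v
    for y, v in zip((2015, 2016, 2017, 2018), (0.05, 0.05, 0.05, 0.05)):
        p[("C1", y)] = v
    return make_panel(p, years=(2015, 2016, 2017, 2018))


@pytest.fixture
def default_effect_config():
    return DgpConfig(effect_path=constant_effect(-0.61), seed=20170101)
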