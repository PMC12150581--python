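"""Panel data model for national quality-indicator results.

The analysis unit is a quality indicator observed once per calendar year at
the national level: a population size ``n_it`` (number of cases) and an
adverse-care-event count ``e_it``.  Indicators belong to either the
``program`` group (covered by the 2017 quality-assurance directive) or the
``control`` group (comparable indicators from clinical areas the directive
never touched).

This module defines the domain types, reads and writes tidy CSV files,
resolves reverse coding (sources that count favorable rather than adverse
events), validates panel balance, and implements the automated control-group
eligibility filter plus the final inclusion rules.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Comparability",
    "Group",
    "IndicatorType",
    "IndicatorMeta",
    "IndicatorYearResult",
    "PanelDataset",
    "PanelValidationError",
    "apply_reverse_coding",
    "load_metadata",
    "load_panel",
    "write_panel",
    "select_control_candidates",
    "apply_final_inclusion",
]


class PanelValidationError(ValueError):
    """Raised when input data violate the panel contract."""


class Comparability(enum.IntEnum):
    """Ordinal year-to-year comparability rating of an indicator definition.

    The ordering matters: eligibility and inclusion rules require ratings of
    at least :attr:`MODERATELY_COMPARABLE`.
    """

    NOT_COMPARABLE = 0
    MODERATELY_COMPARABLE = 1
    FULLY_COMPARABLE = 2

    @classmethod
    def parse(cls, value: "Comparability | str") -> "Comparability":
        if isinstance(value, Comparability):
            return value
        try:
            return cls[str(value).strip().upper()]
        except KeyError:
            raise PanelValidationError(
                f"unknown comparability rating {value!r}; expected one of "
                f"{[m.name.lower() for m in cls]}"
            ) from None


class Group(str, enum.Enum):
    PROGRAM = "program"
    CONTROL = "control"

    @classmethod
    def parse(cls, value: "Group | str") -> "Group":
        if isinstance(value, Group):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise PanelValidationError(
                f"unknown group label {value!r}; expected 'program' or 'control'"
            ) from None


class IndicatorType(str, enum.Enum):
    PROCESS = "process"
    INDICATION = "indication"
    OUTCOME = "outcome"

    @classmethod
    def parse(cls, value: "IndicatorType | str") -> "IndicatorType":
        if isinstance(value, IndicatorType):
            return value
        try:
            return cls(str(value).strip().lower())
        except ValueError:
            raise PanelValidationError(
                f"unknown indicator type {value!r}; expected one of "
                f"{[m.value for m in cls]}"
            ) from None


@dataclass(frozen=True)
class IndicatorMeta:
    """Static attributes of one quality indicator.

    ``comparability_by_year`` maps a data year to the rating of that year's
    indicator definition relative to the previous year.  The three boolean
    2014/2015 attributes encode operational maturity at the time the program
    was designed; ``area_reviewed_for_program`` is true for clinical areas
    that were screened for program inclusion (and are therefore ineligible
    as controls).
    """

    indicator_id: str
    label: str = ""
    clinical_area: str = ""
    group: Group = Group.CONTROL
    indicator_type: IndicatorType = IndicatorType.PROCESS
    reverse_coded: bool = False
    risk_adjusted: bool = False
    comparability_by_year: Mapping[int, Comparability] = field(default_factory=dict)
    has_reference_range_2014_2015: bool = True
    valid_for_national_assessment_2014_2015: bool = True
    area_reviewed_for_program: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "group", Group.parse(self.group))
        object.__setattr__(
            self, "indicator_type", IndicatorType.parse(self.indicator_type)
        )
        object.__setattr__(
            self,
            "comparability_by_year",
            {int(y): Comparability.parse(r) for y, r in self.comparability_by_year.items()},
        )

    def comparability(self, year: int) -> Comparability:
        try:
            return self.comparability_by_year[year]
        except KeyError:
            raise PanelValidationError(
                f"indicator {self.indicator_id!r}: missing attribute "
                f"comparability_by_year[{year}]"
            ) from None


@dataclass(frozen=True)
class IndicatorYearResult:
    """One panel cell: adverse events ``e_it`` out of ``n_it`` cases."""

    indicator_id: str
    year: int
    population_size: int
    event_count: int

    def __post_init__(self) -> None:
        if self.population_size < 0:
            raise PanelValidationError(
                f"indicator {self.indicator_id!r}, year {self.year}: "
                f"negative population size {self.population_size}"
            )
        if not 0 <= self.event_count <= self.population_size:
            raise PanelValidationError(
                f"indicator {self.indicator_id!r}, year {self.year}: event count "
                f"{self.event_count} outside [0, {self.population_size}]"
            )

    @property
    def proportion(self) -> float:
        if self.population_size == 0:
            raise PanelValidationError(
                f"indicator {self.indicator_id!r}, year {self.year}: proportion "
                "undefined for zero population"
            )
        return self.event_count / self.population_size


#: canonical column names of the tidy cell table
CELL_COLUMNS = ["indicator_id", "year", "population_size", "event_count"]


@dataclass
class PanelDataset:
    """A validated, balanced panel of indicator-year results.

    ``cells`` is a tidy :class:`pandas.DataFrame` with one row per
    (indicator, year) and columns ``indicator_id, year, population_size,
    event_count`` where ``event_count`` always counts adverse events.
    The pre-period comprises years before ``program_onset_year``; the
    post-period starts at the onset year.
    """

    metas: dict[str, IndicatorMeta]
    cells: pd.DataFrame
    years: Sequence[int] = tuple(range(2013, 2021))
    program_onset_year: int = 2017
    reference_year: int = 2016

    def __post_init__(self) -> None:
        self.years = tuple(int(y) for y in self.years)
        self.cells = (
            self.cells[CELL_COLUMNS]
            .astype({"indicator_id": str, "year": int, "population_size": np.int64,
                     "event_count": np.int64})
            .sort_values(["indicator_id", "year"], kind="mergesort")
            .reset_index(drop=True)
        )
        self.validate()

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        cells = self.cells
        bad = cells[(cells.event_count < 0) | (cells.event_count > cells.population_size)]
        if len(bad):
            r = bad.iloc[0]
            raise PanelValidationError(
                f"indicator {r.indicator_id!r}, year {int(r.year)}: event count "
                f"{int(r.event_count)} outside [0, {int(r.population_size)}]"
            )
        zero = cells[cells.population_size == 0]
        if len(zero):
            r = zero.iloc[0]
            raise PanelValidationError(
                f"indicator {r.indicator_id!r}, year {int(r.year)}: zero population "
                "size (corrupt input; cells with n=0 are rejected, not imputed)"
            )
        expected = {(i, y) for i in self.metas for y in self.years}
        present = set(zip(cells.indicator_id, cells.year))
        missing = sorted(expected - present)
        if missing:
            i, y = missing[0]
            raise PanelValidationError(
                f"unbalanced panel: indicator {i!r} lacks year {y} "
                f"({len(missing)} missing cell(s) in total)"
            )
        extra = sorted(present - expected)
        if extra:
            i, y = extra[0]
            raise PanelValidationError(
                f"unexpected cell for indicator {i!r}, year {y} "
                "(not in metadata or outside the year range)"
            )
        if len(cells) != len(expected):
            raise PanelValidationError("duplicate (indicator, year) cells present")
        if not self.pre_years or not self.post_years:
            raise PanelValidationError(
                f"program onset {self.program_onset_year} leaves an empty "
                f"pre- or post-period within years {self.years}"
            )
        for g in Group:
            if not self.indicator_ids(g):
                raise PanelValidationError(f"no indicators in group {g.value!r}")

    # -- convenience -----------------------------------------------------
    @property
    def pre_years(self) -> tuple[int, ...]:
        return tuple(y for y in self.years if y < self.program_onset_year)

    @property
    def post_years(self) -> tuple[int, ...]:
        return tuple(y for y in self.years if y >= self.program_onset_year)

    def indicator_ids(self, group: Group | str | None = None) -> list[str]:
        if group is None:
            return sorted(self.metas)
        group = Group.parse(group)
        return sorted(i for i, m in self.metas.items() if m.group == group)

    def cell(self, indicator_id: str, year: int) -> IndicatorYearResult:
        rows = self.cells[
            (self.cells.indicator_id == indicator_id) & (self.cells.year == year)
        ]
        if rows.empty:
            raise KeyError((indicator_id, year))
        r = rows.iloc[0]
        return IndicatorYearResult(
            r.indicator_id, int(r.year), int(r.population_size), int(r.event_count)
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy cell table with group labels and proportions attached."""
        df = self.cells.copy()
        df["group"] = [self.metas[i].group.value for i in df.indicator_id]
        df["proportion"] = df.event_count / df.population_size
        df["period"] = np.where(df.year >= self.program_onset_year, "post", "pre")
        return df

    def subset(self, indicator_ids: Iterable[str]) -> "PanelDataset":
        keep = set(indicator_ids)
        return PanelDataset(
            metas={i: m for i, m in self.metas.items() if i in keep},
            cells=self.cells[self.cells.indicator_id.isin(keep)],
            years=self.years,
            program_onset_year=self.program_onset_year,
            reference_year=self.reference_year,
        )


# ---------------------------------------------------------------------------
# reverse coding
# ---------------------------------------------------------------------------

def apply_reverse_coding(raw_count, population_size, reverse_coded):
    """Convert a raw source count into an adverse-event count.

    Indicators that count favorable events (e.g., "antibiotic prophylaxis
    given") are complemented against the population size so that the stored
    event count always measures adverse care events.  Accepts scalars or
    aligned array-likes.
    """
    raw = np.asarray(raw_count)
    n = np.asarray(population_size)
    rev = np.asarray(reverse_coded, dtype=bool)
    if np.any(raw < 0) or np.any(raw > n):
        raise PanelValidationError("raw count outside [0, population_size]")
    out = np.where(rev, n - raw, raw)
    if out.ndim == 0:
        return int(out)
    return out.astype(np.int64)


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_META_BOOL_FIELDS = (
    "reverse_coded",
    "risk_adjusted",
    "has_reference_range_2014_2015",
    "valid_for_national_assessment_2014_2015",
    "area_reviewed_for_program",
)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"true", "1", "yes", "y"}:
        return True
    if s in {"false", "0", "no", "n"}:
        return False
    raise PanelValidationError(f"cannot interpret {value!r} as boolean")


def load_metadata(path: str | Path, schema: Mapping[str, str] | None = None
                  ) -> dict[str, IndicatorMeta]:
    """Read an indicator metadata CSV into :class:`IndicatorMeta` records.

    One row per indicator.  Year-wise comparability ratings live in columns
    named ``comparability_<year>``.  ``schema`` optionally maps canonical
    column names to the file's column names so externally exported tables
    can be adapted without editing the file.
    """
    df = pd.read_csv(path, dtype=str)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    metas: dict[str, IndicatorMeta] = {}
    for _, row in df.iterrows():
        comp = {
            int(c.split("_")[-1]): Comparability.parse(row[c])
            for c in df.columns
            if c.startswith("comparability_") and pd.notna(row[c])
        }
        kwargs = {}
        for f in _META_BOOL_FIELDS:
            if f in df.columns and pd.notna(row[f]):
                kwargs[f] = _parse_bool(row[f])
        meta = IndicatorMeta(
            indicator_id=str(row["indicator_id"]),
            label=str(row.get("label", "") or ""),
            clinical_area=str(row.get("clinical_area", "") or ""),
            group=Group.parse(row["group"]),
            indicator_type=IndicatorType.parse(row["indicator_type"]),
            comparability_by_year=comp,
            **kwargs,
        )
        if meta.indicator_id in metas:
            raise PanelValidationError(
                f"duplicate indicator_id {meta.indicator_id!r} in metadata"
            )
        metas[meta.indicator_id] = meta
    return metas


def load_panel(
    panel_path: str | Path,
    metadata_path: str | Path | None = None,
    *,
    metas: Mapping[str, IndicatorMeta] | None = None,
    schema: Mapping[str, str] | None = None,
    meta_schema: Mapping[str, str] | None = None,
    years: Sequence[int] | None = None,
    program_onset_year: int = 2017,
    reference_year: int = 2016,
) -> PanelDataset:
    """Read a tidy panel CSV (one row per indicator-year) into a validated panel.

    The file carries either a resolved ``event_count`` column or a raw
    ``event_count_raw`` column together with a per-row ``reverse_coded``
    flag; in the latter case reverse coding is resolved here so that stored
    counts always measure adverse events.  Metadata come from
    ``metadata_path`` (or pre-built ``metas``); if neither is given, minimal
    metadata are derived from a ``group`` column in the panel file itself.
    """
    df = pd.read_csv(panel_path)
    if schema:
        df = df.rename(columns={v: k for k, v in schema.items()})
    for col in ("indicator_id", "year", "population_size"):
        if col not in df.columns:
            raise PanelValidationError(f"panel file lacks required column {col!r}")
    df["indicator_id"] = df["indicator_id"].astype(str)

    if metadata_path is not None:
        metas = load_metadata(metadata_path, schema=meta_schema)
    elif metas is None:
        if "group" not in df.columns:
            raise PanelValidationError(
                "no metadata supplied and panel file has no 'group' column"
            )
        metas = {}
        for iid, sub in df.groupby("indicator_id"):
            labels = {Group.parse(g) for g in sub["group"]}
            if len(labels) > 1:
                raise PanelValidationError(
                    f"indicator {iid!r} has inconsistent group labels"
                )
            rev = bool(_parse_bool(sub.iloc[0]["reverse_coded"])) \
                if "reverse_coded" in df.columns else False
            metas[str(iid)] = IndicatorMeta(
                indicator_id=str(iid),
                group=labels.pop(),
                reverse_coded=rev,
            )
    metas = dict(metas)

    if "event_count" in df.columns:
        events = df["event_count"].to_numpy()
    elif "event_count_raw" in df.columns:
        if "reverse_coded" in df.columns:
            rev = df["reverse_coded"].map(_parse_bool).to_numpy()
        else:
            missing = [i for i in df.indicator_id.unique() if i not in metas]
            if missing:
                raise PanelValidationError(
                    f"indicator {missing[0]!r} present in panel but not in metadata"
                )
            rev = df["indicator_id"].map(lambda i: metas[i].reverse_coded).to_numpy()
        events = apply_reverse_coding(
            df["event_count_raw"].to_numpy(), df["population_size"].to_numpy(), rev
        )
    else:
        raise PanelValidationError(
            "panel file needs an 'event_count' or 'event_count_raw' column"
        )

    cells = pd.DataFrame(
        {
            "indicator_id": df["indicator_id"],
            "year": df["year"].astype(int),
            "population_size": df["population_size"].astype(np.int64),
            "event_count": np.asarray(events, dtype=np.int64),
        }
    )
    if years is None:
        years = tuple(sorted(cells.year.unique()))
    return PanelDataset(
        metas=metas,
        cells=cells,
        years=years,
        program_onset_year=program_onset_year,
        reference_year=reference_year,
    )


def write_panel(panel: PanelDataset, path: str | Path) -> None:
    """Write the resolved tidy panel (adverse-event counts and proportions)."""
    df = panel.to_frame()[
        ["indicator_id", "year", "population_size", "event_count", "group", "proportion"]
    ]
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# eligibility filter and final inclusion
# ---------------------------------------------------------------------------

def select_control_candidates(
    metas: Iterable[IndicatorMeta] | Mapping[str, IndicatorMeta],
) -> list[IndicatorMeta]:
    """Automated eligibility filter for control-group candidate indicators.

    An indicator qualifies as a control candidate iff

    1. its clinical area was never reviewed for program inclusion,
    2. it was operationally mature when the program was designed: at least
       moderately comparable in 2014 and 2015, a reference range in place,
       and judged valid for assessing national need for action, and
    3. it is risk adjusted whenever it measures patient outcomes.

    The filter is a pure predicate over the supplied metadata; it is
    idempotent and independent of input order.
    """
    if isinstance(metas, Mapping):
        metas = list(metas.values())
    selected = []
    for m in metas:
        if m.area_reviewed_for_program:
            continue
        mature = (
            m.comparability(2014) >= Comparability.MODERATELY_COMPARABLE
            and m.comparability(2015) >= Comparability.MODERATELY_COMPARABLE
            and m.has_reference_range_2014_2015
            and m.valid_for_national_assessment_2014_2015
        )
        if not mature:
            continue
        if m.indicator_type == IndicatorType.OUTCOME and not m.risk_adjusted:
            continue
        selected.append(m)
    return sorted(selected, key=lambda m: m.indicator_id)


def apply_final_inclusion(
    metas: Iterable[IndicatorMeta] | Mapping[str, IndicatorMeta],
    cells: pd.DataFrame,
    *,
    years: Sequence[int] = tuple(range(2013, 2021)),
    program_onset_year: int = 2017,
    reference_year: int = 2016,
) -> PanelDataset:
    """Final inclusion rules producing the analysis panel.

    Drops indicators that (a) lack a result for any year of the observation
    window or were strongly modified between years — i.e., rated below
    moderately comparable to the previous year at any point from 2014 on;
    program indicators are exempt from the comparability drop because major
    modifications were ruled out for them — or (b) measure outcome quality,
    whose long time series confound with drifting patient-risk profiles.
    Returns the balanced analysis panel.
    """
    if isinstance(metas, Mapping):
        metas = list(metas.values())
    years = tuple(int(y) for y in years)
    cells = cells.copy()
    cells["indicator_id"] = cells["indicator_id"].astype(str)

    kept: dict[str, IndicatorMeta] = {}
    for m in metas:
        have_years = set(cells.loc[cells.indicator_id == m.indicator_id, "year"])
        if not set(years) <= have_years:
            continue
        if m.indicator_type == IndicatorType.OUTCOME:
            continue
        if m.group != Group.PROGRAM:
            ratings = [m.comparability(y) for y in years if y >= 2014]
            if any(r < Comparability.MODERATELY_COMPARABLE for r in ratings):
                continue
        kept[m.indicator_id] = m

    for g in Group:
        if not any(m.group == g for m in kept.values()):
            raise PanelValidationError(
                f"final inclusion leaves no indicators in group {g.value!r}"
            )
    final_cells = cells[cells.indicator_id.isin(kept) & cells.year.isin(years)]
    return PanelDataset(
        metas=kept,
        cells=final_cells,
        years=years,
        program_onset_year=program_onset_year,
        reference_year=reference_year,
    )
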