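"""Ingestion, validation, cleaning and monthly aggregation of daily series.

The analysis operates on a *monthly exposure table*: one row per calendar
month (climatology) or per (year, month), columns holding the normalized
dry eye disease (DED) outpatient index in percent plus twelve environmental
factors — six air pollutants and six meteorological variables.  All daily
fields are averaged into months except precipitation, which is accumulated
(monthly total).  This module is the only place daily data is touched; every
downstream model consumes the monthly table it emits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger(__name__)

#: Fixed factor order: pollutants first, then meteorology (ties elsewhere
#: are broken by this order).
FACTORS: tuple[str, ...] = (
    "SO2", "PM2.5", "PM10", "NO2", "CO", "O3",
    "AP", "AT", "RH", "PR", "WS", "AV",
)
#: Full monthly-table column order.
COLUMNS: tuple[str, ...] = ("DED",) + FACTORS

#: Fields accumulated (not averaged) when aggregating days into months.
SUM_FIELDS: frozenset[str] = frozenset({"PR"})

#: Fields that must be nonnegative at the daily level.
NONNEGATIVE_FIELDS: frozenset[str] = frozenset(
    {"SO2", "PM2.5", "PM10", "NO2", "CO", "O3", "PR", "WS", "AV", "visits"}
)

UNITS: Mapping[str, str] = {
    "DED": "%", "SO2": "ug/m3", "PM2.5": "ug/m3", "PM10": "ug/m3",
    "NO2": "ug/m3", "CO": "mg/m3", "O3": "ug/m3", "AP": "hPa", "AT": "degC",
    "RH": "%", "PR": "mm", "WS": "m/s", "AV": "km",
}

#: Aliases accepted (case-insensitively) when matching input headers.
_ALIASES: Mapping[str, str] = {
    "pm25": "PM2.5", "pm2.5": "PM2.5", "pm2_5": "PM2.5", "pm10": "PM10",
    "so2": "SO2", "no2": "NO2", "co": "CO", "o3": "O3", "ap": "AP",
    "at": "AT", "rh": "RH", "pr": "PR", "ws": "WS", "av": "AV",
    "ded": "DED", "visits": "visits", "date": "date",
}


class SchemaError(ValueError):
    """Input file does not expose the columns the schema requires."""


class IntegrityError(ValueError):
    """Input violates a structural invariant (e.g. duplicate dates)."""


@dataclass
class CleaningReport:
    """Tally of what validation and cleaning did to a dataset."""

    n_null_dropped: int = 0
    n_outliers_flagged: int = 0
    rules: list[str] = field(default_factory=list)
    excluded_periods: list[tuple[int, int, str]] = field(default_factory=list)

    def merge(self, other: "CleaningReport") -> "CleaningReport":
        return CleaningReport(
            self.n_null_dropped + other.n_null_dropped,
            self.n_outliers_flagged + other.n_outliers_flagged,
            self.rules + other.rules,
            self.excluded_periods + other.excluded_periods,
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(
            {
                "n_null_dropped": int(self.n_null_dropped),
                "n_outliers_flagged": int(self.n_outliers_flagged),
                "rules": list(self.rules),
                "excluded_periods": [
                    {"year": int(y), "month": int(m), "reason": r}
                    for y, m, r in self.excluded_periods
                ],
            },
            sort_keys=False,
        )


#: Default excluded period: the hospital lockdown month, during which the
#: outpatient series does not reflect DED incidence.
DEFAULT_EXCLUSIONS: tuple[tuple[int, int, str], ...] = (
    (2020, 2, "hospital was locked down due to COVID-19"),
)


@dataclass
class CleaningConfig:
    """Cleaning rules for monthly tables.

    ``zscore_k`` flags values further than k per-column standard deviations
    from the column mean (flag-don't-drop unless ``drop_outliers``);
    ``exclusions`` removes whole (year, month) rows with a reason.
    """

    zscore_k: float | None = 4.0
    drop_outliers: bool = False
    exclusions: Sequence[tuple[int, int, str]] = DEFAULT_EXCLUSIONS


@dataclass
class DailyData:
    """Validated daily records plus the report of what validation changed.

    ``frame`` is indexed by date with canonical factor columns (subset of
    :data:`FACTORS`) and optionally ``visits``.
    """

    frame: pd.DataFrame
    report: CleaningReport


@dataclass
class MonthlyExposureTable:
    """Monthly DED index plus factor table.

    ``frame`` is indexed either by calendar month (1–12, a climatology) or by
    a (year, month) MultiIndex; columns follow :data:`COLUMNS` where present.
    ``provenance`` is ``"fixture"`` for packaged published data, ``"computed"``
    for tables built from daily input.
    """

    frame: pd.DataFrame
    provenance: str = "computed"

    def to_csv(self, path_or_buf) -> None:
        # 17 significant digits: float64 values round-trip exactly
        self.frame.to_csv(path_or_buf, float_format="%.17g")

    @classmethod
    def from_csv(cls, path_or_buf, provenance: str = "computed") -> "MonthlyExposureTable":
        frame = pd.read_csv(path_or_buf, float_precision="round_trip")
        if {"year", "month"}.issubset(frame.columns):
            frame = frame.set_index(["year", "month"])
        elif "month" in frame.columns:
            frame = frame.set_index("month")
        return cls(frame=frame, provenance=provenance)

    def climatology(self) -> "MonthlyExposureTable":
        """Collapse a (year, month) table to 12 calendar-month means."""
        if not isinstance(self.frame.index, pd.MultiIndex):
            return self
        out = self.frame.groupby(level="month").mean()
        out.index.name = "month"
        return MonthlyExposureTable(out, provenance=self.provenance)


def _resolve_schema(columns: Iterable[str], schema: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical field names to actual file columns."""
    mapping: dict[str, str] = {}
    if schema:
        lowered = {k.lower(): v for k, v in schema.items()}
        for alias, canon in _ALIASES.items():
            if alias in lowered:
                mapping[canon] = lowered[alias]
    available = {c.lower(): c for c in columns}
    for alias, canon in _ALIASES.items():
        if canon not in mapping and alias in available:
            mapping[canon] = available[alias]
    return mapping


def load_daily(source: str | IO[str], schema: Mapping[str, str] | None = None) -> DailyData:
    """Read a delimited daily file into validated records.

    Parameters
    ----------
    source
        Path or text stream of a headered delimited file with one row per
        day.  Missing values may be empty cells or ``NA``.
    schema
        Optional map from canonical field names (``date``, ``PM10``, ...)
        to the file's column names; unmapped fields are matched by name
        case-insensitively.

    Returns
    -------
    DailyData
        Frame sorted by date plus a :class:`CleaningReport` counting
        unparseable/missing cells and range-violating values (flagged to
        missing, never silently altered).

    Raises
    ------
    SchemaError
        If no date column can be found.
    IntegrityError
        If two records share a date.
    """
    raw = pd.read_csv(source, na_values=["NA", ""], skipinitialspace=True)
    mapping = _resolve_schema(raw.columns, schema)
    if "date" not in mapping:
        raise SchemaError("no date column found; columns were: " + ", ".join(raw.columns))

    report = CleaningReport()
    dates = pd.to_datetime(raw[mapping["date"]], errors="raise")
    dup = dates[dates.duplicated()]
    if not dup.empty:
        raise IntegrityError(f"duplicate date(s): {dup.iloc[0].date()}")

    fields = [f for f in (*FACTORS, "visits") if f in mapping]
    out = pd.DataFrame(index=pd.DatetimeIndex(dates, name="date"))
    for fieldname in fields:
        col = raw[mapping[fieldname]]
        values = pd.to_numeric(col, errors="coerce")
        n_bad = int(values.isna().sum())
        report.n_null_dropped += n_bad
        if fieldname == "RH":
            bad = (values < 0) | (values > 100)
        elif fieldname in NONNEGATIVE_FIELDS:
            bad = values < 0
        else:
            bad = pd.Series(False, index=values.index)
        n_flag = int(bad.sum())
        if n_flag:
            report.n_outliers_flagged += n_flag
            report.rules.append(f"range check: {n_flag} value(s) of {fieldname} flagged to missing")
            values = values.mask(bad)
        out[fieldname] = values.to_numpy()
    out = out.sort_index()
    return DailyData(frame=out, report=report)


def aggregate_daily_to_monthly(daily: pd.DataFrame, fieldname: str) -> pd.DataFrame:
    """Aggregate one daily field to months.

    Means over observed days, except precipitation which is a monthly
    cumulative total.  Months with zero observed days are omitted (and
    logged), never emitted as zero.

    Returns a frame with columns ``year, month, value, n_days_observed,
    aggregation``.
    """
    if fieldname not in daily.columns:
        raise KeyError(f"field {fieldname!r} not present in daily data")
    values = daily[fieldname]
    grouped = values.groupby([values.index.year, values.index.month])
    how = "sum" if fieldname in SUM_FIELDS else "mean"
    rows = []
    for (year, month), chunk in grouped:
        n_obs = int(chunk.notna().sum())
        if n_obs == 0:
            logger.warning("month %d-%02d has no observed %s days; omitted", year, month, fieldname)
            continue
        value = float(chunk.sum() if how == "sum" else chunk.mean())
        rows.append((int(year), int(month), value, n_obs, how))
    return pd.DataFrame(rows, columns=["year", "month", "value", "n_days_observed", "aggregation"])


def normalized_monthly_index(counts: Sequence[float]) -> np.ndarray:
    """Normalized monthly DED index: percent of the year's visits per month.

    ``counts`` are the monthly outpatient-visit totals of one year (missing
    months may be NaN; the index is then computed over observed months and
    still sums to 100 over them).
    """
    arr = np.asarray(counts, dtype=float)
    if arr.size == 0 or np.nanmin(arr) < 0:
        raise ValueError("visit counts must be nonnegative and non-empty")
    total = np.nansum(arr)
    if total <= 0:
        raise ValueError("no visits observed in this year; index undefined")
    return 100.0 * arr / total


def annual_summary(monthly_values: Sequence[float]) -> float:
    """Annual value of a factor: arithmetic mean of its 12 monthly values.

    For precipitation the monthly values are cumulative totals, so this is
    the mean monthly total (the convention behind published annual figures).
    """
    arr = np.asarray(monthly_values, dtype=float)
    if arr.shape != (12,):
        raise ValueError(f"need exactly 12 monthly values, got {arr.shape}")
    missing = [m + 1 for m in range(12) if np.isnan(arr[m])]
    if missing:
        raise ValueError(f"missing months: {missing}")
    return float(arr.mean())


def round_half_away(x: float, ndigits: int = 0) -> float:
    """Round half away from zero (printed-table convention)."""
    factor = 10.0 ** ndigits
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


def monthly_exposure_table(
    daily: pd.DataFrame,
    min_days: int = 20,
) -> MonthlyExposureTable:
    """Build the (year, month) exposure table from daily records.

    Factor columns are monthly aggregates; ``DED`` is the normalized monthly
    index computed within each year from daily visit counts.  Months with
    fewer than ``min_days`` observed days for a factor get a missing value
    there (completeness threshold; available-days means otherwise).
    """
    pieces = {}
    counts = {}
    for fieldname in FACTORS:
        if fieldname not in daily.columns:
            continue
        agg = aggregate_daily_to_monthly(daily, fieldname)
        idx = pd.MultiIndex.from_arrays([agg["year"], agg["month"]], names=["year", "month"])
        value = agg["value"].to_numpy(dtype=float)
        value[agg["n_days_observed"].to_numpy() < min_days] = np.nan
        pieces[fieldname] = pd.Series(value, index=idx)
        counts[fieldname] = pd.Series(agg["n_days_observed"].to_numpy(), index=idx)
    frame = pd.DataFrame(pieces)

    if "visits" in daily.columns:
        visits = daily["visits"]
        grouped = visits.groupby([visits.index.year, visits.index.month]).sum(min_count=1)
        grouped.index = pd.MultiIndex.from_tuples(grouped.index, names=["year", "month"])
        ded = pd.Series(index=grouped.index, dtype=float)
        for year in grouped.index.get_level_values("year").unique():
            year_counts = grouped.loc[year]
            ded.loc[year] = normalized_monthly_index(year_counts.to_numpy())
        frame.insert(0, "DED", ded)

    frame = frame.sort_index()
    frame = frame[[c for c in COLUMNS if c in frame.columns]]
    return MonthlyExposureTable(frame=frame, provenance="computed")


def clean_table(
    table: MonthlyExposureTable,
    rules: CleaningConfig | None = None,
) -> tuple[MonthlyExposureTable, CleaningReport]:
    """Apply period exclusions and the z-score outlier rule to a table.

    Outliers are flagged (counted and reported) by default; with
    ``drop_outliers`` they are set missing.  Excluded (year, month) periods
    are removed with their reason recorded.  An empty config is a no-op.
    """
    rules = rules if rules is not None else CleaningConfig()
    frame = table.frame.copy()
    report = CleaningReport()

    unknown = [c for c in frame.columns if c not in COLUMNS]
    if unknown:
        raise SchemaError(f"unknown column(s) in table: {unknown}")

    if rules.exclusions and isinstance(frame.index, pd.MultiIndex):
        for year, month, reason in rules.exclusions:
            if (year, month) in frame.index:
                frame = frame.drop(index=(year, month))
                report.excluded_periods.append((year, month, reason))
                logger.info("excluded %d-%02d: %s", year, month, reason)

    if rules.zscore_k is not None:
        k = float(rules.zscore_k)
        report.rules.append(f"z-score outlier rule, k={k:g}, " +
                            ("drop" if rules.drop_outliers else "flag only"))
        for col in frame.columns:
            vals = frame[col].to_numpy(dtype=float)
            sd = np.nanstd(vals, ddof=1)
            if not np.isfinite(sd) or sd == 0:
                continue
            z = (vals - np.nanmean(vals)) / sd
            bad = np.abs(z) > k
            n_bad = int(np.nansum(bad))
            if n_bad:
                report.n_outliers_flagged += n_bad
                if rules.drop_outliers:
                    frame[col] = frame[col].mask(bad)
                    report.n_null_dropped += n_bad
    return MonthlyExposureTable(frame=frame, provenance=table.provenance), report
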