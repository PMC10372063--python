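"""Hourly PM2.5 chemical speciation: ingestion, monthly means and DED links.

Speciation records carry water-soluble ions (SO4, NO3, Cl, NH4, Ca2+, K+),
the crustal element Ca, carbon fractions (OC, EC) and the total PM2.5 mass,
all in µg/m³ at hourly resolution.  Ion Ca2+ and element Ca are distinct
measurements (ion chromatography vs ICP-AES) and are never merged.  A mass
closure check flags hours whose component sum exceeds the reported total by
more than a configurable tolerance (15% default); flagged hours are kept.

Monthly component concentrations are arithmetic means of the observed hours;
correlations with the monthly DED index reuse the single Pearson
implementation in :mod:`dedair.association_models`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO

import pandas as pd

from .association_models import CorrelationMatrix, pearson_matrix
from .io_timeseries import CleaningReport

logger = logging.getLogger(__name__)

#: Component column order: ions, element, carbon fractions.
COMPONENTS: tuple[str, ...] = (
    "SO4", "NO3", "Cl", "NH4", "Ca2+", "K+", "Ca", "OC", "EC",
)
TOTAL_COLUMN = "PM2.5"

_ALIASES = {
    "so4": "SO4", "so42-": "SO4", "no3": "NO3", "no3-": "NO3",
    "cl": "Cl", "cl-": "Cl", "nh4": "NH4", "nh4+": "NH4",
    "ca2+": "Ca2+", "ca_ion": "Ca2+", "k": "K+", "k+": "K+", "ca": "Ca",
    "oc": "OC", "ec": "EC", "pm25": "PM2.5", "pm2.5": "PM2.5",
    "timestamp": "timestamp", "datetime": "timestamp", "time": "timestamp",
}


@dataclass
class SpeciationData:
    """Validated hourly speciation frame plus its cleaning report.

    ``frame`` is indexed by hourly timestamps; ``closure_violations`` lists
    timestamps whose component sum exceeded total PM2.5 beyond tolerance.
    """

    frame: pd.DataFrame
    report: CleaningReport
    closure_violations: list[pd.Timestamp] = field(default_factory=list)


def load_speciation(
    source: str | IO[str], closure_tolerance: float = 0.15
) -> SpeciationData:
    """Read and validate an hourly speciation file.

    Negative concentrations are flagged and set missing (logged); mass
    closure violations are flagged but records are kept.
    """
    raw = pd.read_csv(source, na_values=["NA", ""], skipinitialspace=True)
    lower = {c.lower(): c for c in raw.columns}
    mapping = {canon: lower[alias] for alias, canon in _ALIASES.items() if alias in lower}
    if "timestamp" not in mapping:
        raise ValueError("no timestamp column found; columns: " + ", ".join(raw.columns))
    ts = pd.to_datetime(raw[mapping["timestamp"]], errors="raise")

    report = CleaningReport()
    out = pd.DataFrame(index=pd.DatetimeIndex(ts, name="timestamp"))
    for name in (*COMPONENTS, TOTAL_COLUMN):
        if name not in mapping:
            continue
        values = pd.to_numeric(raw[mapping[name]], errors="coerce")
        report.n_null_dropped += int(values.isna().sum())
        neg = values < 0
        if neg.any():
            n_neg = int(neg.sum())
            report.n_outliers_flagged += n_neg
            report.rules.append(f"negative {name}: {n_neg} value(s) set missing")
            logger.warning("%d negative %s value(s) set missing", n_neg, name)
            values = values.mask(neg)
        out[name] = values.to_numpy()
    out = out.sort_index()

    violations: list[pd.Timestamp] = []
    present = [c for c in COMPONENTS if c in out.columns]
    if TOTAL_COLUMN in out.columns and present:
        comp_sum = out[present].sum(axis=1, min_count=1)
        bad = comp_sum > out[TOTAL_COLUMN] * (1.0 + closure_tolerance)
        violations = list(out.index[bad.fillna(False)])
        if violations:
            report.rules.append(
                f"mass closure: {len(violations)} hour(s) exceed total PM2.5 "
                f"by more than {closure_tolerance:.0%}"
            )
    return SpeciationData(frame=out, report=report, closure_violations=violations)


def monthly_component_means(frame: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean of hourly values per (year, month) and component.

    Empty (month, component) cells are left missing; fully empty months are
    omitted with a log entry.
    """
    grouped = frame.groupby([frame.index.year, frame.index.month]).mean()
    grouped.index = pd.MultiIndex.from_tuples(grouped.index, names=["year", "month"])
    all_empty = grouped.isna().all(axis=1)
    for year, month in grouped.index[all_empty]:
        logger.warning("month %d-%02d has no observed hours; omitted", year, month)
    return grouped.loc[~all_empty]


def observed_hours(frame: pd.DataFrame) -> pd.DataFrame:
    """Per-(year, month) count of non-missing hours per component."""
    counts = frame.notna().groupby([frame.index.year, frame.index.month]).sum()
    counts.index = pd.MultiIndex.from_tuples(counts.index, names=["year", "month"])
    return counts.astype(int)


def component_ded_correlations(
    monthly_components: pd.DataFrame, ded_index: pd.Series
) -> CorrelationMatrix:
    """Pearson r and p between each monthly component and the DED index.

    A single shared implementation with the factor-level screen guarantees
    identical numbers on identical inputs.
    """
    joined = monthly_components.copy()
    joined.insert(0, "DED", ded_index)
    return pearson_matrix(joined)


def component_shares(monthly_components: pd.DataFrame) -> pd.DataFrame:
    """Component share of total PM2.5 mass, percent (component mean /
    PM2.5 mean × 100), per month."""
    if TOTAL_COLUMN not in monthly_components.columns:
        raise ValueError("total PM2.5 column required for shares")
    comps = [c for c in COMPONENTS if c in monthly_components.columns]
    return monthly_components[comps].div(monthly_components[TOTAL_COLUMN], axis=0) * 100.0
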