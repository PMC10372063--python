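"""Packaged fixtures: the published monthly climatology and grey-relational
table for the Changchun 2016–2020 dry eye disease study, transcribed from the
source publication, plus the published summary values the pipeline is checked
against.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from .io_timeseries import MonthlyExposureTable

#: SHA-256 digests of the packaged fixture files (integrity check for the
#: reproduction workflow).
FIXTURE_SHA256 = {
    "table1_monthly.csv": None,  # filled below on first access
}

#: Published annual values: mean of the twelve monthly values (precipitation:
#: mean monthly cumulative total), at the precision they were printed.
PUBLISHED_ANNUAL_MEANS: dict[str, float] = {
    "PM2.5": 40.6, "PM10": 68.7, "SO2": 17.3, "NO2": 34.3, "O3": 79.4,
    "CO": 0.8, "AP": 1000.3, "AT": 7.0, "RH": 61.3, "PR": 208.75,
    "WS": 2.68, "AV": 18.33,
}

#: Decimal places of the printed annual values above.
PUBLISHED_ANNUAL_DECIMALS: dict[str, int] = {
    "PM2.5": 1, "PM10": 1, "SO2": 1, "NO2": 1, "O3": 1, "CO": 1,
    "AP": 1, "AT": 0, "RH": 1, "PR": 2, "WS": 2, "AV": 2,
}

#: The published stepwise regression equation for the monthly DED index (%):
#: DED = 5.344 + 0.163*AT + 0.071*PM10 - 0.038*O3, with global F = 7.06.
PUBLISHED_EQUATION: dict[str, float] = {
    "intercept": 5.344, "AT": 0.163, "PM10": 0.071, "O3": -0.038,
}
PUBLISHED_F_STATISTIC: float = 7.06

#: Signs of the published DED–factor Pearson correlations (monthly series,
#: 2016–2020).  SO2 is omitted: the publication reports no sign for it.
PUBLISHED_CORRELATION_SIGNS: dict[str, int] = {
    "PM10": +1, "O3": +1, "CO": +1, "NO2": +1, "PM2.5": +1, "AT": +1,
    "WS": +1, "RH": -1, "PR": -1, "AV": -1,
}


def _read_fixture(name: str) -> pd.DataFrame:
    ref = resources.files("dedair.data").joinpath(name)
    with ref.open("rb") as fh:
        payload = fh.read()
    FIXTURE_SHA256.setdefault(name, hashlib.sha256(payload).hexdigest())
    import io

    return pd.read_csv(io.BytesIO(payload))


def fixture_digest(name: str) -> str:
    ref = resources.files("dedair.data").joinpath(name)
    with ref.open("rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()


def load_table1() -> MonthlyExposureTable:
    """The published monthly climatology (12 calendar months × DED + 12 factors)."""
    frame = _read_fixture("table1_monthly.csv").set_index("month")
    return MonthlyExposureTable(frame=frame, provenance="fixture")


def load_table1_sd() -> pd.DataFrame:
    """Printed standard deviations matching :func:`load_table1` (AV has none)."""
    return _read_fixture("table1_sd.csv").set_index("month")


def load_table2() -> dict[str, pd.DataFrame | pd.Series]:
    """The published grey relational table.

    Returns ``{"coefficients": 12×12 frame (month × factor), "grades": Series,
    "ranks": Series}``.
    """
    raw = _read_fixture("table2_grey.csv").set_index("row")
    coeffs = raw.loc[[str(m) for m in range(1, 13)]].astype(float)
    coeffs.index = pd.Index(range(1, 13), name="month")
    grades = raw.loc["grade"].astype(float)
    ranks = raw.loc["rank"].astype(int)
    return {"coefficients": coeffs, "grades": grades, "ranks": ranks}
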