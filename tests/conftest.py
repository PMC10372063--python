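"""Shared fixtures: the published climatology and small synthetic builders."""

from __future__ import annotations

import io

import numpy as np
import pandas as pd
import pytest

from dedair import datasets
from dedair.io_timeseries import FACTORS


@pytest.fixture(scope="session")
def table1() -> pd.DataFrame:
    return datasets.load_table1().frame


@pytest.fixture(scope="session")
def table1_sd() -> pd.DataFrame:
    return datasets.load_table1_sd()


@pytest.fixture(scope="session")
def table2() -> dict:
    return datasets.load_table2()


@pytest.fixture(scope="session")
def monthly_factor_sampler(table1, table1_sd):
    """Sampler of plausible monthly factor tables: climatology plus
    independent interannual anomalies at the printed SDs.

    Returns a callable ``(rng, n_years) -> DataFrame`` with one row per
    (year, month) and the twelve factor columns.
    """
    means = {f: table1[f].to_numpy(dtype=float) for f in FACTORS}
    sds = {}
    for f in FACTORS:
        sd = table1_sd[f].to_numpy(dtype=float)
        sds[f] = np.nan_to_num(sd, nan=0.15 * np.nanmean(np.abs(means[f])))

    def sample(rng: np.random.Generator, n_years: int = 5) -> pd.DataFrame:
        rows = {}
        for f in FACTORS:
            draws = np.tile(means[f], n_years) + rng.normal(
                0.0, 1.0, 12 * n_years
            ) * np.tile(sds[f], n_years)
            rows[f] = draws
        idx = pd.MultiIndex.from_product(
            [range(2016, 2016 + n_years), range(1, 13)], names=["year", "month"]
        )
        return pd.DataFrame(rows, index=idx)

    return sample


def daily_csv(rows: list[str], header: str = "date,pm10,pm25,rh,pr,visits") -> io.StringIO:
    """Small in-memory daily CSV builder for ingestion tests."""
    return io.StringIO("\n".join([header, *rows]) + "\n")
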