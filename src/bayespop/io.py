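"""CSV dialects of the pipeline and bundled fixture loaders.

All tabular inputs and outputs are plain CSV.  Lines starting with ``#`` are
comments.  The dialects:

- ``tfr.csv``: ``year,tfr``
- ``e0.csv``: ``year,sex,e0`` with sex in {male, female}
- ``asfr_pattern.csv``: ``age_group,weight`` over the 7 reproductive groups
- ``standard_lx.csv``: ``age,lx_male,lx_female,m80_male,m80_female``
  (m80 given on the age-80 row)
- ``base_population.csv``: ``age_group,sex,population_thousands``
- projection tables: wide layout ``age_group,sex,<year>,...`` with an
  ``all_ages`` block, plus a long quantile layout from the engine summary.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .fertility import REPRODUCTIVE_AGE_GROUPS, TFRSeries
from .lifetable import StandardSchedule
from .mortality import E0Series
from .projection import AGE_GROUPS, AgeSexPopulation

__all__ = [
    "read_tfr_csv",
    "write_tfr_csv",
    "read_e0_csv",
    "write_e0_csv",
    "read_asfr_pattern",
    "read_standard_schedules",
    "read_base_population",
    "write_base_population",
    "read_projection_table",
    "load_bangladesh_tfr",
    "load_default_asfr_pattern",
    "load_standard_schedules",
    "load_base_population_2001",
    "load_published_projection",
]

_DATA = resources.files("bayespop") / "data"


def _read_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_tfr_csv(path) -> TFRSeries:
    df = _read_csv(path)
    return TFRSeries(years=df["year"].to_numpy(), values=df["tfr"].to_numpy())


def write_tfr_csv(series: TFRSeries, path) -> None:
    pd.DataFrame({"year": series.years, "tfr": series.values}).to_csv(path, index=False)


def read_e0_csv(path, sex: str | None = None) -> dict[str, E0Series] | E0Series:
    """Read an e0 file; returns one series per sex, or a single series if
    ``sex`` is given."""
    df = _read_csv(path)
    out = {}
    for s, grp in df.groupby("sex"):
        grp = grp.sort_values("year")
        out[s] = E0Series(years=grp["year"].to_numpy(), values=grp["e0"].to_numpy(), sex=s)
    if sex is not None:
        return out[sex]
    return out


def write_e0_csv(series_by_sex: dict[str, E0Series], path) -> None:
    frames = [
        pd.DataFrame({"year": s.years, "sex": sex, "e0": s.values})
        for sex, s in series_by_sex.items()
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_asfr_pattern(path) -> np.ndarray:
    """Read the 7-group proportional fertility pattern, in age order."""
    df = _read_csv(path).set_index("age_group")
    try:
        weights = df.loc[list(REPRODUCTIVE_AGE_GROUPS), "weight"].to_numpy(dtype=float)
    except KeyError as err:
        raise ValueError(f"pattern must cover groups {REPRODUCTIVE_AGE_GROUPS}") from err
    return weights


def read_standard_schedules(path) -> dict[str, StandardSchedule]:
    df = _read_csv(path)
    out = {}
    for sex in ("male", "female"):
        m80 = float(df.loc[df["age"] == 80, f"m80_{sex}"].iloc[0])
        out[sex] = StandardSchedule(
            ages=df["age"].to_numpy(),
            lx=df[f"lx_{sex}"].to_numpy(),
            m80=m80,
            sex=sex,
        )
    return out


def read_base_population(path) -> AgeSexPopulation:
    df = _read_csv(path)
    pops = {}
    for sex in ("male", "female"):
        sub = df[df["sex"] == sex].set_index("age_group")
        pops[sex] = sub.loc[list(AGE_GROUPS), "population_thousands"].to_numpy(dtype=float)
    year_col = df["reference_year"].iloc[0] if "reference_year" in df.columns else 2001
    return AgeSexPopulation(reference_year=int(year_col), male=pops["male"], female=pops["female"])


def write_base_population(pop: AgeSexPopulation, path) -> None:
    pop.to_frame().to_csv(path, index=False)


def read_projection_table(path) -> pd.DataFrame:
    """Read a wide projection table (age_group, sex, one column per year)."""
    return _read_csv(path)


# ---------------------------------------------------------------------------
# Bundled fixtures


def load_bangladesh_tfr() -> TFRSeries:
    """The observed Bangladesh TFR series, 1991-2001 (BBS)."""
    return read_tfr_csv(_DATA / "bangladesh_tfr.csv")


def load_default_asfr_pattern() -> np.ndarray:
    """The bundled illustrative (synthetic) age pattern of fertility."""
    return read_asfr_pattern(_DATA / "asfr_pattern.csv")


def load_standard_schedules() -> dict[str, StandardSchedule]:
    """The bundled synthetic Brass standard, one schedule per sex."""
    return read_standard_schedules(_DATA / "standard_lx.csv")


def load_base_population_2001() -> AgeSexPopulation:
    """The 2001 Bangladesh census base population (thousands)."""
    return read_base_population(_DATA / "base_population_2001.csv")


def load_published_projection() -> pd.DataFrame:
    """The published 2001-2051 projection table (thousands), wide layout."""
    return read_projection_table(_DATA / "projection_2006_2051.csv")
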