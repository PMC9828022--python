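"""Census-side demography from age-structured stock-assessment tables.

Inputs are per-year, per-age abundance (N), total mortality (Z = natural +
fishing, per year), maturity proportion and relative fecundity.  Breeding
abundance at peak spawning discounts the mature abundance by mortality to
the within-year moment of peak spawning (fraction ``p`` of the year, default
10/12 for a November peak):

    N_ps,t = sum_a N_a,t * m_a * exp(-p * Z_a,t)

Generation length is the average parental age at reproduction:
fecundity-weighted for females, equal age-class contribution for males.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AgeStructuredTable",
    "peak_spawning_abundance",
    "generation_length",
    "ne_nc_ratio",
]

_COLUMNS = ("year", "age", "N", "Z", "maturity", "fecundity")


@dataclass
class AgeStructuredTable:
    """Tidy per-(year, age) table of abundance and vital rates."""

    data: pd.DataFrame
    peak_fraction: float = 10.0 / 12.0

    def __post_init__(self) -> None:
        missing = [c for c in _COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"age table missing columns {missing}")
        d = self.data
        if (d["N"] < 0).any() or (d["Z"] < 0).any():
            raise ValueError("N and Z must be non-negative")
        if ((d["maturity"] < 0) | (d["maturity"] > 1)).any():
            raise ValueError("maturity must lie in [0, 1]")
        if (d["fecundity"] < 0).any():
            raise ValueError("fecundity must be non-negative")
        if not 0 <= self.peak_fraction <= 1:
            raise ValueError("peak_fraction must lie in [0, 1]")

    @property
    def years(self) -> list[int]:
        return sorted(self.data["year"].unique())

    def year_slice(self, year: int) -> pd.DataFrame:
        d = self.data[self.data["year"] == year]
        if d.empty:
            raise KeyError(f"year {year} not in table")
        return d.sort_values("age")

    @classmethod
    def read(cls, path, peak_fraction: float = 10.0 / 12.0) -> "AgeStructuredTable":
        sep = "," if str(path).endswith(".csv") else "\t"
        return cls(pd.read_csv(path, sep=sep), peak_fraction)

    def write(self, path) -> None:
        sep = "," if str(path).endswith(".csv") else "\t"
        self.data.to_csv(path, sep=sep, index=False)


def peak_spawning_abundance(tbl: AgeStructuredTable, year: int) -> float:
    """Mature breeding abundance discounted to peak spawning time."""
    d = tbl.year_slice(year)
    mature = d["N"] * d["maturity"]
    return float((mature * np.exp(-tbl.peak_fraction * d["Z"])).sum())


def generation_length(
    tbl: AgeStructuredTable, years: list[int] | None = None
) -> tuple[float, float, float]:
    """(female, male, average) generation length over a range of years.

    Female generation length is the mean female age weighted by egg
    production (N * maturity * fecundity); male generation length assumes
    equal contribution per mature fish (N * maturity).  Years are averaged
    with equal weight.
    """
    years = years if years is not None else tbl.years
    fem, mal = [], []
    for y in years:
        d = tbl.year_slice(y)
        a = d["age"].to_numpy(dtype=float)
        mature = (d["N"] * d["maturity"]).to_numpy(dtype=float)
        eggs = mature * d["fecundity"].to_numpy(dtype=float)
        if eggs.sum() <= 0 or mature.sum() <= 0:
            raise ValueError(f"no mature reproduction in year {y}")
        fem.append(float((a * eggs).sum() / eggs.sum()))
        mal.append(float((a * mature).sum() / mature.sum()))
    f = float(np.mean(fem))
    m = float(np.mean(mal))
    return f, m, (f + m) / 2.0


def ne_nc_ratio(ne_diploid: float, nc: float) -> float:
    """Effective / census size ratio."""
    if nc <= 0:
        raise ValueError("census size must be positive")
    return ne_diploid / nc
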