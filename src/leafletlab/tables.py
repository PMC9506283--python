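"""Effect-size arithmetic on per-species structural tables.

Simulation studies of sterol-containing monolayers report their results as
per-species tables: mean area per lipid (APL) and tail/head/total
thickness for the cholesterol-free (NChol), cholesterol (Chol) and
7-ketocholesterol (KChol) systems, plus static compression moduli at a
reference pressure. The scientifically interesting quantities are derived
contrasts — how much a sterol increases a thickness relative to the
sterol-free system, and how the two sterols compare. The helpers here
compute those contrasts from any such table.

The module also ships the reference tables for the erythrocyte inner
leaflet model systems (DPPC/DPPE/DPPS/PSM + sterol) used as worked-example
inputs throughout the package.
"""

from __future__ import annotations

import pandas as pd

__all__ = [
    "rbc_composition",
    "rbc_area_per_lipid",
    "rbc_tail_thickness",
    "rbc_compression_moduli_30",
    "increase_ratio",
    "relative_increase",
    "ratio",
]

#: Monolayer composition (mol %) of the inner-leaflet model systems.
RBC_COMPOSITION = {
    "DPPC": {"Chol": 12, "KChol": 12, "NChol": 17},
    "DPPE": {"Chol": 38, "KChol": 38, "NChol": 43},
    "DPPS": {"Chol": 22, "KChol": 22, "NChol": 27},
    "PSM": {"Chol": 8, "KChol": 8, "NChol": 13},
    "Chol": {"Chol": 20, "KChol": 0, "NChol": 0},
    "KChol": {"Chol": 0, "KChol": 20, "NChol": 0},
}

#: Mean area per lipid (Å²) per species and system.
RBC_AREA_PER_LIPID = {
    "DPPC": {"NChol": 48.5, "Chol": 44.7, "KChol": 45.3},
    "DPPE": {"NChol": 46.9, "Chol": 43.9, "KChol": 44.8},
    "DPPS": {"NChol": 45.0, "Chol": 43.9, "KChol": 46.6},
    "PSM": {"NChol": 43.2, "Chol": 41.9, "KChol": 45.9},
}

#: Mean acyl-tail thickness (Å) per species and system.
RBC_TAIL_THICKNESS = {
    "DPPC": {"NChol": 16.1, "Chol": 18.1, "KChol": 17.9},
    "DPPE": {"NChol": 16.3, "Chol": 18.2, "KChol": 17.7},
    "DPPS": {"NChol": 16.8, "Chol": 18.3, "KChol": 17.8},
    "PSM": {"NChol": 17.9, "Chol": 19.4, "KChol": 18.4},
}

#: Static compression moduli ε (mN/m) at π = 30 mN/m per system.
RBC_EPSILON_30 = {"Chol": 147.0, "NChol": 207.0, "KChol": 250.0}


def rbc_composition() -> pd.DataFrame:
    return pd.DataFrame(RBC_COMPOSITION).T


def rbc_area_per_lipid() -> pd.DataFrame:
    return pd.DataFrame(RBC_AREA_PER_LIPID).T


def rbc_tail_thickness() -> pd.DataFrame:
    return pd.DataFrame(RBC_TAIL_THICKNESS).T


def rbc_compression_moduli_30() -> pd.Series:
    return pd.Series(RBC_EPSILON_30)


def increase_ratio(table: pd.DataFrame, species: str, reference: str = "NChol",
                   numerator: str = "Chol", denominator: str = "KChol",
                   ndigits: int | None = 1) -> float:
    """Ratio of two systems' increases over a reference system.

    For a per-species table T, returns
    (T[numerator] − T[reference]) / (T[denominator] − T[reference]),
    e.g. how many times larger the cholesterol-induced tail-thickness
    increase is than the 7-ketocholesterol-induced one.
    """
    row = table.loc[species]
    num = row[numerator] - row[reference]
    den = row[denominator] - row[reference]
    if den == 0:
        raise ZeroDivisionError("reference increase is zero")
    value = num / den
    return round(value, ndigits) if ndigits is not None else value


def relative_increase(table: pd.DataFrame, species: str, system: str,
                      reference: str = "NChol",
                      percent: bool = True, ndigits: int | None = 0) -> float:
    """Relative change of a species' value in ``system`` vs ``reference``.

    Returned in percent by default (rounded to the integer percent, the
    precision such tables are quoted at).
    """
    row = table.loc[species]
    value = (row[system] - row[reference]) / row[reference]
    if percent:
        value *= 100.0
    return round(value, ndigits) if ndigits is not None else value


def ratio(values, numerator: str, denominator: str,
          ndigits: int | None = 1) -> float:
    """Plain ratio of two entries of a mapping/Series (e.g. ε ratios)."""
    value = values[numerator] / values[denominator]
    return round(value, ndigits) if ndigits is not None else value
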