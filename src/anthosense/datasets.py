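"""Packaged reference tables from the published caper-flower field survey.

Two small CSVs ship with the package:

* ``capparis_volatiles_lesvos.csv`` — mean floral volatile emission rates
  (ng per flower per hour, toluene equivalents) with standard errors for
  two Lesvos populations (Koudouroudia and Thermi, N = 9 flowers each),
  with biosynthetic class, Kovats retention index and identification
  status per compound;
* ``capparis_visitation_mytilene.csv`` — per-taxon visitation rates
  (visits per flower per hour, mean ± SE over six overnight camera
  sessions) in three diel periods.

These are transcriptions of printed summary tables, used for internal-
consistency checks (totals, composition shares, aggregate rates), not raw
field data.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = [
    "load_lesvos_volatiles",
    "load_mytilene_visitation",
    "ALDOXIMES",
    "POPULATIONS",
]

#: The six identified aldoximes (glucosinolate-pathway volatiles): the
#: syn/anti 2-methyl-propanaldoximes and the syn/anti 2-methyl- and
#: 3-methyl-butyl aldoximes. Pentanal oxime is an oxime but is not part of
#: this branched-chain set.
ALDOXIMES = [
    "Propanaldoxime, 2-methyl, syn-",
    "Propanaldoxime, 2-methyl, anti-",
    "Butyl aldoxime, 2-methyl-, syn-",
    "Butyl aldoxime, 3-methyl-, syn-",
    "Butyl aldoxime, 2-methyl-, anti-",
    "Butyl aldoxime, 3-methyl-, anti-",
]

POPULATIONS = ("koudouroudia", "thermi")


def _data_path(name: str):
    return resources.files("anthosense.data").joinpath(name)


def load_lesvos_volatiles() -> pd.DataFrame:
    """Per-compound mean ERs ± SE for the two populations.

    Returns a DataFrame indexed by compound with columns
    ``biosynthetic_class, kri, id_status, koudouroudia_mean,
    koudouroudia_se, thermi_mean, thermi_se``; a missing mean means the
    compound was not detected in that population.
    """
    with resources.as_file(_data_path("capparis_volatiles_lesvos.csv")) as p:
        df = pd.read_csv(p)
    return df.set_index("compound")


def load_mytilene_visitation() -> pd.DataFrame:
    """Per-taxon, per-period visitation rates (mean ± SE over sessions)."""
    with resources.as_file(_data_path("capparis_visitation_mytilene.csv")) as p:
        return pd.read_csv(p)


def population_means(df: pd.DataFrame | None = None,
                     population: str = "koudouroudia") -> pd.Series:
    """Detected-compound mean ERs of one population (NaN rows dropped)."""
    if df is None:
        df = load_lesvos_volatiles()
    if population not in POPULATIONS:
        raise ValueError(f"unknown population {population!r}")
    return df[f"{population}_mean"].dropna()
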