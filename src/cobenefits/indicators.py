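"""Per-measure co-benefit indicators and the PM2.5 health-impact chain.

Two dimensionless indicators are attached to every energy-saving (ES)
measure in a city X:

- climate-change benefit  ``CCB = EM_SAV / EM_TOT_X`` — the CO2 saved as a
  fraction of the city's total baseline emissions;
- air-quality benefit ``AQB = (E_SAV / E_SEC_X) * (C_SEC_X / C_TOT_X)`` —
  the fraction of the target sector's energy saved, weighted by that
  sector's share of the four-sector urban contribution to the pollutant.
  Both factors lie in [0, 1] for filtered ES measures, so AQB does too; 1
  is the ideal measure that saves all the energy of the single sector
  responsible for all urban pollution.

The health chain converts the PM2.5 AQB into avoided premature deaths via
a log-linear concentration-response function: the relative risk at annual
mean PM is ``RR = rr10 ** (PM / 10)`` with rr10 = 1.062 per 10 µg/m³
(95% CI 1.04–1.083), the attributable fraction is ``AF = (RR - 1) / RR``,
and per inhabitant

    PD = dPM * DR * P30 * AF,     dPM = AQB * C_TOT * PM

with DR the country all-cause death rate above age 30 and P30 the
population fraction above 30.  Years of life saved: ``YLS = PD * YL`` with
YL the mean years of life lost per premature death.  Low/central/high
bounds come solely from the three rr10 values.  Only the PM2.5 chain is
assessed; the NOx AQB is computed but enters no health calculation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Literal, Tuple

import pandas as pd

from .datamodel import AnalysisDataset, CityContext, CountryHealthParams, Measure

RR_PER_10_LOW = 1.04
RR_PER_10_CENTRAL = 1.062
RR_PER_10_HIGH = 1.083

Triple = Tuple[float, float, float]  # (low, central, high)
Eq3Form = Literal["literal", "fractional"]


class UndefinedIndicatorError(ValueError):
    """An indicator's denominator is zero or otherwise undefined for this
    measure/city pair (distinct from the exclusion filter)."""


@dataclass
class RiskParams:
    """Concentration-response parameters of the log-linear model."""

    rr_per_10_low: float = RR_PER_10_LOW
    rr_per_10_central: float = RR_PER_10_CENTRAL
    rr_per_10_high: float = RR_PER_10_HIGH

    def triple(self) -> Triple:
        return (self.rr_per_10_low, self.rr_per_10_central, self.rr_per_10_high)


@dataclass
class IndicatorSet:
    """All indicators for one measure (city totals scale per-capita values
    by the full city population)."""

    measure_id: str
    city_id: str
    sector: str
    ccb: float
    aqb_pm25: float
    aqb_nox: float
    delta_pm25: float  # µg/m³
    pd_per_capita: Triple  # deaths / person / y
    pd_city_total: Triple  # deaths / y
    yls_city_total: Triple  # years / y


def compute_ccb(m: Measure, city: CityContext) -> float:
    """Climate-change benefit: CO2 saved over the city's total baseline CO2."""
    if city.total_co2 <= 0:
        raise UndefinedIndicatorError(
            f"city {city.city_id}: total CO2 must be > 0 to define CCB"
        )
    return (m.co2_reduction or 0.0) / city.total_co2


def compute_aqb(m: Measure, city: CityContext, pollutant: str) -> float:
    """Air-quality benefit of an ES measure for PM2.5 or NOx."""
    e_sec = city.sector_energy.get(m.sector)
    if e_sec is None or e_sec <= 0:
        raise UndefinedIndicatorError(
            f"measure {m.measure_id}: sector '{m.sector}' energy is zero/absent "
            f"in city {city.city_id}"
        )
    c_tot = city.sce_total(pollutant)
    if c_tot <= 0:
        raise UndefinedIndicatorError(
            f"city {city.city_id}: total urban {pollutant} contribution is zero"
        )
    c_sec = city.sce(pollutant).get(m.sector, 0.0)
    return ((m.energy_saved or 0.0) / e_sec) * (c_sec / c_tot)


def relative_risk(pm25: float, rr_per_10: float = RR_PER_10_CENTRAL) -> float:
    """Relative mortality risk at annual-mean PM2.5: ``rr_per_10 ** (pm25/10)``."""
    if pm25 < 0:
        raise ValueError(f"PM2.5 concentration must be >= 0, got {pm25}")
    if rr_per_10 <= 0:
        raise ValueError(f"relative risk per 10 µg/m³ must be > 0, got {rr_per_10}")
    return rr_per_10 ** (pm25 / 10.0)


def attributable_fraction(rf: float) -> float:
    """Fraction of mortality attributable to the exposure: (RF - 1) / RF."""
    if rf < 1:
        raise ValueError(f"risk factor must be >= 1, got {rf}")
    return (rf - 1.0) / rf


def compute_pd(
    m: Measure,
    city: CityContext,
    health: CountryHealthParams,
    risk: RiskParams | None = None,
    eq3: Eq3Form = "literal",
) -> Tuple[Triple, float]:
    """Avoided premature deaths per inhabitant per year, as a
    (low, central, high) triple, plus the PM2.5 concentration decrease.

    ``eq3="literal"`` multiplies the concentration change dPM = AQB*C_TOT*PM
    by DR*P30*AF; ``eq3="fractional"`` drops the PM factor and reads
    AQB*C_TOT as a fractional concentration reduction applied to the
    attributable death rate DR*P30*AF.
    """
    risk = risk or RiskParams()
    aqb = compute_aqb(m, city, "PM2.5")
    c_tot = city.sce_total("PM2.5")
    delta_pm25 = aqb * c_tot * city.pm25_level
    scale = delta_pm25 if eq3 == "literal" else aqb * c_tot
    pd_triple = tuple(
        scale
        * health.death_rate
        * health.frac_over_30
        * attributable_fraction(relative_risk(city.pm25_level, rr))
        for rr in risk.triple()
    )
    return pd_triple, delta_pm25  # type: ignore[return-value]


def compute_yls(pd_per_capita: Triple, health: CountryHealthParams) -> Triple:
    """Years of life saved per inhabitant per year: PD times the mean years
    of life lost per premature death."""
    yl = health.years_lost_per_death
    return tuple(v * yl for v in pd_per_capita)  # type: ignore[return-value]


def compute_indicators(
    m: Measure,
    city: CityContext,
    health: CountryHealthParams,
    risk: RiskParams | None = None,
    eq3: Eq3Form = "literal",
) -> IndicatorSet:
    """All indicators for one measure."""
    pd_pc, delta = compute_pd(m, city, health, risk, eq3)
    yls_pc = compute_yls(pd_pc, health)
    pop = city.population
    return IndicatorSet(
        measure_id=m.measure_id,
        city_id=m.city_id,
        sector=m.sector,
        ccb=compute_ccb(m, city),
        aqb_pm25=compute_aqb(m, city, "PM2.5"),
        aqb_nox=compute_aqb(m, city, "NOx"),
        delta_pm25=delta,
        pd_per_capita=pd_pc,
        pd_city_total=tuple(v * pop for v in pd_pc),  # type: ignore[arg-type]
        yls_city_total=tuple(v * pop for v in yls_pc),  # type: ignore[arg-type]
    )


def indicator_table(
    dataset: AnalysisDataset,
    risk: RiskParams | None = None,
    eq3: Eq3Form = "literal",
) -> pd.DataFrame:
    """Indicator table for a post-filter ES dataset, one row per measure.

    Measures raising :class:`UndefinedIndicatorError` are skipped and
    logged in the dataset provenance.
    """
    rows: List[dict] = []
    for m in dataset.measures:
        city = dataset.cities[m.city_id]
        health = dataset.health[city.country_code]
        try:
            ind = compute_indicators(m, city, health, risk, eq3)
        except UndefinedIndicatorError as exc:
            dataset.log(f"indicators: skipped '{m.measure_id}': {exc}")
            continue
        rows.append(
            {
                "measure_id": ind.measure_id,
                "city_id": ind.city_id,
                "sector": ind.sector,
                "ccb": ind.ccb,
                "aqb_pm25": ind.aqb_pm25,
                "aqb_nox": ind.aqb_nox,
                "delta_pm25": ind.delta_pm25,
                "pd_low": ind.pd_city_total[0],
                "pd_central": ind.pd_city_total[1],
                "pd_high": ind.pd_city_total[2],
                "yls_low": ind.yls_city_total[0],
                "yls_central": ind.yls_city_total[1],
                "yls_high": ind.yls_city_total[2],
                "pd_pc_low": ind.pd_per_capita[0],
                "pd_pc_central": ind.pd_per_capita[1],
                "pd_pc_high": ind.pd_per_capita[2],
                "yls_pc_low": ind.yls_city_total[0] / city.population,
                "yls_pc_central": ind.yls_city_total[1] / city.population,
                "yls_pc_high": ind.yls_city_total[2] / city.population,
            }
        )
    columns = [
        "measure_id", "city_id", "sector", "ccb", "aqb_pm25", "aqb_nox",
        "delta_pm25", "pd_low", "pd_central", "pd_high",
        "yls_low", "yls_central", "yls_high",
        "pd_pc_low", "pd_pc_central", "pd_pc_high",
        "yls_pc_low", "yls_pc_central", "yls_pc_high",
    ]
    return pd.DataFrame(rows, columns=columns)
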