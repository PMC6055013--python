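"""Typed data model for the co-benefits analysis.

The analysis joins five tables: per-measure energy actions reported by city
climate plans, the city baseline emission inventory (per-sector final energy
and total CO2), sectoral source-contribution estimates for urban-background
PM2.5 and NOx, annual-mean pollutant levels, and country-level health
parameters (all-cause death rate above 30 years, population fraction above
30, years of life lost per premature death).

All energies are MWh/y, CO2 masses tCO2-eq/y, concentrations µg/m³ and
source contributions dimensionless fractions in [0, 1].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from pydantic import BaseModel, Field, field_validator, model_validator

SECTORS = ("Buildings", "Traffic", "Industry", "Other")
POLLUTANTS = ("PM2.5", "NOx")


class Category(str, enum.Enum):
    """Measure category: pure energy saving, pure renewable production,
    both, or unclassifiable (zero/missing effort on both axes)."""

    ES = "ES"
    REP = "REP"
    MIX = "MIX"
    UNCLASSIFIED = "UNCLASSIFIED"


class Measure(BaseModel):
    """One mitigation action from a city action plan."""

    measure_id: str
    city_id: str
    sector: str
    energy_saved: Optional[float] = None  # MWh/y, >= 0 or missing
    renewable_production: Optional[float] = None  # MWh/y, >= 0 or missing
    co2_reduction: Optional[float] = None  # tCO2-eq/y, >= 0 or missing
    category: Category = Category.UNCLASSIFIED

    @field_validator("sector")
    @classmethod
    def _sector_known(cls, v: str) -> str:
        if v not in SECTORS:
            raise ValueError(f"unknown sector {v!r}; expected one of {SECTORS}")
        return v

    @field_validator("energy_saved", "renewable_production", "co2_reduction")
    @classmethod
    def _non_negative(cls, v: Optional[float]) -> Optional[float]:
        if v is not None and not (v >= 0):
            raise ValueError(f"value must be >= 0 or missing, got {v}")
        return v


class CityContext(BaseModel):
    """One city's inventory, source contributions and pollution levels.

    ``sce_pm25``/``sce_nox`` map each sector to the fraction of the
    urban-background concentration attributable to that sector's urban
    emissions; their per-pollutant sum (the total urban contribution) must
    lie in (0, 1] — the remainder is non-urban background.
    """

    city_id: str
    country_code: str = Field(min_length=2, max_length=2)
    population: float = Field(gt=0)
    sector_energy: Dict[str, float]  # sector -> MWh/y
    total_co2: float = Field(gt=0)  # tCO2-eq/y
    sce_pm25: Dict[str, float]
    sce_nox: Dict[str, float]
    pm25_level: float = Field(gt=0)  # µg/m³
    nox_level: float = Field(gt=0)  # µg/m³

    @field_validator("sector_energy")
    @classmethod
    def _energy_ok(cls, v: Dict[str, float]) -> Dict[str, float]:
        for s, e in v.items():
            if s not in SECTORS:
                raise ValueError(f"unknown sector {s!r}")
            if not (e >= 0):
                raise ValueError(f"sector energy must be >= 0, got {e} for {s}")
        return v

    @field_validator("sce_pm25", "sce_nox")
    @classmethod
    def _sce_fractions(cls, v: Dict[str, float]) -> Dict[str, float]:
        for s, f in v.items():
            if s not in SECTORS:
                raise ValueError(f"unknown sector {s!r}")
            if not (0.0 <= f <= 1.0):
                raise ValueError(f"SCE fraction out of [0,1]: {f} for {s}")
        return v

    @model_validator(mode="after")
    def _sce_totals(self) -> "CityContext":
        for name, sce in (("PM2.5", self.sce_pm25), ("NOx", self.sce_nox)):
            tot = sum(sce.values())
            if not (0.0 < tot <= 1.0 + 1e-9):
                raise ValueError(
                    f"total urban contribution for {name} must be in (0,1], got {tot}"
                )
        return self

    def sce(self, pollutant: str) -> Dict[str, float]:
        if pollutant == "PM2.5":
            return self.sce_pm25
        if pollutant == "NOx":
            return self.sce_nox
        raise ValueError(f"unknown pollutant {pollutant!r}")

    def sce_total(self, pollutant: str) -> float:
        return float(sum(self.sce(pollutant).values()))


class CountryHealthParams(BaseModel):
    """Country-level inputs of the health-impact chain."""

    country_code: str = Field(min_length=2, max_length=2)
    death_rate: float = Field(gt=0, lt=1)  # deaths/person/y, ages >= 30
    frac_over_30: float = Field(gt=0, le=1)
    years_lost_per_death: float = Field(gt=0)  # years


@dataclass
class AnalysisDataset:
    """Merged, validated analysis-ready dataset.

    Invariants (enforced by the reader, preserved by every stage): every
    measure's ``city_id`` resolves to a city, every city's ``country_code``
    resolves to health parameters.
    """

    measures: List[Measure] = field(default_factory=list)
    cities: Dict[str, CityContext] = field(default_factory=dict)
    health: Dict[str, CountryHealthParams] = field(default_factory=dict)
    provenance: List[str] = field(default_factory=list)

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def check_referential_closure(self) -> None:
        for m in self.measures:
            if m.city_id not in self.cities:
                raise ValueError(f"measure {m.measure_id}: dangling city_id {m.city_id}")
        for c in self.cities.values():
            if c.country_code not in self.health:
                raise ValueError(
                    f"city {c.city_id}: dangling country_code {c.country_code}"
                )

    def subset(self, measures: List[Measure]) -> "AnalysisDataset":
        """New dataset restricted to the given measures and the cities they
        touch (health map is kept whole; it is country-keyed reference data)."""
        city_ids = {m.city_id for m in measures}
        return AnalysisDataset(
            measures=list(measures),
            cities={cid: c for cid, c in self.cities.items() if cid in city_ids},
            health=dict(self.health),
            provenance=list(self.provenance),
        )
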