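"""CSV readers/writers and merge/validation for the five input tables.

Schemas (comma-separated, UTF-8, dot decimal, header row mandatory; empty
cells mean missing):

- ``measures.csv``: measure_id,city_id,sector,energy_saved_mwh,renewable_mwh,co2_reduction_t
- ``bei.csv``: city_id,country,population,sector,energy_mwh,total_co2_t
  (long format, one row per city+sector; country/population/total repeated)
- ``sce.csv``: city_id,pollutant,sector,fraction (pollutant in {PM2.5, NOx})
- ``aq.csv``: city_id,pm25_ugm3,nox_ugm3
- ``hi.csv``: country,death_rate,frac_over_30,yll_per_death

The reader is total: it either returns a dataset satisfying every type
invariant or fails with a named error; invalid rows are dropped and logged
in the dataset's provenance, never returned.
"""

from __future__ import annotations

import logging
import math
import os
from typing import Dict, Iterable, List, Optional, Set

import pandas as pd
from pydantic import ValidationError

from .datamodel import (
    SECTORS,
    AnalysisDataset,
    CityContext,
    CountryHealthParams,
    Measure,
)

logger = logging.getLogger(__name__)

MEASURES_COLUMNS = [
    "measure_id",
    "city_id",
    "sector",
    "energy_saved_mwh",
    "renewable_mwh",
    "co2_reduction_t",
]
BEI_COLUMNS = ["city_id", "country", "population", "sector", "energy_mwh", "total_co2_t"]
SCE_COLUMNS = ["city_id", "pollutant", "sector", "fraction"]
AQ_COLUMNS = ["city_id", "pm25_ugm3", "nox_ugm3"]
HI_COLUMNS = ["country", "death_rate", "frac_over_30", "yll_per_death"]


def _read_csv(path: str, required: List[str]) -> pd.DataFrame:
    if not os.path.exists(path):
        raise FileNotFoundError(f"input table not found: {path}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in required:
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    return df


def _opt_float(raw: str) -> Optional[float]:
    raw = raw.strip()
    if raw == "":
        return None
    v = float(raw)
    if math.isnan(v):
        return None
    return v


def _norm_sector(raw: str, dataset: AnalysisDataset, context: str) -> str:
    s = raw.strip()
    if s in SECTORS:
        return s
    dataset.log(f"{context}: unknown sector '{s}' mapped to Other")
    logger.warning("%s: unknown sector %r mapped to Other", context, s)
    return "Other"


def _read_health(path: str, dataset: AnalysisDataset) -> Dict[str, CountryHealthParams]:
    df = _read_csv(path, HI_COLUMNS)
    out: Dict[str, CountryHealthParams] = {}
    for _, row in df.iterrows():
        try:
            hp = CountryHealthParams(
                country_code=row["country"].strip(),
                death_rate=float(row["death_rate"]),
                frac_over_30=float(row["frac_over_30"]),
                years_lost_per_death=float(row["yll_per_death"]),
            )
        except (ValidationError, ValueError) as exc:
            dataset.log(f"hi: dropped row for country '{row['country']}': {exc}")
            continue
        out[hp.country_code] = hp
    return out


def _read_cities(
    bei_path: str,
    sce_path: str,
    aq_path: str,
    dataset: AnalysisDataset,
    health: Dict[str, CountryHealthParams],
    sce_percent: bool,
) -> Dict[str, CityContext]:
    bei = _read_csv(bei_path, BEI_COLUMNS)
    sce = _read_csv(sce_path, SCE_COLUMNS)
    aq = _read_csv(aq_path, AQ_COLUMNS)

    sce_maps: Dict[str, Dict[str, Dict[str, float]]] = {}
    for _, row in sce.iterrows():
        cid = row["city_id"].strip()
        pol = row["pollutant"].strip()
        if pol not in ("PM2.5", "NOx"):
            dataset.log(f"sce: dropped row for city '{cid}': unknown pollutant '{pol}'")
            continue
        sector = _norm_sector(row["sector"], dataset, f"sce city {cid}")
        try:
            frac = float(row["fraction"])
        except ValueError:
            dataset.log(f"sce: dropped row for city '{cid}': bad fraction")
            continue
        if sce_percent:
            frac /= 100.0
        sce_maps.setdefault(cid, {}).setdefault(pol, {})[sector] = (
            sce_maps.get(cid, {}).get(pol, {}).get(sector, 0.0) + frac
        )

    aq_map: Dict[str, tuple] = {}
    for _, row in aq.iterrows():
        cid = row["city_id"].strip()
        try:
            aq_map[cid] = (float(row["pm25_ugm3"]), float(row["nox_ugm3"]))
        except ValueError:
            dataset.log(f"aq: dropped row for city '{cid}': bad concentration")

    cities: Dict[str, CityContext] = {}
    for cid, grp in bei.groupby("city_id", sort=False):
        cid = str(cid).strip()
        sector_energy: Dict[str, float] = {}
        try:
            for _, row in grp.iterrows():
                sector = _norm_sector(row["sector"], dataset, f"bei city {cid}")
                sector_energy[sector] = sector_energy.get(sector, 0.0) + float(
                    row["energy_mwh"]
                )
            country = grp.iloc[0]["country"].strip()
            population = float(grp.iloc[0]["population"])
            total_co2 = float(grp.iloc[0]["total_co2_t"])
        except ValueError as exc:
            dataset.log(f"bei: dropped city '{cid}': {exc}")
            continue
        if cid not in sce_maps:
            dataset.log(f"merge: dropped city '{cid}': no SCE record")
            continue
        if cid not in aq_map:
            dataset.log(f"merge: dropped city '{cid}': no AQ record")
            continue
        if country not in health:
            dataset.log(f"merge: dropped city '{cid}': no health record for '{country}'")
            continue
        pm25, nox = aq_map[cid]
        try:
            city = CityContext(
                city_id=cid,
                country_code=country,
                population=population,
                sector_energy=sector_energy,
                total_co2=total_co2,
                sce_pm25=sce_maps[cid].get("PM2.5", {}),
                sce_nox=sce_maps[cid].get("NOx", {}),
                pm25_level=pm25,
                nox_level=nox,
            )
        except ValidationError as exc:
            dataset.log(f"merge: dropped city '{cid}': validation failed: {exc}")
            continue
        cities[cid] = city
    return cities


def read_tables(
    measures_path: str,
    bei_path: str,
    sce_path: str,
    aq_path: str,
    hi_path: str,
    sce_percent: bool = False,
) -> AnalysisDataset:
    """Read and merge the five tables into a validated :class:`AnalysisDataset`.

    Rows failing type/range validation are dropped with a provenance entry;
    measures whose city lacks a BEI/SCE/AQ/health record are dropped as
    "unmatched city". Missing files and missing required columns are fatal.

    Parameters
    ----------
    sce_percent:
        If True, SCE fractions in the file are percentages and are divided
        by 100 on read.
    """
    dataset = AnalysisDataset()
    dataset.health = _read_health(hi_path, dataset)
    dataset.cities = _read_cities(
        bei_path, sce_path, aq_path, dataset, dataset.health, sce_percent
    )

    mdf = _read_csv(measures_path, MEASURES_COLUMNS)
    n_dropped_invalid = 0
    n_dropped_unmatched = 0
    for _, row in mdf.iterrows():
        cid = row["city_id"].strip()
        try:
            m = Measure(
                measure_id=row["measure_id"].strip(),
                city_id=cid,
                sector=_norm_sector(row["sector"], dataset, f"measure {row['measure_id']}"),
                energy_saved=_opt_float(row["energy_saved_mwh"]),
                renewable_production=_opt_float(row["renewable_mwh"]),
                co2_reduction=_opt_float(row["co2_reduction_t"]),
            )
        except (ValidationError, ValueError) as exc:
            dataset.log(f"measures: dropped row '{row['measure_id']}': {exc}")
            n_dropped_invalid += 1
            continue
        if cid not in dataset.cities:
            dataset.log(f"measures: dropped '{m.measure_id}': unmatched city '{cid}'")
            n_dropped_unmatched += 1
            continue
        dataset.measures.append(m)

    dataset.log(
        f"read_tables: kept {len(dataset.measures)} measures, "
        f"{len(dataset.cities)} cities, {len(dataset.health)} countries; "
        f"dropped {n_dropped_invalid} invalid and {n_dropped_unmatched} unmatched measure rows"
    )
    dataset.check_referential_closure()
    return dataset


def write_dataset(dataset: AnalysisDataset, out_dir: str) -> Set[str]:
    """Write the dataset back to the five CSV files; inverse of
    :func:`read_tables` up to row order. Returns the set of paths written."""
    os.makedirs(out_dir, exist_ok=True)

    def fmt(v: Optional[float]) -> str:
        return "" if v is None else repr(float(v))

    paths = {
        name: os.path.join(out_dir, f"{name}.csv")
        for name in ("measures", "bei", "sce", "aq", "hi")
    }

    rows = [
        {
            "measure_id": m.measure_id,
            "city_id": m.city_id,
            "sector": m.sector,
            "energy_saved_mwh": fmt(m.energy_saved),
            "renewable_mwh": fmt(m.renewable_production),
            "co2_reduction_t": fmt(m.co2_reduction),
        }
        for m in dataset.measures
    ]
    pd.DataFrame(rows, columns=MEASURES_COLUMNS).to_csv(paths["measures"], index=False)

    bei_rows: List[dict] = []
    sce_rows: List[dict] = []
    aq_rows: List[dict] = []
    for c in dataset.cities.values():
        for sector, energy in c.sector_energy.items():
            bei_rows.append(
                {
                    "city_id": c.city_id,
                    "country": c.country_code,
                    "population": repr(float(c.population)),
                    "sector": sector,
                    "energy_mwh": repr(float(energy)),
                    "total_co2_t": repr(float(c.total_co2)),
                }
            )
        for pol, sce in (("PM2.5", c.sce_pm25), ("NOx", c.sce_nox)):
            for sector, frac in sce.items():
                sce_rows.append(
                    {
                        "city_id": c.city_id,
                        "pollutant": pol,
                        "sector": sector,
                        "fraction": repr(float(frac)),
                    }
                )
        aq_rows.append(
            {
                "city_id": c.city_id,
                "pm25_ugm3": repr(float(c.pm25_level)),
                "nox_ugm3": repr(float(c.nox_level)),
            }
        )
    pd.DataFrame(bei_rows, columns=BEI_COLUMNS).to_csv(paths["bei"], index=False)
    pd.DataFrame(sce_rows, columns=SCE_COLUMNS).to_csv(paths["sce"], index=False)
    pd.DataFrame(aq_rows, columns=AQ_COLUMNS).to_csv(paths["aq"], index=False)

    hi_rows = [
        {
            "country": h.country_code,
            "death_rate": repr(float(h.death_rate)),
            "frac_over_30": repr(float(h.frac_over_30)),
            "yll_per_death": repr(float(h.years_lost_per_death)),
        }
        for h in dataset.health.values()
    ]
    pd.DataFrame(hi_rows, columns=HI_COLUMNS).to_csv(paths["hi"], index=False)
    return set(paths.values())
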