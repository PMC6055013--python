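"""Measure categorisation, the sector-consumption exclusion filter, and
country/sector summary tables.

A measure is ES (energy saving) when it reports positive energy saved and
no renewable production, REP when the reverse, MIX when both, and
UNCLASSIFIED when both are zero or missing.  Only ES measures enter the
air-quality analysis; an ES measure claiming to save more energy than its
city's whole sectoral consumption is physically inconsistent and excluded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Tuple

import pandas as pd

from .datamodel import SECTORS, AnalysisDataset, Category, Measure


def classify_measure(m: Measure) -> Category:
    """Assign the ES/REP/MIX/UNCLASSIFIED category from the two effort fields.

    Zero and missing are treated identically (no effort on that axis).
    """
    es = m.energy_saved is not None and m.energy_saved > 0
    rep = m.renewable_production is not None and m.renewable_production > 0
    if es and rep:
        return Category.MIX
    if es:
        return Category.ES
    if rep:
        return Category.REP
    return Category.UNCLASSIFIED


def classify_dataset(dataset: AnalysisDataset) -> AnalysisDataset:
    """Return a dataset with every measure's ``category`` assigned."""
    measures = [
        m.model_copy(update={"category": classify_measure(m)}) for m in dataset.measures
    ]
    out = dataset.subset(measures)
    counts = category_counts(measures)
    out.log(
        "classify: "
        + ", ".join(f"{c.value}={counts.get(c, 0)}" for c in Category)
    )
    return out


def category_counts(measures: List[Measure]) -> Dict[Category, int]:
    counts: Dict[Category, int] = {c: 0 for c in Category}
    for m in measures:
        counts[m.category] += 1
    return counts


@dataclass
class ClassificationReport:
    """Tally of categories and of ES measures removed by the
    consumption-exceedance rule."""

    counts_by_category: Dict[Category, int] = field(default_factory=dict)
    excluded_count: int = 0  # ES measures with energy_saved > sector consumption
    excluded_no_sector_energy: int = 0  # ES measures whose sector is absent from BEI
    final_es_count: int = 0

    def to_dict(self) -> dict:
        return {
            "counts_by_category": {c.value: n for c, n in self.counts_by_category.items()},
            "excluded_count": self.excluded_count,
            "excluded_no_sector_energy": self.excluded_no_sector_energy,
            "final_es_count": self.final_es_count,
        }


def filter_es(dataset: AnalysisDataset) -> Tuple[AnalysisDataset, ClassificationReport]:
    """Keep only ES measures consistent with their city's sectoral energy.

    An ES measure is excluded when its declared energy saving is strictly
    larger than the whole consumption of the target sector (equality is
    kept).  Measures whose sector is absent from the city's inventory are
    excluded too, logged distinctly.
    """
    report = ClassificationReport(counts_by_category=category_counts(dataset.measures))
    kept: List[Measure] = []
    out_log: List[str] = []
    for m in dataset.measures:
        if m.category is not Category.ES:
            continue
        city = dataset.cities[m.city_id]
        if m.sector not in city.sector_energy:
            report.excluded_no_sector_energy += 1
            out_log.append(
                f"filter_es: excluded '{m.measure_id}': sector '{m.sector}' "
                f"absent from city '{m.city_id}' inventory"
            )
            continue
        if m.energy_saved is not None and m.energy_saved > city.sector_energy[m.sector]:
            report.excluded_count += 1
            out_log.append(
                f"filter_es: excluded '{m.measure_id}': energy saved "
                f"{m.energy_saved} > sector consumption {city.sector_energy[m.sector]}"
            )
            continue
        kept.append(m)
    report.final_es_count = len(kept)
    filtered = dataset.subset(kept)
    for line in out_log:
        filtered.log(line)
    filtered.log(
        f"filter_es: kept {report.final_es_count} ES measures; excluded "
        f"{report.excluded_count} by consumption exceedance, "
        f"{report.excluded_no_sector_energy} with no sector inventory"
    )
    return filtered, report


def summarize_by_country(dataset: AnalysisDataset) -> pd.DataFrame:
    """Per-country totals of signatories, population, ES measures, energy
    saved (TWh/y) and CO2 avoided (Mt/y), plus a final 'Total' row equal to
    the column sums.

    Expects a dataset already filtered to ES measures.
    """
    rows: Dict[str, dict] = {}
    for c in dataset.cities.values():
        r = rows.setdefault(
            c.country_code,
            {
                "country": c.country_code,
                "n_signatories": 0,
                "population": 0.0,
                "n_es_measures": 0,
                "energy_saved_twh": 0.0,
                "co2_reduction_mt": 0.0,
            },
        )
        r["n_signatories"] += 1
        r["population"] += c.population
    for m in dataset.measures:
        r = rows[dataset.cities[m.city_id].country_code]
        r["n_es_measures"] += 1
        r["energy_saved_twh"] += (m.energy_saved or 0.0) * 1e-6
        r["co2_reduction_mt"] += (m.co2_reduction or 0.0) * 1e-6
    table = pd.DataFrame(
        sorted(rows.values(), key=lambda r: r["country"]),
        columns=[
            "country",
            "n_signatories",
            "population",
            "n_es_measures",
            "energy_saved_twh",
            "co2_reduction_mt",
        ],
    )
    total = {
        "country": "Total",
        "n_signatories": int(table["n_signatories"].sum()) if len(table) else 0,
        "population": float(table["population"].sum()) if len(table) else 0.0,
        "n_es_measures": int(table["n_es_measures"].sum()) if len(table) else 0,
        "energy_saved_twh": float(table["energy_saved_twh"].sum()) if len(table) else 0.0,
        "co2_reduction_mt": float(table["co2_reduction_mt"].sum()) if len(table) else 0.0,
    }
    if len(table) == 0:
        return pd.DataFrame([total])
    return pd.concat([table, pd.DataFrame([total])], ignore_index=True)


def integer_percent_shares(values: List[float]) -> List[int]:
    """Render fractional shares as integer percentages summing to 100.

    Uses largest-remainder apportionment: floor each percentage, then hand
    the leftover points to the largest fractional remainders.  This is how
    published pie-chart labels are normally rounded and it keeps the total
    at exactly 100 (plain nearest-integer rounding does not: e.g. shares of
    53.91/24.98/18.60/2.51 would print as 54/25/19/3 = 101).
    """
    total = sum(values)
    if total <= 0:
        return [0 for _ in values]
    pct = [100.0 * v / total for v in values]
    base = [int(math.floor(p)) for p in pct]
    leftover = 100 - sum(base)
    order = sorted(range(len(pct)), key=lambda i: pct[i] - base[i], reverse=True)
    for i in order[:leftover]:
        base[i] += 1
    return base


def summarize_by_sector(dataset: AnalysisDataset) -> pd.DataFrame:
    """Per-sector measure counts, energy saved, and their shares.

    Shares sum to 1 (within 1e-12); the integer-percent rendering uses
    largest-remainder apportionment so the printed percentages total 100.
    Works on either the full cleaned set or the post-filter ES set,
    whichever the caller passes.
    """
    counts = {s: 0 for s in SECTORS}
    energy = {s: 0.0 for s in SECTORS}
    for m in dataset.measures:
        counts[m.sector] += 1
        energy[m.sector] += m.energy_saved or 0.0
    n = sum(counts.values())
    e = sum(energy.values())
    pct_n = integer_percent_shares([counts[s] for s in SECTORS])
    pct_e = integer_percent_shares([energy[s] for s in SECTORS])
    rows = []
    for i, s in enumerate(SECTORS):
        rows.append(
            {
                "sector": s,
                "n_measures": counts[s],
                "share_of_count": counts[s] / n if n else 0.0,
                "share_of_count_pct": pct_n[i],
                "energy_saved_mwh": energy[s],
                "share_of_energy": energy[s] / e if e else 0.0,
                "share_of_energy_pct": pct_e[i],
            }
        )
    return pd.DataFrame(rows)
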