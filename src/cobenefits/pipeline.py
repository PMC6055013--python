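"""End-to-end orchestration: read or simulate the inputs, classify and
filter measures, compute indicators, run the statistical analyses, and
bundle every table for reporting.

The pipeline is deterministic given its configuration (and seed, in
simulate mode): re-running with identical inputs reproduces every output
file byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import classification, indicators, io, stats, synthetic
from .datamodel import AnalysisDataset

logger = logging.getLogger(__name__)


class PipelineConfig(BaseModel):
    """Configuration of a full analysis run.

    Either the five ``*_path`` fields point at input tables, or
    ``simulate`` carries generator parameters; exactly one mode applies.
    """

    measures_path: Optional[str] = None
    bei_path: Optional[str] = None
    sce_path: Optional[str] = None
    aq_path: Optional[str] = None
    hi_path: Optional[str] = None
    sce_percent: bool = False
    simulate: Optional[synthetic.GeneratorParams] = None

    rr_per_10_low: float = indicators.RR_PER_10_LOW
    rr_per_10_central: float = indicators.RR_PER_10_CENTRAL
    rr_per_10_high: float = indicators.RR_PER_10_HIGH
    conf_level: float = 0.95
    size_threshold: float = 200_000.0
    min_r2_report: float = 0.4
    anova_log_transform: bool = True
    eq3_interpretation: indicators.Eq3Form = "literal"
    se_method: stats.SeMethod = "classical"
    out_dir: Optional[str] = None
    seed: int = 0

    def risk_params(self) -> indicators.RiskParams:
        return indicators.RiskParams(
            rr_per_10_low=self.rr_per_10_low,
            rr_per_10_central=self.rr_per_10_central,
            rr_per_10_high=self.rr_per_10_high,
        )


def _fit_to_row(label: str, res: stats.FitResult) -> dict:
    return {
        "group": label,
        "alpha": res.alpha,
        "ci_low": res.alpha_ci[0],
        "ci_high": res.alpha_ci[1],
        "r_squared": res.r_squared,
        "n": res.n,
        "conf_level": res.conf_level,
        "degenerate": res.degenerate,
        "flagged_low_r2": res.flagged_low_r2,
    }


def fits_to_frame(fits: Dict[str, stats.FitResult]) -> pd.DataFrame:
    return pd.DataFrame([_fit_to_row(k, v) for k, v in fits.items()])


@dataclass
class ReportBundle:
    """Every table the analysis produces, ready to be written out."""

    classification_report: classification.ClassificationReport
    country_summary: pd.DataFrame
    sector_summary_all: pd.DataFrame  # over the cleaned, pre-filter set
    sector_summary_es: pd.DataFrame  # over the post-filter ES set
    indicator_table: pd.DataFrame
    fit_tables: Dict[str, pd.DataFrame] = field(default_factory=dict)
    anova_tables: Dict[str, stats.AnovaResult] = field(default_factory=dict)
    health_totals: pd.DataFrame = field(default_factory=pd.DataFrame)
    per_capita_by_size: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    provenance: list = field(default_factory=list)

    def write(self, out_dir: str) -> None:
        os.makedirs(out_dir, exist_ok=True)
        with open(os.path.join(out_dir, "classification_report.json"), "w") as fh:
            json.dump(self.classification_report.to_dict(), fh, indent=2, sort_keys=True)
        self.country_summary.to_csv(os.path.join(out_dir, "country_summary.csv"), index=False)
        self.sector_summary_all.to_csv(
            os.path.join(out_dir, "sector_summary_all.csv"), index=False
        )
        self.sector_summary_es.to_csv(
            os.path.join(out_dir, "sector_summary_es.csv"), index=False
        )
        self.indicator_table.to_csv(os.path.join(out_dir, "indicators.csv"), index=False)
        for name, table in self.fit_tables.items():
            table.to_csv(os.path.join(out_dir, f"fit_{name}.csv"), index=False)
        anova = {
            name: dataclasses.asdict(res) for name, res in self.anova_tables.items()
        }
        with open(os.path.join(out_dir, "anova.json"), "w") as fh:
            json.dump(anova, fh, indent=2, sort_keys=True)
        self.health_totals.to_csv(os.path.join(out_dir, "health_totals.csv"), index=False)
        with open(os.path.join(out_dir, "per_capita_by_size.json"), "w") as fh:
            json.dump(
                {k: list(v) for k, v in self.per_capita_by_size.items()},
                fh, indent=2, sort_keys=True,
            )
        with open(os.path.join(out_dir, "provenance.log"), "w") as fh:
            fh.write("\n".join(self.provenance) + "\n")
        with open(os.path.join(out_dir, "summary.txt"), "w") as fh:
            fh.write(self.render_summary())

    def render_summary(self) -> str:
        rep = self.classification_report
        lines = ["Co-benefits analysis summary", "=" * 28, ""]
        lines.append("Measure categories: " + ", ".join(
            f"{c.value}={n}" for c, n in rep.counts_by_category.items()
        ))
        lines.append(
            f"ES measures excluded (saving > sector consumption): {rep.excluded_count}"
        )
        lines.append(f"Final ES sample: {rep.final_es_count}")
        lines.append("")
        total = self.health_totals[self.health_totals["group"] == "all"].iloc[0]
        lines.append(
            "Avoided premature deaths (low/central/high): "
            f"{total.pd_low:.1f} / {total.pd_central:.1f} / {total.pd_high:.1f}"
        )
        lines.append(
            "Years of life saved (low/central/high): "
            f"{total.yls_low:.1f} / {total.yls_central:.1f} / {total.yls_high:.1f}"
        )
        lines.append("")
        for name, table in self.fit_tables.items():
            lines.append(f"Fit table {name}:")
            lines.append(table.to_string(index=False))
            lines.append("")
        return "\n".join(lines)


def load_inputs(config: PipelineConfig) -> AnalysisDataset:
    """Dataset from files or from the synthetic generator, per config."""
    if config.simulate is not None:
        params = config.simulate.model_copy(update={"seed": config.seed})
        dataset, _ = synthetic.generate(params)
        return dataset
    paths = (
        config.measures_path,
        config.bei_path,
        config.sce_path,
        config.aq_path,
        config.hi_path,
    )
    if any(p is None for p in paths):
        raise ValueError(
            "config must give either simulate parameters or all five input paths"
        )
    return io.read_tables(*paths, sce_percent=config.sce_percent)


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute every stage and return the full report bundle.

    Any stage failure raises with the stage name prefixed.
    """

    def stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"pipeline stage '{name}' failed: {exc}") from exc

    dataset = stage("load", load_inputs, config)
    classified = stage("classify", classification.classify_dataset, dataset)
    filtered, report = stage("filter", classification.filter_es, classified)

    country_summary = stage("summaries", classification.summarize_by_country, filtered)
    sector_all = classification.summarize_by_sector(classified)
    sector_es = classification.summarize_by_sector(filtered)

    table = stage(
        "indicators",
        indicators.indicator_table,
        filtered,
        config.risk_params(),
        config.eq3_interpretation,
    )

    # CO2-reduction vs energy-saved fits (emission-factor recovery).
    es_frame = pd.DataFrame(
        {
            "sector": [m.sector for m in filtered.measures],
            "city_id": [m.city_id for m in filtered.measures],
            "energy_saved": [m.energy_saved or 0.0 for m in filtered.measures],
            "co2_reduction": [m.co2_reduction or 0.0 for m in filtered.measures],
        }
    )
    fit_tables: Dict[str, pd.DataFrame] = {}
    anovas: Dict[str, stats.AnovaResult] = {}
    cluster = "city_id" if config.se_method == "cluster" else None
    if len(es_frame) >= 2:
        fit_tables["co2_vs_energy"] = fits_to_frame(
            stats.sectorwise_fits(
                es_frame, "energy_saved", "co2_reduction",
                min_r2=config.min_r2_report, conf_level=config.conf_level,
                se_method=config.se_method, cluster_col=cluster,
            )
        )
    for pol, ycol in (("pm25", "aqb_pm25"), ("nox", "aqb_nox")):
        if len(table) >= 2:
            fit_tables[f"aqb_{pol}_vs_ccb"] = fits_to_frame(
                stats.sectorwise_fits(
                    table, "ccb", ycol,
                    min_r2=config.min_r2_report, conf_level=config.conf_level,
                    se_method=config.se_method, cluster_col=cluster,
                )
            )

    # City-size segmentation: per-capita CO2 contrast and size-split fits.
    size_spec = stats.SegmentSpec(
        variable="population", rule=config.size_threshold, labels=("large", "small")
    )
    by_size = stage("segment", stats.segment, filtered, size_spec)
    per_capita = stats.per_capita_summary(by_size)
    id_groups = {
        label: {m.measure_id for m in ds.measures} for label, ds in by_size.items()
    }
    for label, ids in id_groups.items():
        sub = table[table["measure_id"].isin(ids)]
        if len(sub) >= 2:
            fit_tables[f"aqb_pm25_vs_ccb_{label}"] = fits_to_frame(
                stats.sectorwise_fits(
                    sub, "ccb", "aqb_pm25",
                    min_r2=config.min_r2_report, conf_level=config.conf_level,
                    se_method=config.se_method, cluster_col=cluster,
                )
            )

    # Health-impact fits (per-inhabitant PD and YLS vs CCB, pooled only).
    if len(table) >= 2:
        fit_tables["pd_vs_ccb"] = fits_to_frame(
            {
                "all": stats.fit_through_origin(
                    table["ccb"], table["pd_pc_central"],
                    conf_level=config.conf_level, se_method=config.se_method,
                    groups=table["city_id"] if cluster else None,
                )
            }
        )
        fit_tables["yls_vs_ccb"] = fits_to_frame(
            {
                "all": stats.fit_through_origin(
                    table["ccb"], table["yls_pc_central"],
                    conf_level=config.conf_level, se_method=config.se_method,
                    groups=table["city_id"] if cluster else None,
                )
            }
        )

    # ANOVA across sectors: CO2 reductions (optionally log10) and AQB values.
    co2_groups: Dict[str, list] = {}
    for m in filtered.measures:
        v = m.co2_reduction or 0.0
        if config.anova_log_transform:
            if v > 0:
                co2_groups.setdefault(m.sector, []).append(np.log10(v))
        else:
            co2_groups.setdefault(m.sector, []).append(v)
    try:
        anovas["co2_by_sector"] = stats.one_way_anova(co2_groups)
    except ValueError as exc:
        logger.warning("co2_by_sector ANOVA skipped: %s", exc)
    for ycol in ("aqb_pm25", "aqb_nox"):
        groups = {
            s: table.loc[table["sector"] == s, ycol].to_numpy()
            for s in table["sector"].unique()
        }
        try:
            anovas[f"{ycol}_by_sector"] = stats.one_way_anova(groups)
        except ValueError as exc:
            logger.warning("%s ANOVA skipped: %s", ycol, exc)

    # Pollution-median segmentation: do high- and low-pollution cities get
    # different benefits per measure?
    for var, tag in (("pm25_level", "pm25"), ("nox_level", "nox")):
        spec = stats.SegmentSpec(variable=var, rule="median", labels=("high", "low"))
        parts = stats.segment(filtered, spec)
        for ycol in ("ccb", f"aqb_{tag}"):
            groups = {}
            for label, ds in parts.items():
                ids = {m.measure_id for m in ds.measures}
                groups[label] = table.loc[table["measure_id"].isin(ids), ycol].to_numpy()
            try:
                anovas[f"{ycol}_by_{tag}_median"] = stats.one_way_anova(groups)
            except ValueError as exc:
                logger.warning("%s median ANOVA skipped: %s", ycol, exc)

    health_totals = stage("health", stats.aggregate_health, table, "sector")

    bundle = ReportBundle(
        classification_report=report,
        country_summary=country_summary,
        sector_summary_all=sector_all,
        sector_summary_es=sector_es,
        indicator_table=table,
        fit_tables=fit_tables,
        anova_tables=anovas,
        health_totals=health_totals,
        per_capita_by_size=per_capita,
        provenance=list(filtered.provenance),
    )
    if config.out_dir:
        stage("write", bundle.write, config.out_dir)
    return bundle
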